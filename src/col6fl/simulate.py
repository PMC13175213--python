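"""Procedural synthesis of multi-site collagen-VI-like fluorescence images.

Each image is a field of curvilinear fibrils with class-dependent density,
orientation coherence, beading and fragmentation, plus punctate deposits,
rendered into the green channel of an RGB frame and passed through a
site-specific acquisition model (background, optical blur, detector gain,
read noise).  Patients are synthetic: each patient belongs to one site and
one class and contributes several images, which is what makes patient-level
splitting meaningful.

The randomness contract is a single root seed; every image's stream is
derived from ``SeedSequence(root, spawn_key=(site_index, image_index))`` so
generation is order-independent and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import vonmises as _vonmises

from .phenotypes import PathogenicClass, TextureParams, sample_texture_params
from .scenario import SiteProfile, Scenario, default_scenario

__all__ = [
    "LabeledImage",
    "FederatedDataset",
    "render_image",
    "generate_federated_dataset",
    "split_patient_level",
]

MIN_RENDER_SIZE = 32

#: relative bleed-through of the fluorophore into the red/blue channels
_CHANNEL_MIX = (0.12, 1.0, 0.08)


@dataclass
class LabeledImage:
    """One image with its class label and provenance (patient, site).

    ``pixels`` is an H x W x 3 float array in [0, 1].  ``partition`` is set
    by :func:`split_patient_level` to "train" or "test" and guards against
    augmenting evaluation data.
    """

    pixels: np.ndarray
    label: PathogenicClass
    patient_id: str
    site_id: str
    partition: str | None = None

    def __post_init__(self) -> None:
        # float32 storage: a full two-site dataset stays ~1 GB instead of 2+
        px = np.asarray(self.pixels)
        if px.dtype != np.float32:
            px = px.astype(np.float32)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if not self.patient_id or not self.site_id:
            raise ValueError("patient_id and site_id must be non-empty")
        if not isinstance(self.label, PathogenicClass):
            raise ValueError(f"label must be a PathogenicClass, got {self.label!r}")
        self.pixels = px


@dataclass
class FederatedDataset:
    """Per-site image collections plus the patient manifest."""

    sites: dict[str, list[LabeledImage]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, tuple[str, PathogenicClass]] = {}
        for sid, images in self.sites.items():
            for im in images:
                if im.site_id != sid:
                    raise ValueError(
                        f"image of patient {im.patient_id} has site_id {im.site_id} "
                        f"but is filed under {sid}"
                    )
                key = im.patient_id
                val = (im.site_id, im.label)
                if seen.setdefault(key, val) != val:
                    raise ValueError(
                        f"patient {key} appears with conflicting site/class"
                    )

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites)

    @property
    def total_images(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def images(self, site_id: str | None = None) -> list[LabeledImage]:
        if site_id is not None:
            return list(self.sites[site_id])
        return [im for v in self.sites.values() for im in v]

    def class_counts(self, site_id: str) -> dict[PathogenicClass, int]:
        counts = {c: 0 for c in PathogenicClass}
        for im in self.sites[site_id]:
            counts[im.label] += 1
        return counts

    def patients(self, site_id: str | None = None) -> set[str]:
        return {im.patient_id for im in self.images(site_id)}

    def manifest(self) -> pd.DataFrame:
        """One row per image: patient_id, site_id, class_label."""
        rows = [
            {"patient_id": im.patient_id, "site_id": im.site_id,
             "class_label": im.label.label}
            for sid in self.sites
            for im in self.sites[sid]
        ]
        return pd.DataFrame(rows, columns=["patient_id", "site_id", "class_label"])


# ---------------------------------------------------------------------------
# rendering


def _derive_rng(root_seed, *key: int) -> np.random.Generator:
    """Counter-scheme stream derivation: one root seed, integer spawn key."""
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=key))


def _coherence_to_kappa(r: float) -> float:
    """Invert the von Mises mean resultant length R(kappa) ~ r (Fisher)."""
    r = min(max(r, 0.0), 0.999)
    if r < 1e-6:
        return 0.0
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def _stamp_spots(canvas: np.ndarray, ys, xs, amps, kernel: np.ndarray) -> None:
    kh, kw = kernel.shape
    ry, rx = kh // 2, kw // 2
    H, W = canvas.shape
    for y, x, a in zip(ys, xs, amps):
        y0, y1 = max(0, y - ry), min(H, y + ry + 1)
        x0, x1 = max(0, x - rx), min(W, x + rx + 1)
        canvas[y0:y1, x0:x1] += a * kernel[
            ry - (y - y0): ry + (y1 - y), rx - (x - x0): rx + (x1 - x)
        ]


def render_image(params: TextureParams, site: SiteProfile, rng_seed) -> np.ndarray:
    """Render one matrix texture under a site's acquisition physics.

    The texture stage draws Poisson-many fibrils (curved random walks with
    von Mises axial orientations, sinusoidal bead modulation and random
    fragmentation gaps) plus Poisson-many puncta.  The acquisition stage
    then applies, in order: background addition, Gaussian blur, gain
    multiplication, additive Gaussian noise, and clipping to [0, 1].

    Returns the H x W x 3 pixel array (signal predominantly green).
    """
    H, W = site.native_size
    if H < MIN_RENDER_SIZE or W < MIN_RENDER_SIZE:
        raise ValueError(
            f"native_size {site.native_size} too small; textures are undefined "
            f"below {MIN_RENDER_SIZE}x{MIN_RENDER_SIZE}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    area_units = H * W / 1e4
    canvas = np.zeros((H, W), dtype=float)

    # ------- fibrils (all filaments sampled and deposited in one batch)
    n_fil = rng.poisson(params.filament_density * area_units)
    mu = rng.uniform(0.0, np.pi)  # dominant axial orientation of this field
    kappa = _coherence_to_kappa(params.orientation_coherence)
    if n_fil > 0:
        if kappa > 0:
            # axial orientations: von Mises on the doubled angle
            thetas = 0.5 * _vonmises.rvs(
                kappa, loc=2.0 * mu, size=n_fil, random_state=rng
            )
        else:
            thetas = rng.uniform(0.0, np.pi, size=n_fil)
        steps = (rng.uniform(0.15, 0.35, n_fil) * min(H, W)).astype(int)
        nmax = int(steps.max())
        y0 = rng.uniform(0, H, n_fil)
        x0 = rng.uniform(0, W, n_fil)
        # curved random-walk centrelines
        angs = thetas[:, None] + np.cumsum(
            rng.normal(0.0, 0.02, (n_fil, nmax)), axis=1
        )
        ys = y0[:, None] + np.cumsum(np.sin(angs), axis=1)
        xs = x0[:, None] + np.cumsum(np.cos(angs), axis=1)
        t = np.arange(nmax)
        phases = rng.uniform(0, 2 * np.pi, n_fil)
        intensity = 1.0 - params.bead_contrast * 0.5 * (
            1.0
            + np.sin(2 * np.pi * t[None, :] / params.bead_spacing + phases[:, None])
        )
        # fragmentation: up to 3 gaps per broken filament
        fragmented = rng.random(n_fil) < params.fragmentation
        n_gaps = rng.integers(1, 4, n_fil)
        centers = rng.uniform(0, 1, (n_fil, 3)) * steps[:, None]
        widths = rng.uniform(0.06, 0.22, (n_fil, 3)) * steps[:, None]
        keep = t[None, :] < steps[:, None]
        for g in range(3):
            active = fragmented & (g < n_gaps)
            gap = (t[None, :] > (centers[:, g] - widths[:, g] / 2)[:, None]) & (
                t[None, :] < (centers[:, g] + widths[:, g] / 2)[:, None]
            )
            keep &= ~(active[:, None] & gap)
        keep &= (ys >= 0) & (ys < H) & (xs >= 0) & (xs < W)
        flat = ys[keep].astype(np.intp) * W + xs[keep].astype(np.intp)
        canvas += np.bincount(
            flat, weights=0.9 * intensity[keep], minlength=H * W
        ).reshape(H, W)

    # ------- puncta
    n_punc = rng.poisson(params.puncta_rate * area_units)
    if n_punc > 0:
        r = 4
        yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
        kernel = np.exp(-(yy**2 + xx**2) / (2 * 1.2**2))
        _stamp_spots(
            canvas,
            rng.integers(0, H, n_punc),
            rng.integers(0, W, n_punc),
            rng.uniform(0.5, 1.1, n_punc),
            kernel,
        )

    # ------- acquisition physics (fixed order: background, blur, gain,
    # noise, clip).  The channel mix is a scalar multiple of one 2-D signal
    # and the background is achromatic (blur maps constants to themselves),
    # so the renderer's 0.7 px anti-alias blur and the site blur compose
    # into a single 2-D Gaussian pass.
    sigma_eff = float(np.hypot(0.7, site.blur_sigma))
    canvas = gaussian_filter(canvas, sigma_eff, truncate=3.0)
    gain = site.brightness_gain
    img = canvas[:, :, None] * (gain * np.asarray(_CHANNEL_MIX))[None, None, :]
    img += gain * site.background_level
    if site.noise_sd > 0:
        img += rng.normal(0.0, site.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0, out=img)


# ---------------------------------------------------------------------------
# dataset generation


def _patient_image_counts(
    n_images: int, n_patients: int, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-patient image counts ~ U{lo..hi}, then adjust to the exact
    class total: surplus goes to the last patient, deficits are absorbed
    walking back from the last patient with every count kept >= 1."""
    sizes = rng.integers(lo, hi + 1, size=n_patients).astype(int)
    diff = n_images - int(sizes.sum())
    if diff > 0:
        sizes[-1] += diff
    else:
        j = n_patients - 1
        while diff < 0:
            take = min(sizes[j] - 1, -diff)
            sizes[j] -= take
            diff += take
            j -= 1
            if j < 0 and diff < 0:
                raise ValueError(
                    "cannot distribute images: fewer images than patients"
                )
    return sizes


def generate_federated_dataset(
    profiles: Iterable[SiteProfile] | Scenario | None = None,
    rng_seed: int = 0,
    texture_bounds=None,
) -> FederatedDataset:
    """Generate the full multi-site labeled dataset.

    Every patient is assigned one site and one class; image counts per
    patient follow the site's ``images_per_patient`` policy adjusted so the
    per-site per-class totals match the profile exactly.  Passing a
    :class:`Scenario` (or nothing, for the packaged default) supplies both
    the profiles and the texture bounds.
    """
    if profiles is None:
        profiles = default_scenario()
    if isinstance(profiles, Scenario):
        if texture_bounds is None:
            texture_bounds = profiles.texture_bounds
        profiles = profiles.sites
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one SiteProfile is required")
    if texture_bounds is None:
        texture_bounds = default_scenario().texture_bounds

    sites: dict[str, list[LabeledImage]] = {}
    for s_idx, site in enumerate(profiles):
        images: list[LabeledImage] = []
        img_counter = 0
        for cls in PathogenicClass:
            n_img = site.class_counts.get(cls, 0)
            if n_img == 0:
                continue
            n_pat = site.patients_per_class.get(cls, 0)
            if n_pat > n_img:
                raise ValueError(
                    f"site {site.site_id}, class {cls.label}: patients_per_class "
                    f"({n_pat}) exceeds class image count ({n_img})"
                )
            lo, hi = site.images_per_patient
            rng_pat = _derive_rng(rng_seed, s_idx, cls.index, 0)
            sizes = _patient_image_counts(n_img, n_pat, lo, hi, rng_pat)
            for p_idx, size in enumerate(sizes):
                pid = f"{site.site_id}-{cls.label}-p{p_idx:02d}"
                for _ in range(size):
                    stream = np.random.SeedSequence(
                        rng_seed, spawn_key=(s_idx, 1 + img_counter)
                    )
                    rng_img = np.random.default_rng(stream)
                    params = sample_texture_params(cls, rng_img, texture_bounds)
                    pixels = render_image(params, site, rng_img)
                    images.append(
                        LabeledImage(pixels, cls, patient_id=pid, site_id=site.site_id)
                    )
                    img_counter += 1
        sites[site.site_id] = images
    return FederatedDataset(sites)


# ---------------------------------------------------------------------------
# patient-level splitting


def split_patient_level(
    dataset: FederatedDataset,
    test_counts: dict[str, int],
    rng_seed: int = 0,
) -> tuple[FederatedDataset, FederatedDataset]:
    """Split into train/test by whole patients, per site.

    Patients are visited in class-stratified round-robin order (shuffled
    within class) and greedily added to the test set, skipping any patient
    whose images would overshoot the requested count; if no exact fill is
    reachable the smallest-overshoot patient is added instead.  No patient
    contributes to both partitions.
    """
    train_sites: dict[str, list[LabeledImage]] = {}
    test_sites: dict[str, list[LabeledImage]] = {}
    for s_idx, (site_id, images) in enumerate(dataset.sites.items()):
        target = int(test_counts.get(site_id, 0))
        if target < 0:
            raise ValueError(f"negative test count for site {site_id}")
        n_total = len(images)
        if target > n_total:
            raise ValueError(
                f"site {site_id}: requested {target} test images but only "
                f"{n_total} exist"
            )
        by_patient: dict[str, list[LabeledImage]] = {}
        for im in images:
            by_patient.setdefault(im.patient_id, []).append(im)
        by_class: dict[PathogenicClass, list[str]] = {}
        for pid, ims in by_patient.items():
            by_class.setdefault(ims[0].label, []).append(pid)

        rng = _derive_rng(rng_seed, 7, s_idx)
        for cls in by_class:
            pids = sorted(by_class[cls])
            rng.shuffle(pids)
            by_class[cls] = pids
        # round-robin across classes (fixed class order) for stratification
        order: list[str] = []
        queues = [list(by_class.get(cls, [])) for cls in PathogenicClass]
        while any(queues):
            for q in queues:
                if q:
                    order.append(q.pop(0))

        chosen: set[str] = set()
        total = 0
        leftovers: list[str] = []
        for pid in order:
            size = len(by_patient[pid])
            if total + size <= target:
                chosen.add(pid)
                total += size
                if total == target:
                    break
            else:
                leftovers.append(pid)
        if total < target and leftovers:
            # minimal excess: smallest patient among the skipped
            pid = min(leftovers, key=lambda p: len(by_patient[p]))
            chosen.add(pid)
            total += len(by_patient[pid])
        if total < target:
            raise ValueError(
                f"site {site_id}: cannot assemble {target} test images from "
                "whole patients"
            )

        train_sites[site_id] = [
            replace(im, partition="train")
            for im in images
            if im.patient_id not in chosen
        ]
        test_sites[site_id] = [
            replace(im, partition="test")
            for im in images
            if im.patient_id in chosen
        ]
    return FederatedDataset(train_sites), FederatedDataset(test_sites)
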
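"""Benchmark scenario definition: site acquisition profiles and class boxes.

A scenario bundles everything needed to synthesize a multi-site dataset:
per-class texture parameter boxes, one :class:`SiteProfile` per node
(acquisition physics plus per-class patient/image counts), and the per-site
held-out test image counts.  The packaged default reproduces the published
two-site image distribution (300 vs 31 images across four classes, 90
patients) with deliberately different acquisition physics per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .phenotypes import PathogenicClass, TextureParams, TextureBounds

__all__ = ["SiteProfile", "Scenario", "load_scenario", "default_scenario"]

_TEXTURE_FIELDS = [
    "filament_density",
    "orientation_coherence",
    "bead_spacing",
    "bead_contrast",
    "fragmentation",
    "puncta_rate",
]


@dataclass
class SiteProfile:
    """Acquisition physics and cohort composition for one node.

    brightness_gain multiplies the whole image, blur_sigma (px) is the
    optical blur, noise_sd the additive Gaussian read-noise SD, and
    background_level the autofluorescence floor added before blur.
    """

    site_id: str
    brightness_gain: float
    blur_sigma: float
    noise_sd: float
    background_level: float
    native_size: tuple[int, int]
    class_counts: dict[PathogenicClass, int]
    patients_per_class: dict[PathogenicClass, int]
    images_per_patient: tuple[int, int] = (2, 6)

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        if self.brightness_gain <= 0:
            raise ValueError("brightness_gain must be > 0")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")
        if not 0 <= self.background_level < 1:
            raise ValueError("background_level must be in [0, 1)")
        self.native_size = (int(self.native_size[0]), int(self.native_size[1]))
        self.class_counts = {
            PathogenicClass.from_label(k) if isinstance(k, str) else k: int(v)
            for k, v in self.class_counts.items()
        }
        self.patients_per_class = {
            PathogenicClass.from_label(k) if isinstance(k, str) else k: int(v)
            for k, v in self.patients_per_class.items()
        }
        for c, n in self.class_counts.items():
            if n < 0:
                raise ValueError(f"negative image count for {c.label} at {self.site_id}")
            npat = self.patients_per_class.get(c, 0)
            if npat < 0:
                raise ValueError(f"negative patient count for {c.label} at {self.site_id}")
            if npat > n:
                raise ValueError(
                    f"site {self.site_id}, class {c.label}: patients_per_class "
                    f"({npat}) exceeds class image count ({n})"
                )
            if n > 0 and npat == 0:
                raise ValueError(
                    f"site {self.site_id}, class {c.label}: images requested but "
                    "patients_per_class is 0"
                )
        lo, hi = self.images_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("images_per_patient must satisfy 1 <= lo <= hi")

    @property
    def total_images(self) -> int:
        return sum(self.class_counts.values())

    @property
    def total_patients(self) -> int:
        return sum(self.patients_per_class.values())


@dataclass
class Scenario:
    """A complete synthetic-benchmark configuration."""

    texture_bounds: TextureBounds
    sites: list[SiteProfile]
    test_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site_id in scenario")
        for sid in self.test_counts:
            if sid not in ids:
                raise ValueError(f"test_counts references unknown site {sid!r}")

    @property
    def total_images(self) -> int:
        return sum(s.total_images for s in self.sites)

    def site(self, site_id: str) -> SiteProfile:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)


def _bounds_from_dict(d: dict) -> TextureBounds:
    out: TextureBounds = {}
    for label, box in d.items():
        cls = PathogenicClass.from_label(label)
        missing = [f for f in _TEXTURE_FIELDS if f not in box]
        if missing:
            raise ValueError(f"texture bounds for {label} missing fields {missing}")
        out[cls] = {f: (float(box[f][0]), float(box[f][1])) for f in _TEXTURE_FIELDS}
        for f, (lo, hi) in out[cls].items():
            if lo > hi:
                raise ValueError(f"texture bound {label}.{f}: lo > hi")
            # validate the corners against the per-field ranges
            TextureParams(**{g: (lo if g == f else out[cls][g][0]) for g in _TEXTURE_FIELDS})
    return out


def scenario_from_dict(d: dict) -> Scenario:
    sites = [
        SiteProfile(
            site_id=s["site_id"],
            brightness_gain=float(s["brightness_gain"]),
            blur_sigma=float(s["blur_sigma"]),
            noise_sd=float(s["noise_sd"]),
            background_level=float(s["background_level"]),
            native_size=tuple(s["native_size"]),
            class_counts=s["class_counts"],
            patients_per_class=s["patients_per_class"],
            images_per_patient=tuple(s.get("images_per_patient", (2, 6))),
        )
        for s in d["sites"]
    ]
    return Scenario(
        texture_bounds=_bounds_from_dict(d["texture_bounds"]),
        sites=sites,
        test_counts={str(k): int(v) for k, v in d.get("test_counts", {}).items()},
    )


def load_scenario(path: str | Path | None = None) -> Scenario:
    """Load a scenario from a YAML file, or the packaged default if None."""
    if path is None:
        text = resources.files("col6fl.data").joinpath("default_scenario.yaml").read_text()
    else:
        text = Path(path).read_text()
    return scenario_from_dict(yaml.safe_load(text))


def default_scenario() -> Scenario:
    """The packaged two-site benchmark scenario (fresh copy each call)."""
    return load_scenario(None)
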
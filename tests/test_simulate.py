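"""Synthetic image rendering, dataset generation and patient-level splits."""

import numpy as np
import pytest

from col6fl import (
    PathogenicClass,
    SiteProfile,
    generate_federated_dataset,
    render_image,
    split_patient_level,
)
from col6fl.phenotypes import TextureParams


def _site(**over):
    base = dict(
        site_id="S",
        brightness_gain=1.0,
        blur_sigma=1.0,
        noise_sd=0.02,
        background_level=0.1,
        native_size=(96, 96),
        class_counts={c: 2 for c in PathogenicClass},
        patients_per_class={c: 1 for c in PathogenicClass},
    )
    base.update(over)
    return SiteProfile(**base)


def _params(**over):
    base = dict(
        filament_density=4.0,
        orientation_coherence=0.7,
        bead_spacing=10.0,
        bead_contrast=0.4,
        fragmentation=0.2,
        puncta_rate=2.0,
    )
    base.update(over)
    return TextureParams(**base)


class TestRenderImage:
    def test_no_signal_yields_constant_background_times_gain(self):
        p = _params(filament_density=0.0, puncta_rate=0.0)
        site = _site(noise_sd=0.0, background_level=0.1, brightness_gain=1.3)
        img = render_image(p, site, 0)
        assert img.shape == (96, 96, 3)
        assert np.allclose(img, 0.1 * 1.3, atol=1e-12)

    def test_seeded_renders_are_bit_identical(self):
        p = _params()
        a = render_image(p, _site(), 42)
        b = render_image(p, _site(), 42)
        assert np.array_equal(a, b)
        c = render_image(p, _site(), 43)
        assert not np.array_equal(a, c)

    def test_doubling_gain_doubles_every_pixel(self):
        """Per-pixel oracle: in the unclipped noise-free regime the whole
        acquisition is linear in the detector gain."""
        p = _params(puncta_rate=0.5)
        lo = _site(noise_sd=0.0, brightness_gain=0.2)
        hi = _site(noise_sd=0.0, brightness_gain=0.4)
        a = render_image(p, lo, 9)
        b = render_image(p, hi, 9)
        assert a.max() < 0.5  # genuinely unclipped
        assert np.allclose(b / a, 2.0, rtol=0, atol=1e-12)

    def test_pixels_clipped_to_unit_interval_and_green_dominant(self):
        p = _params(filament_density=8.0)
        img = render_image(p, _site(brightness_gain=2.5), 3)
        assert img.min() >= 0.0 and img.max() <= 1.0
        sig = img - img.mean(axis=(0, 1))
        assert sig[..., 1].std() > sig[..., 0].std() > sig[..., 2].std()

    def test_tiny_frames_are_rejected(self):
        with pytest.raises(ValueError, match="32"):
            render_image(_params(), _site(native_size=(16, 16)), 0)


class TestGenerateFederatedDataset:
    def test_default_scenario_reproduces_published_distribution(self, default_dataset):
        ds = default_dataset
        assert len(ds.sites["NIH"]) == 300
        assert len(ds.sites["UCL"]) == 31
        assert ds.total_images == 331
        nih = ds.class_counts("NIH")
        ucl = ds.class_counts("UCL")
        assert nih[PathogenicClass.exon_skipping] == 71
        assert nih[PathogenicClass.control] == 84
        assert nih[PathogenicClass.glycine_substitution] == 94
        assert nih[PathogenicClass.pseudoexon_insertion] == 51
        assert ucl[PathogenicClass.pseudoexon_insertion] == 8
        assert ucl[PathogenicClass.control] == 7
        assert ucl[PathogenicClass.glycine_substitution] == 5
        assert ucl[PathogenicClass.exon_skipping] == 11

    def test_ninety_patients_split_across_disjoint_sites(self, default_dataset):
        nih = default_dataset.patients("NIH")
        ucl = default_dataset.patients("UCL")
        assert len(nih | ucl) == 90
        assert not (nih & ucl)

    def test_every_patient_has_one_site_and_one_class(self, tiny_dataset):
        m = tiny_dataset.manifest()
        per_patient = m.groupby("patient_id")[["site_id", "class_label"]].nunique()
        assert (per_patient == 1).all().all()

    def test_generation_is_bit_reproducible(self, tiny_scenario):
        a = generate_federated_dataset(tiny_scenario, rng_seed=3)
        b = generate_federated_dataset(tiny_scenario, rng_seed=3)
        for sid in a.sites:
            for x, y in zip(a.sites[sid], b.sites[sid]):
                assert np.array_equal(x.pixels, y.pixels)
                assert x.patient_id == y.patient_id

    def test_too_many_patients_for_class_count_rejected(self):
        # the profile itself refuses the inconsistency, before any rendering
        with pytest.raises(ValueError, match="exceeds"):
            _site(
                class_counts={PathogenicClass.control: 2},
                patients_per_class={PathogenicClass.control: 3},
            )


class TestSplitPatientLevel:
    def test_default_holdout_is_exactly_24_images(self, default_dataset):
        train, test = split_patient_level(default_dataset, {"NIH": 20, "UCL": 4}, 0)
        assert test.total_images == 24
        assert len(test.sites["NIH"]) == 20
        assert len(test.sites["UCL"]) == 4
        assert train.total_images == 331 - 24

    def test_no_patient_straddles_the_split(self, tiny_dataset):
        train, test = split_patient_level(tiny_dataset, {"A": 4, "B": 2}, 1)
        assert not (train.patients() & test.patients())
        assert all(im.partition == "train" for im in train.images())
        assert all(im.partition == "test" for im in test.images())

    def test_split_is_deterministic(self, tiny_dataset):
        s1 = split_patient_level(tiny_dataset, {"A": 4, "B": 2}, 5)
        s2 = split_patient_level(tiny_dataset, {"A": 4, "B": 2}, 5)
        assert s1[1].patients() == s2[1].patients()

    def test_unachievable_request_names_the_site(self, tiny_dataset):
        with pytest.raises(ValueError, match="B"):
            split_patient_level(tiny_dataset, {"B": 500}, 0)


def test_site_mean_intensity_shift_is_statistically_real(default_dataset):
    """The two default sites must induce genuine covariate shift: a
    two-sample test on per-image mean intensity rejects equality."""
    from scipy.stats import mannwhitneyu

    nih = [im.pixels.mean() for im in default_dataset.images("NIH")]
    ucl = [im.pixels.mean() for im in default_dataset.images("UCL")]
    assert mannwhitneyu(nih, ucl).pvalue < 1e-6
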
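"""Fluorescence overlay, rolling-ball punctae separation and intensity gating."""

import numpy as np
import pandas as pd
import pytest
import scipy.ndimage as ndi

from mitoqpi.classify import (
    CLASS_CANCER,
    CLASS_MACROPHAGE,
    CLASS_OTHER,
    CLASS_RECIPIENT,
    FluorImage,
    GateParams,
    background_level,
    classify_population,
    extract_punctae,
    per_cell_intensity,
    persistent_punctae,
    punctae_mask,
    resize_to_match,
)
from mitoqpi.errors import InputError, InvalidParameterError
from mitoqpi.qpi import LabelMap, OpticalConstants

OPT = OpticalConstants()


def label_map(shape=(60, 60), boxes=((10, 10, 20, 20),)):
    labels = np.zeros(shape, dtype=int)
    rows = []
    for i, (r0, c0, r1, c1) in enumerate(boxes, start=1):
        labels[r0:r1, c0:c1] = i
        rows.append({"label": i, "area": (r1 - r0) * (c1 - c0),
                     "row": (r0 + r1) / 2, "col": (c0 + c1) / 2, "mass_pg": 0.0})
    return LabelMap(labels, pd.DataFrame(rows))


class TestResize:
    def test_same_shape_identity(self):
        img = FluorImage(np.arange(36.0).reshape(6, 6))
        out = resize_to_match(img, (6, 6))
        np.testing.assert_array_equal(out.values, img.values)

    def test_constant_preserved_on_upsample(self):
        img = FluorImage(np.full((8, 8), 3.5))
        out = resize_to_match(img, (16, 16))
        np.testing.assert_allclose(out.values, 3.5, rtol=1e-12)

    def test_punctae_centroids_survive_round_trip(self):
        """Downsampled 2x then restored: punctae centers move < 1 px."""
        img = np.zeros((64, 64))
        centers = [(16, 16), (40, 48)]
        for r, c in centers:
            img[r - 1 : r + 2, c - 1 : c + 2] = 100.0
        small = resize_to_match(FluorImage(img), (32, 32))
        restored = resize_to_match(small, (64, 64))
        lab, n = ndi.label(restored.values > 20.0)
        assert n == len(centers)
        found = ndi.center_of_mass(restored.values, lab, index=range(1, n + 1))
        for (r, c), (fr, fc) in zip(centers, sorted(found)):
            assert abs(fr - r) < 1.0 and abs(fc - c) < 1.0

    def test_zero_target_rejected(self):
        with pytest.raises(InputError):
            resize_to_match(FluorImage(np.zeros((4, 4))), (0, 4))


class TestPerCellIntensity:
    def test_uniform_region(self):
        lm = label_map()
        img = FluorImage(np.full((60, 60), 7.0))
        assert per_cell_intensity(img, lm).loc[1] == pytest.approx(7.0)

    def test_zero_channel(self):
        lm = label_map()
        out = per_cell_intensity(FluorImage(np.zeros((60, 60))), lm)
        assert (out == 0).all()

    def test_half_bright_half_dark(self):
        lm = label_map(boxes=((10, 10, 20, 20),))
        v = np.zeros((60, 60))
        v[10:20, 10:15] = 10.0  # half the region
        assert per_cell_intensity(FluorImage(v), lm).loc[1] == pytest.approx(5.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            per_cell_intensity(FluorImage(np.zeros((10, 10))), label_map())


class TestExtractPunctae:
    def test_constant_image_gives_no_punctae(self):
        p, bg = extract_punctae(FluorImage(np.full((40, 40), 5.0)), GateParams(), OPT)
        assert np.abs(p.values).max() < 1e-9
        assert not punctae_mask(p).any()

    def test_small_disc_recovered_at_90pct(self):
        """A 1.5-um disc on flat background passes the ball nearly intact."""
        img = np.full((80, 80), 10.0)
        yy, xx = np.mgrid[:80, :80]
        r_px = 1.5 / 2 / OPT.pixel_size
        img[(yy - 40) ** 2 + (xx - 40) ** 2 <= r_px**2] += 100.0
        p, _ = extract_punctae(FluorImage(img), GateParams(), OPT)
        assert p.values.max() >= 0.9 * 100.0

    def test_broad_network_blob_suppressed(self):
        """A 20-um Gaussian blob is absorbed into the rolling-ball background."""
        yy, xx = np.mgrid[:120, :120]
        sigma_px = 20.0 / 2 / OPT.pixel_size
        img = 10.0 + 100.0 * np.exp(-((yy - 60) ** 2 + (xx - 60) ** 2) / (2 * sigma_px**2))
        p, _ = extract_punctae(FluorImage(img), GateParams(), OPT)
        assert p.values.max() < 0.1 * 100.0

    def test_agrees_with_independent_rolling_ball(self):
        """Background matches skimage's rolling-ball implementation."""
        from skimage import restoration

        rng = np.random.default_rng(0)
        img = 10.0 + rng.random((50, 50))
        img[20:22, 20:22] += 50.0
        gates = GateParams(ball_diameter=6.0)
        _, bg = extract_punctae(FluorImage(img), gates, OPT)
        radius_px = gates.ball_diameter / 2 / OPT.pixel_size
        ref = restoration.rolling_ball(img, radius=radius_px)
        np.testing.assert_allclose(bg.values, ref, atol=0.05 * img.max())

    def test_idempotent_on_own_background(self):
        """Re-filtering the extracted background changes it by < 1%."""
        rng = np.random.default_rng(1)
        img = 20.0 + 2.0 * rng.random((60, 60))
        img[30:32, 30:32] += 80.0
        _, bg = extract_punctae(FluorImage(img), GateParams(), OPT)
        p2, bg2 = extract_punctae(bg, GateParams(), OPT)
        assert np.abs(bg2.values - bg.values).max() <= 0.01 * bg.values.max()

    def test_background_never_exceeds_input(self):
        rng = np.random.default_rng(2)
        img = 5.0 + rng.random((40, 40)) * 10.0
        p, bg = extract_punctae(FluorImage(img), GateParams(), OPT)
        assert np.all(bg.values <= img + 1e-9)
        np.testing.assert_allclose(p.values + bg.values, img, atol=1e-9)

    def test_tiny_ball_rejected(self):
        wide_px = OpticalConstants(pixel_area=100.0)  # 10 um pixels
        with pytest.raises(InvalidParameterError):
            extract_punctae(FluorImage(np.zeros((20, 20))), GateParams(), wide_px)


def _classify_one(rfp, donor, punctae, gates=GateParams()):
    intens = pd.DataFrame(
        {"recipient_marker": [rfp], "donor_mito": [donor]}, index=[0]
    )
    flags = pd.Series({0: punctae})
    recs = classify_population(
        intens, flags, {"recipient_marker": 100.0, "donor_mito": 100.0}, gates
    )
    return recs[0].cell_class


class TestClassifyPopulation:
    def test_below_rfp_gate_is_other(self):
        assert _classify_one(140.0, 50.0, False) == CLASS_OTHER

    def test_recipient_requires_gate_and_punctae(self):
        assert _classify_one(160.0, 50.0, True) == CLASS_RECIPIENT
        assert _classify_one(160.0, 50.0, False) == CLASS_CANCER

    def test_donor_gate_makes_macrophage(self):
        assert _classify_one(50.0, 250.0, False) == CLASS_MACROPHAGE

    def test_double_positive_fusion_excluded(self):
        assert _classify_one(160.0, 250.0, True) == CLASS_OTHER

    def test_gate_monotonicity(self):
        """Raising marker intensity never demotes cancer; punctae never demote recipient."""
        base = _classify_one(150.0, 50.0, True)
        assert base == CLASS_RECIPIENT
        for rfp in (200.0, 500.0, 1000.0):
            assert _classify_one(rfp, 50.0, True) == CLASS_RECIPIENT

    def test_missing_channel_rejected(self):
        with pytest.raises(InputError):
            classify_population(
                pd.DataFrame({"recipient_marker": [1.0]}),
                pd.Series({0: False}),
                {"recipient_marker": 1.0, "donor_mito": 1.0},
            )


class TestTrackLevelCalls:
    def test_persistence_needs_consecutive_frames(self):
        assert persistent_punctae([False, True, True, False])
        assert not persistent_punctae([True, False, True, False])
        assert not persistent_punctae([])

    def test_background_level_is_median_outside_cells(self):
        lm = label_map()
        v = np.full((60, 60), 9.0)
        v[lm.values == 1] = 1000.0
        assert background_level(FluorImage(v), lm) == pytest.approx(9.0)
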
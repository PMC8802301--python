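import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydrotherm as ht
from hydrotherm.features import find_extrema

from _oracles import brute_force_extrema


def _profile(x, F, condition=None, baseline=None):
    x = np.asarray(x, dtype=float)
    F = np.asarray(F, dtype=float)
    return ht.PMFProfile(
        bin_centers=x,
        F=F,
        condition=condition or ht.Condition(298.0, 0.0),
        window_shifts=np.zeros(1),
        total_counts=np.where(np.isnan(F), 0, 1000).astype(int),
        converged=True,
        n_iter=1,
        baseline_range=baseline,
    )


def _three_feature_curve(x):
    """Constructed CM (6.2, -1.8), DM (8.0, +0.6), SSM (9.8, -0.4)."""
    return (
        -1.8 * np.exp(-((x - 6.2) ** 2) / (2 * 0.45**2))
        + 0.6 * np.exp(-((x - 8.0) ** 2) / (2 * 0.4**2))
        - 0.4 * np.exp(-((x - 9.8) ** 2) / (2 * 0.45**2))
        + 30.0 * np.exp(-(x - 3.0) / 0.25)
    )


class TestFindExtrema:
    def test_constructed_three_feature_profile(self):
        x = np.arange(4.0, 14.0, 0.1)
        f = find_extrema(_profile(x, _three_feature_curve(x)), smooth_window=1)
        assert f.cm_pos == pytest.approx(6.2, abs=0.051)
        assert f.cm_depth == pytest.approx(-1.8, abs=0.02)
        assert f.has_dm and f.has_ssm
        assert f.dm_pos == pytest.approx(8.0, abs=0.051)
        assert f.dm_height == pytest.approx(0.6, abs=0.02)
        assert f.ssm_pos == pytest.approx(9.8, abs=0.051)
        assert f.ssm_depth == pytest.approx(-0.4, abs=0.02)

    def test_single_minimum_profile_has_no_dm_ssm(self):
        x = np.arange(4.0, 12.0, 0.1)
        F = -1.5 * np.exp(-((x - 5.5) ** 2) / (2 * 0.8**2)) + 20 * np.exp(-(x - 3) / 0.3)
        f = find_extrema(_profile(x, F))
        assert f.cm_pos == pytest.approx(5.5, abs=0.11)
        assert not f.has_dm
        assert not f.has_ssm
        assert f.dm_pos is None and f.ssm_pos is None

    def test_noiseless_model_cm_within_one_bin(self, adamantane_model, cond298):
        x = np.arange(4.0, 16.0, 0.1)
        F = adamantane_model.energy(x, cond298)
        # brute-force grid argmin as the oracle for the CM location
        oracle_pos = x[np.argmin(F)]
        f = find_extrema(_profile(x, F), smooth_window=3)
        assert abs(f.cm_pos - oracle_pos) <= 0.1 + 1e-9
        assert abs(f.cm_pos - adamantane_model.cm_pos) <= 0.1 + 1e-9

    def test_flat_profile_raises_no_contact_minimum(self):
        x = np.arange(4.0, 10.0, 0.1)
        with pytest.raises(ValueError, match="no contact minimum"):
            find_extrema(_profile(x, np.zeros_like(x)))

    def test_too_few_bins_rejected(self):
        x = np.array([4.0, 4.1, 4.2, 4.3])
        with pytest.raises(ValueError, match="5 defined bins"):
            find_extrema(_profile(x, np.zeros_like(x)))

    def test_depths_read_from_unsmoothed_profile(self):
        """Smoothing locates extrema but must not alter reported values."""
        x = np.arange(4.0, 14.0, 0.1)
        F = _three_feature_curve(x)
        f = find_extrema(_profile(x, F), smooth_window=5)
        i_cm = int(np.argmin(np.abs(x - f.cm_pos)))
        assert f.cm_depth == F[i_cm]

    def test_baseline_region_excluded_from_search(self):
        """Wiggles inside the declared flat tail are not promoted to features."""
        x = np.arange(4.0, 16.0, 0.1)
        F = -1.5 * np.exp(-((x - 5.5) ** 2) / (2 * 0.8**2)) + 20 * np.exp(-(x - 3) / 0.3)
        F = F + np.where(x > 13.0, 0.3 * np.sin(8 * x), 0.0)  # tail artifact
        f = find_extrema(_profile(x, F, baseline=(12.0, 13.5)))
        assert not f.has_dm and not f.has_ssm


class TestInvariants:
    @given(shift=st.floats(-5.0, 5.0))
    @settings(deadline=None, max_examples=25)
    def test_translation_moves_depths_not_positions(self, shift):
        x = np.arange(4.0, 14.0, 0.1)
        F = _three_feature_curve(x)
        f0 = find_extrema(_profile(x, F))
        f1 = find_extrema(_profile(x, F + shift))
        assert f1.cm_pos == f0.cm_pos
        assert f1.dm_pos == f0.dm_pos
        assert f1.ssm_pos == f0.ssm_pos
        assert f1.cm_depth - f0.cm_depth == pytest.approx(shift, abs=1e-9)

    def test_refinement_stability_on_noiseless_profile(self, adamantane_model, cond298):
        coarse_x = np.arange(4.0, 16.0, 0.1)
        fine_x = np.arange(4.0, 16.0, 0.05)
        f_coarse = find_extrema(_profile(coarse_x, adamantane_model.energy(coarse_x, cond298)))
        f_fine = find_extrema(_profile(fine_x, adamantane_model.energy(fine_x, cond298)))
        assert abs(f_coarse.cm_pos - f_fine.cm_pos) <= 0.1 + 1e-9
        assert abs(f_coarse.dm_pos - f_fine.dm_pos) <= 0.1 + 1e-9

    def test_zero_prominence_no_smoothing_matches_brute_scan(self):
        rng = np.random.default_rng(11)
        x = np.arange(4.0, 8.0, 0.1)
        # smooth random profile with a guaranteed interior minimum
        F = np.cumsum(rng.normal(0, 0.05, len(x))) + 0.3 * (x - 6.0) ** 2
        f = find_extrema(_profile(x, F), smooth_window=1, min_prominence=0.0)
        minima, _ = brute_force_extrema(F)
        assert int(round((f.cm_pos - 4.0) / 0.1)) in minima
        assert F[minima].min() == f.cm_depth
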
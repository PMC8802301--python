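import numpy as np
import pytest

import hydrotherm as ht
from hydrotherm.constants import KB_KCAL, kt
from hydrotherm.wham import HistogramSet, build_histograms, wham_solve

from _oracles import brute_force_wham


def _series(xi, window, condition, seed=0):
    xi = np.asarray(xi, dtype=float)
    return ht.ReactionCoordinateSeries(
        window=window,
        condition=condition,
        times=0.2 * (1 + np.arange(len(xi))),
        xi=xi,
        seed=seed,
    )


class TestBuildHistograms:
    def test_direct_binning(self, cond298):
        w = ht.WindowSpec(4.0, 2.0)
        s = _series([4.05, 4.24, 4.26], w, cond298)
        h = build_histograms([s], bin_width=0.2, hist_range=(4.0, 4.4))
        assert np.array_equal(h.counts[0], [1, 2])

    def test_interior_edge_sample_goes_right(self, cond298):
        w = ht.WindowSpec(4.0, 2.0)
        s = _series([4.2], w, cond298)
        h = build_histograms([s], bin_width=0.2, hist_range=(4.0, 4.4))
        assert np.array_equal(h.counts[0], [0, 1])

    def test_retained_plus_dropped_conserved(self, cond298):
        rng = np.random.default_rng(0)
        w = ht.WindowSpec(6.0, 2.0)
        s = _series(rng.uniform(2.0, 20.0, size=500), w, cond298)
        h = build_histograms([s], bin_width=0.1, hist_range=(5.0, 7.0))
        assert h.counts[0].sum() + h.n_dropped[0] == 500

    def test_mixed_conditions_rejected(self):
        w = ht.WindowSpec(6.0, 2.0)
        s1 = _series([6.0], w, ht.Condition(298.0, 0.0))
        s2 = _series([6.0], w, ht.Condition(310.0, 0.0))
        with pytest.raises(ValueError, match="mixed conditions"):
            build_histograms([s1, s2])

    def test_empty_series_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_histograms([])


class TestWhamSolve:
    def test_zero_bias_single_window_is_boltzmann_inversion(self, cond298):
        """With no bias, WHAM must reduce to F = -kT ln(n_j/N) + const."""
        rng = np.random.default_rng(42)
        w = ht.WindowSpec(d0=6.0, k=0.0)
        xi = rng.normal(6.0, 0.5, size=20_000)
        s = _series(xi, w, cond298)
        h = build_histograms([s], bin_width=0.1, hist_range=(4.0, 8.0))
        pmf = wham_solve(h)
        counts = h.counts[0]
        mask = counts > 0
        kT = kt(298.0)
        direct = -kT * np.log(counts[mask] / counts.sum())
        diff = pmf.F[mask] - direct
        assert np.max(np.abs(diff - diff.mean())) < 1e-8

    def test_toy_instance_matches_brute_force_oracle(self, cond298):
        """5-bin, 2-window instance against the independently coded
        fixed-point solver run at 10x tighter tolerance."""
        w1 = ht.WindowSpec(d0=4.2, k=2.0)
        w2 = ht.WindowSpec(d0=4.6, k=2.0)
        counts = np.array([[40, 60, 30, 5, 1], [2, 20, 50, 60, 20]])
        edges = 4.0 + 0.2 * np.arange(6)
        h = HistogramSet(
            bin_edges=edges,
            counts=counts,
            n_total=counts.sum(axis=1),
            windows=(w1, w2),
            condition=cond298,
        )
        pmf = wham_solve(h, tol=1e-8)
        centers = h.bin_centers
        bias = [
            [2.0 * (c - w.d0) ** 2 for c in centers] for w in (w1, w2)
        ]
        p_ref, f_ref = brute_force_wham(
            counts.tolist(), counts.sum(axis=1).tolist(), bias, kt(298.0), tol=1e-9
        )
        p_impl = np.exp(-pmf.F / kt(298.0))
        p_impl /= p_impl.sum()
        assert np.allclose(p_impl, p_ref, atol=1e-8)
        assert np.allclose(pmf.window_shifts, f_ref, atol=1e-7)

    def test_exact_gaussian_windows_give_flat_profile(self, cond298):
        """Counts taken from the exact biased densities of a flat potential
        must reconstruct a flat PMF."""
        kT = kt(298.0)
        windows = tuple(ht.WindowSpec(d0=d, k=2.0) for d in (5.0, 6.0, 7.0))
        edges = 4.0 + 0.1 * np.arange(41)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = []
        for w in windows:
            dens = np.exp(-2.0 * (centers - w.d0) ** 2 / kT)
            counts.append(np.round(1e6 * dens / dens.sum()).astype(int))
        counts = np.array(counts)
        h = HistogramSet(
            bin_edges=edges,
            counts=counts,
            n_total=counts.sum(axis=1),
            windows=windows,
            condition=cond298,
        )
        pmf = wham_solve(h, tol=1e-9)
        spread = pmf.F[pmf.defined] - np.mean(pmf.F[pmf.defined])
        assert np.max(np.abs(spread)) < 0.01  # discretization noise only

    def test_gauge_invariance_under_constant_bias_shift(self, cond298, monkeypatch):
        """Adding a constant to every bias energy must not change the PMF."""
        import hydrotherm.wham as wham_mod

        rng = np.random.default_rng(3)
        windows = [ht.WindowSpec(d0=d, k=2.0) for d in (5.0, 6.0)]
        series = [
            _series(rng.normal(w.d0, 0.4, size=5000), w, cond298) for w in windows
        ]
        h = build_histograms(series, bin_width=0.1, hist_range=(4.0, 8.0))
        base = wham_solve(h, tol=1e-9)

        orig = wham_mod._bias_matrix
        monkeypatch.setattr(wham_mod, "_bias_matrix", lambda hist: orig(hist) + 7.3)
        shifted = wham_solve(h, tol=1e-9)

        d = base.F - shifted.F
        d = d[np.isfinite(d)]
        assert np.max(np.abs(d - d.mean())) < 1e-8

    def test_fixed_point_is_stationary(self, small_hexane_pmf, small_hexane_dataset, cond298):
        """Re-applying one iteration at the solution moves f by < tol."""
        series = small_hexane_dataset.for_condition(cond298)
        h = build_histograms(series)
        again = wham_solve(h, tol=1e-7, f_init=small_hexane_pmf.window_shifts)
        assert again.n_iter <= 2

    def test_unconverged_flag_and_warning(self, small_hexane_dataset, cond298):
        series = small_hexane_dataset.for_condition(cond298)
        h = build_histograms(series)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            pmf = wham_solve(h, tol=1e-12, max_iter=5)
        assert not pmf.converged

    def test_all_empty_histogram_rejected(self, cond298):
        w = ht.WindowSpec(6.0, 2.0)
        h = HistogramSet(
            bin_edges=np.array([4.0, 4.1, 4.2]),
            counts=np.zeros((1, 2), dtype=int),
            n_total=np.array([100]),
            windows=(w,),
            condition=cond298,
        )
        with pytest.raises(ValueError, match="empty"):
            wham_solve(h)


class TestBaseline:
    def test_tail_mean_zero_after_subtraction(self, small_hexane_pmf):
        lo, hi = small_hexane_pmf.baseline_range
        mask = (
            (small_hexane_pmf.bin_centers >= lo)
            & (small_hexane_pmf.bin_centers <= hi)
            & small_hexane_pmf.defined
        )
        assert abs(np.mean(small_hexane_pmf.F[mask])) < 1e-10

    def test_constant_profile_shifted_to_zero(self, cond298):
        pmf = ht.PMFProfile(
            bin_centers=np.linspace(10.0, 16.0, 61),
            F=np.full(61, 3.2),
            condition=cond298,
            window_shifts=np.zeros(1),
            total_counts=np.ones(61, dtype=int),
            converged=True,
            n_iter=1,
        )
        out = ht.subtract_baseline(pmf, (14.0, 15.4))
        mask = (out.bin_centers >= 14.0) & (out.bin_centers <= 15.4)
        assert np.mean(out.F[mask]) == pytest.approx(0.0, abs=1e-12)

    def test_range_outside_grid_rejected(self, small_hexane_pmf):
        with pytest.raises(ValueError, match="baseline"):
            ht.subtract_baseline(small_hexane_pmf, (100.0, 101.0))


class TestBootstrap:
    def test_deterministic_in_seed(self, cond298):
        rng = np.random.default_rng(5)
        windows = [ht.WindowSpec(d0=d, k=2.0) for d in (5.0, 6.0, 7.0)]
        series = [
            _series(rng.normal(w.d0, 0.4, size=3000), w, cond298) for w in windows
        ]
        kwargs = dict(baseline_range=(6.5, 7.5), n_boot=5, block_len=50)
        e1 = ht.bootstrap_pmf_uncertainty(series, seed=7, **kwargs)
        e2 = ht.bootstrap_pmf_uncertainty(series, seed=7, **kwargs)
        assert np.array_equal(e1, e2, equal_nan=True)

    def test_constant_series_gives_zero_error(self, cond298):
        w = ht.WindowSpec(d0=6.0, k=2.0)
        s = _series(np.full(1000, 6.03), w, cond298)
        err = ht.bootstrap_pmf_uncertainty(
            [s], n_boot=4, block_len=10, seed=1, hist_range=(5.0, 7.0)
        )
        centers_bin = int((6.03 - 5.0) / 0.1)
        assert err[centers_bin] == 0.0

    def test_block_len_must_be_shorter_than_series(self, cond298):
        w = ht.WindowSpec(d0=6.0, k=2.0)
        s = _series(np.random.default_rng(0).normal(6, 0.3, 100), w, cond298)
        with pytest.raises(ValueError, match="block_len"):
            ht.bootstrap_pmf_uncertainty([s], n_boot=2, block_len=100, seed=1)

    def test_error_scale_matches_replicate_scatter(self, flat_model):
        """Bootstrap F_err within a factor 2 of the across-regeneration
        standard deviation on a flat-potential study."""
        cond = ht.Condition(298.0, 0.0)
        windows = tuple(ht.WindowSpec(d0=d, k=2.0, label=f"w{d}") for d in (5.0, 6.0, 7.0))
        kwargs = dict(bin_width=0.1, hist_range=(4.0, 8.5))
        baseline = (7.0, 8.0)

        profiles = []
        for rep in range(20):
            series = [
                ht.sample_window(flat_model, w, cond, 4000, seed=1000 + 31 * rep + i)
                for i, w in enumerate(windows)
            ]
            pmf = ht.wham_solve(ht.build_histograms(series, **kwargs))
            profiles.append(ht.subtract_baseline(pmf, baseline).F)
        across = np.nanstd(np.stack(profiles), axis=0, ddof=1)

        series = [
            ht.sample_window(flat_model, w, cond, 4000, seed=1000 + i)
            for i, w in enumerate(windows)
        ]
        err = ht.bootstrap_pmf_uncertainty(
            series, baseline_range=baseline, n_boot=20, block_len=50, seed=2, **kwargs
        )
        mask = np.isfinite(across) & np.isfinite(err) & (across > 0)
        ratio = np.nanmean(err[mask]) / np.nanmean(across[mask])
        assert 0.5 < ratio < 2.0
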
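"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Reconstructs the unbiased potential of mean force F(ξ) from the biased
per-window histograms by iterating the standard self-consistent pair of
equations

    p_j ∝ (Σ_i n_ij) / (Σ_i N_i exp[−(w_i(ξ_j) − f_i)/k_BT])
    f_i = −k_BT ln Σ_j p_j exp[−w_i(ξ_j)/k_BT]

with w_i the bias of window i evaluated at bin centre j and f_i the window
free-energy constants (gauge f_1 = 0).  All exponentials are evaluated in
shifted (log-sum-exp) form so the iteration cannot overflow.  The PMF is
F_j = −k_BT ln p_j, anchored by the tail-baseline rule, with uncertainties
from a moving-block bootstrap over each window's time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .constants import kt
from .model import Condition, WindowSpec, bias_energy
from .sampling import ReactionCoordinateSeries

__all__ = [
    "HistogramSet",
    "PMFProfile",
    "build_histograms",
    "wham_solve",
    "subtract_baseline",
    "bootstrap_pmf_uncertainty",
]


@dataclass(frozen=True)
class HistogramSet:
    """Per-window histograms of the reaction coordinate at one state point."""

    bin_edges: np.ndarray  # (n_bins + 1,), strictly increasing, Å
    counts: np.ndarray  # (n_windows, n_bins) integer counts
    n_total: np.ndarray  # (n_windows,) samples before range clipping
    windows: Tuple[WindowSpec, ...]
    condition: Condition
    bias_convention: str = "k_sq"

    def __post_init__(self):
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")
        if np.any(self.counts.sum(axis=1) > self.n_total):
            raise ValueError("retained counts exceed totals")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_dropped(self) -> np.ndarray:
        """Per-window samples outside the histogram range."""
        return self.n_total - self.counts.sum(axis=1)


@dataclass
class PMFProfile:
    """Binned free-energy profile F(ξ) with metadata.

    ``F`` is NaN on bins where no window contributed counts; downstream
    consumers must skip those bins.
    """

    bin_centers: np.ndarray
    F: np.ndarray  # kcal/mol, NaN where undefined
    condition: Condition
    window_shifts: np.ndarray  # WHAM constants f_i, kcal/mol
    total_counts: np.ndarray  # per-bin summed counts over windows
    converged: bool
    n_iter: int
    F_err: Optional[np.ndarray] = None
    baseline_range: Optional[Tuple[float, float]] = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.F)


def build_histograms(
    series: Sequence[ReactionCoordinateSeries],
    bin_width: float = 0.1,
    hist_range: Optional[Tuple[float, float]] = None,
    bias_convention: str = "k_sq",
) -> HistogramSet:
    """Bin each window's samples on a common grid of half-open bins [l, r).

    The default grid spans min(d₀) − 1 Å to max(d₀) + 2 Å.  Samples outside
    the grid are dropped but accounted for (retained + dropped = n_samples).
    """
    if not series:
        raise ValueError("empty series list")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cond = series[0].condition
    for s in series[1:]:
        if s.condition != cond:
            raise ValueError(
                f"mixed conditions: {s.condition} vs {cond}; "
                "histogram one state point at a time"
            )
    if hist_range is None:
        d0s = [s.window.d0 for s in series]
        hist_range = (min(d0s) - 1.0, max(d0s) + 2.0)
    lo, hi = hist_range
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)

    counts = np.zeros((len(series), n_bins), dtype=np.int64)
    for i, s in enumerate(series):
        # half-open bins: index floor((x - lo)/width), valid in [0, n_bins)
        idx = np.floor((np.asarray(s.xi) - lo) / bin_width).astype(np.int64)
        ok = (idx >= 0) & (idx < n_bins) & (np.asarray(s.xi) < edges[-1])
        counts[i] = np.bincount(idx[ok], minlength=n_bins)
    return HistogramSet(
        bin_edges=edges,
        counts=counts,
        n_total=np.array([len(s) for s in series], dtype=np.int64),
        windows=tuple(s.window for s in series),
        condition=cond,
        bias_convention=bias_convention,
    )


def _bias_matrix(hist: HistogramSet) -> np.ndarray:
    """(n_windows, n_bins) bias energies at bin centres, kcal/mol."""
    centers = hist.bin_centers
    return np.stack(
        [bias_energy(w, centers, convention=hist.bias_convention) for w in hist.windows]
    )


def wham_solve(
    hist: HistogramSet,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    f_init: Optional[np.ndarray] = None,
) -> PMFProfile:
    """Self-consistent WHAM solution of a histogram set.

    Iterates until the largest change in any window constant f_i drops below
    ``tol`` (kcal/mol).  If ``max_iter`` is exhausted first, the profile is
    returned with ``converged=False`` and a warning.  ``f_init`` warm-starts
    the iteration (used by the bootstrap).
    """
    if hist.counts.sum() == 0:
        raise ValueError("all-empty histogram set")
    kT = kt(hist.condition.T)
    w = _bias_matrix(hist)  # (W, B)
    n_w = w.shape[0]
    N = hist.n_total.astype(float)  # (W,)
    log_N = np.log(np.where(N > 0, N, 1.0))
    sum_counts = hist.counts.sum(axis=0).astype(float)  # (B,)
    occupied = sum_counts > 0
    with np.errstate(divide="ignore"):
        log_num = np.log(sum_counts)  # -inf on empty bins

    f = np.zeros(n_w) if f_init is None else np.array(f_init, dtype=float)
    neg_w_kT = -w / kT  # (W, B)
    # constant part of the log-denominator; only occupied bins matter
    occ = np.flatnonzero(occupied)
    A = (log_N[:, None] + neg_w_kT)[:, occ]  # (W, B_occ)
    neg_w_occ = neg_w_kT[:, occ]
    log_num_occ = log_num[occ]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # log denominator_j = logsumexp_i [ log N_i + (f_i - w_ij)/kT ]
        B = A + (f / kT)[:, None]
        m = B.max(axis=0)
        log_den = m + np.log(np.exp(B - m).sum(axis=0))
        log_p = log_num_occ - log_den
        mp = log_p.max()
        log_p -= mp + np.log(np.exp(log_p - mp).sum())
        # f_i = -kT * logsumexp_j [ log p_j - w_ij/kT ]
        C = log_p[None, :] + neg_w_occ
        mc = C.max(axis=1)
        f_new = -kT * (mc + np.log(np.exp(C - mc[:, None]).sum(axis=1)))
        f_new -= f_new[0]  # gauge: f_1 = 0
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max |Δf| = {delta:.3g} kcal/mol)",
            RuntimeWarning,
        )

    log_den = logsumexp(log_N[:, None] + f[:, None] / kT + neg_w_kT, axis=0)
    log_p = log_num - log_den
    log_p -= logsumexp(log_p[occupied])
    F = np.where(occupied, -kT * log_p, np.nan)
    return PMFProfile(
        bin_centers=hist.bin_centers,
        F=F,
        condition=hist.condition,
        window_shifts=f,
        total_counts=sum_counts.astype(np.int64),
        converged=converged,
        n_iter=n_iter,
    )


def subtract_baseline(
    pmf: PMFProfile, baseline_range: Tuple[float, float]
) -> PMFProfile:
    """Anchor the PMF so its mean over the tail baseline range is zero.

    The unweighted mean of F over defined bins whose centres lie in the closed
    range is subtracted; the study-protocol defaults are 14–15.4 Å
    (adamantane-like) and 12–13.5 Å (hexane-like).
    """
    lo, hi = baseline_range
    in_range = (pmf.bin_centers >= lo) & (pmf.bin_centers <= hi) & pmf.defined
    if in_range.sum() < 2:
        raise ValueError(
            f"baseline range {baseline_range} overlaps fewer than 2 defined bins"
        )
    offset = float(np.mean(pmf.F[in_range]))
    return replace(
        pmf,
        F=pmf.F - offset,
        baseline_range=(float(lo), float(hi)),
    )


def _moving_block_resample(
    x: np.ndarray, block_len: int, rng: np.random.Generator
) -> np.ndarray:
    """One moving-block bootstrap replicate of a time series."""
    n = len(x)
    n_blocks = -(-n // block_len)
    starts = rng.integers(0, n - block_len + 1, size=n_blocks)
    out = np.concatenate([x[s : s + block_len] for s in starts])
    return out[:n]


def bootstrap_pmf_uncertainty(
    series: Sequence[ReactionCoordinateSeries],
    bin_width: float = 0.1,
    hist_range: Optional[Tuple[float, float]] = None,
    baseline_range: Optional[Tuple[float, float]] = None,
    n_boot: int = 20,
    block_len: int = 200,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bias_convention: str = "k_sq",
) -> np.ndarray:
    """Per-bin PMF standard errors from a moving-block bootstrap.

    Each replicate resamples every window's time series in moving blocks of
    ``block_len`` samples (preserving short-range autocorrelation), rebuilds
    the histograms, re-solves WHAM (warm-started from the full-data solution)
    and applies the baseline rule; F_err is the per-bin standard deviation
    over replicates (NaN where any replicate leaves the bin undefined is
    ignored bin-wise).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    for s in series:
        if block_len >= len(s):
            raise ValueError(
                f"block_len {block_len} must be shorter than the series ({len(s)})"
            )
    base_hist = build_histograms(
        series, bin_width=bin_width, hist_range=hist_range, bias_convention=bias_convention
    )
    base = wham_solve(base_hist, tol=tol, max_iter=max_iter)
    if baseline_range is None:
        lo = base_hist.bin_edges[0]
        hi = base_hist.bin_edges[-1]
        baseline_range = (hi - 0.15 * (hi - lo), hi)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        resampled = [
            ReactionCoordinateSeries(
                window=s.window,
                condition=s.condition,
                times=s.times,
                xi=_moving_block_resample(np.asarray(s.xi), block_len, rng),
                seed=s.seed,
            )
            for s in series
        ]
        h = build_histograms(
            resampled, bin_width=bin_width, hist_range=hist_range, bias_convention=bias_convention
        )
        prof = wham_solve(h, tol=tol, max_iter=max_iter, f_init=base.window_shifts)
        if prof.defined.sum() >= 2:
            prof = subtract_baseline(prof, baseline_range)
        else:
            # degenerate (all mass in one bin): gauge that bin to zero
            prof.F = prof.F - np.nanmin(prof.F)
        boots.append(prof.F)
    stack = np.stack(boots)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(stack, axis=0, ddof=1)
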
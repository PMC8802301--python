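"""Independent brute-force oracles used only by the tests.

Everything here is deliberately written in plain loops, independent of the
package's vectorized implementations, so the two can disagree.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np

KB = 0.0019872041  # kcal/mol/K


def brute_force_wham(
    counts: Sequence[Sequence[int]],
    n_totals: Sequence[int],
    bias: Sequence[Sequence[float]],
    kT: float,
    tol: float = 1e-9,
    max_iter: int = 2_000_000,
) -> Tuple[List[float], List[float]]:
    """Fixed-point WHAM by direct per-element iteration.

    counts[i][j]: window i, bin j; bias[i][j]: bias energy at bin centre j.
    Returns (p, f) with p normalized over bins that have any counts and the
    gauge f[0] = 0.
    """
    n_win = len(counts)
    n_bin = len(counts[0])
    sum_counts = [sum(counts[i][j] for i in range(n_win)) for j in range(n_bin)]
    occupied = [j for j in range(n_bin) if sum_counts[j] > 0]
    f = [0.0] * n_win
    p = [0.0] * n_bin
    for _ in range(max_iter):
        for j in occupied:
            den = 0.0
            for i in range(n_win):
                den += n_totals[i] * math.exp(-(bias[i][j] - f[i]) / kT)
            p[j] = sum_counts[j] / den
        norm = sum(p[j] for j in occupied)
        for j in occupied:
            p[j] /= norm
        f_new = []
        for i in range(n_win):
            z = 0.0
            for j in occupied:
                z += p[j] * math.exp(-bias[i][j] / kT)
            f_new.append(-kT * math.log(z))
        f0 = f_new[0]
        f_new = [v - f0 for v in f_new]
        delta = max(abs(f_new[i] - f[i]) for i in range(n_win))
        f = f_new
        if delta < tol:
            break
    return p, f


def brute_force_extrema(y: Sequence[float]) -> Tuple[List[int], List[int]]:
    """All strict interior local minima and maxima of a sequence."""
    minima, maxima = [], []
    for i in range(1, len(y) - 1):
        if y[i] < y[i - 1] and y[i] <= y[i + 1]:
            minima.append(i)
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            maxima.append(i)
    return minima, maxima


def biased_cdf_quadrature(
    potential, window, condition, lo: float, hi: float, n_grid: int = 20_001
):
    """Analytic CDF of the biased density by trapezoidal quadrature.

    Returns (grid, cdf) with cdf normalized to 1 on [lo, hi].
    ``potential`` maps (xi_array, condition) -> energies; ``window`` supplies
    d0 and k of the harmonic restraint k(xi - d0)^2.
    """
    x = np.linspace(lo, hi, n_grid)
    u = potential(x, condition) + window.k * (x - window.d0) ** 2
    u = u - u.min()
    dens = np.exp(-u / (KB * condition.T))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(x))])
    return x, cdf / cdf[-1]


def effective_sample_size(x: np.ndarray, segment_len: int) -> float:
    """ESS of a concatenation of independent stationary chain segments.

    Integrated autocorrelation time is estimated per segment (initial
    positive sequence) and averaged.
    """
    n_seg = len(x) // segment_len
    taus = []
    for s in range(n_seg):
        seg = x[s * segment_len : (s + 1) * segment_len]
        seg = seg - seg.mean()
        var = float(seg @ seg) / len(seg)
        if var == 0:
            continue
        tau = 1.0
        for lag in range(1, min(200, len(seg) // 2)):
            rho = float(seg[:-lag] @ seg[lag:]) / (len(seg) * var)
            if rho <= 0:
                break
            tau += 2.0 * rho
        taus.append(tau)
    tau_mean = float(np.mean(taus)) if taus else 1.0
    return len(x) / tau_mean
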
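"""Location and quantification of PMF features.

A hydrophobic-association PMF shows up to three landmarks: the contact
minimum (CM) at closest approach, the desolvation maximum (DM) — the barrier
to expelling the interfacial water layer — and the solvent-separated minimum
(SSM) one water layer out.  Compact solutes typically show all three; a
single CM with a monotone rise to the baseline is the prolate-solute
(hexane-like) signature.

Extrema are located on a lightly smoothed copy of the profile (centred
moving average) with a prominence filter to suppress bootstrap-level
wiggles; the reported depths and heights are always read from the raw,
unsmoothed profile at the located bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .wham import PMFProfile

__all__ = ["PMFFeatures", "find_extrema"]


@dataclass(frozen=True)
class PMFFeatures:
    """Positions (Å) and values (kcal/mol) of the CM/DM/SSM landmarks."""

    cm_pos: float
    cm_depth: float
    has_dm: bool = False
    dm_pos: Optional[float] = None
    dm_height: Optional[float] = None
    has_ssm: bool = False
    ssm_pos: Optional[float] = None
    ssm_depth: Optional[float] = None

    def __post_init__(self):
        if self.has_dm and self.dm_pos is not None and self.cm_pos >= self.dm_pos:
            raise ValueError("CM must lie at smaller distance than DM")
        if (
            self.has_dm
            and self.has_ssm
            and self.dm_pos is not None
            and self.ssm_pos is not None
            and self.dm_pos >= self.ssm_pos
        ):
            raise ValueError("DM must lie at smaller distance than SSM")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation; window <= 1 is identity."""
    if window <= 1:
        return y.copy()
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def find_extrema(
    pmf: PMFProfile,
    smooth_window: int = 3,
    min_prominence: float = 0.05,
) -> PMFFeatures:
    """Locate the CM, DM and SSM of a baseline-subtracted profile.

    The CM is the global minimum of the smoothed profile (ties broken toward
    smaller ξ — contact geometry); the DM is the highest maximum of
    prominence ≥ ``min_prominence`` between the CM and the next qualifying
    minimum, which in turn is the SSM.  Absent features are flagged, never
    fabricated.  Raises if no interior minimum reaches ``min_prominence``.
    """
    defined = pmf.defined
    # The baseline range declares the flat tail of the profile: landmarks
    # are definitionally absent there, so the scan stops where it starts.
    if pmf.baseline_range is not None:
        defined = defined & (pmf.bin_centers <= pmf.baseline_range[0])
    if defined.sum() < 5:
        raise ValueError("need at least 5 defined bins")
    # work on the longest contiguous run of defined bins
    runs = _contiguous_runs(defined)
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    x = pmf.bin_centers[start:stop]
    raw = pmf.F[start:stop]
    sm = _smooth(raw, smooth_window)

    minima, _ = find_peaks(-sm, prominence=min_prominence if min_prominence > 0 else None)
    if min_prominence <= 0:
        minima = np.array(
            [i for i in range(1, len(sm) - 1) if sm[i] < sm[i - 1] and sm[i] <= sm[i + 1]],
            dtype=int,
        )
    if len(minima) == 0:
        raise ValueError(
            f"no contact minimum: no interior minimum with prominence >= "
            f"{min_prominence} kcal/mol"
        )
    # global minimum among candidates; ties toward smaller xi
    cm_idx = minima[np.lexsort((minima, sm[minima]))[0]]

    maxima, _ = find_peaks(sm, prominence=min_prominence if min_prominence > 0 else None)
    if min_prominence <= 0:
        maxima = np.array(
            [i for i in range(1, len(sm) - 1) if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1]],
            dtype=int,
        )

    later_minima = minima[minima > cm_idx]
    dm_idx = ssm_idx = None
    if len(later_minima) > 0:
        ssm_candidate = int(later_minima[0])
        between = maxima[(maxima > cm_idx) & (maxima < ssm_candidate)]
        if len(between) > 0:
            cand = int(between[np.argmax(sm[between])])
            # A barrier flanked by a deep CM inherits a large one-sided
            # prominence from the well; demand that the drop on the far
            # side (DM → SSM) itself reaches the prominence floor, so that
            # noise ripples in the flat tail are not promoted to features.
            if sm[cand] - sm[ssm_candidate] >= min_prominence:
                dm_idx = cand
                ssm_idx = ssm_candidate

    return PMFFeatures(
        cm_pos=float(x[cm_idx]),
        cm_depth=float(raw[cm_idx]),
        has_dm=dm_idx is not None,
        dm_pos=float(x[dm_idx]) if dm_idx is not None else None,
        dm_height=float(raw[dm_idx]) if dm_idx is not None else None,
        has_ssm=ssm_idx is not None,
        ssm_pos=float(x[ssm_idx]) if ssm_idx is not None else None,
        ssm_depth=float(raw[ssm_idx]) if ssm_idx is not None else None,
    )


def _contiguous_runs(mask: np.ndarray):
    """[(start, stop), ...] half-open index runs where mask is True."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs
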
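"""Umbrella-window sampling of the model potential.

Stands in for the MD engine: for each window the biased one-dimensional
density p(ξ) ∝ exp[−(W(ξ) + V_bias(ξ))/k_BT] is sampled with an ensemble of
Gaussian random-walk Metropolis chains.  The proposal step is auto-tuned
during burn-in to a 30–50% acceptance rate; burn-in (10% of the production
steps per chain) is discarded and the production is thinned before the chains
are concatenated.  Everything is a pure function of its inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import kt
from .model import (
    ADAMANTANE_LADDER,
    DEFAULT_FORCE_CONSTANT,
    HEXANE_LADDER,
    IONIC_STRENGTHS_M,
    TEMPERATURES_K,
    Condition,
    ModelPotential,
    WindowSpec,
    adamantane_like_model,
    bias_energy,
    hexane_like_model,
)

__all__ = [
    "ReactionCoordinateSeries",
    "StudyProtocol",
    "StudyDataset",
    "sample_window",
    "generate_study",
    "hexane_like_protocol",
    "adamantane_like_protocol",
]

#: Save stride of the emulated trajectory, ps per retained sample.
TIME_STRIDE_PS = 0.2


@dataclass(frozen=True)
class ReactionCoordinateSeries:
    """Sampled reaction-coordinate values for one window at one state point."""

    window: WindowSpec
    condition: Condition
    times: np.ndarray  # ps, strictly increasing
    xi: np.ndarray  # Å
    seed: int

    def __post_init__(self):
        if len(self.times) != len(self.xi):
            raise ValueError("times and xi must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.asarray(self.xi) <= 0):
            raise ValueError("all xi must be positive")

    def __len__(self) -> int:
        return len(self.xi)


def _tune_step(step: float, acc_rate: float) -> float:
    """Nudge the proposal step toward the 30–50% acceptance band."""
    if acc_rate < 0.30:
        return step * 0.7
    if acc_rate > 0.50:
        return step * 1.4
    return step


def sample_window(
    model: ModelPotential,
    window: WindowSpec,
    condition: Condition,
    n_samples: int,
    seed: int,
    *,
    n_chains: int = 256,
    thin: int = 5,
    bias_convention: str = "k_sq",
) -> ReactionCoordinateSeries:
    """Sample the biased density of one umbrella window.

    Runs ``n_chains`` independent random-walk Metropolis chains in parallel
    on the coordinate ξ, targeting exp[−(W(ξ) + k(ξ−d₀)²)/k_BT].  Each chain
    keeps every ``thin``-th state after discarding a burn-in of 10% of its
    production steps (during which the step size is adapted in blocks of 50
    steps).  The kept states are concatenated and truncated to ``n_samples``.

    The returned series carries a synthetic time column (index × 0.2 ps).
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if n_chains < 1 or thin < 1:
        raise ValueError("n_chains and thin must be >= 1")

    beta = 1.0 / kt(condition.T)

    def neg_log_target(x: np.ndarray) -> np.ndarray:
        return beta * (
            model._energy_unchecked(x, condition)
            + bias_energy(window, x, convention=bias_convention)
        )

    rng = np.random.default_rng(seed)
    keep_per_chain = -(-n_samples // n_chains)  # ceil
    prod_steps = keep_per_chain * thin
    burn_steps = max(50, prod_steps // 10)

    # Start all chains at the restraint centre, clipped off the wall.
    x = np.full(n_chains, max(window.d0, model.wall_pos + 3.0 * model.wall_scale))
    x = x + 0.05 * rng.standard_normal(n_chains)
    x = np.maximum(x, model.wall_pos + 1e-3)
    u = neg_log_target(x)

    # Initial step from the restraint width where the bias dominates.
    k_eff = max(window.k, 0.1)
    step = float(np.sqrt(1.0 / (2.0 * beta * k_eff)))

    def metro_block(x, u, step, n_steps, record=None):
        n_acc = 0
        noise = rng.standard_normal((n_steps, n_chains))
        log_unif = np.log(rng.random((n_steps, n_chains)))
        for s in range(n_steps):
            prop = x + step * noise[s]
            u_prop = neg_log_target(prop)
            accept = log_unif[s] < u - u_prop
            x = np.where(accept, prop, x)
            u = np.where(accept, u_prop, u)
            n_acc += int(accept.sum())
            if record is not None and (s + 1) % thin == 0:
                record.append(x.copy())
        return x, u, n_acc / (n_steps * n_chains)

    # Burn-in with step adaptation in blocks of 50 steps.
    done = 0
    while done < burn_steps:
        block = min(50, burn_steps - done)
        x, u, acc = metro_block(x, u, step, block)
        step = _tune_step(step, acc)
        done += block

    kept: List[np.ndarray] = []
    x, u, _ = metro_block(x, u, step, prod_steps, record=kept)

    # kept is a list of (n_chains,) snapshots: transpose so each chain's
    # trajectory stays contiguous in time, then truncate.
    samples = np.asarray(kept).T.reshape(-1)[:n_samples]
    times = TIME_STRIDE_PS * (1.0 + np.arange(n_samples))
    return ReactionCoordinateSeries(
        window=window,
        condition=condition,
        times=times,
        xi=samples,
        seed=int(seed),
    )


@dataclass(frozen=True)
class StudyProtocol:
    """Declarative description of a synthetic umbrella-sampling study."""

    model: ModelPotential
    ladder: Tuple[WindowSpec, ...]
    temperatures: Tuple[float, ...] = TEMPERATURES_K
    ionic_strengths: Tuple[float, ...] = IONIC_STRENGTHS_M
    n_samples: int = 50_000
    n_chains: int = 64
    thin: int = 5
    bias_convention: str = "k_sq"
    baseline_range: Tuple[float, float] = (12.0, 13.5)
    name: str = "study"

    def __post_init__(self):
        d0s = [w.d0 for w in self.ladder]
        if len(set(d0s)) != len(d0s):
            raise ValueError("duplicate restraint centres in ladder")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("duplicate temperatures declared")
        if len(set(self.ionic_strengths)) != len(self.ionic_strengths):
            raise ValueError("duplicate ionic strengths declared")

    @property
    def conditions(self) -> List[Condition]:
        return [
            Condition(T=T, IS=IS)
            for IS in self.ionic_strengths
            for T in self.temperatures
        ]


@dataclass
class StudyDataset:
    """All series of a study, keyed by (window label, T, IS), plus provenance."""

    protocol: StudyProtocol
    ground_truth: ModelPotential
    series: Dict[Tuple[str, float, float], ReactionCoordinateSeries]
    master_seed: int

    def for_condition(self, condition: Condition) -> List[ReactionCoordinateSeries]:
        out = [
            s
            for s in self.series.values()
            if s.condition.T == condition.T and s.condition.IS == condition.IS
        ]
        if not out:
            raise KeyError(f"no series for {condition}")
        return sorted(out, key=lambda s: s.window.d0)

    def __len__(self) -> int:
        return len(self.series)


def _ladder_from_d0s(d0s: Sequence[float], k: float) -> Tuple[WindowSpec, ...]:
    return tuple(
        WindowSpec(d0=float(d), k=k, label=f"w{i + 1:02d}")
        for i, d in enumerate(d0s)
    )


def hexane_like_protocol(**overrides) -> StudyProtocol:
    """11-window ladder (4–14 Å), single-minimum model, tail baseline 12–13.5 Å."""
    defaults = dict(
        model=hexane_like_model(),
        ladder=_ladder_from_d0s(HEXANE_LADDER, DEFAULT_FORCE_CONSTANT),
        baseline_range=(12.0, 13.5),
        name="hexane_like",
    )
    defaults.update(overrides)
    return StudyProtocol(**defaults)


def adamantane_like_protocol(**overrides) -> StudyProtocol:
    """24-window ladder (4–18 Å), CM/DM/SSM model, tail baseline 14–15.4 Å."""
    defaults = dict(
        model=adamantane_like_model(),
        ladder=_ladder_from_d0s(ADAMANTANE_LADDER, DEFAULT_FORCE_CONSTANT),
        baseline_range=(14.0, 15.4),
        name="adamantane_like",
    )
    defaults.update(overrides)
    return StudyProtocol(**defaults)


def generate_study(protocol: StudyProtocol, seed: int) -> StudyDataset:
    """Generate the complete (window × T × IS) grid of series.

    Per-series seeds are derived deterministically from the master seed via
    a ``numpy`` SeedSequence spawned in fixed grid order, so the dataset is a
    pure function of (protocol, seed).
    """
    ss = np.random.SeedSequence(seed)
    cells = [
        (w, c)
        for c in protocol.conditions
        for w in protocol.ladder
    ]
    children = ss.spawn(len(cells))
    series: Dict[Tuple[str, float, float], ReactionCoordinateSeries] = {}
    for (w, cond), child in zip(cells, children):
        key = (w.label, cond.T, cond.IS)
        if key in series:  # pragma: no cover - guarded by StudyProtocol
            raise ValueError(f"duplicate (window, condition) cell {key}")
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        series[key] = sample_window(
            protocol.model,
            w,
            cond,
            protocol.n_samples,
            child_seed,
            n_chains=protocol.n_chains,
            thin=protocol.thin,
            bias_convention=protocol.bias_convention,
        )
    return StudyDataset(
        protocol=protocol,
        ground_truth=protocol.model,
        series=series,
        master_seed=int(seed),
    )
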
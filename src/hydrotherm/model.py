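"""Ground-truth model potentials and umbrella-window definitions.

The synthetic study replaces explicit-solvent molecular dynamics with direct
sampling of a one-dimensional model potential of mean force W(ξ) along the
solute–solute distance ξ.  The model is a sum of a shifted-exponential
repulsive wall and up to three Gaussian features — the contact minimum (CM),
the desolvation maximum (DM) and the solvent-separated minimum (SSM) — and
tends to zero at large separation, mirroring the flat tail of a converged
distance PMF.

The CM depth carries the thermodynamics: it varies quadratically with
temperature (so that the excess entropy, energy and heat capacity of
association are exact closed forms) and linearly with ionic strength
(salting-out).  The Gaussian amplitude of the CM is re-solved at every
(T, IS) so that W(cm_pos) equals the configured depth exactly, whatever the
overlap with the wall and the other features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "WindowSpec",
    "Condition",
    "ModelPotential",
    "bias_energy",
    "model_pmf_value",
    "hexane_like_model",
    "adamantane_like_model",
    "HEXANE_LADDER",
    "ADAMANTANE_LADDER",
    "DEFAULT_FORCE_CONSTANT",
    "TEMPERATURES_K",
    "IONIC_STRENGTHS_M",
]

#: Umbrella force constant, kcal·mol⁻¹·Å⁻².
DEFAULT_FORCE_CONSTANT = 2.0

#: The nine study temperatures, K.
TEMPERATURES_K = (273.0, 285.0, 298.0, 310.0, 323.0, 335.0, 348.0, 360.0, 373.0)

#: The five study ionic strengths, mol/dm³.
IONIC_STRENGTHS_M = (0.0, 0.4, 1.0, 1.5, 2.0)

#: Restraint-center ladder for the hexane-like study: 4.0, 5.0, …, 14.0 Å.
HEXANE_LADDER = tuple(float(d) for d in np.arange(4.0, 14.0 + 0.5, 1.0))

#: Restraint-center ladder for the adamantane-like study (24 windows).
ADAMANTANE_LADDER = (
    4.0, 5.0, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 9.5, 10.0, 10.5,
    11.0, 11.5, 12.0, 12.5, 13.0, 13.5, 14.0, 14.5, 15.0, 16.0, 17.0, 18.0,
)


@dataclass(frozen=True)
class WindowSpec:
    """One umbrella window: a harmonic restraint centred at ``d0``.

    Parameters
    ----------
    d0 : float
        Restraint centre (equilibrium distance), Å.  Must be positive.
    k : float
        Force constant, kcal·mol⁻¹·Å⁻².  Must be non-negative.
    label : str
        Free-text identifier (e.g. ``"w03"``).
    """

    d0: float
    k: float = DEFAULT_FORCE_CONSTANT
    label: str = ""

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError(f"d0 must be positive, got {self.d0}")
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")


@dataclass(frozen=True)
class Condition:
    """A thermodynamic state point: temperature (K) and ionic strength (mol/dm³)."""

    T: float
    IS: float = 0.0

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.IS < 0:
            raise ValueError(f"IS must be non-negative, got {self.IS}")


def bias_energy(window: WindowSpec, xi, convention: str = "k_sq"):
    """Harmonic umbrella restraint energy at distance(s) ``xi``.

    Two conventions are supported: ``"k_sq"`` gives k·(ξ − d₀)² (the default,
    the convention of the MD engine family the study protocol follows) and
    ``"half_k_sq"`` gives ½·k·(ξ − d₀)².

    Returns a float for scalar input, an ndarray for array input (kcal/mol).
    """
    xi = np.asarray(xi, dtype=float)
    e = window.k * (xi - window.d0) ** 2
    if convention == "half_k_sq":
        e = 0.5 * e
    elif convention != "k_sq":
        raise ValueError(f"unknown bias convention {convention!r}")
    return e if e.ndim else float(e)


@dataclass(frozen=True)
class ModelPotential:
    """Synthetic ground-truth PMF with (T, IS)-dependent contact-minimum depth.

    The potential is

        W(ξ) = h_w · exp(−(ξ − ξ_w)/s_w)
             + A_cm(T, IS) · g(ξ; cm_pos, cm_width)
             + dm_height · g(ξ; dm_pos, dm_width)
             + ssm_depth · g(ξ; ssm_pos, ssm_width)

    with g a unit Gaussian bump, and A_cm(T, IS) solved so that
    W(cm_pos) = depth(T, IS) = (a + b·T + c·T²) + depth_IS_slope·IS exactly.
    The wall diverges only formally: evaluation at ξ ≤ wall_pos is a domain
    error, and h_w is large enough that the region near the wall is never
    visited at thermal energies.
    """

    cm_pos: float
    depth_T_quad: Tuple[float, float, float]
    depth_IS_slope: float = 0.0
    cm_width: float = 0.8
    dm_pos: Optional[float] = None
    dm_height: float = 0.0
    dm_width: float = 0.5
    ssm_pos: Optional[float] = None
    ssm_depth: float = 0.0
    ssm_width: float = 0.6
    wall_pos: float = 2.0
    wall_scale: float = 0.3
    wall_height: float = 400.0
    T_ref: float = 298.0

    def __post_init__(self):
        if self.cm_pos <= self.wall_pos:
            raise ValueError("cm_pos must lie beyond the repulsive wall")
        for w in (self.cm_width, self.dm_width, self.ssm_width, self.wall_scale):
            if w <= 0:
                raise ValueError("feature widths and wall_scale must be positive")
        if self.dm_pos is not None and self.dm_height < 0:
            raise ValueError("dm_height must be non-negative")
        if self.ssm_pos is not None and self.ssm_depth > 0:
            raise ValueError("ssm_depth must be non-positive (it is a well)")

    # -- depth law ---------------------------------------------------------

    def cm_depth(self, condition: Condition) -> float:
        """Configured CM depth at a state point, kcal/mol (≤ 0)."""
        a, b, c = self.depth_T_quad
        T = condition.T
        depth = (a + b * T + c * T * T) + self.depth_IS_slope * condition.IS
        if depth > 0:
            raise ValueError(
                f"configured CM depth is positive ({depth:.3f} kcal/mol) at "
                f"T={T} K, IS={condition.IS} M; not an associating pair"
            )
        return depth

    @property
    def cm_depth0(self) -> float:
        """CM depth at the reference state (T_ref, IS = 0), kcal/mol."""
        return self.cm_depth(Condition(T=self.T_ref, IS=0.0))

    # -- evaluation --------------------------------------------------------

    def _wall(self, xi: np.ndarray) -> np.ndarray:
        return self.wall_height * np.exp(-(xi - self.wall_pos) / self.wall_scale)

    @staticmethod
    def _bump(xi: np.ndarray, pos: float, width: float) -> np.ndarray:
        z = (xi - pos) / width
        return np.exp(-0.5 * z * z)

    def _fixed_part(self, xi: np.ndarray) -> np.ndarray:
        """Wall + DM + SSM contributions (everything except the CM Gaussian)."""
        v = self._wall(xi)
        if self.dm_pos is not None and self.dm_height != 0.0:
            v = v + self.dm_height * self._bump(xi, self.dm_pos, self.dm_width)
        if self.ssm_pos is not None and self.ssm_depth != 0.0:
            v = v + self.ssm_depth * self._bump(xi, self.ssm_pos, self.ssm_width)
        return v

    def cm_amplitude(self, condition: Condition) -> float:
        """CM Gaussian amplitude solving W(cm_pos) = cm_depth(T, IS) exactly."""
        fixed_at_cm = float(self._fixed_part(np.asarray([self.cm_pos]))[0])
        return self.cm_depth(condition) - fixed_at_cm

    def energy(self, xi, condition: Condition):
        """Ground-truth PMF W(ξ) in kcal/mol; domain error for ξ ≤ wall_pos."""
        xi_arr = np.asarray(xi, dtype=float)
        if np.any(xi_arr <= self.wall_pos):
            raise ValueError(
                f"xi must exceed the wall position {self.wall_pos} Å"
            )
        v = self._energy_unchecked(xi_arr, condition)
        return v if v.ndim else float(v)

    def _energy_unchecked(self, xi: np.ndarray, condition: Condition) -> np.ndarray:
        """Vectorized evaluation returning +inf at/inside the wall (sampler path)."""
        v = self._fixed_part(xi)
        v = v + self.cm_amplitude(condition) * self._bump(xi, self.cm_pos, self.cm_width)
        return np.where(xi > self.wall_pos, v, np.inf)


def model_pmf_value(model: ModelPotential, xi: float, condition: Condition) -> float:
    """Ground-truth PMF value W(ξ) at a single distance, kcal/mol."""
    return model.energy(xi, condition)


def hexane_like_model() -> ModelPotential:
    """Hexane-like preset: a single contact minimum, no DM/SSM.

    The depth law gives ΔF(CM) = −1.5 kcal/mol at 298 K and zero salt,
    deepening with temperature throughout 273–373 K and with ionic strength,
    and a heat capacity of association ΔC_V(298 K) ≈ −40 cal·mol⁻¹·K⁻¹.
    """
    return ModelPotential(
        cm_pos=5.5,
        cm_width=0.8,
        depth_T_quad=(8.026166, -0.051933, 6.7e-5),
        depth_IS_slope=-0.15,
    )


def adamantane_like_model() -> ModelPotential:
    """Adamantane-like preset: CM, desolvation maximum and solvent-separated
    minimum, ΔF(CM) = −2.0 kcal/mol and ΔC_V ≈ −20 cal·mol⁻¹·K⁻¹ at 298 K / 0 M."""
    return ModelPotential(
        cm_pos=6.4,
        cm_width=0.7,
        depth_T_quad=(3.6658144, -0.0290256, 3.36e-5),
        depth_IS_slope=-0.2,
        dm_pos=8.2,
        dm_height=0.35,
        dm_width=0.5,
        ssm_pos=10.0,
        ssm_depth=-0.25,
        ssm_width=0.6,
        wall_pos=2.5,
    )
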
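"""Thermodynamic decomposition of the contact-minimum free energy.

The depth of the PMF at the contact minimum is the excess association free
energy ΔF(CM).  Its temperature dependence over the nine-temperature grid is
fitted with a quadratic,

    ΔF(T) = a + b·T + c·T²,

from which the standard relations give the excess entropy, energy and heat
capacity of association:

    ΔS  = −∂ΔF/∂T = −(b + 2cT)
    ΔU  = ΔF + T·ΔS = a − c·T²
    ΔC_V = ∂ΔU/∂T = −2cT      (reported in cal·mol⁻¹·K⁻¹)

A positive curvature (c > 0) therefore encodes the negative heat capacity of
hydrophobic association.  The ionic-strength dependence of ΔF(CM) at fixed T
is effectively linear and fitted as such.  Uncertainties come from the fit
covariance by first-order propagation; confidence intervals use the normal
quantile when per-point sigmas are supplied (known-variance weighting) and
the Student-t quantile when the residual variance is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .constants import KCAL_TO_CAL

__all__ = [
    "ThermoFit",
    "ThermoState",
    "IonicFit",
    "fit_free_energy_vs_temperature",
    "thermo_state",
    "fit_free_energy_vs_ionic_strength",
]


def _polyfit_with_cov(
    x: np.ndarray,
    y: np.ndarray,
    sigma: Optional[np.ndarray],
    degree: int,
) -> Tuple[np.ndarray, np.ndarray, int, bool]:
    """Weighted LS fit of y = Σ_k β_k x^k; returns (beta, cov, dof, sigma_known).

    With per-point sigmas the covariance is the exact (XᵀWX)⁻¹; without, it
    is (XᵀX)⁻¹ scaled by the residual variance (flagged NaN for a saturated
    fit with zero degrees of freedom).
    """
    n_par = degree + 1
    X = np.vander(x, n_par, increasing=True)
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigmas must be positive")
        Xw = X / sigma[:, None]
        yw = y / sigma
    else:
        Xw, yw = X, y
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(xtx) < n_par:
        raise ValueError("singular design: not enough distinct x values")
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    cov_unit = np.linalg.inv(xtx)
    dof = len(x) - n_par
    if sigma is not None:
        cov = cov_unit
        sigma_known = True
    else:
        resid = y - X @ beta
        s2 = float(resid @ resid) / dof if dof > 0 else np.nan
        cov = cov_unit * s2
        sigma_known = False
    return beta, cov, dof, sigma_known


def _ci_halfwidth(var: float, dof: int, sigma_known: bool, level: float) -> float:
    if np.isnan(var):
        return np.nan
    if sigma_known:
        q = stats.norm.ppf(0.5 + level / 2)
    else:
        if dof <= 0:
            return np.nan
        q = stats.t.ppf(0.5 + level / 2, dof)
    return float(q * np.sqrt(var))


@dataclass(frozen=True)
class ThermoFit:
    """Quadratic fit ΔF(T) = a + bT + cT² with covariance."""

    a: float  # kcal/mol
    b: float  # kcal/mol/K
    c: float  # kcal/mol/K²
    cov: np.ndarray  # 3x3, ordered (a, b, c)
    n_points: int
    dof: int
    sigma_known: bool
    condition_IS: Optional[float] = None

    def __post_init__(self):
        cov = np.asarray(self.cov)
        if cov.shape != (3, 3):
            raise ValueError("cov must be 3x3")
        if not np.allclose(cov, cov.T, equal_nan=True):
            raise ValueError("cov must be symmetric")

    @property
    def coeffs(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def predict(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return self.a + self.b * T + self.c * T * T

    def ci_c(self, level: float = 0.95) -> Tuple[float, float]:
        """Confidence interval for the curvature coefficient c."""
        h = _ci_halfwidth(float(self.cov[2, 2]), self.dof, self.sigma_known, level)
        return (self.c - h, self.c + h)


@dataclass(frozen=True)
class ThermoState:
    """Excess thermodynamics of association at one temperature.

    Energies in kcal/mol, entropy in kcal·mol⁻¹·K⁻¹, heat capacity in
    cal·mol⁻¹·K⁻¹ (the conventional unit for hydration heat capacities).
    """

    T: float
    dF: float
    dU: float
    dS: float
    dCv: float
    dF_err: float = np.nan
    dU_err: float = np.nan
    dS_err: float = np.nan
    dCv_err: float = np.nan

    def __post_init__(self):
        if abs(self.dF - (self.dU - self.T * self.dS)) > 1e-10:
            raise ValueError("thermodynamic identity dF = dU - T*dS violated")


@dataclass(frozen=True)
class IonicFit:
    """Linear fit ΔF(IS) = intercept + slope·IS at fixed temperature."""

    slope: float  # kcal/mol per mol/dm³
    intercept: float  # kcal/mol
    cov: np.ndarray  # 2x2, ordered (intercept, slope)
    n_points: int
    dof: int
    sigma_known: bool
    condition_T: Optional[float] = None

    @property
    def saturated(self) -> bool:
        """True when the fit has no residual degrees of freedom (cov undefined)."""
        return (not self.sigma_known) and self.dof == 0

    def ci_slope(self, level: float = 0.95) -> Tuple[float, float]:
        h = _ci_halfwidth(float(self.cov[1, 1]), self.dof, self.sigma_known, level)
        return (self.slope - h, self.slope + h)


def fit_free_energy_vs_temperature(
    points: Sequence[Tuple[float, float]] | Sequence[Tuple[float, float, float]],
    condition_IS: Optional[float] = None,
) -> ThermoFit:
    """Fit ΔF(CM)(T) = a + bT + cT² by (weighted) least squares.

    ``points`` is a sequence of (T, dF) or (T, dF, sigma) tuples; with sigmas
    the weights are 1/σ².  At least three distinct temperatures are required.
    """
    pts = [tuple(p) for p in points]
    T = np.array([p[0] for p in pts], dtype=float)
    dF = np.array([p[1] for p in pts], dtype=float)
    sigma = None
    if all(len(p) >= 3 and p[2] is not None for p in pts):
        sigma = np.array([p[2] for p in pts], dtype=float)
    if len(np.unique(T)) < 3:
        raise ValueError("need at least 3 distinct temperatures")
    beta, cov, dof, known = _polyfit_with_cov(T, dF, sigma, degree=2)
    return ThermoFit(
        a=float(beta[0]),
        b=float(beta[1]),
        c=float(beta[2]),
        cov=cov,
        n_points=len(T),
        dof=dof,
        sigma_known=known,
        condition_IS=condition_IS,
    )


def thermo_state(fit: ThermoFit, T: float) -> ThermoState:
    """Evaluate the excess thermodynamics implied by a quadratic fit at T."""
    if T <= 0:
        raise ValueError("T must be positive")
    a, b, c = fit.a, fit.b, fit.c
    dF = a + b * T + c * T * T
    dS = -(b + 2 * c * T)
    dU = a - c * T * T  # = dF + T*dS
    dCv = -2 * c * T * KCAL_TO_CAL

    def prop(grad: np.ndarray) -> float:
        v = float(grad @ fit.cov @ grad)
        return float(np.sqrt(v)) if v >= 0 and not np.isnan(v) else np.nan

    return ThermoState(
        T=float(T),
        dF=dF,
        dU=dU,
        dS=dS,
        dCv=dCv,
        dF_err=prop(np.array([1.0, T, T * T])),
        dU_err=prop(np.array([1.0, 0.0, -T * T])),
        dS_err=prop(np.array([0.0, -1.0, -2.0 * T])),
        dCv_err=prop(np.array([0.0, 0.0, -2.0 * T])) * KCAL_TO_CAL,
    )


def fit_free_energy_vs_ionic_strength(
    points: Sequence[Tuple[float, float]] | Sequence[Tuple[float, float, float]],
    T: Optional[float] = None,
) -> IonicFit:
    """Fit ΔF(CM)(IS) with a straight line at fixed temperature.

    A negative slope is the salting-out signature (deeper contact minimum
    with added salt).  Two points give exact interpolation with an undefined
    residual covariance, flagged via ``saturated``.
    """
    pts = [tuple(p) for p in points]
    IS = np.array([p[0] for p in pts], dtype=float)
    dF = np.array([p[1] for p in pts], dtype=float)
    sigma = None
    if all(len(p) >= 3 and p[2] is not None for p in pts):
        sigma = np.array([p[2] for p in pts], dtype=float)
    if len(np.unique(IS)) < 2:
        raise ValueError("need at least 2 distinct ionic strengths")
    beta, cov, dof, known = _polyfit_with_cov(IS, dF, sigma, degree=1)
    return IonicFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        cov=cov,
        n_points=len(IS),
        dof=dof,
        sigma_known=known,
        condition_T=T,
    )
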
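# Methods

## Scope

`hydrotherm` implements the desk-scale analysis chain for umbrella-sampling
studies of pairwise hydrophobic association: biased one-dimensional
reaction-coordinate series → WHAM potential of mean force → landmark
(CM/DM/SSM) extraction → excess free-energy / energy / entropy /
heat-capacity decomposition over temperature and ionic strength.  Explicit
solvent molecular dynamics is out of scope; a synthetic sampler with a known
ground-truth potential takes its place so that every stage can be verified
quantitatively.

## The synthetic model potential

The ground truth is a sum of a shifted-exponential repulsive wall and up to
three Gaussian features:

    W(ξ) = h_w e^{−(ξ−ξ_w)/s_w}
         + A_cm(T, IS) g(ξ; ξ_cm, σ_cm)
         + h_dm g(ξ; ξ_dm, σ_dm)
         + d_ssm g(ξ; ξ_ssm, σ_ssm),

g a unit Gaussian.  It tends to zero at large separation (the flat tail of
a converged distance PMF) and is evaluated only for ξ beyond the wall
(domain error otherwise).  The contact-minimum depth carries the
thermodynamics:

    depth(T, IS) = (a + bT + cT²) + m·IS,

and the CM amplitude A_cm is re-solved at each state point so that
W(ξ_cm) equals depth(T, IS) *exactly*, whatever the overlap with the wall
and the other features.  Quadratic-in-T depth makes the excess quantities
closed forms of (a, b, c); linear-in-IS depth is the salting-out law.

Two presets define the default study conditions:

| preset | windows (d₀, Å) | CM | DM / SSM | depth(298, 0) | ΔC_V(298) | m |
|---|---|---|---|---|---|---|
| hexane-like | 4, 5, …, 14 (11) | 5.5 Å | none | −1.50 kcal/mol | −39.9 cal/mol/K | −0.15 |
| adamantane-like | 4 … 18 (24, denser mid-ladder) | 6.4 Å | 8.2 / 10.0 Å | −2.00 kcal/mol | −20.0 cal/mol/K | −0.20 |

Both use k = 2 kcal·mol⁻¹·Å⁻² restraints, nine temperatures 273–373 K,
ionic strengths 0–2 mol/dm³ and 50,000 samples per window.  The curvature
is positive (c > 0, i.e. ΔF(T) convex) in both presets, so the implied heat
capacity of association is negative, the entropy positive and the energy
positive at 298 K — the canonical signature of hydrophobic association, in
which the single-minimum profile is characteristic of a prolate solute and
the three-landmark profile of a compact one.  The (a, b) coefficients were
chosen so the depth decreases monotonically over the whole 273–373 K range
(the quadratic's vertex lies above 373 K) with magnitudes of a few
kcal/mol, and the baseline tail ranges are 12–13.5 Å (hexane-like) and
14–15.4 Å (adamantane-like).

## Sampling

Each window's biased density p(ξ) ∝ exp[−(W(ξ) + k(ξ−d₀)²)/k_BT] is
sampled by an ensemble of independent Gaussian random-walk Metropolis
chains (default 256), started at the restraint centre, with the proposal
step adapted in 50-step blocks during burn-in toward 30–50% acceptance.
Burn-in is 10% of each chain's production steps and is discarded;
production is thinned (default every 5th step) and the chains are
concatenated, keeping each chain's trajectory contiguous, then truncated to
the requested count.  The ensemble layout vectorizes what would otherwise
be a long scalar chain; since the biased densities are effectively unimodal
under the restraint, short per-chain histories mix fully (verified by the
Kolmogorov–Smirnov tests against quadrature-normalized target CDFs in the
suite).  The restraint convention is V = k(ξ−d₀)² with no ½ factor; a
`half_k_sq` switch is provided.  No radial 4πr² Jacobian is applied — the
model is a distance profile with a flat zero tail, not a 3-D density.  The
time column is synthetic (sample index × 0.2 ps).  A study is a pure
function of (protocol, master seed); per-series seeds are spawned
deterministically from the master seed in fixed grid order.

## WHAM

Histograms use half-open bins [l, r) of default width 0.1 Å on a grid
spanning min(d₀) − 1 Å to max(d₀) + 2 Å; out-of-range samples are dropped
but accounted for.  The standard two-equation fixed point is iterated with
all exponentials in max-shifted (log-sum-exp) form, restricted to occupied
bins, until the largest change in any window constant f_i is below the
tolerance (default 10⁻⁷ kcal/mol, cap 10⁵ iterations; non-convergence
returns a flagged profile plus a warning rather than raising).  The gauge
is f₁ = 0.  Bias energies are evaluated at bin centres — standard practice
at this bin width.  Empty bins carry NaN (never ±∞); consumers skip them.
The baseline rule subtracts the unweighted mean of F over defined bins in
the declared tail range.

Uncertainties come from a moving-block bootstrap (default 20 replicates,
block length 200 samples ≈ 40 ps of the emulated trajectory): each window's
series is resampled in blocks, histograms rebuilt, WHAM re-solved
warm-started from the full-data constants, the baseline re-applied, and
F_err taken as the per-bin standard deviation across replicates.  This is a
pragmatic uncertainty model, not a reproduction of any particular published
error analysis.

## Landmark extraction

Extrema are located on a centred-moving-average copy of the profile
(default 3 bins) over the longest contiguous run of defined bins, with
reported depths always read from the raw profile at the located bins.  The
CM is the global minimum among interior minima of prominence ≥ the floor
(default 0.05 kcal/mol, chosen to sit above bootstrap-level wiggle
amplitudes), ties broken toward smaller ξ.  The DM is the highest maximum
between the CM and the next qualifying minimum, which becomes the SSM.  Two
guards keep noise from being promoted to physics: the scan stops where the
declared baseline tail begins (the tail is flat by construction, so
landmarks there are definitionally absent), and the DM→SSM drop itself must
reach the prominence floor — a barrier adjacent to a deep CM otherwise
inherits a large one-sided prominence from the well.  Absent features are
flagged, never fabricated; a profile with no qualifying interior minimum is
an error ("no contact minimum").

## Thermodynamic decomposition

ΔF(CM)(T) at each ionic strength is fitted with ΔF = a + bT + cT² by least
squares — weighted by 1/σ² when per-point uncertainties (the bootstrap
error at the CM bin) are available, unweighted otherwise.  The covariance
is the exact (XᵀWX)⁻¹ in the weighted case (known-σ convention, normal
quantiles for intervals) and the residual-scaled (XᵀX)⁻¹ with Student-t
quantiles in the unweighted case; a saturated fit (zero residual degrees of
freedom) is flagged with NaN intervals rather than guessed.  The excess
quantities follow from the standard relations applied to the quadratic:

    ΔS = −∂ΔF/∂T = −(b + 2cT)
    ΔU = ΔF + TΔS = a − cT²
    ΔC_V = ∂ΔU/∂T = −2cT

with first-order propagation through the coefficient covariance.  The
constant-volume symbol is deliberate (NVT ensemble); no pressure–volume
correction is applied and no cubic ΔF(T) model is offered.  Heat capacity
is reported in cal·mol⁻¹·K⁻¹ (×1000 from kcal), the conventional unit for
hydration heat capacities; all other energies stay in kcal/mol.  The
ionic-strength dependence at fixed T is fitted as a straight line; a
negative slope is the salting-out signature.  ΔC_V is evaluated as −2cT at
the requested temperature exactly (no finite-difference variant).

## Pipeline

Each temperature is solved by WHAM independently at its own k_BT; there is
no multi-temperature reweighting.  Grid cells fail independently (an
unconverged WHAM or a feature-less profile is recorded per cell without
aborting the run), the thermo stage is skipped with an explicit note when
fewer than three temperatures are usable, and all outputs are plain TSV
with `#` metadata headers.  Reports are deterministic: identical config and
seed reproduce byte-identical tables.

## Problem sizes used in verification

The test suite and the acceptance script run the hexane-like preset at its
full per-window budget (11 windows × 50,000 samples) over nine temperatures
and three ionic strengths (0, 1, 2 mol/dm³) — 297 window series — with
20 bootstrap replicates per state point; unit tests use smaller grids.  At
these sizes the WHAM reconstruction error is ≈ 0.03 kcal/mol RMS against
the ground truth (well under the 0.1 kcal/mol recovery target), and the
fitted curvature, heat capacity and salt slope recover the generating
values within their propagated 95% intervals.

## Limitations

The synthetic sampler emulates the *statistics* of umbrella-sampling data
— biased draws from a one-dimensional landscape with tunable landmark
depths — not molecular reality: there is no explicit solvent, no
force-field energetics, no solute orientation (so no analogue of
orientation-resolved contact analyses), no distinction between
atom-pair and centre-of-centre distance definitions, and its autocorrelation
structure (thinned Metropolis ensemble) is milder than that of contiguous
MD trajectories, which flatters the block bootstrap.  Passing recovery
tests therefore demonstrates the correctness of the estimators, not the
accuracy of any molecular model.  The depth laws are exactly quadratic in T
and linear in IS, so the fit-model mismatch present in real data is absent
by construction; the CI-calibration and recovery checks quantify estimator
behaviour under the model's own assumptions.
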
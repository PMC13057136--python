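# Methods

This note records the models, the numerical choices and the design
decisions behind `pnpaging`, and what the synthetic-data studies do and do
not demonstrate.

## Binding model and unit conventions

The receptor is a hexameric enzyme treated as a **trimer of dimers**: the
multi-site binding models are written per *trimer*, each trimer carrying
one site of every class (1–3 nonequivalent classes). All receptor
concentrations in the binding modules are therefore µM **trimer** unless
stated otherwise; `monomer_to_trimer`/`trimer_to_monomer` (÷3 / ×3) convert
explicitly, and no conversion is ever implicit. Site classes are
independent — the binding polynomial is a product of single-site factors —
because the global models being reproduced contain no cooperativity
coupling; Hill/Adair schemes are out of scope. Whether the three classes
are equally abundant per trimer is not constrained by the data modelled
here; 1:1:1 is assumed throughout.

Free ligand is the root of the monotone mass balance on [0, L_tot], found
by Brent's method at relative tolerance 1e-12; monotonicity guarantees the
bracket, so the solver cannot silently converge to a wrong root. For one
site the solution coincides with the quadratic closed form (tested to
1e-10 relative).

The **incompetent fraction** f_inc ∈ [0, 1) is the part of the protein that
does not bind ligand at all; only total × (1 − f_inc) enters the mass
balance. It is a *local* parameter (per titration curve / per ITC
experiment) initialized at 0 in every fit.

## Fluorescence signal model

F = i0 · (1 + (1 − f_inc) Σᵢ αᵢ θᵢ(L_free)), with global (K_d, α) and local
(i0, f_inc). The per-site coefficients αᵢ are relative signal changes at
saturation (negative = quench); incompetent protein is assumed to fluoresce
like unliganded active protein, so it contributes to i0 but not to the
ligand-dependent term — the simplest model consistent with a
binding/incompetent partition. Ligand depletion is always modelled even
when ligand ≫ protein; correctness at the low-ligand points costs nothing.

**Identifiability caveat.** When receptor depletion is negligible,
(1 − f_inc) multiplies αᵢ exactly, so the two are not separately
identifiable from fluorescence data. The fitter therefore holds f_inc at
its initial value 0 by default and frees it only on request
(`vary_incompetent=True`), which is only meaningful when the protein
concentration is comparable to the smallest K_d. ITC does not share this
degeneracy (the heat scale is absolute), so there f_inc varies by default.

K_d is fitted on a log10 scale (positivity); multi-start initialization
draws log-uniform K_d guesses over the observed ligand range (8 starts,
fixed seed), keeps the lowest-RSS solution and breaks near-ties toward the
lowest K_d1. Fitted site classes are reported sorted by ascending K_d.
Standard errors for K_d are delta-method transforms of the log-scale
errors. A K_d estimated above the highest ligand concentration is flagged
as poorly constrained rather than rejected.

## ITC forward model

Fixed-volume perfusion bookkeeping: injection j of volume v into cell
volume V0 dilutes cell species by (1 − v/V0) and adds syringe ligand with
the same factor on what was present. With cell heat content
Q_j = V0 · P_active,j · Σᵢ ΔHᵢ θᵢ(L_free,j), the measured normalized heat is

NDH_j = [Q_j − Q_{j−1} + (v_j/V0)(Q_j + Q_{j−1})/2] / n_inj,j + offset,

the middle term being the trapezoidal correction for heat carried out with
the displaced volume — the de-facto standard model for 200 µL
ITC200-class cells, which is also the default cell volume (configurable,
and required metadata for real data files). The per-experiment `offset` is
a constant dilution-heat baseline rather than a fitted blank titration.
Input is integrated NDH per injection; peak integration of raw thermograms
is upstream and out of scope. An `exclude_first` flag drops the (often
unreliable) first injection; default off. Because the model is linear in
(ΔH, offset) at fixed (K_d, f_inc), each multi-start solves those linearly
first, which makes the 12-parameter three-site global fit converge reliably
from generic starts.

## Model discrimination

Candidates are fitted simplest-first (1 → 2 → 3 sites); escalation happens
only when the Wald–Wolfowitz runs test on the pooled residual signs rejects
randomness at α = 0.05 two-sided (α is a convention choice). Exact zeros
are dropped before sign coding. The two-sided p comes from the exact
run-count distribution below 20 residuals and the normal approximation
(μ = 2n₊n₋/n + 1, σ² = 2n₊n₋(2n₊n₋ − n)/(n²(n − 1))) above. Residuals are
pooled across the curves of a series for the decision; per-curve tests are
reported alongside. AIC = n ln(RSS/n) + 2k and AICc are recorded for every
fitted candidate; when the AIC ranking disagrees with the runs-test ladder
the runs-test decision stands and the disagreement is flagged. Fits whose
RSS is at numerical zero (below n·(1e-8·scale)²) are treated as exact: their
residual signs are floating-point artifacts, so they neither trigger
escalation nor enter log-RSS comparisons.

## Decay catalogue and weighting

Six families: linear, bi-exponential + offset, exponential + linear, and
1/2/3-phase generalized-logistic (Richards) sums with phase fractions
p, q, 1 − p − q. The three-phase form is implemented as a **sum** of three
weighted logistic terms. Conventions: logistic t_k are half-times directly
(A crosses the phase midpoint at t_k); exponential phases are parameterized
by time constants τ and *reported* as half-times ln 2 · τ, so recovery
checks are self-consistent; linear phases report the slope in (U/mg)/day.
Steepnesses h are bounded negative for decaying series (positive allowed
when the series increases). Fractions are fitted on a simplex transform
(s₁, s₂ ∈ [0,1] → p = s₁, q = (1 − s₁)s₂), which enforces p, q ≥ 0,
p + q ≤ 1 by construction. Phases are canonicalized to ascending half-time
after fitting.

Weighted fits use w = 1/SD² from the replicate standard deviations, which
keeps occasional high-SD points from steering the solution. Multi-start
initialization seeds phase half-times at quantiles (5, 12, 25, 50, 80% of
the span) and their combinations; amplitudes start from the data range.
`compare_decay_models` ranks all families by AICc on the weighted
residuals, ties toward fewer parameters, with the same numerical-zero RSS
floor as above (exact fits rank among themselves by parameter count).

## Synthetic data: what it emulates, and what not

Generators draw replicate-level Gaussian noise (relative by default) with
integer-seeded NumPy generators: identical output for identical seeds, and
`scale=0` reproduces the forward model bit-exactly. Defaults mirror the
study conditions: activity points are means of 3–5 replicates with ≤5%
relative error carrying the replicate SD of the mean (feeding the 1/SD²
weights); titration series are five curves at protein 0.5–2.5 µM monomer
with 1% signal noise; ITC sets are three experiments spanning a 10–30-fold
receptor-concentration range, 20 × 2 µL injections into 200 µL.

Reference parameter choices not fully pinned by the published values: the
exponential + linear storage-decay series uses fast-phase amplitude
A₁ = 146.7 U/mg so that A₁ + A₂ ≈ 220 U/mg, the observed extrapolation of
the exponential part to time zero; the three-phase logistic reference uses
equal fractions p = q = 1/3, common steepness −0.05/day, A₀ = 110 U/mg,
A∞ = 0. The Monte-Carlo titration study uses K_d = (5, 50, 800) µM, a grid
of zero plus 35 log-spaced points from 0.5 µM to 70 mM (the experimental
titrations extend to 70 mM), and α = (−0.5, −0.25, −0.2): a strong total
quench led by the tightest class. This choice matters — with weakly
contrasted coefficients the maximum-likelihood estimate of K_d1 itself
wanders ~20% at 1% noise (verified against multi-start with 4× more
starts), i.e. the limitation is the experiment's information content, not
the optimizer. Under the chosen conditions the discrimination ladder
reaches the three-site model in 20/20 seeds with median K_d1 error ≈ 4%.

What passing these studies shows: the fitters invert their own forward
models correctly, the discrimination ladder has the intended operating
characteristics under iid Gaussian noise, and the bookkeeping reproduces
the published worked-example arithmetic. What they do not show: robustness
to the structure of real data — drift, inner-filter effects, correlated
injection errors, non-Gaussian replicate scatter, model misspecification
(e.g. genuine cooperativity) — none of which the generators emulate.

## Known limitations and degenerate inputs

- The published catalytic concentration of one reference sample ("ITC
  experiment 5") does not follow from its own inputs (37.11/117 × 69.28 =
  21.97 µM, not 14.53 µM); the package reports the recomputed value and
  prints a note rather than silently matching either number.
- Three-site ITC parameters at a single cell concentration are weakly
  identifiable; ≥2 concentrations are recommended, and parameters with
  relative standard error >100% are flagged.
- The runs test is degenerate when all residuals share one sign (R = 1 is
  reported, p = 1, flagged); all-zero residual vectors are treated as
  perfect fits.
- The maximum specific activity used in the catalytic-fraction ratio
  defaults to 117 U/mg but is a parameter: freshly thawed preparations have
  shown transient activities above 200 U/mg, so the true maximum may be
  higher and the default makes the catalytic fraction an upper bound.
- Problem sizes in the validation studies (20 injections × 3 experiments;
  36–60 points per curve/series; 20 Monte-Carlo seeds) were chosen so each
  stage's parameters are comfortably identifiable at the study's noise
  levels while the whole suite stays desk-scale.
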
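# Methods

## Turnover model

Each protein fraction is modelled as a single well-mixed pool with
zero-order synthesis and first-order degradation, dP/dt = k_syn − k_deg·P.
Closed forms used throughout (P₀ is the pool at label start, t in days):

- P(t) = P₀e^(−k_deg t) + P_eq(1 − e^(−k_deg t)), with P_eq = k_syn/k_deg;
- newly synthesized mass surviving to t: N(t) = P_eq(1 − e^(−k_deg t))
  (new protein is degraded at the same first-order rate as old);
- fraction new f = N(t)/P(t); pool ratio r = P(t)/P₀.

k_deg = 0 is handled as the linear-growth limit (P = P₀ + k_syn t), and the
1 − e^(−kt) factor is computed with `expm1` so trajectories remain accurate
down to k_deg·t ≈ 0.

Inversion: the original protein surviving the window is
P₀e^(−k_deg t) = P(t)(1 − f), giving k_deg = −ln(r(1−f))/t and, from the
trajectory, k_syn = k_deg P₀ (r − e^(−k_deg t))/(1 − e^(−k_deg t)). At r = 1
these reduce to the steady-state formulas −ln(1−f)/t and k_deg·P₀ (the two
code paths share the same float operations so the limit is bit-exact). A
bracketed root-finding fallback (k_deg ∈ [0, 5]/day, tolerance 1e−12)
backs the closed form near r(1−f) ≈ 1. Assumptions: a single kinetically
homogeneous pool per fraction, constant rate constants over the window, and
a precursor that equilibrates fast relative to protein turnover (no
multi-compartment precursor delay).

**Identifiability guard.** r(1−f) > 1 would imply a negative degradation
rate; such samples are flagged invalid and excluded from summaries with a
surfaced count — never silently truncated at zero.

**Units.** Pools are normalised to P₀ = 1 (absolute pool mass is not
measured), so k_syn is in initial-pool fractions per day and k_deg in 1/day.
The published group means the generator plants carry no printed units; this
package assumes 1/day throughout and notes the assumption here only.

## Enrichment and MIDA

Isotopomer distributions are fractional abundances over mass shifts M0…M3,
matching a GC-MS selected-ion window for the
pentafluorobenzyl-N,N-di(pentafluorobenzyl) alanine derivative. The
natural-abundance baseline is computed by elemental convolution for the
composition C24H10F15NO2 (alanine with three hydrogens replaced by CH2–C6F5
groups), truncated to M0…M3 and renormalised; since the derivative
chemistry admits variants, the baseline is a config vector everywhere.

The labelling map is linear in the molar excess enrichment E: a fraction E
of molecules moves up one mass unit. Within the tracked window the top bin
absorbs outflow, which conserves the distribution sum exactly and makes the
map exactly invertible — the correction step recovers E to better than
1e−10 at zero noise, either from the M1 excess alone (default; coefficient
nat₀ − nat₁) or by least-squares projection onto the full shift basis
("matrix" mode, which averages noise over all bins). An exact binomial
model at integer site count is provided and agrees with the linear map to
first order in the body-water enrichment (cross-checked in tests at n = 4).

Precursor enrichment: p = n_sites × body-water enrichment (linear MIDA,
default n_sites = 3.7, adequate for body water ≲ 0.05), with an exact
integer-n binomial mode p = 1 − (1 − A_bw)^n. f = E/p is clamped to [0, 1]
when within 0.02 of the boundary (measurement noise) with a warning and a
surfaced count; further out the sample is flagged invalid.

## Synthetic cohort generator

The generator emulates a 5-day labelling experiment in a 2×2 design
(genotype × tumour implantation), n = 8 per cell by default:

- **Body water**: one-compartment kinetics — the i.p. bolus (default
  20 μL/g of 99 atom% D₂O into a 0.6 mL/g body-water pool) sets the initial
  enrichment (~0.032), which relaxes at the water turnover rate (default
  0.3/day) toward the drinking-water plateau. The plateau is taken as the
  drinking-water molar fraction D (default 0.08); metabolic-water dilution
  is ignored, and no plateau measurements exist to anchor it, so both the
  plateau and the turnover rate are flagged assumptions. A
  `constant_plateau` shortcut holds the curve flat. The pipeline itself
  always consumes measured plasma values, so these choices affect only
  simulation. The end-of-label plasma value is used as the precursor
  measurement.
- **Pools**: planted (k_syn, k_deg) per fraction and group. Degradation
  constants default to the published myofibrillar and mitochondrial group
  means; synthesis rates are set via the target pool ratio over the window
  (saline groups at steady state; tumour-bearing groups losing 5–25% of
  myofibrillar/mitochondrial protein; Sod1KO-saline gaining mitochondrial
  mass), reflecting the reported direction and rough magnitude of mass and
  marker changes. Cytosolic rates (0.06/0.065/0.06/0.12 per day) are a
  documented choice honouring the reported fold statements; no cytosolic
  values are printed.
- **Noise**: Gaussian absolute noise on isotopomer fractions (default sd
  5e−4, clip-at-zero then renormalise, clips surfaced), optional relative
  noise on the labelling signal itself (`isotopomer_cv`, default 0 — used
  by the rank-order robustness study at 10%), lognormal multiplicative
  noise on marker ratios (default CV 1%), Gaussian noise on Ct values
  (default 0.15 cycles). The marker default is deliberately at the
  precision of a wet-weight measurement: at k_deg ≈ 0.0085/day and t = 5 d
  the survival signal is only ~4%, so a marker CV much above a few percent
  makes per-animal non-steady corrections noise-dominated (a real
  densitometry marker is noisier; see Limitations).
- **Other measurements**: conduction velocities are Gaussian per group
  (means anchored to the published WT values; SDs from the published SEMs
  at n = 8), fibre cross-sectional areas are lognormal (mean 2200 μm²
  saline / 1650 μm² tumour-bearing, σ = 0.45), and the qPCR panel (Runx1,
  Gadd45α, AchRα, Sln vs 18s) plants 2–3-fold denervation-marker increases
  in Sod1KO groups.
- **Reproducibility**: every animal draws from `default_rng([seed,
  counter])`, so a (config, seed) pair regenerates byte-identical tables.

What the generator does *not* emulate: correlated within-animal errors,
chromatographic interference or drift, precursor-pool time lags,
animal-to-animal variation in the true rate constants, attrition
(mid-study deaths), or tumour growth itself. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated noise
model, not robustness to every failure mode of real GC-MS data.

## Marker policy

The pool ratio r feeding the non-steady inversion comes, per fraction, from:
mitochondrial — the CoxIV content-marker ratio (the study's stated
convention); myofibrillar — the muscle wet-weight ratio; cytosolic — no
content marker exists, so the steady-state estimator is used. The policy is
a config mapping; a missing marker downgrades that sample to the
steady-state method with a logged flag.

## Statistics

Two-way factorial ANOVA with interaction by cell-means model comparison on
dummy-coded least-squares fits. Type-II sums of squares by default
(each main effect adjusted for the other, interaction last): the design is
mildly unbalanced in practice (n = 6–8 with attrition) and no evidence
suggests interaction-driven hypotheses; Type III under sum-to-zero coding
is available by flag. Both are validated against statsmodels `anova_lm`.
Balanced designs conserve SS_A + SS_B + SS_AB + SS_E = SS_total to 1e−9
relative; a flat response is reported as degenerate (NaN F/p) rather than
propagating division errors. Null calibration: per-factor type-I error
0.05 ± 0.01 at α = 0.05 (10,000-replicate simulation in the test suite).

Post hoc: all 6 pairwise comparisons among the 4 cell means (matching the
annotation style of the study's figures; per-factor comparisons can be
obtained by subsetting), with q = |mᵢ − mⱼ|/√(MSE/2·(1/nᵢ + 1/nⱼ))
referred to the studentized range with k = 4 and the residual df — the
Kramer form, reducing to Tukey's HSD at equal n. Comparisons are gated on a
significant F by default (flag to override). The studentized-range upper
tail is computed by double Gauss–Legendre quadrature (400 nodes over the
normal range integral, 160 nodes over the chi-distributed scale, windows
truncated at 1e−11 tail mass); absolute accuracy ≈1e−9 for k ≤ 10, df ≥ 2,
verified against the k = 2 t-distribution identity, scipy's implementation
and a 10⁶-draw Monte-Carlo null. p-values below ~1e−11 are reported at
that floor.

## Assays

- ΔΔCT: ΔCt = Ct_gene − Ct_reference per animal; ΔΔCt centres on the
  calibrator-group mean ΔCt; relative quantity 2^−ΔΔCT. The calibrator
  group's *geometric* mean is exactly 1 (the arithmetic mean exceeds 1 by
  Jensen's inequality whenever Ct noise is present).
- Respirometry: (state flux − antimycin-A flux)/bundle wet weight. The
  complex-IV (ascorbate/TMPD) state is background-subtracted by default —
  TMPD autoxidation is not modelled — with a flag to disable. Negative
  corrected fluxes clamp to zero with a warning.
- Fibre CSA: small = [200, 1200] μm² (inclusive upper edge — the stated
  ranges leave the boundary open; inclusive was chosen and is configurable),
  average = (1200, 2400], large = (2400, ∞); sub-threshold fibres
  (< 200 μm²) are reported separately so counts partition the input.
- Mass normalisation: muscle mass / (body weight − tumour weight).

## Problem sizes

The test suite and acceptance script run: single-animal noise-free
recoveries (seconds); a 1,134-point (f, r, t) oracle grid against
fixed-step RK4 integration plus bisection; 500 replicate cohorts at n = 8
for the rank-order robustness study; 10,000-replicate ANOVA null
calibration; 10⁶-draw studentized-range Monte Carlo; and a 10,000-animal
conduction-velocity draw. The full default pipeline (32 animals, 3
fractions) completes in under a second.

## Known limitations

- The linear MIDA mapping degrades above body-water enrichment ≈ 0.05; the
  default simulated plateau (~0.069 at day 5) slightly exceeds this, which
  is immaterial for round-trip validation (the same mapping is used forward
  and backward) but matters when fitting real data — use the binomial mode
  or measured calibrations there.
- Real content-marker ratios (immunoblot densitometry) often carry ≥5% CV;
  at the low end of the observed degradation rates the non-steady
  correction then contributes more variance than it removes bias. Group
  sizes, not the estimator, are the remedy.
- The published mitochondrial WT-LLC degradation value (0.167) is
  inconsistent with the same source's "four-fold increase" statement
  (0.167/0.0204 ≈ 8-fold); the printed value is used verbatim as the
  generator default, with no reconciliation attempted.
- Whether the cytosolic rates in the source analysis used a non-steady
  correction is unstated; this package's policy (steady-state for
  cytosolic) is explicit configuration.
- Survival/attrition, repeated measures and mixed models are out of scope.
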
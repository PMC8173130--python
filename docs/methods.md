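# Methods

This note documents the models, the numerical choices, and the design
decisions behind `hypoximap`, and states what the synthetic-data validation
does and does not demonstrate.

## Pharmacokinetic model

The tissue model is the standard Tofts model: a single extravascular
extracellular compartment exchanging with plasma at rate constant K^trans
(min⁻¹, influx) and k_ep = K^trans/v_e (min⁻¹, efflux), with no
intravascular term. The extended Tofts model is deliberately out of scope:
at frame intervals of 14.8 s (preclinical) and 29 s (clinical) the first
pass is too coarsely sampled to separate an intravascular contribution.

The plasma input is a population bi-exponential
C_a(t) = A·e^(−Bt) + C·e^(−Dt). Two presets are built in:

| preset | A (mM) | B (s⁻¹) | C (mM) | D (s⁻¹) | agent |
|---|---|---|---|---|---|
| murine | 2.55 | 0.080 | 1.20 | 0.0010 | Gd-DOTA |
| human | 5.10 | 14.2 | 0.99 | 0.159 | Gd-DTPA |

AIF rates are stored in s⁻¹ as reported; inside the forward model all
rates are converted to min⁻¹ (×60), the unit in which K^trans thresholds
are quoted. With this AIF the convolution has a closed form per
exponential component, C_t = K^trans·M_i·(e^(−m_i t) − e^(−k_ep t))/(k_ep − m_i);
when |k_ep − m_i| < 10⁻⁸ min⁻¹ the analytic limit K^trans·M_i·t·e^(−m_i t)
is used to avoid 0/0. The closed form is verified in the tests against
fine-step (0.01 s) trapezoidal quadrature of the defining integral to
better than 10⁻⁶ mM.

**Fitting.** Bounded trust-region least squares (`scipy.optimize.least_squares`,
`trf`, ftol 10⁻¹⁰) with K^trans ∈ [0, 5] min⁻¹ and v_e ∈ [10⁻³, 3]. The
v_e bound deliberately admits values above 1 so that necrotic voxels —
where the compartment assumptions fail — remain representable; they are
flagged rather than clipped. Two starts are used, (0.1, 0.3) for typical
viable tissue and (0.01, 1.5) for the slow-efflux regime, keeping the
lower-residual solution: when k_ep·T ≪ 1 the residual surface has a flat
ridge in v_e and a single viable-tissue start can stall in a spurious
low-v_e minimum. All-zero or non-finite curves are not fitted (K^trans = 0,
`converged=False`). Contrast arrival is the first frame (t = 0); no
bolus-arrival-time estimation is performed.

## Hypoxia classification

All four strategies use strict inequalities; a voxel exactly at a
threshold is normoxic. Voxels with v_e > 1 (v_e = 1 exactly is still
classifiable) or non-finite parameters are labelled unphysiological and
are never hypoxic. The hypoxic fraction is computed over viable voxels
only — the analogue of HF_PIM being defined as an area fraction of viable
tissue — with a switch (`include_unphysiological=True`) to keep
unphysiological voxels in the denominator, since the original denominator
convention is not documented. An ROI with no classifiable voxel raises
rather than silently returning 0.

Structural identities that follow from the definitions, and are enforced
by tests: HF is non-decreasing in each threshold; the hypoxic sets nest
(iv ⊆ iii ⊆ i, iii ⊆ ii at equal thresholds); strategy iii equals
strategy i once v_e0 exceeds every v_e in the ROI, and strategy iv
converges to strategy i as v_e0 → ∞. The last identity is the package's
testable restatement of the empirical finding that combined
(K^trans, v_e) rules end up defining hypoxia through K^trans alone when
their optimal v_e0 is large.

## Similarity calibration

Similarity(x, y) = 2·cov(x, y)/(var(x) + var(y)) — the displayed
denominator of the source formula is read as (N−1)·(var x + var y)/2, the
unique reading under which the statistic equals 1 exactly when y = x +
constant (slope-1 agreement). It is symmetric, bounded by 1 in magnitude
(AM–GM), shift-invariant, and strictly below 1 for any slope ≠ 1 — unlike
the Pearson correlation, which is what makes it a calibration objective
rather than an association measure. It is undefined (raised/NaN) when both
inputs are constant.

Calibration computes HF_MRI for every tumor at every grid point and takes
the argmax of the Similarity against HF_PIM, ties broken toward smaller
thresholds (K₀^trans first, then v_e0 for 2-D sweeps). The per-tumor HF
versus threshold curve is computed by rewriting each strategy's predicate
as a scalar per-voxel score compared against K₀^trans (for strategy iv,
K^trans/(1 − v_e/v_e0) on the voxels with v_e < v_e0), so one sort plus one
`searchsorted` covers the whole axis. Default preclinical grids:
K₀^trans 0.001–0.100 min⁻¹ step 0.001; v_e0 0.01–1.0 step 0.01
(conjunction) or 50 log-spaced points over 0.1–16 (weighted sum, whose
useful v_e0 range extends far above 1). All tumors are pooled in one
calibration regardless of model and treatment arm; per-model calibration
is a caller-side filter. Agreement at the optimum is reported as Pearson
r² (with two-sided p) and the ordinary least-squares line. No p-values
are attached to the Similarity itself.

## Survival evaluation

The cohort split takes the ⌊N/3⌋ patients with the highest HF_MRI as the
high-risk group (26 of 80), motivated by first-line treatment failing in
roughly one-third of locally-advanced cervical cancer patients. Ties at
the boundary are resolved deterministically by patient id and flagged;
patients missing HF are excluded with a warning. Kaplan–Meier estimation
and the two-group log-rank test (hypergeometric variance, simultaneous
risk-set accounting for ties) are delegated to `lifelines`; the test suite
cross-checks the statistic against an independently coded hypergeometric
accumulation and the p-value against exhaustive permutation enumeration on
small cohorts. A comparison with zero events returns statistic 0, p = 1,
flagged degenerate. Threshold sweeps rerun split + log-rank per grid point
and record the per-threshold p-value, the p < 0.05 set, the argmin-p
optimum (ties toward smaller thresholds) and the number of thresholds
tested; no multiplicity correction is applied across the sweep, matching
the per-threshold evaluation procedure being reproduced, and per-endpoint
(DFS, OS) optima are reported separately. Degenerate grid points (all
patients sharing one HF) are recorded as missing, not zero.

On cohorts of ≤ 8 patients the asymptotic chi-square p-value and the exact
permutation p agree only up to the granularity of the exact distribution,
whose atoms reach ~0.1 at these sizes (e.g. 1/20-step atoms for a 3-vs-3
split with heavy ties); the oracle tests therefore assert agreement with
the permutation mid-p within 0.1 and containment in the exact
[P(S>s₀), P(S≥s₀)] bracket for the fully separated worked example.

## Synthetic-data generator

The generators reproduce the *statistical structure* the analysis needs,
not anatomy.

**Phantom** (per tumor): a disc of radius R (default 24 voxels on a 64×64
grid, 0.23×0.23×1.0 mm voxels preclinically; 0.78×0.78×5.0 mm clinical
template) with a necrotic core (radius fraction 0.3), a peri-necrotic
hypoxic annulus sized so a target fraction (default 0.3) of the viable
area is hypoxic, and a periphery. Viable-tissue K^trans is lognormal
around zone means 0.007 (hypoxic) and 0.05 (periphery) min⁻¹ with
log-scale σ = 0.5 — within-tumor K^trans spreads with CV ≳ 50% are the
norm in DCE data. v_e is Gaussian (mean 0.25, σ = 0.05) clipped to (0, 1];
necrotic voxels get v_e ≈ 2.5 and K^trans 0.03 min⁻¹ with a smaller spread
(σ = 0.2; passive diffusion into dead tissue is homogeneous). Ground-truth
labels come from applying the tumor's true rule (default strategy i at
0.015 min⁻¹) to the generated fields; the lognormal spread is tissue
heterogeneity, part of the ground truth, not measurement noise.

**Preclinical cohort**: per-tumor geometry drawn around the template
(radius ×U(0.6, 1), core fraction U(0.05, 0.4), hypoxic fraction
U(0.05, 0.6)) plus a per-tumor lognormal perfusion scale (log-σ 0.6)
multiplying both viable-zone means — xenograft lines differ in median
K^trans by factors of several, and this between-tumor heterogeneity is
essential: the Similarity statistic is invariant to a uniform HF shift
across tumors, so a threshold is only identifiable through differential
HF responses. Without it the Similarity surface is flat near the optimum
and no noise level, however small, localizes the threshold. HF_PIM = true
HF + truncated Gaussian noise (σ default 0.05), clipped to [0, 1]. Model
labels cycle over BK-12/ED-15/HL-16/LA-19 and every fourth tumor is
labelled bevacizumab-treated (≈ the 24/98 treated share); treatment is a
label only, with no generative effect. Default size 98 tumors.

**Clinical cohort** (default 80 patients): HF ~ Beta(2, 4) (mean 1/3), or
the true HF of a per-patient phantom when maps are requested. DFS event
times are exponential with hazard h₀·exp(β·HF); the OS event time adds an
independent exponential with the same hazard, so OS ≥ DFS pathwise; a
shared U(0, horizon) censoring time right-censors both. Defaults
h₀ = 0.01/month, β = 3, horizon = 60 months give ≈ 45% DFS events and a
≈ 2.5-fold hazard ratio across the interquartile HF range — the scale of
effect expected for a strong adverse imaging biomarker in this disease.
Exponential proportional hazards with uniform censoring is a modelling
choice (the simplest mechanism producing "high HF → worse outcome"), not a
claim about the original cohort.

**Acquisition**: every ROI voxel's closed-form Tofts curve at the
configured frame interval (14.8 s preclinical, 29 s clinical) plus i.i.d.
Gaussian noise (σ default 0.02 mM). Necrotic voxels are simulated at their
stored (low K^trans, v_e > 1) parameters, which produces the low, slowly
and steadily rising uptake characteristic of necrosis. The acquisition
duration defaults to 900 s: the designation "fitted v_e > 1" is carried by
the late accumulation phase (a v_e ≤ 1 model must visibly saturate below
the data), and at 10 minutes that contrast is still noise-limited for
slow-efflux voxels, whereas at 15 minutes — well within standard DCE
protocols — the fit recovers v_e > 1 in ≈ 99% of necrotic voxels.

What passing the synthetic validation shows: the estimators are correct
and the pipeline is self-consistent (round trips recover ground truth;
calibration recovers the generating threshold; the log-rank machinery is
correctly calibrated under the null and powered under the alternative).
What it does not show: performance on real signal data (no T1 mapping or
signal-to-concentration conversion is modelled), robustness to ROI
misregistration, spatially correlated noise, bolus-arrival jitter, or
inter-scanner variation — none of which the generator emulates.

## Problem sizes and determinism

Validation runs use a 98-tumor preclinical cohort on 64×64 grids,
80-patient clinical cohorts (32×32 per-patient phantoms when maps are
needed), 24×24 phantoms for fit-intensive round trips, 1000 replicates for
null calibration and 50/25 replicates for the calibration/sweep Monte
Carlo properties — sizes chosen to exercise the full design at desk scale.
All generators are deterministic given a seed; the CLI records config
hash, seed and package version in a manifest, and reruns with the same
config are byte-identical for deterministic stages.

## Known limitations

- The voxel fitter is a per-voxel Python loop; large 3-D volumes would
  want vectorization or parallel fitting.
- The necrotic-curve family is the Tofts closed form itself at v_e > 1
  rather than an independent accumulation model; it reproduces the
  qualitative shape but inherits the model's functional form.
- Similarity p-values are not computed (only Pearson r² p-values at the
  optimum).
- The CLI's `stratify` subcommand consumes precomputed HF columns; full
  sweep-from-maps orchestration is library-level.
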
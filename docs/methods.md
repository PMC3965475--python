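# Methods

## The kinetic model

Particles live on a discrete diameter grid (default: 60 log-spaced bins
over 19–80 nm; LDL 19–23 nm in three sub-bands, IDL 23–27 nm, VLDL
27–80 nm in three sub-bands — conventional NMR subclass boundaries; all
configurable). Six processes act:

* production into bin *i* at rate P_i = f_prod_total · w_i, with w a
  log-normal density in diameter (median `prod_mu` nm, log-width
  `prod_sigma`), normalized over the grid;
* LPL lipolysis at rate k_lpl·f_L(d), f_L a rising logistic (midpoint
  30 nm, scale 2 nm) — LPL prefers large triglyceride-rich particles;
* HL lipolysis at rate k_hl·f_H(d), f_H a falling logistic (midpoint
  26 nm, scale 2 nm) — HL prefers small remnants;
* liver attachment at rate k_att·g(d), g ≡ 1 by default (configurable
  hook);
* uptake of attached particles at rate k_upt, with no detachment.

A lipolysis event shrinks a particle by exactly one bin; lipolysis out of
the smallest bin leaves the system. The steady-state balance in bin *i*
(bins ordered small → large) is

    (λ_i + a_i) · c_i = P_i + λ_{i+1} · c_{i+1},   λ_{n+1} c_{n+1} = 0,

solved by downward recursion from the largest bin; this equals the dense
bidiagonal linear solve to 1e-9 (tested). Particle number is conserved:
production = uptake + smallest-bin lipolysis exit, to 1e-10 relative.

**Assumptions.** One-bin shrink per lipolysis event (a discrete stand-in
for continuous size drift); first-order kinetics throughout; no particle
detachment from the liver; no HDL compartment; no compositional
(triglyceride/cholesterol) sub-model.

**Identifiability.** Concentrations are invariant under joint rescaling
of {f_prod_total, k_lpl, k_hl, k_att, k_upt}; only ratios are meaningful.
The canonical form fixes f_prod_total = 1. Additionally, because
attached particles never detach, k_upt affects only the (unobserved)
liver-attached pool and is not identifiable from a plasma profile; the
canonical form therefore ties k_upt = k_att, and the synthetic population
uses the same convention. All indicators are invariant under the
rescaling (property-tested to 1e-12), so neither convention affects any
downstream result.

## Inverse fitting

Five free parameters (prod_mu, prod_sigma, k_lpl, k_hl, k_att) are
optimized in log space by trust-region least squares
(`scipy.optimize.least_squares`, method `trf`, ftol 1e-12) on relative
subclass residuals (model − obs)/(obs + ε), ε = 1e-6 nmol/L. Ten
multi-starts are drawn from a seeded Latin hypercube; the rate-constant
start box is centred on 1/(total observed concentration), the scale the
balance equation itself implies for unit-production parameters, spanning
±3 log units; production-location starts span the interior of the grid.
Bounds are [1e-6, 1e6] per canonical parameter — wide, because with
f_prod_total = 1 and realistic particle numbers (~3·10³ nmol/L) the true
canonical attachment rate sits near 1e-4, and a tighter box would clip
it. The search stops early once a start reaches objective < 1e-16.
Noise-free profiles are recovered to ~1e-13 relative; under 8%
multiplicative noise the median relative error over 100 replicate fits is
≈ 6% for VLDL_E and ≈ 13% for VLDL_H.

Profiles with fewer than 4 nonzero subclasses raise an unfittable-profile
error; if no start converges, a convergence error carries the best-effort
parameters flagged unreliable.

## Indicators

For each of three ranges (VLDL-to-LDL, VLDL-only, IDL-to-LDL) the six
process fluxes are aggregated (F_prod = ΣP_i, F_LPL = Σk_lpl f_L c_i,
F_HL = Σk_hl f_H c_i, F_att = F_upt = Σa_i c_i, total = LPL + HL), plus
the lipolysis influx across the range's upper boundary (zero when the
range contains the largest bin) and the concentration-weighted mean HL
rate constant. All 15 unordered pair ratios per range (45 total) plus
VLDL_E and VLDL_H form the candidate indicator matrix; zero-denominator
ratios are stored as NaN, never imputed.

Note that the range-summed lipolysis flux counts every one-bin shrink
step, so VLDL_E is the mean number of LPL lipolysis steps per incoming
VLDL particle; on a fine grid with slow attachment it exceeds 1 (typical
values ~15–25 on the default grid). It is bounded by 1 only when each
particle is lipolysed at most once inside the range (e.g. on coarse
grids). Its value is grid-resolution-dependent, but monotone in k_lpl
and scale-invariant, which is what its use as a between-subject marker
requires. "Rate constant of hepatic VLDL lipolysis" in VLDL_H is read
as the concentration-weighted mean HL rate constant over VLDL bins, and
"rate of VLDL attachment" as the attachment flux; both readings are
scale-invariant and isolated behind one function, so an alternative
reading is a one-line change.

## Synthetic cohort

The generator emulates a Framingham-offspring-style population:

* **Kinetics**: log-normal population of (f_prod_total, prod_mu,
  prod_sigma, k_lpl, k_hl, k_att); default medians (80 nmol/L/h, 45 nm,
  0.25, 2.0/h, 0.15/h, 0.015/h) chosen to give NMR-plausible profiles
  (LDL particle number well above VLDL); default log-SDs 0.30 (0.05 for
  prod_mu, 0.15 for prod_sigma), diagonal covariance (full covariance
  accepted via config).
* **Measurement**: each subclass multiplied by an independent unit-mean
  log-normal factor with CV `noise_cv` (default 0.08).
* **Risk factors**: sex-specific Gaussian marginals (age, BP, BMI,
  glucose, cholesterol) and Bernoulli prevalences (BP medication,
  smoking variables) matching the published baseline table; truncation
  at physiological bounds (age 25–80, SBP 80–250, glucose 40–400, BMI
  15–60, cigarettes 0–80). Cigarettes/day are zero-inflated: only
  smokers (prevalence 21.2%) get a positive count, with smoker moments
  derived from the configured overall mean/SD. Physician BP readings
  are the nurse reading plus independent measurement error. NMR
  cholesterol columns are coupled to the simulated profile (VLDL
  cholesterol ∝ VLDL particle number; LDLc by subtraction), so
  dataset-2 markers carry realistic profile-derived information.
* **Outcome**: Bernoulli with logit linear in internally standardized
  covariates; the intercept is calibrated by bisection so the expected
  event rate matches the target (default 145/1981 ≈ 7.32%) to 0.1%
  absolute. Default per-SD log-odds: age +0.65, SBP +0.35,
  cigarettes +0.30, glucose +0.25, BP medication +0.25, LDLc +0.45,
  HDLc −0.40, VLDL_E −0.40, VLDL_H −0.35 — qualitative structure (lower
  indicator, higher risk) with magnitudes giving full-model AUC ≈ 0.8 at
  n ≈ 2000.

Risk factors are drawn independently given sex; the generator does not
copy any real covariance structure, censoring, or repeated-visit
correlation. Passing tests on this cohort therefore shows the pipeline
detects the signal it plants under honest noise — not that any real
population carries that signal.

## Risk model and selection

The classifier is `sklearn.svm.SVC` (RBF kernel, L2-regularized hinge
loss) on features standardized by training-split statistics, with
balanced class weights for the rare outcome. The kernel bandwidth is
parameterized as gamma = m/n_features; (C, m) are grid-searched
(C ∈ {0.5, 2, 8}, m ∈ {0.01, 0.03, 0.1, 0.3}) on the selection split at
the start of each protocol stage and held fixed within the stage (the
near-linear end of the bandwidth grid is usually selected, and matters:
overly local kernels lose ~0.1 AUC in this event-rate regime). Platt
calibration is fitted by unregularized BFGS maximum likelihood with
Platt's target smoothing; the sigmoid is strictly monotone, so
calibrated probabilities preserve AUC exactly.

Selection runs on a seeded stratified 2:1 train/test split: stage 1
forces age and sex and forward-selects classical variables to six by
test-split AUC (fixed count); stage 2 adds two cholesterol markers the
same way; stage 3 adds indicators only while the AUC gain is ≥ δ = 0.005
and the candidate has r² < 0.25 with every included variable (computed on
the training split). Ties break by candidate name order. The final
model's probabilities come from seeded 10-fold stratified
cross-validation on the complete dataset, with per-fold Platt
calibration. The five benchmark variable lists (conventional without
cholesterol; conventional; LDLc; LDLc+HDLc; LDLc+HDLc+indicators) can
also be fitted directly with fixed features.

A caveat measured during development: with a ~7% event rate, the null
distribution of the single-split AUC gain from one added feature has
SD ≈ 0.006 at n = 1000–2000 (for the SVM and for a logistic refit
alike), so the δ = 0.005 gate admits a pure-noise candidate with
probability ≈ 5–9% per candidate. Stage-3 false selection is therefore
rare but not negligible; at n = 2000 with two noise candidates, no
selection occurs in ≈ 95% of replicates.

## Evaluation statistics

* **AUC**: midrank (ties = ½) formula, equal to exhaustive pair counting
  (tested); SE by DeLong's structural components.
* **DeLong test**: paired structural-component covariance; z = ΔAUC/SE,
  two-sided normal p. A plain z-test from an externally supplied
  (Δ, SE) pair is exposed for worked examples, as is an exact binomial
  sign test on discordant concordance pairs (offered alongside, not used
  for headline numbers).
* **NRI**: risk classes [0, .06), [.06, .20), [.20, 1] (half-open,
  lower-inclusive); NRI = [P(up|event) − P(down|event)] +
  [P(down|non-event) − P(up|non-event)]; group-wise asymptotic SEs
  (p_up + p_down − (p_up − p_down)²)/n and z-tests, combined SE by
  quadrature.
* **IDI**: difference of group-mean probability changes; SE from the two
  groups' paired-difference variances; relative IDI divides by model 1's
  discrimination slope, which makes IDI / relative-IDI constant across
  comparisons sharing model 1 (property-tested).
* **Intermediate-risk subgroup**: NRI restricted to subjects with
  model-1 calibrated probability in [.06, .20); an empty subgroup
  returns an explicit empty result. Calibrated (post-Platt)
  probabilities define the subgroup.
* **Report tables**: four CSVs mirroring the published layouts; the
  "% incremental AUC improvement from random" column is
  100·(AUC_m − AUC_baseline)/(AUC_m − 0.5) with the no-cholesterol
  conventional model as baseline — this reverse-engineered form
  reproduces every printed value of that column (12.2, 11.0, 12.8,
  17.0).

## Numerical choices and degenerate inputs

Production densities are normalized in log space (stable for extreme
location/width during optimization). A bin with zero total outflow but
nonzero inflow has no steady state and raises a degenerate-model error;
zero rate constants are otherwise allowed (absent process), while
negative or non-finite parameters are rejected. Zero-denominator
indicator ratios propagate as NaN. The outcome-intercept bisection
searches [−200, 200] and raises if the target rate is unreachable
(e.g. under an extreme coefficient). All randomness flows from explicit
seeds (`numpy.random.default_rng` / `SeedSequence.spawn`); cohort
generation, selection, and cross-validation are pure functions of
(config, seed), and repeated runs produce byte-identical files.

## Problem sizes

Defaults used by the test suite and acceptance script: 60-bin grid;
50 subjects for noise-free recovery; 100 replicate fits at 8% noise;
1000 draws for conservation; 1000 replicates at n = 500 for the
null calibration of NRI/IDI; n = 2000 cohorts (100 replicates for the
stage-3 null) for the selection protocol. These sizes give Monte-Carlo
tolerances well inside the asserted bounds while keeping a full run in
the minutes range on one CPU.

## Known limitations

* VLDL_E depends on grid resolution (it counts discrete lipolysis
  steps); comparisons are only meaningful within one grid.
* k_upt is reported by convention (= k_att), not measured.
* The synthetic cohort has independent risk factors given sex and an
  uncensored binary outcome; real cohorts have covariance structure and
  censoring the generator does not emulate.
* The intermediate-risk subgroup is defined on calibrated probabilities;
  defining it pre-calibration would change subgroup membership.
* Single-split AUC forward selection is noisy at rare event rates (see
  above); results at n ≲ 1000 should be treated as exploratory.
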
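# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `qalbench`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Synthetic cohort generator

The generator (`qalbench.cohort`) emulates a 200-patient rectal-resection
cohort with binary exposures DM, Smoking, ACSP, NoCoil, ICG and a binary
LEAK outcome.

**Exposure model.** DM, Smoking, ACSP and NoCoil are independent
Bernoulli draws at prevalences 0.18, 0.17, 0.325 and 0.275. ICG is drawn
conditionally on NoCoil so that the population ICG×NoCoil odds ratio
equals a configurable value while the 0.50 ICG marginal is preserved;
the joint cell probabilities come from Plackett's closed-form solution
of the margins-plus-odds-ratio system. The default coupling odds ratio
is **4.0**: the two interventions are applied together in practice and a
four-fold odds increase expresses a strong but not deterministic
association; no published value exists, so this is a package choice.
All other pairwise dependencies are left at independence because the
real joint distribution is unpublished.

**Outcome model.** LEAK is Bernoulli with probability
`logistic(b0 + Σ β_j x_j)` where the x_j are *protective-state*
indicators (1 = comorbidity absent / intervention applied) and the β_j
are the published negative slopes (−1.149 DM, −1.429 Smoking, −0.952
ACSP, −1.610 NoCoil). This coding is a deliberate reconstruction: the
source material's equation and its odds-ratio statements disagree in
sign, and only the protective coding reproduces every quoted odds ratio
(e.g. 5.00 for the tube) *and* the quoted extreme-patient probabilities
(0.8078 all-risk, 0.0240 all-protective) simultaneously. Reports emitted
by the package flag the coding in their metadata.

**Intercept calibration.** The published slopes with independent
exposures and intercept 1.436 imply a marginal leak prevalence well
above the cohort's ≈14%, so by default the intercept is recalibrated:
the expected prevalence is computed by exact enumeration of the 2⁴
exposure cells and a bracketed root solve (Brent) adjusts b0 until it
equals the target (default 0.14) to within 1e−10. The expectation is
strictly monotone in b0, so the solve is unconditionally stable. The
printed intercept remains selectable (`target_prevalence=None`) for
fidelity runs.

**Continuous covariates.** CRP, BMI, LN, Age and HB can be generated
per outcome group as log-normals matched to the published group medians
and IQRs (σ = ln(q3/q1)/(2·0.6745)). They feed only the rank-based
comparison stage; no temporal/kinetic structure is modelled.

What passing tests show — and do not. The generator reproduces the
published *marginal* structure and the assumed logistic outcome law.
Real cohorts have correlated comorbidities, informative missingness and
outcome mechanisms that are not exactly logistic; agreement of any model
ranking on synthetic data therefore demonstrates correctness of the
pipeline, not clinical transportability.

## Univariate statistics

2×2 tables put the risk category (comorbidity present, intervention
absent) in the first row. Relative risk uses the Katz log-normal
interval. Independence tests route by expected counts: uncorrected
Pearson chi-square (df = 1) when all expected cells are ≥ 5 — the
uncorrected statistic is what reproduces the published p-values — and
the two-sided Fisher exact test otherwise, since only an exact test can
report p > 0.999 on sparse rows. Continuous covariates use the
Mann–Whitney test (exact enumeration when both groups have ≤ 10
untied observations, tie-corrected normal approximation otherwise) with
the Hodges–Lehmann estimate (median of pairwise differences) and its
conventional rank-order 95% interval.

## Logistic modelling

`fit_logistic` is a damped Newton/IRLS maximiser of the Bernoulli
log-likelihood with a 1e−8 ridge jitter on the information matrix for
near-separation stability; coefficients exceeding |40| raise a
separation error rather than returning a divergent fit. Wald p-values
use the normal reference, standard for ML logistic fits. AIC = 2k − 2ℓ
and BIC = k·ln n − 2ℓ with k counting the intercept — the convention
verified against the published (ℓ, AIC) pairs. Stepwise selection is
backward-only elimination on AIC or BIC; the intercept-only model is an
admissible endpoint. Odds ratios are reported risky-vs-protective,
OR = exp(|β|), matching the coding above.

## Quantum simulator

States live on n ≤ ~10 qubits with qubit 0 as the leftmost bitstring
bit. The noiseless path evolves statevectors; the noisy path evolves
density matrices, fusing each single-qubit gate with its trailing
depolarizing channel into a single 4×4 superoperator on that qubit's
row/column index pair (an algebraically exact rewrite that saves
several tensor contractions per gate). CX gates are applied noiselessly
— errors attach to single-qubit gates only. Channel validity
(ΣK†K = I to 1e−12) is asserted on entry.

Circuit conventions:

* ZZ feature map, per repetition: H on every qubit, P(2x_i) on every
  qubit, then for each pair i < j in lexicographic order
  CX(i,j) · P(2φ(x_i,x_j)) on j · CX(i,j). The default data map is
  φ = x_i·x_j; the (π−x_i)(π−x_j) dialect is selectable. Binary
  features are encoded unscaled, in radians.
* RealAmplitudes: (reps+1) RY layers interleaved with linear CX chains;
  EfficientSU2: rotation layers of RY then RZ per qubit. Depth is the
  longest path of the gate-dependency DAG under as-soon-as-possible
  layering. The composed network's depth is reported both as the sum of
  component depths (the convention behind the quoted 28/32 totals) and
  as the ASAP depth of the concatenation, which may interleave at the
  boundary.
* Measurement decoding: class 1 = odd bitstring parity. The original
  decoding is unstated; parity is the conventional choice and is
  documented as such. In shot mode the parity frequency is drawn as a
  seeded binomial at the exact parity probability, which is
  distributionally identical to sampling bitstrings and reducing them.

Out of scope: T1/T2 relaxation, readout error, transpilation to hardware
gate sets.

## Training

The loss is mean binary cross-entropy of the parity probability —
consistent with log-loss reporting and with final losses straddling
ln 2; probabilities are clipped to [1e−12, 1−1e−12]. Parameters start
uniform in [−π, π]; each configuration runs 10 independent seeded runs
and reports mean ± population sd of the final losses. The split is
stratified 70/30, shared by all models of a benchmark run for paired
comparison.

Optimizers (75 iterations each):

* **CMA-ES** — native (μ/μ_w, λ) implementation, σ0 = 0.15,
  λ = ⌈4 + 3 ln m⌉ (natural log, the CMA-ES convention), parent
  fraction 0.5, mean-update factor 1.0, damping factor 1.0; remaining
  constants (c_σ, d_σ, c_c, c_1, c_μ) follow the standard defaults. A
  non-finite objective value triggers one resample, then an abort.
* **SPSA** — Rademacher perturbations, gains a_k = a/(k+1+A)^0.602,
  c_k = c/(k+1)^0.101 with c = 0.1 and A = 0.1·max_iter; `a` is
  calibrated from a 5-probe gradient-magnitude estimate so the first
  step moves ≈0.25, a moderate fraction of the [−π, π] scale. Blocking
  rejects steps worsening the reference loss by more than 1e−3; on
  rejection the reference is re-evaluated so a lucky noise draw cannot
  freeze the chain (stochastic objectives are never cached). The run
  terminates early after 10 consecutive blocked steps — the termination
  window's semantics are unspecified in the source material, and this
  reading ties it to the blocking mechanism it is configured alongside.
  The best-seen solution is tracked over accepted iterates only, since
  a noisy minimum over gradient-probe points is an artefact.
* **BFGS (L-BFGS-B), SLSQP, COBYLA** — scipy implementations with
  maxiter 75 and ftol 1e−4, finite-difference gradients on the
  (possibly stochastic) objective.

Because the four model features are binary, encoded feature-map states
are cached per distinct input row (≤ 2⁴ encodings per cohort) and the
ansatz is applied to the cached batch; this changes nothing numerically
and makes the 100-run grids tractable on one CPU.

## Evaluation metrics

AUC uses the Mann–Whitney midrank identity (ties count half). The fixed
sensitivity protocol: candidate thresholds are the distinct score
values under the rule `score ≥ t` (ties predicted positive); among
candidates with sensitivity ≥ 0.83, the F-beta maximiser wins (β = 2 by
default, weighting recall four times precision — the sensitivity-first
intent; ties break to higher specificity, then higher threshold); if
the target is unattainable the maximal-sensitivity threshold is used.
Count R² is defined as accuracy at the operating threshold, not at 0.5.
McKelvey–Zavoina R² is computed on the latent logit(p) scale with
residual variance π²/3. Degenerate rates (empty denominators) are
reported as NaN, never as 0, and any NaN poisons the corresponding
multi-run aggregate with an explicit "undefined" flag. Final-loss
aggregation over training runs uses the population sd; metric
aggregation over run reports uses the sample sd (both conventions are
fixed by their respective worked examples).

## Interpretability

Permutation importance shuffles one feature column per repeat (100
repeats, fresh permutation each time) and averages the AUC drop;
negative mean drops are clipped at 0 before normalising the scores to
sum to 1, so the output is a distribution over features. If no feature
carries signal the normalised scores are NaN. Gradient importance adds
ε = 0.01 (raw feature scale, before angle encoding) to one feature at a
time and averages |Δprobability|; a constant predictor is an error.
Importance analysis evaluates the QNN in exact-probability mode by
default so perturbation effects are not confounded with shot noise;
shot mode remains available.

## Classical baselines

LR reuses the package's own logistic fitter. LDA and GNB are closed-form
Gaussian classifiers (pooled covariance; per-feature variances with a
1e−9 floor). AdaBoost uses depth-1 stumps with exponential-loss weight
updates and maps the ensemble margin to a probability via the logistic
of twice the margin. The MLP has one hidden layer of 8 logistic units
trained by full-batch gradient descent on BCE with weight decay 1e−4
and a seeded initialisation. These are fixed, documented settings; the
original study's tuned hyperparameters are unavailable, so parity with
its classical rows is explicitly not claimed.

## Problem sizes

The default benchmark trains 2 ansatze × 5 optimizers × 10 runs on an
n = 200 cohort in exact-probability mode; convergence checks in the
test suite use n = 200,000 draws for marginal prevalences (binomial se
≈ 0.001), n = 50,000 for logistic parameter recovery (±0.05), 10,000
simulated null tables for the chi-square type-I rate, and 5,000
replicates for the likelihood-ratio null rejection rate. These sizes
put Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The exposure joint distribution beyond the ICG–NoCoil pair is
  independent by construction.
* Parity decoding and the ε, β, coupling-odds-ratio defaults are
  conventions where the source material is silent; all are configurable.
* The density-matrix path scales as 4ⁿ; it is intended for the 4-qubit
  clinical model, not large registers.
* Published real-cohort performance tables are not reproducible from
  synthetic data and are covered structurally (e.g. final loss below
  ln 2 for every optimizer-ansatz pair), not numerically.
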
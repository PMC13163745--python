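# Methods

This note records the modelling choices behind `balfprofiler`, the defaults
that matter, and what the synthetic tests do and do not demonstrate.

## Fingerprints and binding indices

A fingerprint is the 10-vector of binding indices for five
carbohydrate-functionalized fluorescent ligands (L1–L5; positions 1, 2 and 5
are mannose-type, 3 and 4 galactose-type), measured natively and again under
mannan competition (ML1–ML5). The binding index is
`100·(F_initial − F_final)/F_initial`, the percent of ligand depleted by
cell binding. Indices live on the 0–100 percent scale throughout. A negative
raw index (final signal above initial, which noisy plates produce) is
measurement noise by construction, so it is clipped to 0 with a logged
warning rather than rejected. Competed indices are treated as binding
measured with mannan present, not as percent inhibition.

Ligand identity is positional plus a header name; a table whose header
departs from `sample_id,L1..L5,ML1..ML5` is an error, never a silent
reorder. Tables are written with 6 significant digits, which makes
write→read→write byte-stable.

## Deconvolution

`S = c₁V(M0) + c₂V(M1) + c₃V(M2a) + ε` with `cᵢ ≥ 0` is solved by
Lawson–Hanson NNLS (scipy). The problem is convex; with a rank-3 basis the
minimiser is unique, and the basis is rank-checked at load time.
Coefficients are *not* constrained to sum to 1 during optimisation;
normalisation is post hoc. No per-ligand weighting is applied.

The residual fraction is `100·‖ε‖₂/‖S‖₂` (L2 norm; capped at 100), and the
remaining `100 − residual` is allocated proportionally to the coefficients,
so the four reported percentages always sum to 100. If all coefficients are
zero the sample is 100% residual. A zero-norm fingerprint is a degenerate
sample and an error. The residual is a feature, not noise: it aggregates
M2b/M2c/M2d and transitional states the tripartite basis deliberately
omits, and a high residual reads as an uncommitted, plastic compartment.

## Severity rubric

Reference intervals (closed on both ends): WBC 4.5–12.0 ×10⁹/L, neutrophils
37–60%, eosinophils 1–5%, monocytes 2–10%; CRP is one-sided, normal below
5.0 mg/L, so exactly 5.0 is flagged. A parameter scores 1 only when strictly
outside its interval — boundary values are normal (4.6% eosinophils at the
upper limit does not flag; 36.0% neutrophils just below the range does).
The score is the unweighted sum over the five parameters; weighted variants
are deliberately not offered. Fever never enters the automatic score.
Escalations that depart from the rubric are possible only through an
explicit override carrying a free-text note, preserving both
reproducibility and the audit trail; the packaged 10-patient cohort ships
with its single override (a febrile patient with CRP 44.7 mg/L escalated
from rubric score 1 to 3). Eosinopenia (<1%) flags through the generic
interval rule; only eosinophilia ≥ 5.0% defines the allergic endotype.

## Discriminant model

Features are z-scored with training statistics (constant features get unit
scale and stay inert); z-scoring is chosen for scale invariance since the
ligand indices have heterogeneous dynamic ranges. Within-class scatter
`S_W` is shrunk to `(1−γ)S_W + γ·diag(S_W)` with default γ = 0.1 — with 10
features and small classes the pooled scatter is often ill-conditioned, and
shrinking toward the diagonal preserves the per-feature variances. γ is a
config knob, 0 recovers plain Fisher LDA.

The canonical axes solve the generalised eigenproblem `S_B v = λ S_W v`
(scipy `eigh`); up to `min(k−1, 10)` axes exist, the model keeps 1 or 2.
Axes are unit-normalised; explained variance ratios are the normalised
eigenvalues. Sign conventions are deterministic: LD1 is oriented so the
worst prognostic class present has the higher mean LD1 (higher = worse;
negative shifts mean consolidation toward the favourable state), and
further axes make their largest-magnitude loading positive.

Numerical floor: when classes are point masses, `S_W` (and its diagonal) is
exactly zero and the shrinkage target cannot regularise it; a tiny absolute
ridge (1e-8-scaled identity) is then added once. It is invisible for any
non-degenerate fit. If even that fails, the error advises increasing γ.
A fit with no between-class variance (identical class means) is flagged
degenerate rather than silently returning noise axes; projection and
classification refuse degenerate models.

Classification is prior-free nearest centroid in canonical space — the
decision regions are convex polygons bounded by perpendicular bisectors,
matching the mesh-grid visualisation. Ties break toward the worse
prognosis (conservative triage). LOOCV refits per left-out patient; folds
whose removal would leave a class with fewer than two members are skipped
and counted in `skipped_folds`, never imputed. Accuracy is reported to two
decimals.

The LD1–severity relation is summarised by the product-moment correlation
and a two-parameter exponential fit `severity ≈ a·exp(b·LD1)` (no offset
term), fitted by nonlinear least squares initialised from a log-linear
regression on the positive severities; R² is computed on the original
scale. The no-offset form is the simplest curve consistent with
accelerating deterioration at high LD1.

## Remodeling statistics

Phenotype deltas are componentwise treated-minus-intact percentages and sum
to zero by construction. The cohort-level test is a one-sample t-test on
the deltas — algebraically identical to a paired t-test on intact vs
treated — with two-sided p-values. No multiplicity correction is applied by
default (per-agent tests are reported raw); a Benjamini–Hochberg option
exists for cohort-wide screens. Centroid profiles are unweighted means of
the member fingerprints of the Good and Poor strata.

## Synthetic cohort generator

The generator's defaults are the study conditions the rest of the package
assumes; they are declared here once and not tuned per test.

* **Reference basis.** Templates follow the receptor logic: M2a binds
  strongly across the panel and is profoundly mannan-suppressed on the
  mannose ligands (CD206/CD209-rich); M1 is low-to-moderate,
  galactose-leaning, with near-zero suppression (mannose receptors scarcely
  expressed); M0 is uniformly low with moderate suppression. Each draw
  jitters the templates (sd 2.5 pp), enforces competed ≤ native, and
  resamples (≤100 tries) if the ordering rules or the rank-3 requirement
  break. The templates were chosen to be well-conditioned (condition number
  ≈ 8 for the design matrix) so that deconvolution does not amplify plate
  noise; a nearly collinear M0/M1 pair would be both biologically wrong
  (the phenotypes differ in receptor repertoire, not just brightness) and
  numerically fragile.
* **Patients.** `S = Σ wᵢVᵢ + a·A + η`, clipped to [0, 100]. `A` is one
  fixed direction orthogonalised against the basis span and scaled to 0.6×
  the mean basis row norm, so a unit atypical weight contributes signal of
  the same order as a unit mixture weight; one degree of freedom stands in
  for all aggregated atypical states. η is i.i.d. Gaussian on the percent
  scale, default sd 2 — a plate-to-plate repeatability figure typical of
  fluorescence depletion assays; the assay's true noise model is unknown,
  so this is a declared assumption.
* **Classes.** Default cohort: 72 patients split 22/39/11
  (Good/Neutral/Poor) by largest-remainder rounding. Mixture recipes:
  Good (0.40, 0.15, 0.20 | 0.25 atypical) — balanced with a sizeable
  uncommitted share (preserved plasticity); Neutral (0.28, 0.40, 0.20 |
  0.12); Poor (0.08, 0.68, 0.06 | 0.18) — M1-dominant and rigid.
  Per-patient weight jitter sd 0.03.
* **Separation.** The `separation` knob is the minimum over class pairs of
  centroid distance in fingerprint space divided by the within-class sd
  along that pair's direction (measurement noise plus propagated weight
  jitter). Recipes are rescaled about their mean so this minimum equals the
  requested value; the default 4 yields LOOCV accuracies of 98.6–100%
  across seeds.
* **Blood panels** are drawn so the rubric reproduces the intended class
  exactly: Good panels have 0 out-of-range parameters, Neutral 1–2, Poor
  3–5, with values drawn safely inside or outside the reference windows.
* **Treatment effects** are maps on the true weights, then the fingerprint
  is regenerated under the same noise model: doxycycline-like
  (M1 → 0.1·M1, M2a += 0.8·M1, M0 gains part of M1 and of the depleted
  atypical pool, atypical → 0.4·atypical — an M1→M2a repolarisation with
  residual depletion), MUmb-like (M0 → M1 activation), paclitaxel-like
  (deactivation toward M0), and identity. With the same seed the identity
  effect reproduces the intact fingerprint bit-for-bit.
* **Seeding.** All randomness flows from one seed through numpy
  `SeedSequence` spawn keys (a counter-based split), so each stream is
  reproducible in isolation and cohort generation is byte-deterministic.

What passing synthetic tests show — and what they do not: they demonstrate
that the estimators recover the structure the generator emits (exact
mixtures, severity-linked classes, directional treatment effects) at
realistic noise. Real BALF data adds ligand-correlated noise, batch
effects, basis mismatch between donor-derived references and patient
macrophages, and class overlap that no separation knob controls; clinical
performance figures therefore cannot be inferred from these tests.

## Problem sizes and runtime

Default sizes keep the whole suite fast on one CPU: 72-patient cohorts for
discriminant work, 100-problem oracle comparisons, 200-replicate
directionality and noise-monotonicity checks, 500-patient recovery error.
The acceptance script uses the same sizes.

## Known limitations

* The basis is donor-derived M0/M1/M2a only; M2b/M2c/M2d are observable
  solely through the residual, by design.
* The severity rubric is unweighted and interval-based; it reproduces
  printed clinical scores only up to explicitly logged overrides.
* The exponential LD1–severity fit has no offset term and is undefined for
  constant inputs; for cohorts whose severity is mostly zero the log-linear
  initialisation falls back to a flat curve.
* Nearest-centroid classification ignores class priors and covariance
  anisotropy in canonical space; this matches the intended geometric
  decision regions but is not the Bayes rule under unequal priors.
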
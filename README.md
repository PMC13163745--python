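# balfprofiler

Ex vivo macrophage phenotype profiling for bronchoalveolar lavage fluid
(BALF) samples: from competitive ligand-binding fingerprints to phenotype
fractions, prognosis classes and drug-remodeling vectors.

## The problem

Alveolar macrophages dominate the cellular content of BALF and their
polarization state — resting M0, pro-inflammatory M1, alternatively
activated M2a, plus atypical/transitional variants — tracks the clinical
trajectory of obstructive respiratory disease. A panel of five
carbohydrate-functionalized fluorescent ligands (mannose- and
galactose-type), each measured with and without mannan competition for the
mannose-recognising receptors (CD206/CD209), yields a 10-index binding
fingerprint per sample. This package implements the complete analysis that
turns those fingerprints into clinical readouts, for laboratory scientists
and biostatisticians working with such profiling data.

## The model

**Binding index.** For each ligand, the percent bound is
`100 · (F_initial − F_final) / F_initial`, clipped to [0, 100].

**Phenotype deconvolution.** A sample fingerprint *S* is modelled as a
non-negative mixture of reference signatures,

    S = c₁·V(M0) + c₂·V(M1) + c₃·V(M2a) + ε,   cᵢ ≥ 0,

solved by non-negative least squares. The residual fraction
`100·‖ε‖₂/‖S‖₂` quantifies atypical/transitional states the tripartite
basis deliberately does not model; the remaining mass is split
proportionally to the cᵢ, so the four reported percentages sum to 100.

**Severity rubric.** An unweighted binary score (0–5): one point per blood
parameter (WBC, neutrophil %, eosinophil %, monocyte %, CRP) outside its
reference interval; 0 → Good, 1–2 → Neutral, ≥3 → Poor prognosis. Fever is
recorded but never scored; clinical escalations are explicit, note-carrying
overrides. Eosinophils ≥ 5.0% flag the allergic endotype.

**Prognostic discriminant.** A shrunken Fisher discriminant on z-scored
fingerprints: within-class scatter S_W is shrunk to
`(1−γ)·S_W + γ·diag(S_W)` and the canonical axes LD1/LD2 are the leading
eigenvectors of `S_W⁻¹·S_B`. LD1 is oriented so higher = worse prognosis.
Classification is prior-free nearest centroid (ties break toward the worse
class); validation is patient-level leave-one-out cross-validation.

**Remodeling.** Drug effects are quantified as treated-minus-intact
phenotype deltas (summing to zero), therapeutic vectors in canonical space
(negative ΔLD1 = movement toward the Good cluster), centroid correlations
against Good/Poor reference profiles, and cohort-level paired t-tests.

A synthetic-cohort generator reproduces the assumed data structure —
non-negative mixtures of receptor-logic-consistent basis signatures, an
out-of-span "atypical" component, Gaussian measurement noise, and
severity-linked class recipes — so every stage is testable end to end.

## Worked example

```python
import balfprofiler as bp

basis = bp.generate_reference_basis(seed=7)
fp, _ = bp.generate_patient(weights=[0.20, 0.55, 0.10], atypical_weight=0.15,
                            noise_sd=2.0, basis=basis, seed=3)
comp = bp.deconvolve(fp, basis)
print(comp.m0_pct, comp.m1_pct, comp.m2a_pct, comp.residual_pct)
```

prints (rounded) `23.8 57.5 6.6 12.2` — an M1-dominant split mirroring the
generating weights (20/55/10 plus a 0.15-weight atypical component), with
the residual absorbing the atypical signal and measurement noise. The
scripts in `examples/` walk through each capability; for instance
`python examples/03_discriminant_prognosis.py` trains the discriminant on a
72-patient synthetic cohort (22 Good / 39 Neutral / 11 Poor) and prints

```
LOOCV accuracy: 100.00%  (0 folds skipped)
LD1 vs severity: Pearson r=0.879, exponential fit severity ~ 1.19*exp(0.37*LD1), R^2=0.725
```

showing the fingerprints carry the prognostic signal, with LD1 acting as a
continuous severity biomarker.

## Command line

```bash
balfprofiler simulate --seed 42 --outdir data/
balfprofiler deconvolve --fingerprints data/fingerprints.csv --basis data/basis.csv --out comp.csv
balfprofiler score --out scores.csv            # packaged 10-patient cohort
balfprofiler train --fingerprints data/fingerprints.csv --labels data/labels.csv --out model.json
balfprofiler loocv --fingerprints data/fingerprints.csv --labels data/labels.csv --out cm.csv
balfprofiler run-all --seed 42 --outdir report/
```

`run-all` chains every stage and writes a deterministic report bundle
(tables plus `manifest.json`); re-running with the same seed is
byte-identical. Exit codes: 0 success, 2 validation error, 3 numerical
error.

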
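# metabrisk

Serum NMR-metabolomic risk scoring for early breast cancer (eBC).

Blood serum carries a metabolic signature of disease burden.  `metabrisk`
implements, as a tested and reusable pipeline, an analysis in which
bucketed 1H NMR serum spectra are used to (1) train a random-forest
classifier separating relapse-free early-stage patients from metastatic
(aBC) patients, (2) read each early patient's fraction of "metastatic"
tree votes as a continuous **metabolomic risk score**, and (3) ask whether
the dichotomized risk class predicts later disease recurrence.  It is
aimed at metabolomics and biostatistics practitioners who want to apply or
stress-test this kind of vote-fraction prognostic signature.

## The model

For sample *i* with bucketed, normalized spectrum **x**ᵢ and a forest of
*T* unpruned trees (each grown on a bootstrap of the training set with
⌊√p⌋ candidate features per split, p = 456 buckets):

* risk score  sᵢ = (1/|Tᵢ|) Σ_{t ∈ Tᵢ} 1[tree_t(**x**ᵢ) = aBC],
  where Tᵢ is the whole forest for validation samples and the out-of-bag
  (OOB) trees only for training samples;
* risk class  highᵢ ⇔ sᵢ ≥ τ (pipeline default: τ = training prevalence
  of the metastatic class);
* AUC is the Mann-Whitney probability P(s_aBC > s_eBC), and the classifier
  significance is a training-label permutation test,
  p = (1 + #{permuted ≥ observed}) / (1 + n_perm);
* the recurrence-free interval (RFI: time to recurrence or BC-related
  death, which by definition follows a relapse) is compared between risk
  classes by Kaplan-Meier, log-rank and Cox models
  (HR = exp(β), Efron ties, Wald 95% CIs);
* each of 28 quantified metabolites gets a logistic model
  logit P(aBC) = β₀ + β₁·z(concentration) + β₂·(acquisition time),
  with Benjamini-Hochberg FDR control at α = 0.05 across the panel.

Preprocessing follows the serum-NMR standard: 0.02 ppm buckets over
0.2–10.0 ppm, removal of the 34-bucket residual-water window
(4.42–5.10 ppm, leaving 456 features), probabilistic quotient
normalization, and per-bucket regression removal of the acquisition-date
trend.  Because no patient-level data are distributable, a synthetic
cohort generator (140 eBC / 29 relapsed / 27 aBC by default, with a
latent "metastatic likeness" driving both metabolite shifts and relapse
hazard) makes every stage testable; see `docs/methods.md`.

## Worked example

```python
import metabrisk as mb
from metabrisk.pipeline import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(pulse_sequences=("NOESY1D",), seed=0))
m = bundle.metrics["NOESY1D"]
print(f"AUC {m['auc']:.2f}  sens {m['sensitivity']:.0%} "
      f"spec {m['specificity']:.0%}  acc {m['accuracy']:.0%}")
print(f"relapsed patients flagged high risk: "
      f"{m['validation_high_risk']}/{m['n_validation']}")
hr = bundle.survival["univariate"].set_index("term").loc["risk_class[high]"]
print(f"RFI hazard ratio, high vs low risk: "
      f"{hr['hr']:.2f} (95% CI {hr['ci_low']:.2f}-{hr['ci_high']:.2f})")
```

prints

```
AUC 0.83  sens 89% spec 63%  acc 68%
relapsed patients flagged high risk: 18/29
RFI hazard ratio, high vs low risk: 2.24 (95% CI 1.06-4.74)
```

Read: the stage classifier separates metastatic from relapse-free-early
sera with AUC 0.83 on out-of-bag votes; 18 of the 29 early patients who
later relapsed are flagged metastatic-like at baseline; and the high-risk
class carries roughly a doubled recurrence hazard in this replicate.  The
numbers vary with the seed because the cohort itself is simulated.

The same run is available from a shell:

```bash
metabrisk run-all --seed 0 --output-dir out/ --pulse-seq NOESY1D
```

with stagewise subcommands (`simulate`, `preprocess`, `score`,
`associate`, `survival`) reading and writing CSV intermediates in the
output directory.

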
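# echointerchange

Interchangeability and diagnostic-accuracy analysis for multi-reader,
multi-device echocardiographic measurements.

When an AI system reports a left ventricular ejection fraction (LVEF) from an
echocardiogram, two clinical questions follow. Can the automated measurement
**replace** a human one — i.e. is it *interchangeable* with expert analysis?
And how accurately does it **detect the reduced-EF phenotype** (LVEF ≤ 40%,
the threshold that drives heart-failure therapy)? This package implements the
statistical machinery for both questions for settings where each patient is
measured by several methods — a *method* being a device (handheld or
cart-based scanner) crossed with an analyst (AI software, the usual-care
clinical sonographer, or a blinded core-laboratory reader) — together with a
synthetic cohort generator, so the full pipeline runs and is testable without
patient data.

## The individual equivalence coefficient

For each patient with a test measurement *t* and two human reference
measurements *r₁*, *r₂* of the same parameter (a complete *triad*), define

```
Q_RR = mean over patients of (r1 − r2)²
Q_TR = mean over patients of [(t − r1)² + (t − r2)²] / 2
IEC  = (Q_TR − Q_RR) / (Q_RR / 2)
```

`Q_RR` is the disagreement among the human references; `Q_TR` the
disagreement between the test method and the references. A negative IEC means
the test method sits closer to the humans than the humans sit to each other;
IEC ≥ −2 always. Confidence intervals come from a patient-level percentile
bootstrap (2,000 resamples by default; BCa behind a flag), and
**interchangeability is declared when the upper bound of the 95% CI is
below 0.25** (strict inequality).

Around that core the package provides:

- **Diagnostic accuracy at an LVEF cutoff** — confusion matrix at ≤ 40%
  (or strict < for e.g. a 50% rule), accuracy / sensitivity / specificity /
  PPV / NPV with Wilson or exact binomial CIs, Mann–Whitney ROC AUC with
  midrank ties and a Hanley–McNeil or DeLong CI.
- **Bland–Altman agreement** — bias (test − reference), 1.96·SD limits of
  agreement, t-based CI for the mean difference, Pearson correlation.
- **Reporting rates** — the fraction of scans each method could measure at
  all, with averages over named reader pairs.
- **Utilities** — margin-of-error sample size for a prevalence estimate, and
  an exhaustive search for integer 2×2 tables consistent with a published,
  rounded metric set.
- **Synthetic cohorts** — truncated-normal LVEF mixture (≈10% reduced-EF
  prevalence), additive per-method bias and noise, per-method reporting
  probabilities, and a five-level image-quality covariate that inflates noise
  and depresses reporting. The additive model gives the population IEC in
  closed form (`closed_form_iec`), which serves as the oracle for every
  estimator.

## Worked example

```python
from echointerchange import (
    CohortSpec, simulate_cohort, select_triads, bootstrap_iec_ci,
    reporting_rates, confusion_at_cutoff, accuracy_metrics, empirical_auc,
    MethodId, sample_size_prevalence,
)

HH_AI   = MethodId("handheld", "ai")
CLIN    = MethodId("cart", "human_clinical")
CORELAB = MethodId("cart", "human_corelab_1")

gen = simulate_cohort(CohortSpec(n_patients=867, seed=1))

rr = reporting_rates(gen.cohort, "lvef")
print({k: rr.display_pct(k) for k in rr.pair_averages})
# {'handheld_corelab_avg': 76, 'cart_human_avg': 75}

triads = select_triads(gen.cohort, "lvef", HH_AI, (CLIN, CORELAB))
res = bootstrap_iec_ci(triads, n_boot=2000, seed=1)
print(f"n={res.n_triads}  IEC={res.iec:.2f} "
      f"(95% CI {res.ci_low:.2f}, {res.ci_high:.2f})  "
      f"interchangeable={res.interchangeable}")
# n=301  IEC=-0.30 (95% CI -0.56, 0.01)  interchangeable=True

print(sample_size_prevalence(0.10, 0.02, 0.95))
# 864
```

The IEC of −0.30 says the simulated AI-handheld LVEF disagrees with the two
human cart readings *less* than those humans disagree with each other; since
the CI's upper bound (0.01) is below 0.25, the methods are declared
interchangeable on this cohort. 301 of 867 patients contribute a complete
triad because each method reports only 61–83% of scans. The 864 is the cohort
size needed to estimate a 10% prevalence to within a 2-point margin of error
at 95% confidence.

The same analyses are available from a CLI
(`echointerchange simulate|rates|accuracy|iec|agreement|report`); the
`report` subcommand runs every stage — reporting rates, the ≤ 40% primary
endpoint, the IEC arms, agreement, and IEC stratified by image quality — and
writes one CSV/JSON pair per section:

```sh
echointerchange report --n-patients 867 --seed 1 --outdir out/
```

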
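# pulsespec

Harmonic spectral analysis of radial arterial blood-pressure waveforms (BPW)
for cognitive screening: a tested, reusable pipeline covering synthetic
cohort generation, beat segmentation, spectral-index extraction, group
statistics, cross-validated machine-learning classification, and regression
of classifier output against cognitive score.

## The scientific problem

Arterial stiffening accompanies dementia, and stiffness changes reshape how
the pulse wave propagates to distal measurement sites. A 3-minute radial
pressure recording can therefore carry information about cognitive status.
The analysis decomposes each cardiac beat into its first ten Fourier
harmonics of the beat's own fundamental frequency and summarizes a recording
by four index families per harmonic *n* = 1…10 (40 indices per subject):

- **Cₙ** — amplitude proportion: the harmonic-*n* amplitude as a percentage
  of a reference (the fundamental, or the total harmonic amplitude), in %;
- **CVₙ** — coefficient of variation of Cₙ across beats (beat-to-beat
  amplitude variability), in %;
- **Pₙ** — phase angle of harmonic *n* relative to the beat onset (pulse
  foot), cosine convention, degrees in (−180, 180];
- **Pₙ_SD** — standard deviation of Pₙ across beats (phase stability),
  degrees.

Stiffer, less-regulated vasculature shifts energy into higher harmonics and
raises beat-to-beat variability, so impaired groups show larger high-order
Cₙ, CVₙ and Pₙ_SD. The 40-index vectors feed eight classifier families
(SVM, MLP, GNB, DT, RF, LR, LDA, KNN) evaluated by subject-level threefold
cross-validation (AD patients = class 1, controls = class 0), and the
trained model's AD probability for external community cohorts is regressed
on the Mini-Mental State Examination score (MMSE, 0–30; lower = worse) by
OLS with an F-test.

Because clinical recordings of this kind are not publicly distributable,
the package ships a first-class synthetic generator: quasi-periodic beats
built from a 10-harmonic cosine series with configurable per-harmonic
amplitude/phase jitter, period jitter, noise and drift, plus cohort-level
MMSE-coupled group effects — with every drawn parameter exported as ground
truth so extraction accuracy is testable.

## Worked example

```python
from pulsespec import (ModelSpec, run_cv, synthesize_cohort, extract_features,
                       attach_metadata, compare_groups)
from pulsespec.config import default_group_specs

specs = default_group_specs()
records, metadata, truth = synthesize_cohort(
    [specs["AD"], specs["Control"]], [10, 10], duration_s=60.0, fs=500.0, seed=7)
features, failures = extract_features(records)
table = attach_metadata(features, metadata)

print(dict(table.groupby("group")["CV5"].mean().round(2)))
result = [r for r in compare_groups(table, "AD", "Control")
          if r.index_name == "CV5"][0]
print(f"CV5 AD vs Control: p = {result.p_value:.2e} ({result.band})")
report = run_cv(table, ModelSpec("MLP"), seed=1)
print(f"MLP threefold CV: accuracy {report.avg_accuracy_pct:.2f}%, "
      f"AUC {report.avg_auc:.2f}")
```

prints

```
{'AD': 10.82, 'Control': 4.31}
CV5 AD vs Control: p = 5.49e-11 (p<0.05)
MLP threefold CV: accuracy 90.48%, AUC 1.00
```

The AD-like group's beat-to-beat amplitude variability at harmonic 5 is
more than double the control level (10.8% vs 4.3%, a configured property of
the generator), the two-group t-test flags it far below the 0.05 band, and
the cross-validated perceptron separates the groups nearly perfectly —
synthetic group contrasts are cleaner than clinical ones, so classification
metrics on simulated cohorts sit near ceiling (see `docs/methods.md`).

The same pipeline is scriptable from the shell via the `pulsespec` command
(`simulate`, `extract`, `compare`, `train-eval`, `predict`, `correlate`);
each subcommand reads and writes plain CSV/JSON/text artifacts.

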
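# ieeg-focality

Quantifying the focality of epileptic networks from **interictal**
intracranial EEG.

When drug-resistant epilepsy patients undergo invasive iEEG evaluation, the
core clinical question is whether the epileptic network is focal — and hence
a candidate for resection or ablation — or distributed, favouring
neurostimulation. This package implements a quantitative answer built from
seizure-free recordings alone, for researchers working with iEEG cohorts:

1. **Signal features** — bipolar-referenced clips are band-passed 0.5–80 Hz,
   notched at 60 Hz and resampled to 200 Hz; relative band power in the five
   canonical bands and magnitude-squared coherence between all channel pairs
   are estimated with 2 s Hamming windows at 1 s overlap.
2. **Normative abnormality** — each channel's features are Z-scored against
   a normative atlas of (ROI, band) distributions built from presumed-normal
   electrodes; per-channel abnormality weights are the median |Z| over 20
   interictal clips.
3. **Spatial dispersion** — the *implant distance*
   `SD = √(Σ(x−X̄)²/n + Σ(y−Ȳ)²/n + Σ(z−Z̄)²/n)` summarizes electrode
   coverage, and the *abnormality distance* (WSD) is the same statistic
   weighted by per-contact abnormality about the weighted mean centre: small
   when abnormality is tightly clustered, large when it is widespread.
4. **Prediction** — leave-one-out cross-validated L1 logistic regression
   over three nested feature sets (pre-implant 5-SENSE score alone;
   + implant distance; + the 12 abnormality distances), compared with paired
   DeLong tests under Holm-Bonferroni correction, with subgroup analyses by
   therapy, surgical outcome, implant type and non-focal subtype.

A fully deterministic synthetic-cohort generator (electrode geometries,
colored-noise signals with injected band-power and coherence abnormalities,
atlas populations, clinical covariates) makes every stage testable without
access to clinical data.

## Worked example

Run a complete synthetic study — generate a 101-patient cohort (65 focal /
36 non-focal), build a normative atlas from an independent normal
population, extract features, and fit the three cross-validated models:

```python
from ieeg_focality import CohortConfig, run_synthetic_study, analyze_features

config = CohortConfig.scaled_down(seed=1)   # 10 s clips at 400 Hz
features, cohort = run_synthetic_study(config)
analysis = analyze_features(features)
print(analysis["comparison"]["models"][["model", "auc", "sensitivity", "specificity"]])
```

which prints (about 30 s on one CPU):

```
                            model       auc  sensitivity  specificity
0                 five_sense_only  0.573932     0.292308     0.888889
1              five_sense+implant  0.794444     0.800000     0.694444
2  five_sense+implant+abnormality  0.825214     0.646154     0.888889
```

The pre-implant score alone is a weak predictor (AUC 0.57 in this cohort);
adding the spatial dispersion of the implant and of its interictal
abnormalities raises the cross-validated AUC to 0.83. The paired DeLong
comparison of the full model against the score alone is in
`analysis["comparison"]["comparisons"]` (here ΔAUC = 0.25, Holm-corrected
p ≈ 1.3 × 10⁻⁴), and `analysis["subgroups"]` breaks the full model's
predictions down by therapy, outcome and implant type. In this synthetic
cohort the score-vs-implant-distance correlation is r = −0.23: patients
with a higher pre-implant probability of focality received more compact
implants, a structure the generator builds in deliberately.

The same pipeline is available from the shell and writes a run directory
with `electrodes.tsv`, `cohort.csv`, `atlas.json`, per-channel abnormality
weights, per-patient features and `report.json`:

```bash
ieeg-focality run --out runs/demo --seed 1
ieeg-focality report --run-dir runs/demo
```

`simulate`, `features`, `atlas-build`, `predict` and `validate` subcommands
expose the individual stages for user-supplied data (TSV electrode tables,
CSV clips); re-runs skip stages whose input hashes are unchanged.

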
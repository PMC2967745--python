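# clinarray-ica

Discovery of latent physiological factors from clinical laboratory data
by ensemble independent component analysis.

Hospital laboratory systems accumulate years of quantitative biomarker
measurements (serum sodium, platelet count, ALT, …) for every patient.
Summarizing each patient's history as a vector of per-test medians — a
**clinarray** — turns a cohort into a biomarkers × patients matrix `X`
that can be analyzed with the same unsupervised machinery developed for
expression microarrays.  This package implements that analysis for
biostatisticians and clinical informaticians: it models `X = A S` as a
linear mixture of statistically independent, non-Gaussian latent
physiological factors `S`, estimates the unmixing `Y = W X ≈ S` with the
fixed-point FastICA algorithm (negentropy contrast, symmetric
decorrelation), and — because FastICA converges to
initialization-dependent local optima and returns components in no
particular order — repeats the decomposition hundreds of times and
extracts **significant biomarkers** by two consensus rules over the
absolute loadings `|Â[b, c]|`:

1. biomarkers whose *mean* absolute loading (across components and
   runs) reaches the top fraction of the loading distribution;
2. biomarkers that carry the *highest* absolute loading of some
   component in **every** converged run.

The package also provides the surrounding pipeline — median aggregation
of long-format lab records, patient/biomarker pruning (patients with
< 10 distinct tests, tests observed in < 50% of remaining patients),
KNN imputation (K = 10) of missing cells, per-biomarker
standardization — and a synthetic cohort generator with *planted*
factor-driven biomarkers, so every stage can be validated against a
known answer.  See `docs/methods.md` for the full model description and
design rationale.

## Worked example

Generate a synthetic cohort of 4000 patients and a 30-test panel driven
by 3 latent factors, with three factor-driven ("planted") biomarkers,
then run a 50-decomposition ensemble and extract the consensus:

```python
from clinarray_ica import (
    IcaConfig, SyntheticConfig, build_clinarray, extract_significant,
    generate_records, run_ensemble, standardize, summarize,
)

cfg = SyntheticConfig(
    n_patients=4000, n_biomarkers=30, n_sources=3,
    visits_per_patient=1, visit_noise_sd=0.0, observation_noise_sd=4.0,
    missing_rate=0.0, n_planted=3, planted_gain=5.0, seed=7,
)
records, truth = generate_records(cfg)          # long-format lab records
matrix = build_clinarray(records)               # biomarkers x patients medians
standardized, _, _ = standardize(matrix)        # rows: mean 0, variance 1
ensemble = run_ensemble(
    standardized, IcaConfig(n_components=3, contrast="cube"),
    n_runs=50, master_seed=1,
)
result = extract_significant(ensemble, fraction=0.1, threshold_basis="means")
print(summarize(ensemble, result))
```

prints

```
consensus report
================
runs: 50 total, 50 converged (0 excluded)
components per run: 3
loading threshold: 0.352231

significant biomarkers (top-fraction rule):
  bm003  mean |loading| = 0.4347
  bm002  mean |loading| = 0.4332
  bm001  mean |loading| = 0.4300

significant biomarkers (argmax-consistency rule):
  bm001  argmax in 50/50 runs
  bm002  argmax in 50/50 runs
  bm003  argmax in 50/50 runs

both extraction rules yielded exactly the same biomarker set
```

`bm001–bm003` are exactly the planted biomarkers
(`sorted(truth.planted_biomarkers)`), and the two rules agree: the mean
rule ranks them above the 90th-percentile threshold of the biomarker
means (0.352), and each one carries the top loading of its component in
all 50 runs.

The same analysis is available from the shell:

```bash
clinarray-ica simulate --out cohort/ --seed 7
clinarray-ica build --records cohort/records.tsv --out matrix.tsv
clinarray-ica analyze --matrix matrix.tsv --runs 50 --components 3 \
    --contrast cube --fraction 0.1 --threshold-basis means \
    --seed 1 --out analysis/
```

All artifacts are tab-separated text with `NA` as the missing-value
token; `clinarray-ica run --config pipeline.yaml` executes the whole
pipeline reproducibly (a manifest records the config hash and every
derived seed, and a rerun is byte-identical).

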
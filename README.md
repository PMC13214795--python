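# akipipe

A reproducible pipeline for studying acute kidney injury (AKI) after cardiac
surgery from two simulated electronic-health-record sources:

* **`akipipe.synth`** — generates a hospital-information-system extract
  (demographics, comorbidities, surgeries, discharge outcome), an ICU
  patient-data-management extract (timestamped creatinine, hourly urine
  volumes, body weight, dialysis sessions) and a ground-truth ledger.  Series
  are built by inversion: the detector provably recovers the ledger's maximum
  stage for every computable episode.
* **`akipipe.fusion`** — links the extracts by patient identifier, maps each
  surgery to the earliest ICU stay within a 48-h window, resolves redundantly
  recorded parameters by source quality rank, and applies the computability
  exclusion (≥2 urine values, or ≥1 creatinine, or ≥1 dialysis record),
  emitting a cohort-flow accounting.
* **`akipipe.kdigo`** — full KDIGO detection and staging: rolling-window
  urine-output criteria (mean or all-hours semantics, gaps break windows),
  creatinine 48-h delta and 7-day ratio-to-baseline bands, dialysis as stage
  3; yields first/maximum stage, onset times and criterion attribution.
* **`akipipe.stats`** — stratified rate tables, Pearson chi-square, tie-corrected
  rank-sum test, Kaplan–Meier/log-rank survival (via lifelines), logistic
  regression by IRLS with Wald intervals and separation diagnostics, and a
  simulation-based power calculation.
* **`akipipe.cli`** — `simulate` / `fuse` / `detect` / `analyze` / `run` /
  `validate` subcommands with YAML configuration, a single `--seed`, and a
  run manifest for byte-stable reruns.

## CLI

```sh
# full pipeline into ./out (all files CSV/JSON, reproducible under the seed)
akipipe run --seed 42 --out out

# or stage by stage
akipipe simulate --seed 42 --out out/extracts
akipipe validate out/extracts
akipipe fuse --extracts out/extracts --out out/fused
akipipe detect --fused out/fused --out out/detected
akipipe analyze --fused out/fused --seed 42 --out out/analysis
```

`akipipe run` writes the extracts, `cohort_flow.json`, fused episodes,
`aki_assessments.csv` + `aki_summary.json`, characteristics/risk-factor/rate
tables, `km_curves.csv`, `power.json` and `manifest.json`.  A YAML config
(see `akipipe.cli.RunConfig`) overrides any cohort or detection option, e.g.
`--uo-window-mode` semantics via `kdigo.uo_window_mode: all`.

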
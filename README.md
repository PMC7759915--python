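# bnctkit

Analysis toolkit for preclinical boron neutron capture therapy (BNCT)
experiments: clonogenic survival-fraction analysis, linear–quadratic (LQ)
dose–response fitting, iso-effect beam RBE and compound CBE estimation, the
four-component physical / photon-equivalent dose model, tissue boron
biodistribution ratios, and Kaplan–Meier / log-rank / %ILS survival analysis —
plus a seeded synthetic-data generator so every stage can be exercised and
validated end to end without any external data.

## Layout

| module | what it does |
| --- | --- |
| `bnctkit.assay` | colony counts → plating efficiency & survival fraction; uptake t-tests; retention rates |
| `bnctkit.radiobiology` | LQ fit (NNLS on −ln SF), analytic iso-effect inversion, beam RBE, compound CBE |
| `bnctkit.dosimetry` | D_B + D_N + D_H + D_γ physical dose and CBE/RBE-weighted Gy-Eq dose; dose report tables |
| `bnctkit.biodistribution` | per-group mean/SD/n summaries, tumor/brain & tumor/blood ratios, detection-floor flags |
| `bnctkit.survival` | Kaplan–Meier, median survival, Mantel–Cox log-rank, percent increased lifespan |
| `bnctkit.synthetic` | seeded generators for colony, photon, biodistribution and survival datasets |
| `bnctkit.pipeline` | orchestration of all stages into a reproducible report bundle |
| `bnctkit.cli` | `bnctkit` command-line interface |

The CBE definition used throughout (documented in `bnctkit.radiobiology`):
with `t*` the irradiation time at which the compound-loaded cells reach the
iso-effect survival level (default SF = 0.1) and `D_x` the photon dose
producing the same level,

```
CBE = (D_x − RBE_N·D_N(t*) − RBE_H·D_H(t*) − D_γ(t*)) / D_B(t*)
```

Reported table cells use half-up rounding to one decimal; full precision is
kept internally and available via `round_to=None` / `--full-precision`.

## CLI

```bash
# write a fully synthetic dataset (colony, photon, biodistribution, survival CSVs + manifest)
bnctkit simulate --out data/ --seed 1

# individual stages
bnctkit assay --input data/colony_assay.csv --out assay.csv
bnctkit lq-fit --input data/photon_assay.csv
bnctkit biodist-summary --input data/biodistribution.csv --floor 0.5 --out biodist.csv
bnctkit survival-report --input data/survival.csv --control-group control --out surv.csv
bnctkit dose-report --input-dir data/ --out-dir bundle/

# everything with available inputs -> report bundle (CSVs + report.json)
bnctkit run-all --input-dir data/ --out-dir bundle/
```

CSV column schemas are documented in the `--help` of each subcommand and in
the module docstrings; all files are UTF-8, comma-delimited with a header row.

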
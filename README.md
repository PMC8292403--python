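# gravisyn

Muscle-synergy analysis of treadmill walking under simulated reduced gravity:
EMG conditioning and gait-cycle normalization, NMF extraction of spatial and
temporal modules with cross-validated module-number selection, constrained
cosine k-means clustering of modules across gravity levels, nonnegative
CANDECOMP/PARAFAC (CP) tensor decomposition with per-condition gains, and
similarity statistics with bootstrap chance levels. A synthetic-data module
generates ground-truth modular EMG (cycle matrices, condition tensors, and
raw trials with limb kinematics) so that every stage can be tested for
parameter recovery.

## Package layout

| module | contents |
| --- | --- |
| `gravisyn.synthetic` | ground-truth generator: spatial/temporal modules, gravity-dependent gain profiles (constant, linear-decreasing, threshold-decreasing, U-shaped), cycle matrices, raw trials |
| `gravisyn.preprocessing` | zero-phase Butterworth conditioning (100 Hz high-pass, demean, rectify, 10 Hz low-pass), foot-contact detection from the limb-axis elevation angle, 200-bin cycle normalization, amplitude and unit-variance scaling, Froude-number protocol utilities |
| `gravisyn.factorization` | Lee–Seung NMF with restarts, VAF, 5-fold × 20-repeat cross-validated VAF curves, minimum-N-above-90% selection |
| `gravisyn.clustering` | spherical (cosine) k-means, within-participant de-duplication, representative modules, COP-k-means with same-gravity cannot-link constraints, silhouette-based k selection over 2–10 |
| `gravisyn.tensor` | 3-way tensor construction (muscles × bins × condition instances) and nonnegative CP via multiplicative updates with unit-norm factors and explicit λ |
| `gravisyn.similarity` | cosine/correlation similarity, optimal (Hungarian) module matching, 10,000-round bootstrap chance levels, NNLS cross-model reconstruction |
| `gravisyn.pipeline` | config-driven orchestration with deterministic per-stage seeds |

## CLI

All commands are subcommands of `gravisyn` (see `--help` for options):

```bash
gravisyn simulate --out sim/ --seed 1                 # synthetic cycle matrices + ground truth
gravisyn extract-cycles --emg emg.csv --markers mk.csv --config cfg.yaml --out cycles/
gravisyn nmf --matrix sim/P00_1g.csv --select --seed 2 --out nmf/
gravisyn cluster --modules modules.csv --k auto --constrained --seed 3 --out clusters/
gravisyn tensor --in slices/ --n 4 --seed 4 --out cp/
gravisyn compare --a spc_1g.csv --b spc_038g.csv --metric cosine --seed 5 --out cmp.json
gravisyn pipeline --config config.yaml --simulate     # full analysis
```

The pipeline config is YAML with the field names of
`gravisyn.pipeline.AnalysisConfig` (seed, gravity_labels, NMF/clustering/
tensor/bootstrap settings, …). Outputs are JSON and CSV only.

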
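# rlmvpa

Simulation and analysis pipeline for prospective-reward studies on a
three-arm bandit: Rescorla–Wagner modeling of behavior, cross-subject MVPA
decoding of reward outcomes, trial-level coupling between expected value and
choice-time pattern reactivation, and moderation/mediation statistics linking
internalizing symptoms, striatal coupling, and exploitation strategy. All
inputs are produced by a first-class synthetic cohort generator with planted,
configurable effect structure, so the complete pipeline runs and is testable
without any external data.

## What's inside

| Module | Purpose |
| --- | --- |
| `rlmvpa.task_env` | Three-arm bandit: block-permuted reward schedules ({0.8, 0.5, 0.2}, re-permuted every 30 of 90 trials), ±$10 payoffs, agent–environment sessions |
| `rlmvpa.rl_models` | 2×2 Rescorla–Wagner family (counterfactual A± × risk-sensitive RS±), softmax policy, likelihood, simulation |
| `rlmvpa.model_fitting` | Empirical-Bayes hierarchical EM (per-subject MAP + Laplace), AIC model comparison |
| `rlmvpa.synthetic_data` | Cohort generator: covariates, behavior, per-network trial×voxel patterns with planted coupling structure |
| `rlmvpa.mvpa` | Leave-one-subject-out RBF-SVM reward decoding; balanced accuracy; choice-phase hyperplane distances |
| `rlmvpa.coupling` | Trial-level mixed-effects coupling and moderation (random intercepts for site and subject-within-site, Bonferroni control) |
| `rlmvpa.mediation` | Subject-level coupling slopes; percentile (or BCa) bootstrap mediation |
| `rlmvpa.pipeline`, `rlmvpa.cli` | Orchestration, manifests with checksums, reporting, CLI |

## CLI

One subcommand per stage plus `all`:

```bash
rlmvpa all --seed 1 --outdir runs/demo          # full pipeline, defaults
rlmvpa all --config my.yaml --skip mediate      # YAML config, toggle stages
rlmvpa simulate --seed 1 --outdir runs/demo     # single stage
rlmvpa report --outdir runs/demo                # rebuild report.md
```

The default configuration (60 subjects, 2 sites, 8 networks, 200
voxels/network, 90 trials) completes in about 7 minutes on one CPU. Each run
directory contains every stage's CSV/JSON outputs, `report.md` (model
comparison, per-network decoding accuracy, coupling/moderation tables with
the Bonferroni-corrected alpha, mediation paths with CI), and
`run_manifest.json` with per-stage seeds, wall times, and file checksums;
re-running with the same master seed reproduces the checksums exactly.

Stage seeds derive from the master seed as
`SeedSequence(master_seed, spawn_key=(stage_index,))`; the synthetic
generator further splits its stream into named substreams recorded in the
cohort manifest.

## Python API sketch

```python
from rlmvpa.synthetic_data import CohortConfig, generate_cohort
from rlmvpa.model_fitting import fit_hierarchical_em, compare_models
from rlmvpa.rl_models import MODEL_SPECS
from rlmvpa.mvpa import loso_decode, decoding_report
from rlmvpa.coupling import assemble_trial_table, fit_coupling_lmem

cohort = generate_cohort(CohortConfig(), seed=1)
fits = [fit_hierarchical_em(cohort.trial_records, spec, seed=0) for spec in MODEL_SPECS]
print(compare_models(fits))                      # summed AIC, winner
results = loso_decode(cohort.network_sessions(0))
print(decoding_report(results))                  # balanced accuracy + CI
```
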
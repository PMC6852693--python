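# acoustocc

Dynamic (multi-season) occupancy modelling from automated acoustic
monitoring data — a simulation and estimation toolkit for researchers
who want to know whether their detector + classifier + aggregation
pipeline will deliver unbiased occupancy, colonization and extinction
estimates before they commit to it.

Automated detectors applied to autonomous-recording-unit audio emit
*event-level* detections that are a mix of true species calls and false
alarms, each tagged by a classifier with a target-signal probability
(score). `acoustocc` covers the full chain:

1. **dynamics** — latent site occupancy across seasons: initial
   occupancy ψ, colonization γ, extinction ε;
2. **soundscape** — Poisson call events (rate λ_c per hour, occupied
   sites only) and false-alarm events (λ_f per hour, everywhere) within
   a recording schedule, scored by beta-distributed classifiers;
3. **aggregation** — event scores collapse into survey-level encounter
   histories with three states (0 = no detection, 1 = uncertain
   automated detection, 2 = certain manually-verified detection) via
   the "at least one true signal" rule
   `q = 1 − ∏(1 − score_j)` and a detection threshold, with a random
   subset of surveys manually confirmed;
4. **miller** — maximum-likelihood fitting of the multi-state dynamic
   occupancy model with false positives (parameters ψ, γ, ε, p10, p11,
   b), marginalising latent states by a forward recursion;
5. **experiments** — a scenario-grid driver (the full design crosses
   128 scenarios) with replicate seeding, convergence tracking and
   raw-bias summaries.

The aggregation and fitting stages also accept user-supplied tables
(CSV event tables and encounter histories), so the same machinery runs
on real detection data.

## Worked example

```python
import numpy as np
from acoustocc import (
    DYNAMICS_SCENARIOS, GOOD_CLASSIFIER, ScenarioConfig,
    run_replicate, survey_detection_probability, true_detection_params,
)

# Aggregating one survey's event scores: three events scoring
# 0.15/0.04/0.11 leave a 0.726 chance that all are false alarms.
q1 = survey_detection_probability([0.15, 0.04, 0.11])
q2 = survey_detection_probability([0.56, 0.88, 0.71])
print(f"survey 1: q = {q1:.4f}   survey 2: q = {q2:.4f}")

# One full replicate: high occupancy/high turnover, 100 calls/h,
# good classifier, 100 sites, 1-day surveys at threshold 0.95, 5%
# confirmation (all defaults of the reference design).
cfg = ScenarioConfig(dynamics=DYNAMICS_SCENARIOS["HH"], lambda_c=100.0,
                     classifier=GOOD_CLASSIFIER, n_sites=100, seed=42)
truth = true_detection_params(cfg)
print(f"induced truth: p10={truth.p10:.4f} p11={truth.p11:.4f} b={truth.b:.4f}")
res = run_replicate(cfg, rep_seed=0)
est = res.fit.estimates
print(f"tp_rate={res.rates.tp_rate:.3f} fp_rate={res.rates.fp_rate:.3f}")
print(f"estimates: psi={est.psi:.3f} gamma={est.gamma:.3f} epsilon={est.epsilon:.3f}")
```

prints

```
survey 1: q = 0.2738   survey 2: q = 0.9847
induced truth: p10=0.0131 p11=0.9980 b=0.0501
tp_rate=0.998 fp_rate=0.016
estimates: psi=0.600 gamma=0.275 epsilon=0.333
```

Survey 1 stays below a 0.95 detection threshold (coded 0), survey 2
exceeds it (coded 1). The detection parameters are *induced* by the
pipeline: with a good classifier and a high call rate, nearly every
occupied survey is detected (p11 ≈ 1) while only ~1.3% of unoccupied
surveys cross the threshold. The single-replicate estimates sit near
the generating values (ψ = 0.60, γ = ε = 0.25); individual replicates
scatter by up to ~0.1 in the turnover parameters, which is why bias is
judged over replicated fits (`run_scenario_grid` + `summarize_bias`),
where mean bias lands within ±0.03.

The same stages are scriptable from the shell:

```bash
acoustocc simulate  --config scenario.yaml --out-events events.csv --out-occupancy occ.csv
acoustocc aggregate --config scenario.yaml --events events.csv --occupancy occ.csv --out history.csv
acoustocc fit       --history history.csv --config scenario.yaml --out fit.json
acoustocc grid      --config grid.yaml --n-reps 100 --out results.csv --summary bias.csv
```

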
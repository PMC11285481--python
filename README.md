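# reeftrack

Fine-scale acoustic-telemetry analysis for receiver arrays around
artificial structures: synthetic telemetry generation, receiver clock
synchronization, TDOA positioning with HPE quality filtering, kernel
home-range / site-fidelity / residency metrics, a 4-state hidden Markov
model inferring shelter ("hiding") use from detection-derived streams, a
3-state behavioural HMM on step length and body acceleration with
covariate-dependent transitions and AIC model selection, and a binomial
additive model of daily hiding proportions.

## Layout

| module | contents |
| --- | --- |
| `reeftrack.simulate` | ground-truthed tracks (hiding/local/transit regimes), range-dependent detections with clock drift and sync pings, tidal/seasonal environment series |
| `reeftrack.positioning` | clock sync (linear offset+drift, transitive), Gauss–Newton TDOA solver, HPE metric, quantile filter, tag-loss screening |
| `reeftrack.spaceuse` | fixed-bandwidth KDE utilization distributions, UD95 isopleths, diel splitting, structure association, fidelity, residency |
| `reeftrack.hmm` | generic HMM core: Gamma (mean/sd, optional zero mass) and Bernoulli streams, multinomial-logit transition covariates, scaled forward likelihood with missing data, direct ML fitting, Viterbi, AIC ranking |
| `reeftrack.hiding` | 10-min bins from all detections, 4-state hiding HMM (HS1–HS4), daily hiding proportion, penalized additive model |
| `reeftrack.behaviour` | 10-min step/VeDBA bins, 3-state behavioural HMM (BS1–BS3) with covariate search, per-state spatial densities |
| `reeftrack.experiments` | seeded end-to-end recovery and validation experiments |
| `reeftrack.cli` / `reeftrack.config` | `reeftrack` command-line pipeline and YAML configuration |

## CLI

```bash
reeftrack simulate --config cfg.yaml --seed 1 --out run/
reeftrack position --in run/ --out run/positions.csv
reeftrack spaceuse --positions run/positions.csv --structures run/structures.csv
reeftrack run-all --config cfg.yaml --seed 1 --out run/
```

`run-all` executes every stage in dependency order, writes CSV outputs
plus a provenance manifest, and is byte-reproducible under a fixed seed.
A config file only needs the entries you want to override, e.g.:

```yaml
simulate:
  n_fish: 10
  duration_days: 60
behaviour:
  candidates: [[], [current], [current, sst]]
```

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact 2% HPE
removal, UD95 mass band, TDOA minimum-receiver contract, brute-force
HMM oracle equivalence, positioning/HMM parameter recovery, AIC
covariate selection, fidelity/filter constants, GAM sign recovery).

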
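# jitaikit

A toolkit for geofence-triggered just-in-time adaptive interventions
(JITAIs) in smoking cessation, with three tightly coupled parts:

* **Decision engine** (`jitaikit.engine`, `jitaikit.tailoring`) — a
  deterministic per-user state machine that learns smoking locations from
  self-reports before a quit date, builds circular geofences around places
  reported more than once, and — after the quit date — fires tailored
  support messages when the user dwells ≥5 minutes inside a learned fence,
  re-deciding every 3 hours, within an 08:00–21:30 local window, with
  per-time-bin frequency thresholds, per-fence cooldowns, a relapse
  detector (>1 episode/day on 2 consecutive days), a quit-date reset, and
  a maintenance phase whose message frequency halves month over month
  until support stops 3 months post-quit.
* **Cohort simulator** (`jitaikit.simulate`) — synthetic smokers with
  weekly movement templates, per-place smoking behaviour and situational
  context, a cue-exposure lapse hazard modulated by fired messages, app
  installation (~75%) and heavy-tailed engagement (median ~10 days),
  follow-up response, abstinence misreporting and differential saliva
  return, and stratified permuted-block randomization. Two fidelity
  levels: `detail="events"` runs the engine in the loop on full event
  streams; `detail="outcomes"` uses a closed-form daily survival model for
  trial-scale calibration studies.
* **Trial statistics** (`jitaikit.stats`) — Russell-standard outcome
  derivation (cotinine < 10 ng/ml, anabasine < 0.2 ng/ml under nicotine
  substitution, missing = smoking), Wald odds-ratio intervals, Newcombe
  hybrid Wilson-score risk differences, Wald and Clopper–Pearson
  proportion intervals, uncorrected Pearson chi-square, a flat-prior
  posterior OR-exceedance probability, and IRLS logistic regression with
  separation diagnostics.

## Command line

```sh
# simulate a 2-arm trial dataset (participants.csv + manifest.json)
jitaikit simulate --config examples/trial.yaml --out out/

# replay an event log through the decision engine -> decisions CSV
jitaikit replay --log events.jsonl --config examples/trial.yaml --out decisions.csv

# derive outcomes and effect estimates from a dataset
jitaikit analyze --dataset out/participants.csv --out reports/
jitaikit report  --dataset out/participants.csv
```

Event logs are line-delimited JSON (one record per line, typed by a
`kind` field: `fix` | `report` | `reset`) with a schema-version header;
round-trips are bit-stable. Every stochastic command requires a seed
(config key `seed` or `--seed`) and is a pure function of its inputs,
configuration and seed.

## Library sketch

```python
from jitaikit.engine import EngineConfig, replay_event_log
from jitaikit.simulate import SimulationParams, simulate_trial
from jitaikit.stats import TwoByTwo, odds_ratio_wald, risk_difference_newcombe

state, decisions = replay_event_log(events, EngineConfig(), seed=1)

dataset = simulate_trial(104, 105, SimulationParams(), seed=1)

t = TwoByTwo.from_events(16, 104, 5, 105)
odds_ratio_wald(t)            # 3.64 (1.28, 10.33)
risk_difference_newcombe(t)   # 10.6% (2.4%, 19.2%)
```

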
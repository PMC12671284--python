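# rehabgame

Software re-implementation of a game-based hand-rehabilitation platform:
a simulated one-degree-of-freedom rotary handle ("manipulandum") mapped
to a screen coordinate, a catch-the-falling-target practice game with
frame-level logging, parameterised virtual players that emulate
able-bodied and stroke-like responses, a kinematic assessment pipeline
(success rate, movement onset time, movement duration, overshoots,
variability), and clinical outcome aggregation (15-task upper-extremity
function test scoring, MCID flagging, group mean/SD tables) with bundled
per-participant fixture data.

## Layout

| Module | Role |
|---|---|
| `rehabgame.device` | Handle simulation: angle→screen mapping, working range / sensitivity, unidirectional constant-torque field, semi-implicit Euler dynamics |
| `rehabgame.engine` | Event scheduler (randomised, direction-balanced), catch detection, session logging |
| `rehabgame.players` | Generative movement models and the four severity presets (`able_bodied`, `stroke_mild`, `stroke_moderate`, `stroke_severe`) |
| `rehabgame.metrics` | Trace segmentation, onset detection, SR/MOT/duration/overshoot/variability summaries |
| `rehabgame.clinical` | Function-test totals, change scores, MCID flags, group summaries, fixture tables |
| `rehabgame.report` | Markdown rendering and cell-by-cell verification of the printed tables |
| `rehabgame.cli` / `rehabgame.config` / `rehabgame.logio` | CLI verbs, TOML run configuration, CSV+JSON log round trip |

Per-participant clinical fixtures (function-test scores, per-object
success rates and response times, demographics, game catalog) live in
`src/rehabgame/data/` as plain CSV.

## CLI

```sh
rehabgame simulate --preset able_bodied --seed 1 --out session
rehabgame analyze session --out-json metrics.json --overlay overlay.csv
rehabgame simulate --config examples/run.toml --out session2
rehabgame reproduce-tables     # re-derives every printed "mean (SD)" cell; exit 1 on mismatch
rehabgame report --out-dir reports
rehabgame presets
```

`simulate` writes `<prefix>.frames.csv` (one row per frame per active
object) plus `<prefix>.session.json` (events, catch flags, config
snapshot, seed) and prints the session metrics. A fixed `--seed` makes
the run byte-for-byte reproducible.

## Notes

- "Response time" in milliseconds and movement onset time (MOT) in
  seconds are the same quantity in different units
  (`response_time_ms = 1000 * mot_avg_s`).
- Group statistics use the sample standard deviation (n−1) and
  half-away-from-zero rounding; MCID "surpassed" means strictly greater
  than the threshold.
- All virtual-player parameters are artifact constructs tuned once to
  reproduce the qualitative phenotypes (prompt/smooth/accurate vs
  delayed/hypometric/non-smooth with overshoots); they are not
  measurements of patients.
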
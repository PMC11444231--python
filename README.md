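# adhersim

A headless, seeded simulation of a gamified antibiotic-adherence laboratory
task, plus the statistics used to analyse it.

In the simulated task, a 2048 sliding-tile game stands in for "everyday
life". At session start the screen is fully blurred ("illness onset"); the
participant must enter a code once per minute ("take a dose") for 14 minutes
30 seconds. Each correct entry clears part of the blur; after 7 correct
entries (14 on the *elongated* arm) symptoms are cleared. Once cleared,
every window without a correct on-time entry carries a relapse hazard that
starts at 2% and doubles per consecutive miss; a relapse re-blurs the screen
by 25%. Earnings start at Rs 80, grow with game score, and are capped at
Rs 500. Five arms are implemented: **control**, **incentive** (Rs 5 per
on-time entry), **reminder** (popup at each dose time), **commitment**
(signed sticker, agent-side only), and **elongated** (symptoms clear twice
as slowly).

Synthetic agents replace human participants: per-window Bernoulli attendance
with symptom-free lapses, reminder/incentive/commitment boosts, Gaussian
timing jitter, and a wrong-code probability. Defaults are calibrated so the
control arm's mean adherence is ~44% and the reminder arm ~67%, echoing the
published pattern.

## Layout

| module | contents |
| --- | --- |
| `adhersim.game` | deterministic 2048 engine (slide/merge, spawn, game over) |
| `adhersim.env` | session config, dose schedule, entry classification, blur, relapse hazard, earnings |
| `adhersim.interventions` | the five condition arms and the reminder schedule |
| `adhersim.agents` | synthetic-participant model, score accrual, calibration |
| `adhersim.harness` | single-session and full-experiment runners with counter-based seeding |
| `adhersim.io` | CSV participant tables, JSON Lines event logs, YAML configs |
| `adhersim.analysis` | group summaries, summary-statistics ANOVA, partial eta squared, Bonferroni CIs, classification/relapse tables |

## CLI

```sh
# one arm, 50 synthetic participants
adhersim run --condition reminder --n 50 --seed 7 --out out/reminder

# every arm of the default plan (104/106/97/102/100 participants)
adhersim run-all --seed 7 --out out/experiment

# statistics from a participant table
adhersim analyze out/experiment/records.csv --out out/analysis

# recompute the published headline statistics from built-in summaries
adhersim reproduce-paper
```

`run-all` accepts `--plan config.yaml`; the YAML holds `session`, `agent`
and `plan` sections whose keys mirror the `SessionConfig`, `AgentParams`
and `ExperimentPlan` fields. The `agent` section can be combined with
per-parameter hyperpriors for population heterogeneity (see
`adhersim.agents.sample_agent_params`).

### Output column dictionary

`records.csv` — one row per participant:

| column | meaning |
| --- | --- |
| `participant_id` | `<condition>-<index>` |
| `condition` | arm name |
| `seed` | per-participant substream seed |
| `adherence_rate` | percent of the 14 scheduled doses entered correct **and on time** |
| `n_on_time` / `n_off_time` / `n_wrong_code` / `n_missed` | outcome counts (sum to 14) |
| `relapse_round` | dose index of the (single) relapse, empty if none |
| `final_score` | cumulative game score over the session |
| `earnings` | final rupees (show-up fee + score payout + incentive bonus, capped) |

`events.jsonl` — one JSON object per line: `type: "dose"` rows carry
`dose_index`, `scheduled_t`, `entry_t`, `entered_code`, `outcome`,
`blur_after`, `relapse_triggered`; `type: "score"` rows carry the
inter-window segment (`t_start`, `t_end`, `blur`, `points`).

## Notes on conventions

- On-time window: ±15 s around each scheduled minute (configurable;
  classification is correct for any window inside `(0, 30)` s).
- Correct-but-off-time entries count toward the pill counter and blur
  clearance but not toward the adherence rate, and they do not reset the
  consecutive-miss counter feeding the relapse hazard.
- Game-score payout is linear (Rs 420 per 20,000 points) and configurable;
  spawn behaviour follows the open-source 2048 original (90% twos, two
  starting tiles).
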
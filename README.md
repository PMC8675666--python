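# ssgnet — passing-network analysis of bio-banded small-sided games

`ssgnet` is a Python toolkit for analysing passing behaviour in 4v4
small-sided soccer games (SSGs) played under *bio-banding* — grouping
youth players by somatic maturity (percentage of predicted adult height,
PAH%) instead of chronological age, with Early (PAH% ≥ 90) and Late
(PAH% < 90) maturity bands.  It is aimed at sports scientists and
performance analysts who have per-game pass-event logs (e.g. from
foot-mounted inertial sensors) and want to go from raw releases to
team/player network metrics and mixed-model effect sizes.

The package covers the full chain:

1. **Event handling** — validated event/roster/game tables, shot
   removal, and possession segmentation (a possession is a maximal run
   of consecutive same-team releases; its duration runs to the
   opponent's first release).
2. **Passing networks** — per team per game, a weighted directed graph
   with players as nodes and successful passes as edges
   (`w[i,j]` = passes i→j, `a[i,j] = 1` iff `w[i,j] ≥ 1`):

   - density  `Σᵢⱼ aᵢⱼ / n(n−1)` — fraction of the 12 ordered 4v4
     passing options used;
   - intensity `(1/T) Σᵢⱼ wᵢⱼ` — successful passes per minute of
     possession time T;
   - degree `Σⱼ wᵢⱼ + Σⱼ wⱼᵢ`; closeness `1/Σⱼ dist(i,j)`;
     betweenness `Σⱼ≠ᵢ Σₖ≠ᵢ σⱼₖ(i)/σⱼₖ` (unnormalised, directed);
     PageRank `PR(i) = (1−d)/N + d Σⱼ∈M(i) PR(j)/C(j)`.
3. **Traditional metrics & GTSC** — mean possession duration, pass
   attempts, completion %, passes per possession; Game Technical
   Scoring Chart sums (ten 0–5 coach-rated criteria).
4. **Inference** — random-intercept linear mixed models (ML) per metric
   with pitch size, game type and maturation as categorical fixed
   effects; generalized likelihood-ratio tests; local Cohen's
   `f² = (R²_full − R²_reduced)/(1 − R²_full)` with residual-variance
   R² against the intercept+random-intercept null; 95% cluster-bootstrap
   CIs (players resampled whole); categories at 0.02/0.13/0.26.
5. **Synthetic studies** — a calibrated generator reproducing the full
   design: 2 clubs × 16 players (8 Early/8 Late), four weekly pitch
   sizes (36.1/72.0/108.8/144.5 m² per player), per club-week a 6-game
   bio-banded mini-league plus 6 mixed-maturity games — 96 games.

## Worked example

```python
from ssgnet import (GeneratorConfig, simulate_study,
                    segment_all_possessions, team_metric_table,
                    analyze_tables, player_metric_table)

ds = simulate_study(GeneratorConfig(seed=7))     # 96 games, 32 players
team = team_metric_table(ds)                     # one row per team-game
print(team["pass_attempts"].mean().round(1),
      team["completion_pct"].mean().round(1))
# 30.1 52.8

effects = analyze_tables(team, player_metric_table(ds))
row = effects.query("metric == 'mean_possession_s'"
                    " and effect == 'pitch'").iloc[0]
print(round(row.f2, 2), f"{row.p_value:.2g}", row.category)
# 1.1 1e-30 large
```

The first line says this synthetic study averages 30.1 pass attempts
per team per game at 52.8% completion; the second that pitch size has a
large effect on mean possession duration (possessions lengthen as the
pitch grows) once the team-composition random intercept is accounted
for — the generator's dominant injected effect, recovered by the
modelling chain.

The same pipeline runs from the shell:

```bash
ssgnet simulate --seed 7 --out study/
ssgnet analyze --events study/events.csv --roster study/roster.csv \
               --games study/games.csv --gtsc study/gtsc.csv --out results/
# or in one step:
ssgnet report --simulate --seed 7 --out results/
```

`results/` then holds the tidy metric tables, `effects.csv` (one row
per metric × population × effect with LRT p, f², CI and category), a
markdown report with mean (SD) per game type, and a MANIFEST recording
the configuration and seed; identical seeds give byte-identical output.

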
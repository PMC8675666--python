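"""End-to-end orchestration: data in, tables, models and report out.

``run_pipeline`` executes the full chain — load or simulate a study,
filter shots, segment possessions, build networks, assemble the tidy
metric tables, fit the mixed models — and writes everything to an output
directory together with a MANIFEST recording the configuration, package
version, seed and which stages completed.  Given the same inputs,
configuration and seed the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .events import MatchDataset, read_dataset, segment_all_possessions, write_dataset
from .inference import F2_THRESHOLDS, analyze_metric
from .networks import PageRankParams
from .simulate import GeneratorConfig, simulate_study
from .tables import edge_table, player_metric_table, team_metric_table

__all__ = ["RunConfig", "run_pipeline", "analyze_tables", "TEAM_RESPONSES",
           "PLAYER_RESPONSES"]

TEAM_RESPONSES = ["mean_possession_s", "pass_attempts", "completion_pct",
                  "passes_per_possession", "density", "intensity"]
PLAYER_RESPONSES = ["degree", "closeness", "betweenness", "pagerank",
                    "gtsc_passing", "gtsc_sum"]

#: Reference levels mirroring the study design: small pitch and the
#: maturity-matched Early/Early game type.
REF_LEVELS = {"pitch": "small", "game_type": "EarlyEarly", "band": "Early"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: either the three (plus optional GTSC) CSV
    paths, or ``simulate=True`` with a generator configuration.
    """

    out_dir: str = "ssgnet_out"
    simulate: bool = False
    events_path: str | None = None
    roster_path: str | None = None
    games_path: str | None = None
    gtsc_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int | None = None
    weighting: str = "hops"  # shortest-path edge-length convention
    damping: float = 0.85
    thresholds: tuple = F2_THRESHOLDS
    bootstrap_B: int = 1000
    analyze: bool = True

    def validate(self) -> "RunConfig":
        have_files = any([self.events_path, self.roster_path, self.games_path])
        if self.simulate and have_files:
            raise ValueError("choose either file inputs or --simulate, not both")
        if not self.simulate:
            missing = [n for n in ("events_path", "roster_path", "games_path")
                       if getattr(self, n) is None]
            if missing:
                raise ValueError(f"file input mode needs {missing}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        # the output directory is where the manifest lives; keeping it out
        # makes runs byte-identical regardless of destination
        d.pop("out_dir")
        return d


def analyze_tables(team: pd.DataFrame, player: pd.DataFrame,
                   thresholds=F2_THRESHOLDS, bootstrap_B: int = 0,
                   seed: int = 0) -> pd.DataFrame:
    """Fit every metric's mixed models and collect the effect tests.

    Team metrics are modelled with game type and pitch size as fixed
    effects and a random intercept per team composition; player metrics
    add maturation and use a random intercept per player, run on the
    pooled sample and on each maturity band separately.
    """
    records = []

    def run(rows, response, fixed, group, population, effects=None):
        if response not in rows or rows[response].notna().sum() == 0:
            return
        sub = rows
        usable_fixed = tuple(f for f in fixed
                             if sub[f].nunique(dropna=True) > 1)
        if len(usable_fixed) < len(fixed):
            dropped = set(fixed) - set(usable_fixed)
            warnings.warn(f"{response} ({population}): constant factor(s) "
                          f"{sorted(dropped)} dropped from the model",
                          UserWarning, stacklevel=2)
        eff = [e for e in (effects or usable_fixed) if e in usable_fixed]
        for t in analyze_metric(
                sub, response, usable_fixed, group=group,
                population=population, effects=eff,
                bootstrap_B=bootstrap_B, seed=seed, thresholds=thresholds,
                ref_levels=REF_LEVELS):
            records.append(t.to_row())

    for resp in TEAM_RESPONSES:
        run(team, resp, ("game_type", "pitch"), "team_id", "pooled")
    for resp in PLAYER_RESPONSES:
        run(player, resp, ("game_type", "pitch", "band"), "player_id",
            "pooled")
        for population, band in (("early_only", "Early"),
                                 ("late_only", "Late")):
            run(player.loc[player["band"] == band], resp,
                ("game_type", "pitch"), "player_id", population)
    return pd.DataFrame.from_records(records)


def _summary_by_game_type(table: pd.DataFrame, responses,
                          extra_keys=()) -> pd.DataFrame:
    """Mean (SD) of each metric by game type, table-shaped for the report."""
    rows = []
    for resp in responses:
        if resp not in table:
            continue
        for keys, sub in table.groupby(["game_type", *extra_keys]):
            keys = (keys,) if not isinstance(keys, tuple) else keys
            rows.append({
                "metric": resp, "game_type": keys[0],
                **dict(zip(extra_keys, keys[1:])),
                "mean": sub[resp].mean(), "sd": sub[resp].std(ddof=1),
                "n": int(sub[resp].notna().sum()),
            })
    return pd.DataFrame(rows)


def _report_markdown(team_summary, player_summary, effects) -> str:
    def fmt_summary(df, title):
        lines = [f"## {title}", "",
                 "| Metric | Early/Early | Late/Late | Early/Late | Mixed |",
                 "|---|---|---|---|---|"]
        order = ["EarlyEarly", "LateLate", "EarlyLate", "Mixed"]
        for metric in df["metric"].unique():
            sub = df.loc[df["metric"] == metric].set_index("game_type")
            cells = []
            for gt in order:
                if gt in sub.index:
                    r = sub.loc[gt]
                    cells.append(f"{r['mean']:.2f} ({r['sd']:.2f})")
                else:
                    cells.append("—")
            lines.append(f"| {metric} | " + " | ".join(cells) + " |")
        lines.append("")
        return lines

    lines = ["# Passing-network analysis report", "",
             "Values are mean (SD) per game type; effect sizes are local "
             "Cohen's f² with 95% cluster-bootstrap CIs and likelihood-"
             "ratio p-values.", ""]
    lines += fmt_summary(team_summary, "Team metrics (per team per game)")
    lines += fmt_summary(player_summary,
                         "Player metrics (per player per game)")
    lines += ["## Effects", "",
              "| Metric | Population | Effect | f² | 95% CI | p | Category |",
              "|---|---|---|---|---|---|---|"]
    for r in effects.itertuples(index=False):
        ci = ("—" if pd.isna(r.ci_low)
              else f"[{r.ci_low:.2f}–{r.ci_high:.2f}]")
        p = "<0.001" if r.p_value < 0.001 else f"{r.p_value:.3f}"
        lines.append(f"| {r.metric} | {r.population} | {r.effect} | "
                     f"{r.f2:.2f} | {ci} | {p} | {r.category} |")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns a dict of output paths and tables.

    Partial outputs are retained on failure, with the MANIFEST marking
    which stages completed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "ssgnet", "version": __version__,
        "config": config.to_dict(), "stages": [], "complete": False,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    results: dict = {"out_dir": out, "manifest": manifest}

    def done(stage):
        manifest["stages"].append(stage)
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        print(f"[ssgnet] stage complete: {stage}", file=sys.stderr)

    try:
        if config.simulate:
            gen = config.generator
            if config.seed is not None:
                gen = gen.replace(seed=config.seed)
            dataset = simulate_study(gen)
            write_dataset(dataset, out / "dataset")
            gen.to_yaml(out / "dataset" / "generator.yaml")
        else:
            dataset = read_dataset(config.events_path, config.roster_path,
                                   config.games_path, config.gtsc_path)
        results["dataset"] = dataset
        done("load")

        poss = segment_all_possessions(dataset)
        poss.to_csv(out / "possessions.csv", index=False)
        done("possessions")

        pr_params = PageRankParams(d=config.damping)
        team = team_metric_table(dataset)
        player = player_metric_table(dataset, pr_params,
                                     weighting=config.weighting)
        team.to_csv(out / "team_metrics.csv", index=False)
        player.to_csv(out / "player_metrics.csv", index=False)
        edge_table(dataset).to_csv(out / "edges.csv", index=False)
        results["team"], results["player"] = team, player
        done("metrics")

        if config.analyze:
            n_types = team["game_type"].nunique()
            if n_types < 4:
                warnings.warn(
                    f"only {n_types} game type(s) present; game-type "
                    "contrasts are reduced", UserWarning, stacklevel=2)
            seed = config.seed if config.seed is not None else 0
            effects = analyze_tables(team, player,
                                     thresholds=config.thresholds,
                                     bootstrap_B=config.bootstrap_B,
                                     seed=seed)
            effects.to_csv(out / "effects.csv", index=False)
            results["effects"] = effects
            done("models")

            team_summary = _summary_by_game_type(team, TEAM_RESPONSES)
            player_summary = _summary_by_game_type(player, PLAYER_RESPONSES)
            team_summary.to_csv(out / "summary_team.csv", index=False)
            player_summary.to_csv(out / "summary_player.csv", index=False)
            (out / "report.md").write_text(
                _report_markdown(team_summary, player_summary, effects))
            done("report")

        manifest["complete"] = True
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    return results
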
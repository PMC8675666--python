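"""Traditional team passing metrics and coach-rated technical scores.

The traditional metrics are the notational-analysis staples computed per
team per game from the shot-filtered possession spells: mean possession
duration, total pass attempts, completion percentage and mean passes per
possession.  The Game Technical Scoring Chart (GTSC) is a subjective
coach rating of ten soccer-specific criteria on a 0–5 scale whose sum
(0–50) summarises overall technical performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import GTSC_CRITERIA

__all__ = [
    "TeamTraditionalMetrics",
    "traditional_team_metrics",
    "traditional_metrics_table",
    "gtsc_sum",
    "gtsc_sum_table",
]


@dataclass
class TeamTraditionalMetrics:
    game_id: str
    team_id: str
    mean_possession_s: float
    pass_attempts: int
    completion_pct: float  # NaN when no attempts were made
    passes_per_possession: float


def traditional_team_metrics(possessions: pd.DataFrame, game: pd.Series,
                             team_id) -> TeamTraditionalMetrics:
    """Per-team per-game traditional metrics from possession spells.

    ``completion_pct`` is 100 * successful / attempted passes and is
    reported as NaN when the team attempted no passes.
    """
    gid = game["game_id"]
    if len(possessions) and (possessions["game_id"] != gid).any():
        raise ValueError("possessions must come from a single game")
    own = possessions.loc[possessions["team_id"] == team_id]
    n_poss = len(own)
    attempts = int(own["n_pass_attempts"].sum())
    successes = int(own["n_successful"].sum())
    return TeamTraditionalMetrics(
        game_id=gid,
        team_id=team_id,
        mean_possession_s=(
            float((own["end_s"] - own["start_s"]).mean()) if n_poss else np.nan),
        pass_attempts=attempts,
        completion_pct=100.0 * successes / attempts if attempts else np.nan,
        passes_per_possession=attempts / n_poss if n_poss else np.nan,
    )


def traditional_metrics_table(possessions: pd.DataFrame) -> pd.DataFrame:
    """Vectorised traditional metrics for every (game, team) present.

    ``possessions`` may span many games (e.g. from
    :func:`ssgnet.events.segment_all_possessions`).
    """
    if not len(possessions):
        return pd.DataFrame(columns=[
            "game_id", "team_id", "mean_possession_s", "pass_attempts",
            "completion_pct", "passes_per_possession"])
    p = possessions.assign(duration_s=lambda d: d["end_s"] - d["start_s"])
    g = p.groupby(["game_id", "team_id"], sort=True).agg(
        mean_possession_s=("duration_s", "mean"),
        pass_attempts=("n_pass_attempts", "sum"),
        n_successful=("n_successful", "sum"),
        n_possessions=("n_pass_attempts", "size"),
    ).reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        g["completion_pct"] = np.where(
            g["pass_attempts"] > 0,
            100.0 * g["n_successful"] / g["pass_attempts"], np.nan)
        g["passes_per_possession"] = g["pass_attempts"] / g["n_possessions"]
    return g.drop(columns=["n_successful", "n_possessions"])


def gtsc_sum(sheet) -> int:
    """Sum the ten GTSC criterion scores (overall technical performance).

    ``sheet`` is a mapping or Series holding the ten criterion columns.
    Raises ``ValueError`` naming any missing criterion.
    """
    missing = [c for c in GTSC_CRITERIA
               if c not in sheet or pd.isna(sheet[c])]
    if missing:
        raise ValueError(f"GTSC sheet is missing criteria: {missing}")
    total = 0
    for c in GTSC_CRITERIA:
        v = int(sheet[c])
        if not 0 <= v <= 5:
            raise ValueError(f"GTSC criterion '{c}' out of 0–5 range: {v}")
        total += v
    return total


def gtsc_sum_table(gtsc: pd.DataFrame) -> pd.DataFrame:
    """Per (game, player) GTSC passing score and sum score."""
    out = gtsc[["game_id", "player_id"]].copy()
    out["gtsc_passing"] = gtsc["passing"].astype(int)
    out["gtsc_sum"] = gtsc[GTSC_CRITERIA].astype(int).sum(axis=1)
    return out
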
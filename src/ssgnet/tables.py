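"""Tidy per-observation metric tables feeding the mixed models.

Metrics are computed per team per game (macro) and per player per game
(micro) and only then modelled — pooling across games before modelling
would destroy the repeated-measures structure the random intercepts are
there to absorb.  ``team_id`` doubles as the team-composition identifier
for team-level random effects: bio-banded line-ups keep one label across
weeks while re-drawn mixed line-ups get fresh weekly labels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .events import MatchDataset, filter_shots, segment_all_possessions
from .networks import (PageRankParams, build_network, centrality_table,
                       edge_list, network_density, network_intensity)
from .performance import gtsc_sum_table, traditional_metrics_table

__all__ = ["team_metric_table", "player_metric_table", "edge_table",
           "PITCH_LEVEL_BY_WEEK"]

PITCH_LEVEL_BY_WEEK = {1: "small", 2: "medium", 3: "large", 4: "expansive"}

_GAME_META = ["game_id", "week", "game_type", "area_per_player_m2"]


def _game_meta(games: pd.DataFrame) -> pd.DataFrame:
    meta = games[_GAME_META].copy()
    meta["pitch"] = meta["week"].map(PITCH_LEVEL_BY_WEEK)
    return meta


def _iter_team_games(dataset: MatchDataset):
    """Yield (game row, team_id, roster, successful passes, possessions)."""
    ev = filter_shots(dataset.events)
    poss = segment_all_possessions(dataset)
    ev_by_game = dict(iter(ev.groupby("game_id", sort=False))) if len(ev) else {}
    poss_by = dict(iter(poss.groupby(["game_id", "team_id"], sort=False))) \
        if len(poss) else {}
    empty_ev = ev.iloc[0:0]
    empty_poss = poss.iloc[0:0]
    for _, game in dataset.games.iterrows():
        gev = ev_by_game.get(game["game_id"], empty_ev)
        for team_id in (game["team_a_id"], game["team_b_id"]):
            roster = dataset.roster(game["game_id"], team_id)
            tev = gev.loc[(gev["team_id"] == team_id) & gev["success"]]
            tposs = poss_by.get((game["game_id"], team_id), empty_poss)
            yield game, team_id, roster, tev, tposs


def _networks(dataset: MatchDataset):
    for game, team_id, roster, tev, tposs in _iter_team_games(dataset):
        yield game, team_id, build_network(tev, tposs, roster)


def team_metric_table(dataset: MatchDataset) -> pd.DataFrame:
    """One row per (game, team): traditional + macro network metrics.

    Columns: game metadata (week, pitch level, area per player, game
    type), ``mean_possession_s``, ``pass_attempts``, ``completion_pct``,
    ``passes_per_possession``, ``density``, ``intensity``.
    """
    poss = segment_all_possessions(dataset)
    trad = traditional_metrics_table(poss)
    rows = []
    for game, team_id, net in _networks(dataset):
        if net.possession_time_min > 0:
            intensity = network_intensity(net)
        else:
            if net.total_passes > 0:
                warnings.warn(
                    f"game {game['game_id']}, team {team_id}: passes with "
                    "zero possession time; intensity reported as missing",
                    UserWarning, stacklevel=2)
            intensity = np.nan
        rows.append({
            "game_id": game["game_id"], "team_id": team_id,
            "density": network_density(net),
            "intensity": intensity,
        })
    nets = pd.DataFrame(rows)
    out = nets.merge(trad, on=["game_id", "team_id"], how="left")
    out = out.merge(_game_meta(dataset.games), on="game_id", how="left")
    cols = ["game_id", "team_id", "week", "pitch", "area_per_player_m2",
            "game_type", "mean_possession_s", "pass_attempts",
            "completion_pct", "passes_per_possession", "density", "intensity"]
    return out[cols].sort_values(["game_id", "team_id"]).reset_index(drop=True)


def player_metric_table(dataset: MatchDataset,
                        pagerank_params: PageRankParams | None = None,
                        weighting: str = "hops") -> pd.DataFrame:
    """One row per (game, player): the four centralities plus GTSC scores.

    The player's maturity band and the game metadata are merged in so the
    table can be fed straight to the pooled or per-band mixed models.
    """
    rows = []
    for game, team_id, net in _networks(dataset):
        cent = centrality_table(net, pagerank_params, weighting=weighting)
        cent.insert(0, "game_id", game["game_id"])
        cent.insert(1, "team_id", team_id)
        rows.append(cent)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["game_id", "team_id", "player_id", "degree", "closeness",
                 "betweenness", "pagerank"])
    out = out.merge(dataset.players[["player_id", "band"]],
                    on="player_id", how="left")
    out = out.merge(_game_meta(dataset.games), on="game_id", how="left")
    if dataset.gtsc is not None and len(dataset.gtsc):
        out = out.merge(gtsc_sum_table(dataset.gtsc),
                        on=["game_id", "player_id"], how="left")
    else:
        out["gtsc_passing"] = np.nan
        out["gtsc_sum"] = np.nan
    cols = ["game_id", "team_id", "player_id", "band", "week", "pitch",
            "area_per_player_m2", "game_type", "degree", "closeness",
            "betweenness", "pagerank", "gtsc_passing", "gtsc_sum"]
    return out[cols].sort_values(
        ["game_id", "team_id", "player_id"]).reset_index(drop=True)


def edge_table(dataset: MatchDataset) -> pd.DataFrame:
    """Every team-game network as one tidy edge list for export."""
    parts = [edge_list(net, game["game_id"], team_id)
             for game, team_id, net in _networks(dataset)]
    if not parts:
        return pd.DataFrame(columns=["game_id", "team_id", "passer_id",
                                     "receiver_id", "weight"])
    return pd.concat(parts, ignore_index=True)
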
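"""Event-log data model for 4v4 small-sided games.

The unit of raw data is a *release* of the ball: one player passes (or
shoots) and, if the pass is completed, a teammate receives.  Everything
downstream — possession spells, traditional team metrics, passing
networks — is derived from the time-ordered table of these releases.

Tables are plain :class:`pandas.DataFrame` objects with fixed schemas
(see :data:`EVENT_COLUMNS` etc.); :class:`MatchDataset` bundles them and
enforces referential integrity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "ROSTER_COLUMNS",
    "GAME_COLUMNS",
    "GTSC_CRITERIA",
    "GTSC_COLUMNS",
    "BAND_EARLY",
    "BAND_LATE",
    "GAME_TYPES",
    "MatchDataset",
    "DatasetError",
    "SchemaError",
    "IntegrityError",
    "assign_band",
    "filter_shots",
    "segment_possessions",
    "segment_all_possessions",
    "read_dataset",
    "write_dataset",
]

EVENT_COLUMNS = [
    "game_id", "time_s", "team_id", "passer_id", "receiver_id",
    "success", "is_shot",
]
ROSTER_COLUMNS = ["player_id", "club_id", "pah_percent"]
GAME_COLUMNS = [
    "game_id", "week", "pitch_length_m", "pitch_width_m", "game_type",
    "duration_s", "team_a_id", "team_b_id", "team_a_ids", "team_b_ids",
]
GTSC_CRITERIA = [
    "assists", "communication", "control", "cover_support",
    "decision_making", "first_touch", "marking", "one_v_one",
    "passing", "shooting",
]
GTSC_COLUMNS = ["game_id", "player_id"] + GTSC_CRITERIA

BAND_EARLY = "Early"
BAND_LATE = "Late"
#: Maturity threshold: players at or above this percentage of predicted
#: adult height are classed as early maturing.
PAH_EARLY_THRESHOLD = 90.0

GAME_TYPES = ["EarlyEarly", "LateLate", "EarlyLate", "Mixed"]

PLAYERS_PER_SIDE = 4


class DatasetError(ValueError):
    """Base class for malformed input data."""


class SchemaError(DatasetError):
    """A table is missing required columns."""


class IntegrityError(DatasetError):
    """Cross-table references do not resolve or invariants are violated."""


def assign_band(pah_percent: float) -> str:
    """Classify somatic maturity from percentage of predicted adult height.

    Players at >= 90% of their predicted adult height are ``"Early"``
    (around or past peak height velocity), those below are ``"Late"``.

    Parameters
    ----------
    pah_percent : float
        Estimated percentage of adult height (Khamis–Roche style input).

    Returns
    -------
    str
        ``"Early"`` or ``"Late"``.
    """
    if not math.isfinite(pah_percent):
        raise ValueError(f"pah_percent must be finite, got {pah_percent!r}")
    return BAND_EARLY if pah_percent >= PAH_EARLY_THRESHOLD else BAND_LATE


def assign_bands(pah_percent: pd.Series | np.ndarray) -> np.ndarray:
    """Vectorised :func:`assign_band`."""
    arr = np.asarray(pah_percent, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = np.flatnonzero(~np.isfinite(arr))
        raise ValueError(f"non-finite pah_percent at rows {bad.tolist()}")
    return np.where(arr >= PAH_EARLY_THRESHOLD, BAND_EARLY, BAND_LATE)


def filter_shots(events: pd.DataFrame) -> pd.DataFrame:
    """Drop shot events, keeping only genuine pass attempts.

    The upstream detection hardware cannot reliably distinguish a shot at
    goal from a pass, so shots are flagged in the log and removed before
    any possession or network computation.  Row order is preserved.
    """
    out = events.loc[~events["is_shot"].astype(bool)].copy()
    return out


def _check_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing columns {missing}")


@dataclass
class MatchDataset:
    """A complete study: rosters, games, releases and optional coach scores.

    Attributes
    ----------
    players : pandas.DataFrame
        One row per player: ``player_id, club_id, pah_percent`` plus a
        derived ``band`` column.
    games : pandas.DataFrame
        One row per game with pitch geometry, week, game type, the two
        team labels and their ``;``-separated rosters.  A derived
        ``area_per_player_m2`` column is added on validation.
    events : pandas.DataFrame
        The time-ordered release log (shots included).
    gtsc : pandas.DataFrame or None
        Optional Game Technical Scoring Chart sheets, one row per
        (game, player) with the ten 0–5 criterion scores.
    """

    players: pd.DataFrame
    games: pd.DataFrame
    events: pd.DataFrame
    gtsc: pd.DataFrame | None = None
    _rosters: dict = field(default_factory=dict, repr=False)

    def validate(self) -> "MatchDataset":
        """Check schemas, invariants and referential integrity in place.

        Returns self so calls can be chained.  Events out of time order
        are autocorrected with a warning (stable sort, so ties keep file
        order).
        """
        _check_columns(self.players, ROSTER_COLUMNS, "roster")
        _check_columns(self.games, GAME_COLUMNS, "games")
        _check_columns(self.events, EVENT_COLUMNS, "events")
        if self.gtsc is not None:
            _check_columns(self.gtsc, GTSC_COLUMNS, "gtsc")

        players = self.players
        if players["player_id"].duplicated().any():
            dup = players.loc[players["player_id"].duplicated(), "player_id"]
            raise IntegrityError(f"duplicate player_id(s): {sorted(set(dup))}")
        pah = players["pah_percent"].astype(float)
        if ((pah <= 50) | (pah >= 110)).any():
            bad = players.loc[(pah <= 50) | (pah >= 110), "player_id"].tolist()
            raise IntegrityError(
                f"pah_percent outside plausible (50, 110) range for {bad}")
        players["band"] = assign_bands(pah)

        games = self.games
        if games["game_id"].duplicated().any():
            raise IntegrityError("duplicate game_id(s)")
        games["area_per_player_m2"] = (
            games["pitch_length_m"].astype(float)
            * games["pitch_width_m"].astype(float) / (2 * PLAYERS_PER_SIDE)
        )
        known_players = set(players["player_id"])
        rosters: dict[tuple, tuple] = {}
        for row in games.itertuples(index=False):
            a = tuple(str(row.team_a_ids).split(";"))
            b = tuple(str(row.team_b_ids).split(";"))
            if len(a) != PLAYERS_PER_SIDE or len(b) != PLAYERS_PER_SIDE:
                raise IntegrityError(
                    f"game {row.game_id}: rosters must have "
                    f"{PLAYERS_PER_SIDE} players each")
            if set(a) & set(b):
                raise IntegrityError(
                    f"game {row.game_id}: rosters overlap: {set(a) & set(b)}")
            for pid in a + b:
                if pid not in known_players:
                    raise IntegrityError(
                        f"game {row.game_id} references unknown player "
                        f"'{pid}'")
            if float(row.duration_s) <= 0:
                raise IntegrityError(f"game {row.game_id}: duration_s <= 0")
            rosters[(row.game_id, row.team_a_id)] = a
            rosters[(row.game_id, row.team_b_id)] = b
        if games["game_type"].isin(GAME_TYPES).all() is False:
            bad = sorted(set(games["game_type"]) - set(GAME_TYPES))
            raise IntegrityError(f"unknown game_type(s): {bad}")
        self._rosters = rosters

        ev = self.events
        ev["time_s"] = ev["time_s"].astype(float)
        ev["success"] = ev["success"].astype(bool)
        ev["is_shot"] = ev["is_shot"].astype(bool)
        ev["receiver_id"] = ev["receiver_id"].fillna("").astype(str)
        if len(ev):
            order = ev.sort_values(["game_id", "time_s"], kind="stable").index
            if not np.array_equal(order.to_numpy(), ev.index.to_numpy()):
                warnings.warn(
                    "events were not sorted by (game_id, time_s); "
                    "autocorrecting with a stable sort", stacklevel=2)
                self.events = ev = ev.loc[order].reset_index(drop=True)
            self._validate_events(ev, games, rosters)

        if self.gtsc is not None:
            g = self.gtsc
            for crit in GTSC_CRITERIA:
                vals = g[crit].astype(int)
                if ((vals < 0) | (vals > 5)).any():
                    raise IntegrityError(
                        f"gtsc criterion '{crit}' outside 0–5 range")
            unknown = set(g["player_id"]) - known_players
            if unknown:
                raise IntegrityError(f"gtsc names unknown players {sorted(unknown)}")
        return self

    def _validate_events(self, ev, games, rosters) -> None:
        durations = games.set_index("game_id")["duration_s"].astype(float)
        known_games = set(durations.index)
        for i, row in enumerate(ev.itertuples(index=False)):
            if row.game_id not in known_games:
                raise IntegrityError(
                    f"event row {i}: unknown game_id '{row.game_id}'")
            key = (row.game_id, row.team_id)
            if key not in rosters:
                raise IntegrityError(
                    f"event row {i}: team '{row.team_id}' not in game "
                    f"'{row.game_id}'")
            roster = rosters[key]
            if row.passer_id not in roster:
                raise IntegrityError(
                    f"event row {i}: passer '{row.passer_id}' not on team "
                    f"'{row.team_id}' in game '{row.game_id}'")
            if not 0 <= row.time_s <= durations[row.game_id]:
                raise IntegrityError(
                    f"event row {i}: time_s {row.time_s} outside game")
            if row.success:
                if not row.receiver_id:
                    raise IntegrityError(
                        f"event row {i}: successful pass without receiver")
                if row.receiver_id not in roster:
                    raise IntegrityError(
                        f"event row {i}: receiver '{row.receiver_id}' not a "
                        f"teammate of '{row.passer_id}'")

    def roster(self, game_id, team_id) -> tuple:
        """Roster (tuple of player ids) of ``team_id`` in ``game_id``."""
        if not self._rosters:
            self.validate()
        return self._rosters[(game_id, team_id)]

    def game_events(self, game_id) -> pd.DataFrame:
        return self.events.loc[self.events["game_id"] == game_id]


def segment_possessions(events: pd.DataFrame, game: pd.Series) -> pd.DataFrame:
    """Partition one game's shot-filtered releases into possession spells.

    A possession is a maximal run of consecutive same-team releases.  Its
    duration runs from the run's first release to the first release of the
    next (opposing) run — i.e. until the opponent demonstrably has the
    ball — and the final run of the game closes at its own last release.
    An unsuccessful pass does not by itself end a possession: the team of
    the *next* release decides whether the ball was turned over.

    Parameters
    ----------
    events : pandas.DataFrame
        Shot-filtered events of a single game, time-sorted.
    game : pandas.Series or mapping
        The corresponding game row (only ``game_id`` is used).

    Returns
    -------
    pandas.DataFrame
        Columns ``game_id, team_id, start_s, end_s, n_pass_attempts,
        n_successful``, in chronological order.
    """
    gid = game["game_id"]
    if len(events) and (events["game_id"] != gid).any():
        extra = sorted(set(events["game_id"]) - {gid})
        raise ValueError(
            f"segment_possessions expects events of game '{gid}' only; "
            f"also found {extra}")
    return _segment_sorted(events)


def _segment_sorted(events: pd.DataFrame) -> pd.DataFrame:
    """Core run-length segmentation; events must be time-sorted and may
    span several games (runs never cross a game boundary)."""
    cols = ["game_id", "team_id", "start_s", "end_s",
            "n_pass_attempts", "n_successful"]
    if not len(events):
        return pd.DataFrame(columns=cols)
    gid = events["game_id"].to_numpy()
    team = events["team_id"].to_numpy()
    t = events["time_s"].to_numpy(dtype=float)
    succ = events["success"].to_numpy(dtype=bool)

    new_run = np.ones(len(events), dtype=bool)
    new_run[1:] = (gid[1:] != gid[:-1]) | (team[1:] != team[:-1])
    run_id = np.cumsum(new_run) - 1
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], len(events)) - 1  # last event index per run

    start_s = t[starts]
    # end = start of the next run when it is in the same game (a turnover),
    # else the run's own last event (final possession of the game)
    end_s = t[ends].copy()
    has_next = np.zeros(len(starts), dtype=bool)
    has_next[:-1] = gid[starts[1:]] == gid[starts[:-1]]
    end_s[has_next[:-1].nonzero()[0]] = t[starts[1:][has_next[:-1]]]
    n_att = np.bincount(run_id, minlength=len(starts))
    n_succ = np.bincount(run_id, weights=succ.astype(float),
                         minlength=len(starts)).astype(int)
    return pd.DataFrame({
        "game_id": gid[starts],
        "team_id": team[starts],
        "start_s": start_s,
        "end_s": end_s,
        "n_pass_attempts": n_att,
        "n_successful": n_succ,
    })


def segment_all_possessions(dataset: MatchDataset) -> pd.DataFrame:
    """Shot-filter and segment every game of a dataset in one pass."""
    ev = filter_shots(dataset.events)
    return _segment_sorted(ev)


# ---------------------------------------------------------------------------
# IO

def _read_csv(path, required, table) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} file not found: {path}")
    df = pd.read_csv(path, dtype={c: str for c in (
        "game_id", "team_id", "player_id", "club_id", "passer_id",
        "receiver_id", "team_a_id", "team_b_id", "team_a_ids", "team_b_ids",
    ) if True}, keep_default_na=False, na_values=[])
    _check_columns(df, required, table)
    return df


def read_dataset(events_path, roster_path, games_path,
                 gtsc_path=None) -> MatchDataset:
    """Read and validate a study from its CSV files.

    Booleans are encoded 0/1; a missing receiver is an empty string.
    Raises :class:`SchemaError` / :class:`IntegrityError` with offending
    ids on malformed input.
    """
    events = _read_csv(events_path, EVENT_COLUMNS, "events")
    players = _read_csv(roster_path, ROSTER_COLUMNS, "roster")
    games = _read_csv(games_path, GAME_COLUMNS, "games")
    gtsc = _read_csv(gtsc_path, GTSC_COLUMNS, "gtsc") if gtsc_path else None
    for col in ("time_s",):
        events[col] = pd.to_numeric(events[col])
    for col in ("success", "is_shot"):
        events[col] = pd.to_numeric(events[col]).astype(bool)
    players["pah_percent"] = pd.to_numeric(players["pah_percent"])
    for col in ("week", "duration_s", "pitch_length_m", "pitch_width_m"):
        games[col] = pd.to_numeric(games[col])
    if gtsc is not None:
        for crit in GTSC_CRITERIA:
            gtsc[crit] = pd.to_numeric(gtsc[crit]).astype(int)
    return MatchDataset(players=players, games=games, events=events,
                        gtsc=gtsc).validate()


def write_dataset(dataset: MatchDataset, outdir) -> dict:
    """Write a dataset to ``events.csv``/``roster.csv``/``games.csv``
    (and ``gtsc.csv`` when present) under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ev = dataset.events.copy()
    ev["success"] = ev["success"].astype(int)
    ev["is_shot"] = ev["is_shot"].astype(int)
    paths["events"] = outdir / "events.csv"
    ev[EVENT_COLUMNS].to_csv(paths["events"], index=False)
    paths["roster"] = outdir / "roster.csv"
    dataset.players[ROSTER_COLUMNS].to_csv(paths["roster"], index=False)
    paths["games"] = outdir / "games.csv"
    dataset.games[GAME_COLUMNS].to_csv(paths["games"], index=False)
    if dataset.gtsc is not None:
        paths["gtsc"] = outdir / "gtsc.csv"
        dataset.gtsc[GTSC_COLUMNS].to_csv(paths["gtsc"], index=False)
    return paths
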
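"""Synthetic 4v4 small-sided-game study generator.

Emulates a two-club, four-week bio-banding study: each club fields 16
players (8 early, 8 late maturing, split by percentage of predicted
adult height at 90%), splits each band into two teams of four, and each
week plays a 6-game bio-banded mini-league (game types Early/Early x1,
Late/Late x1, Early/Late x4) followed by 6 games between freshly drawn
mixed-maturity teams — 12 games per club per week, 96 games in all.
Pitch area per player doubles in steps across the four weeks (36.1,
72.0, 108.8, 144.5 m^2).

Game play is an alternating-possession renewal process: possession
durations are lognormal with a pitch-size-dependent mean (larger pitch,
longer possessions), each possession is anchored by the release that
starts it plus Poisson-thinned further attempts, and every attempt
succeeds with a probability set by the passer's maturity band plus a
per-player skill offset.  In mixed-maturity teams, receiver selection
weights early-maturing teammates upward — the single mechanism through
which late players' over-reliance on early teammates, and the resulting
centrality shifts, enter the synthetic data.

Default parameters are calibrated once against the study-level grand
means (about 29 pass attempts per team per game at about 53% completion,
mean possession about 6.5 s, about 1.3 passes per possession) and frozen
here; ``scripts/calibrate_generator.py`` reproduces the calibration
summary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .events import (BAND_EARLY, BAND_LATE, GTSC_CRITERIA, MatchDataset,
                     assign_bands)

__all__ = [
    "GeneratorConfig",
    "PITCH_LEVELS",
    "make_players",
    "make_schedule",
    "simulate_game",
    "simulate_study",
]

#: Week-indexed pitch-size condition labels.
PITCH_LEVELS = ["small", "medium", "large", "expansive"]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; defaults are the calibrated set."""

    seed: int = 0
    n_clubs: int = 2
    players_per_club: int = 16  # 8 early + 8 late
    weeks: int = 4
    #: (length, width) in metres per week; areas/8 give 36.1, 72.0,
    #: 108.8, 144.5 m^2 per player.
    pitch_dims_m: tuple = ((17.0, 17.0), (24.0, 24.0),
                           (29.5, 29.5), (34.0, 34.0))
    game_duration_s: float = 300.0
    #: Mean possession duration (s) per pitch level, small -> expansive.
    possession_mean_s: tuple = (5.9, 6.4, 6.8, 7.3)
    #: Coefficient of variation of the lognormal possession durations.
    possession_cv: float = 0.34
    #: Rate of *additional* pass attempts while in possession (per min);
    #: the release that opens a possession is always present.  A rate of
    #: exactly 0 disables event generation entirely (degenerate guard).
    pass_rate_per_min: float = 2.7
    #: Baseline completion probability by passer maturity band.
    success_prob: dict = field(default_factory=lambda: {
        BAND_EARLY: 0.575, BAND_LATE: 0.495})
    #: SD of the per-player offset added to the completion probability.
    player_skill_sd: float = 0.03
    #: Receiver-choice weight multiplier for early-maturing teammates in
    #: mixed-maturity teams (1 = no preference).
    mixed_preference_to_early: float = 1.6
    #: Probability that a possession ends with a shot at goal.
    shot_prob: float = 0.08
    #: GTSC criterion-score means by band, on the 0–5 scale.
    gtsc_mean: dict = field(default_factory=lambda: {
        BAND_EARLY: 2.70, BAND_LATE: 2.50})
    gtsc_noise_sd: float = 0.9
    gtsc_player_sd: float = 0.4
    #: Additive pitch-level offset to GTSC means (small -> expansive).
    gtsc_pitch_offset: tuple = (-0.10, 0.10, 0.00, 0.05)

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        for key in ("pitch_dims_m", "possession_mean_s", "gtsc_pitch_offset"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(x) if isinstance(x, list) else x
                                 for x in raw[key])
        return cls(**raw)

    def validate(self) -> "GeneratorConfig":
        if not all(0 <= p <= 1 for p in self.success_prob.values()):
            raise ValueError("success probabilities must lie in [0, 1]")
        if min(self.possession_mean_s) <= 0 or self.game_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.mixed_preference_to_early < 1:
            raise ValueError("mixed_preference_to_early must be >= 1")
        if not 0 <= self.shot_prob <= 1:
            raise ValueError("shot_prob must lie in [0, 1]")
        return self


def make_players(config: GeneratorConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Roster table: per club, 8 early (PAH% ~ U(90, 97)) and 8 late
    (PAH% ~ U(83, 89.9)) maturing players."""
    half = config.players_per_club // 2
    rows = []
    for c in range(1, config.n_clubs + 1):
        club = f"C{c}"
        early = rng.uniform(90.0, 97.0, size=half)
        late = rng.uniform(83.0, 89.9, size=half)
        for k, pah in enumerate(np.concatenate([early, late]), start=1):
            rows.append((f"{club}-P{k:02d}", club, round(float(pah), 2)))
    players = pd.DataFrame(rows, columns=["player_id", "club_id", "pah_percent"])
    players["band"] = assign_bands(players["pah_percent"])
    return players


# Mini-league pairing order among four teams (fixed across weeks): with
# teams (E1, E2, L1, L2) this yields game types EE x1, LL x1, EL x4.
_BANDED_PAIRS = [(0, 1), (2, 3), (0, 2), (1, 3), (0, 3), (1, 2)]
_MIXED_PAIRS = [(0, 1), (2, 3), (0, 2), (1, 3), (0, 3), (1, 2)]


def _game_type(bands_a, bands_b) -> str:
    def team_kind(bands):
        s = set(bands)
        return bands[0] if len(s) == 1 else "Mixed"
    ka, kb = team_kind(bands_a), team_kind(bands_b)
    if ka == "Mixed" or kb == "Mixed":
        return "Mixed"
    if ka == kb:
        return "EarlyEarly" if ka == BAND_EARLY else "LateLate"
    return "EarlyLate"


def make_schedule(players: pd.DataFrame, config: GeneratorConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Game table for the full design.

    Bio-banded teams are drawn once per club and kept for all four weeks
    (the match order is fixed); mixed teams (two early + two late players
    each) are re-drawn every week.
    """
    band_lookup = dict(zip(players["player_id"], players["band"]))
    games = []

    def add_game(game_id, week, team_ids, rosters):
        length, width = config.pitch_dims_m[week - 1]
        (ta, tb), (ra, rb) = team_ids, rosters
        games.append({
            "game_id": game_id, "week": week,
            "pitch_length_m": length, "pitch_width_m": width,
            "game_type": _game_type([band_lookup[p] for p in ra],
                                    [band_lookup[p] for p in rb]),
            "duration_s": config.game_duration_s,
            "team_a_id": ta, "team_b_id": tb,
            "team_a_ids": ";".join(ra), "team_b_ids": ";".join(rb),
        })

    for c in range(1, config.n_clubs + 1):
        club = f"C{c}"
        mine = players.loc[players["club_id"] == club]
        early = rng.permutation(mine.loc[mine["band"] == BAND_EARLY,
                                         "player_id"].to_numpy())
        late = rng.permutation(mine.loc[mine["band"] == BAND_LATE,
                                        "player_id"].to_numpy())
        banded_teams = [  # E1, E2, L1, L2
            (f"{club}-E1", tuple(early[:4])), (f"{club}-E2", tuple(early[4:])),
            (f"{club}-L1", tuple(late[:4])), (f"{club}-L2", tuple(late[4:])),
        ]
        for w in range(1, config.weeks + 1):
            for g, (i, j) in enumerate(_BANDED_PAIRS, start=1):
                (ta, ra), (tb, rb) = banded_teams[i], banded_teams[j]
                add_game(f"{club}-W{w}-B{g}", w, (ta, tb), (list(ra), list(rb)))
            ep = rng.permutation(early)
            lp = rng.permutation(late)
            mixed_teams = [
                (f"{club}-W{w}-M{m + 1}",
                 tuple(ep[2 * m: 2 * m + 2]) + tuple(lp[2 * m: 2 * m + 2]))
                for m in range(4)
            ]
            for g, (i, j) in enumerate(_MIXED_PAIRS, start=1):
                (ta, ra), (tb, rb) = mixed_teams[i], mixed_teams[j]
                add_game(f"{club}-W{w}-X{g}", w, (ta, tb), (list(ra), list(rb)))
    return pd.DataFrame(games)


def _lognormal(rng, mean, cv):
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_game(game, players: pd.DataFrame, config: GeneratorConfig,
                  rng: np.random.Generator,
                  skill: dict | None = None,
                  gtsc_skill: dict | None = None):
    """Simulate one game's event log and GTSC sheets.

    Returns ``(events, gtsc)`` as lists of row dicts in chronological /
    roster order.  ``skill`` and ``gtsc_skill`` are optional per-player
    offsets (completion probability and GTSC mean respectively); they
    default to zero.
    """
    skill = skill or {}
    gtsc_skill = gtsc_skill or {}
    band = dict(zip(players["player_id"], players["band"]))
    week = int(game["week"])
    d_mean = config.possession_mean_s[week - 1]
    duration = float(game["duration_s"])
    rosters = {
        game["team_a_id"]: list(game["team_a_ids"].split(";")),
        game["team_b_id"]: list(game["team_b_ids"].split(";")),
    }
    team_ids = list(rosters)

    def receiver_weights(team_roster, passer):
        others = [p for p in team_roster if p != passer]
        bands = {band[p] for p in team_roster}
        if len(bands) > 1 and config.mixed_preference_to_early != 1.0:
            w = np.array([config.mixed_preference_to_early
                          if band[p] == BAND_EARLY else 1.0 for p in others])
        else:
            w = np.ones(len(others))
        return others, w / w.sum()

    events = []
    t = float(rng.uniform(1.0, 3.0))  # kickoff settling time
    side = int(rng.integers(2))
    while t < duration - 1.0:
        team_id = team_ids[side]
        roster = rosters[team_id]
        dur = _lognormal(rng, d_mean, config.possession_cv)
        if config.pass_rate_per_min > 0:
            n_extra = int(rng.poisson(
                config.pass_rate_per_min * dur / 60.0))
            offsets = np.concatenate(
                [[0.0], np.sort(rng.uniform(0.05 * dur, 0.90 * dur, n_extra))])
            passer = roster[int(rng.integers(4))]
            for off in offsets:
                time_s = min(t + off, duration)
                others, w = receiver_weights(roster, passer)
                target = others[int(rng.choice(len(others), p=w))]
                p_succ = float(np.clip(
                    config.success_prob[band[passer]]
                    + skill.get(passer, 0.0), 0.05, 0.95))
                ok = bool(rng.random() < p_succ)
                events.append({
                    "game_id": game["game_id"], "time_s": round(time_s, 3),
                    "team_id": team_id, "passer_id": passer,
                    "receiver_id": target if ok else "",
                    "success": ok, "is_shot": False,
                })
                passer = target if ok else roster[int(rng.integers(4))]
            if rng.random() < config.shot_prob:
                time_s = min(t + 0.95 * dur, duration)
                events.append({
                    "game_id": game["game_id"], "time_s": round(time_s, 3),
                    "team_id": team_id, "passer_id": passer,
                    "receiver_id": "", "success": False, "is_shot": True,
                })
        t += dur
        side = 1 - side

    gtsc = []
    pitch_off = config.gtsc_pitch_offset[week - 1]
    for team_id in team_ids:
        for p in rosters[team_id]:
            mu = (config.gtsc_mean[band[p]] + gtsc_skill.get(p, 0.0)
                  + pitch_off)
            scores = np.clip(
                np.rint(rng.normal(mu, config.gtsc_noise_sd, len(GTSC_CRITERIA))),
                0, 5).astype(int)
            row = {"game_id": game["game_id"], "player_id": p}
            row.update(dict(zip(GTSC_CRITERIA, scores.tolist())))
            gtsc.append(row)
    return events, gtsc


def simulate_study(config: GeneratorConfig | None = None,
                   seed: int | None = None) -> MatchDataset:
    """Generate a complete validated study dataset.

    Fully reproducible from ``config.seed`` (or the ``seed`` override).
    """
    config = (config or GeneratorConfig()).validate()
    if seed is not None:
        config = config.replace(seed=seed)
    rng = np.random.default_rng(config.seed)
    players = make_players(config, rng)
    skill = dict(zip(players["player_id"],
                     rng.normal(0.0, config.player_skill_sd, len(players))))
    gtsc_skill = dict(zip(players["player_id"],
                          rng.normal(0.0, config.gtsc_player_sd, len(players))))
    games = make_schedule(players, config, rng)
    all_events, all_gtsc = [], []
    for _, game in games.iterrows():
        ev, sheets = simulate_game(game, players, config, rng,
                                   skill=skill, gtsc_skill=gtsc_skill)
        all_events.extend(ev)
        all_gtsc.extend(sheets)
    events = pd.DataFrame(all_events, columns=[
        "game_id", "time_s", "team_id", "passer_id", "receiver_id",
        "success", "is_shot"])
    events = events.sort_values(["game_id", "time_s"],
                                kind="stable").reset_index(drop=True)
    gtsc = pd.DataFrame(all_gtsc)
    return MatchDataset(players=players, games=games, events=events,
                        gtsc=gtsc if len(gtsc) else None).validate()
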
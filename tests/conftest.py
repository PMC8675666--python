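import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from ssgnet.events import MatchDataset
from ssgnet.simulate import GeneratorConfig, simulate_study

PLAYERS_A = ["A1", "A2", "A3", "A4"]
PLAYERS_B = ["B1", "B2", "B3", "B4"]


def make_event(game_id="G1", time_s=0.0, team_id="TA", passer="A1",
               receiver="A2", success=True, is_shot=False):
    return {"game_id": game_id, "time_s": time_s, "team_id": team_id,
            "passer_id": passer, "receiver_id": receiver if success else "",
            "success": success, "is_shot": is_shot}


def tiny_dataset(event_rows, game_type="Mixed", duration_s=300.0,
                 week=1, gtsc=None) -> MatchDataset:
    """One-game dataset around a hand-written event list."""
    players = pd.DataFrame({
        "player_id": PLAYERS_A + PLAYERS_B,
        "club_id": "C1",
        "pah_percent": [92.0, 91.0, 88.0, 87.0, 93.0, 90.0, 86.0, 85.0],
    })
    games = pd.DataFrame([{
        "game_id": "G1", "week": week, "pitch_length_m": 17.0,
        "pitch_width_m": 17.0, "game_type": game_type,
        "duration_s": duration_s, "team_a_id": "TA", "team_b_id": "TB",
        "team_a_ids": ";".join(PLAYERS_A), "team_b_ids": ";".join(PLAYERS_B),
    }])
    events = pd.DataFrame(event_rows, columns=[
        "game_id", "time_s", "team_id", "passer_id", "receiver_id",
        "success", "is_shot"])
    return MatchDataset(players=players, games=games, events=events,
                        gtsc=gtsc).validate()


@pytest.fixture
def simple_events():
    """Three possessions: TA (3 attempts), TB (2), TA (1)."""
    return [
        make_event(time_s=2.0, passer="A1", receiver="A2"),
        make_event(time_s=5.0, passer="A2", receiver="A3"),
        make_event(time_s=8.0, passer="A3", receiver="", success=False),
        make_event(time_s=11.0, team_id="TB", passer="B1", receiver="B2"),
        make_event(time_s=14.0, team_id="TB", passer="B2", receiver="",
                   success=False),
        make_event(time_s=20.0, passer="A4", receiver="A1"),
    ]


@pytest.fixture
def simple_dataset(simple_events):
    return tiny_dataset(simple_events)


@pytest.fixture(scope="session")
def default_study() -> MatchDataset:
    """One simulated study with default calibrated parameters."""
    return simulate_study(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
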
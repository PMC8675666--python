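"""Passing networks and their macro/micro metrics.

A team's passing network over one game is a weighted directed graph:
players are nodes, and the edge weight w[i, j] counts successful passes
from player i to player j.  The binary adjacency a[i, j] = (w[i, j] > 0)
records which of the n(n-1) ordered passing options (12 in a 4v4 game)
were used at least once.

Macro (team) metrics
    density    — fraction of ordered passing options used,  sum(a) / n(n-1)
    intensity  — successful passes per minute of possession, sum(w) / T

Micro (player) metrics
    degree      — passes made + received, row-sum + column-sum of w
    closeness   — 1 / sum of shortest-path distances to the other players
    betweenness — sum over ordered pairs (j, k) of the fraction of
                  shortest j→k paths that pass through the player
    pagerank    — stationary importance, PR(i) = (1-d)/N
                  + d * sum over in-neighbours j of PR(j)/C(j)

Path-based metrics use hop counts on the binary digraph by default; an
inverse-weight edge-length variant (length 1/w) is available for
sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PassingNetwork",
    "GraphPaths",
    "PageRankParams",
    "build_network",
    "network_density",
    "network_intensity",
    "degree_centrality",
    "degree_centralities",
    "shortest_paths",
    "closeness_centrality",
    "betweenness_centrality",
    "page_rank",
    "page_rank_linear",
    "centrality_table",
]


@dataclass
class PassingNetwork:
    """Weighted directed passing network of one team over one game."""

    node_ids: list
    w: np.ndarray
    possession_time_min: float

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.node_ids)
        if self.w.shape != (n, n):
            raise ValueError(f"w must be {n}x{n}, got {self.w.shape}")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("self-passes are not allowed (diagonal of w)")
        if self.possession_time_min < 0:
            raise ValueError("possession_time_min must be >= 0")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def a(self) -> np.ndarray:
        """Binary adjacency: 1 where at least one successful pass was made."""
        return (self.w > 0).astype(int)

    @property
    def total_passes(self) -> float:
        return float(self.w.sum())

    def index(self, player_id) -> int:
        try:
            return self.node_ids.index(player_id)
        except ValueError:
            raise KeyError(f"player {player_id!r} not in network") from None


@dataclass
class GraphPaths:
    """All-pairs shortest-path structure of a passing digraph.

    ``dist[j, k]`` is the shortest directed path length (np.inf when k is
    unreachable from j), ``sigma[j, k]`` the number of distinct shortest
    j→k paths, and ``sigma_through[i, j, k]`` the number of those that
    pass through intermediate node i.
    """

    dist: np.ndarray
    sigma: np.ndarray
    sigma_through: np.ndarray


@dataclass
class PageRankParams:
    """Damping factor and iteration controls for the PageRank fixed point."""

    d: float = 0.85
    tol: float = 1e-9
    max_iter: int = 1000

    def __post_init__(self):
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("damping factor d must be in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def build_network(events: pd.DataFrame, possessions: pd.DataFrame,
                  roster) -> PassingNetwork:
    """Build a team's network from its successful shot-filtered passes.

    Parameters
    ----------
    events : pandas.DataFrame
        Successful, shot-filtered pass events of one team in one game.
    possessions : pandas.DataFrame
        That team's possession spells in the game (duration source for T).
    roster : sequence
        The team's players, in the node order the network should use.

    Raises
    ------
    ValueError
        If an event is unsuccessful or names a player outside the roster.
    """
    node_ids = list(roster)
    n = len(node_ids)
    idx = {p: i for i, p in enumerate(node_ids)}
    w = np.zeros((n, n))
    if len(events):
        if not events["success"].all():
            raise ValueError("build_network expects only successful passes")
        if "is_shot" in events and events["is_shot"].any():
            raise ValueError("build_network expects shot-filtered events")
        for passer, receiver in zip(events["passer_id"], events["receiver_id"]):
            if passer not in idx or receiver not in idx:
                raise ValueError(
                    f"pass {passer!r}→{receiver!r} names a player outside "
                    f"the roster {node_ids}")
            w[idx[passer], idx[receiver]] += 1
    if len(possessions):
        t_min = float((possessions["end_s"] - possessions["start_s"]).sum()) / 60.0
    else:
        t_min = 0.0
    return PassingNetwork(node_ids=node_ids, w=w, possession_time_min=t_min)


def network_density(net: PassingNetwork) -> float:
    """Proportion of the n(n-1) ordered passing options used at least once."""
    n = net.n
    if n < 2:
        raise ValueError("density undefined for fewer than 2 players")
    return float(net.a.sum()) / (n * (n - 1))


def network_intensity(net: PassingNetwork) -> float:
    """Successful passes per minute of possession (passing tempo)."""
    total = net.total_passes
    t = net.possession_time_min
    if t <= 0:
        if total == 0:
            warnings.warn("zero possession time and zero passes; "
                          "intensity reported as 0", stacklevel=2)
            return 0.0
        raise ValueError("intensity undefined: passes recorded with zero "
                         "possession time")
    return total / t


def degree_centrality(net: PassingNetwork, player_id) -> float:
    """Total successful passes made and received by the player."""
    i = net.index(player_id)
    return float(net.w[i, :].sum() + net.w[:, i].sum())


def degree_centralities(net: PassingNetwork) -> np.ndarray:
    """Degree of every node, in node order."""
    return net.w.sum(axis=1) + net.w.sum(axis=0)


def _edge_lengths(net: PassingNetwork, weighting: str) -> np.ndarray:
    if weighting == "hops":
        L = np.where(net.a > 0, 1.0, np.inf)
    elif weighting == "inverse-weight":
        with np.errstate(divide="ignore"):
            L = np.where(net.w > 0, 1.0 / net.w, np.inf)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    np.fill_diagonal(L, np.inf)  # no self-loop edges
    return L


def shortest_paths(net: PassingNetwork, weighting: str = "hops",
                   rtol: float = 1e-12) -> GraphPaths:
    """All-pairs shortest paths with path counting.

    Distances and path counts are computed by |V|-step relaxation
    (Floyd–Warshall style with simultaneous count tracking), exact for
    the small networks of a 4v4 game.  ``sigma_through`` uses the
    standard decomposition sigma_jk(i) = sigma_ji * sigma_ik when i lies
    on a shortest j→k path.
    """
    n = net.n
    L = _edge_lengths(net, weighting)
    dist = L.copy()
    np.fill_diagonal(dist, 0.0)
    for m in range(n):  # Floyd–Warshall relaxation for distances
        via = dist[:, m][:, None] + dist[m, :][None, :]
        dist = np.minimum(dist, via)

    # Count shortest paths per source by summing over predecessors in
    # order of increasing distance (exact for positive edge lengths).
    sigma = np.zeros((n, n))
    for j in range(n):
        sigma[j, j] = 1.0
        finite = np.flatnonzero(np.isfinite(dist[j, :]))
        for k in sorted(finite, key=lambda k: dist[j, k]):
            if k == j:
                continue
            preds = np.flatnonzero(
                np.isfinite(L[:, k])
                & np.isclose(dist[j, :] + L[:, k], dist[j, k], rtol=rtol))
            sigma[j, k] = sigma[j, preds].sum()

    sigma_through = np.zeros((n, n, n))
    for i in range(n):
        on_path = np.isclose(dist[:, i][:, None] + dist[i, :][None, :],
                             dist, rtol=rtol)
        on_path &= np.isfinite(dist)
        on_path[i, :] = False
        on_path[:, i] = False
        np.fill_diagonal(on_path, False)
        sigma_through[i] = np.where(
            on_path, sigma[:, i][:, None] * sigma[i, :][None, :], 0.0)
    return GraphPaths(dist=dist, sigma=sigma, sigma_through=sigma_through)


def closeness_centrality(paths: GraphPaths, i: int,
                         n: int | None = None) -> float:
    """Inverse of the summed shortest-path distance from node i.

    Unreachable players contribute a bounded penalty of n (the network
    size) instead of infinity; a player who reaches no-one scores 0.
    """
    dist = paths.dist
    if n is None:
        n = dist.shape[0]
    d = np.delete(dist[i, :], i)
    if not np.any(np.isfinite(d)):
        return 0.0
    total = float(np.where(np.isfinite(d), d, n).sum())
    return 1.0 / total if total > 0 else 0.0


def betweenness_centrality(paths: GraphPaths, i: int) -> float:
    """Unnormalised directed betweenness of node i (endpoints excluded).

    For each ordered pair (j, k) with at least one shortest path, adds
    the fraction of those paths that route through i.  The maximum for a
    4-player network is therefore 6.
    """
    sigma = paths.sigma
    st = paths.sigma_through[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(sigma > 0, st / np.where(sigma > 0, sigma, 1.0), 0.0)
    return float(frac.sum())


def page_rank(net: PassingNetwork, params: PageRankParams | None = None,
              weighted: bool = False) -> np.ndarray:
    """PageRank of every player on the passing digraph.

    Iterates PR(i) = (1-d)/N + d * sum_{j in M(i)} PR(j)/C(j) on the
    binary adjacency (C(j) = out-degree), or splits each player's mass
    proportionally to pass counts when ``weighted=True``.  Players with
    no out-edges (dangling) redistribute their mass uniformly, keeping
    the total at 1.

    Raises
    ------
    RuntimeError
        If the iteration has not converged after ``max_iter`` sweeps; the
        message carries the tail of the convergence trace.
    """
    if params is None:
        params = PageRankParams()
    n = net.n
    if n == 0:
        raise ValueError("empty network")
    M = net.w if weighted else net.a.astype(float)
    out = M.sum(axis=1)
    dangling = out == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(out[:, None] > 0, M / np.where(out[:, None] > 0, out[:, None], 1.0), 0.0)
    pr = np.full(n, 1.0 / n)
    d = params.d
    trace = []
    for _ in range(params.max_iter):
        new = (1 - d) / n + d * (P.T @ pr + pr[dangling].sum() / n)
        delta = float(np.max(np.abs(new - pr)))
        trace.append(delta)
        pr = new
        if delta < params.tol:
            return pr
    raise RuntimeError(
        f"PageRank did not converge in {params.max_iter} iterations; "
        f"last deltas: {trace[-5:]}")


def page_rank_linear(net: PassingNetwork, params: PageRankParams | None = None,
                     weighted: bool = False) -> np.ndarray:
    """Direct linear solve of the PageRank stationarity equations.

    Solves (I - d * (P^T + u 1_dangling^T)) pr = (1-d)/N * 1 where u is
    the uniform vector; used as an internal cross-check of the iterative
    fixed point.
    """
    if params is None:
        params = PageRankParams()
    n = net.n
    M = net.w if weighted else net.a.astype(float)
    out = M.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(out[:, None] > 0, M / np.where(out[:, None] > 0, out[:, None], 1.0), 0.0)
    # dangling rows spread uniformly
    P = P + np.where(out[:, None] == 0, 1.0 / n, 0.0)
    A = np.eye(n) - params.d * P.T
    b = np.full(n, (1 - params.d) / n)
    return np.linalg.solve(A, b)


def centrality_table(net: PassingNetwork, params: PageRankParams | None = None,
                     weighting: str = "hops") -> pd.DataFrame:
    """All four player centralities of one network, in node order.

    Returns a DataFrame with columns ``player_id, degree, closeness,
    betweenness, pagerank``.  PageRank values sum to 1 (within 1e-8).
    """
    paths = shortest_paths(net, weighting=weighting)
    pr = page_rank(net, params)
    rows = {
        "player_id": list(net.node_ids),
        "degree": degree_centralities(net),
        "closeness": [closeness_centrality(paths, i) for i in range(net.n)],
        "betweenness": [betweenness_centrality(paths, i) for i in range(net.n)],
        "pagerank": pr,
    }
    return pd.DataFrame(rows)


def edge_list(net: PassingNetwork, game_id, team_id) -> pd.DataFrame:
    """Nonzero edges as a tidy table for CSV export."""
    src, dst = np.nonzero(net.w)
    return pd.DataFrame({
        "game_id": game_id,
        "team_id": team_id,
        "passer_id": [net.node_ids[i] for i in src],
        "receiver_id": [net.node_ids[j] for j in dst],
        "weight": net.w[src, dst].astype(int),
    })
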
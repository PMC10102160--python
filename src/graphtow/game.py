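"""Tug-of-War games on weighted graphs: DPP fixed point and Monte Carlo.

Two players move a token on the graph. Each turn, with probability alpha/2
the maximizing player moves, with beta/2 the minimizing player, and with
gamma the token jumps to a random neighbour drawn proportionally to the
edge weights; (alpha + beta)/2 + gamma = 1. Play stops on the boundary,
where the terminal payoff g is collected; a running payoff h accrues at
every interior visit. The game value solves the dynamic programming
principle

    u = NLA(u) + h   on the interior,      u = g   on the boundary,

which is the same fixed point the Dirichlet solver computes - the Monte
Carlo engine therefore doubles as a stochastic oracle for it.

On unit-weight graphs the pure Tug-of-War (alpha = beta = 1) playout is the
classical fair-coin game; its pairwise form moves the token to the
maximizer's choice y with probability P(x,y,z) = sqrt(w(x,y)) /
(sqrt(w(x,y)) + sqrt(w(x,z))) and to the minimizer's choice z otherwise.
For general (alpha, beta, gamma) on non-unit weights the playout is
exploratory; the DPP remains the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import WeightedGraph
from .operators import GameParameters, nl_average
from .interpolation import DirichletSpec, SolveReport, solve_dirichlet

__all__ = [
    "GameSpec",
    "ValueEstimate",
    "move_probability",
    "dpp_operator",
    "value_iteration",
    "simulate_game",
]


@dataclass
class GameSpec:
    """Graph game: boundary payoff g, running payoff h, move parameters."""

    graph: WeightedGraph
    boundary: np.ndarray
    g: np.ndarray
    params: GameParameters = field(default_factory=GameParameters)
    h: np.ndarray | None = None
    max_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=int)
        self.g = np.asarray(self.g, dtype=float)
        if self.boundary.size == 0:
            raise ValueError("boundary must be nonempty")
        self.interior = np.setdiff1d(np.arange(self.graph.n_vertices), self.boundary)
        self.dirichlet = DirichletSpec(interior=self.interior, boundary=self.boundary,
                                       g=self.g, h=self.h)
        self.dirichlet.validate_against(self.graph)


@dataclass
class ValueEstimate:
    mean: float
    se: float
    n_playouts: int
    capped: int = 0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")


def move_probability(w_xy: float, w_xz: float) -> float:
    """P(x,y,z): chance the token lands on y rather than z after a move."""
    if w_xy <= 0 or w_xz <= 0:
        raise ValueError("weights must be positive")
    sy, sz = np.sqrt(w_xy), np.sqrt(w_xz)
    return float(sy / (sy + sz))


def dpp_operator(graph: WeightedGraph, u: np.ndarray, spec: GameSpec) -> np.ndarray:
    """One application of the DPP: NLA(u) + h on the interior, g elsewhere."""
    v = nl_average(graph, u, spec.params)
    if spec.h is not None:
        v[spec.interior] += np.asarray(spec.h, dtype=float)
    v[spec.boundary] = spec.g
    return v


def value_iteration(spec: GameSpec, tol: float = 1e-10,
                    max_iter: int = 1_000_000) -> tuple[np.ndarray, SolveReport]:
    """Game value by iterating the DPP to a sup-norm fixed point."""
    return solve_dirichlet(spec.graph, spec.dirichlet, spec.params,
                           tol=tol, max_iter=max_iter)


def _greedy_choices(graph: WeightedGraph, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex argmax/argmin of u over I(x) + {x} (ties: smaller index)."""
    n = graph.n_vertices
    best_max = np.arange(n)
    best_min = np.arange(n)
    for x in range(n):
        cand = np.r_[x, graph.neighbors(x)]
        vals = u[cand]
        best_max[x] = cand[np.argmax(vals)]
        best_min[x] = cand[np.argmin(vals)]
    return best_max, best_min


def simulate_game(spec: GameSpec, start: int, n_playouts: int,
                  value_function: np.ndarray | None = None,
                  rng: np.random.Generator | None = None) -> ValueEstimate:
    """Monte-Carlo estimate of the game value at ``start``.

    Both players play greedily against ``value_function`` (default: the
    value-iteration fixed point); each playout accumulates h at interior
    visits and ends with g at the absorbing boundary vertex. Episodes
    hitting ``spec.max_steps`` are excluded from the mean and counted in
    ``capped``. All playouts are advanced in lockstep (vectorised), which
    is step-for-step equivalent to independent episodes.
    """
    graph = spec.graph
    n = graph.n_vertices
    if not 0 <= start < n:
        raise ValueError("start vertex out of range")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    gfull = np.zeros(n)
    gfull[spec.boundary] = spec.g
    if start in set(spec.boundary.tolist()):
        return ValueEstimate(mean=float(gfull[start]), se=0.0, n_playouts=n_playouts)
    if value_function is None:
        value_function, _ = value_iteration(spec)
    u = np.asarray(value_function, dtype=float)
    best_max, best_min = _greedy_choices(graph, u)
    hfull = np.zeros(n)
    if spec.h is not None:
        hfull[spec.interior] = np.asarray(spec.h, dtype=float)
    is_boundary = np.zeros(n, dtype=bool)
    is_boundary[spec.boundary] = True
    a, b, g = (np.broadcast_to(np.asarray(v, float), (n,))
               for v in (spec.params.alpha, spec.params.beta, spec.params.gamma))
    # per-vertex cumulative move-type thresholds and neighbour tables
    maxdeg = int(graph.degrees().max())
    nbr_tab = np.zeros((n, maxdeg), dtype=int)
    cumw = np.ones((n, maxdeg))
    for x in range(n):
        nb, wt = graph.neighbors(x), graph.neighbor_weights(x)
        if nb.size:
            nbr_tab[x, :nb.size] = nb
            cw = np.cumsum(wt) / wt.sum()
            cumw[x, :nb.size] = cw
            cumw[x, nb.size:] = 1.0
    pos = np.full(n_playouts, start, dtype=int)
    payoff = np.zeros(n_playouts)
    active = np.ones(n_playouts, dtype=bool)
    capped = np.zeros(n_playouts, dtype=bool)
    for _ in range(spec.max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        cur = pos[idx]
        payoff[idx] += hfull[cur]
        r = rng.random(idx.size)
        move_max = r < a[cur] / 2
        move_min = (~move_max) & (r < a[cur] / 2 + b[cur] / 2)
        move_rnd = ~move_max & ~move_min
        nxt = np.empty(idx.size, dtype=int)
        nxt[move_max] = best_max[cur[move_max]]
        nxt[move_min] = best_min[cur[move_min]]
        if move_rnd.any():
            rr = rng.random(move_rnd.sum())
            rows = cur[move_rnd]
            choice = (rr[:, None] > cumw[rows]).sum(axis=1)
            nxt[move_rnd] = nbr_tab[rows, choice]
        pos[idx] = nxt
        done = is_boundary[nxt]
        fin = idx[done]
        payoff[fin] += gfull[pos[fin]]
        active[fin] = False
    capped[:] = active
    ok = ~capped
    n_ok = int(ok.sum())
    if n_ok == 0:
        return ValueEstimate(mean=np.nan, se=np.nan, n_playouts=n_playouts,
                             capped=int(capped.sum()))
    mean = float(payoff[ok].mean())
    se = float(payoff[ok].std(ddof=1) / np.sqrt(n_ok)) if n_ok > 1 else 0.0
    return ValueEstimate(mean=mean, se=se, n_playouts=n_playouts,
                         capped=int(capped.sum()))
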
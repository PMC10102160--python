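"""Discrete difference operators on weighted graphs.

Upwind gradients, the 2-, infinity- and game p-Laplacians, the nonlocal
morphological operators (dilation NLD, erosion NLE, mean NLM), and their
(alpha, beta, gamma)-convex combination NLA, with

    Delta_{a,b,g} u = (a/2) ||grad+ u||_inf - (b/2) ||grad- u||_inf
                      + g * Delta_2 u  =  NLA(u) - u.

All operators act channel-wise on multi-channel signals and treat isolated
vertices as a hard error: neighbourhood-based averages are undefined there.

The upwind gradient at x keeps one-sided weighted differences to neighbours:
d_y^{+-} u(x) = (sqrt(w(x,y)) (u(y) - u(x)))^{+-}, with a^+ = max(a, 0) and
a^- = max(-a, 0).  The finite-p norm raises the clamped difference to the
power p inside the sum (the p -> inf limit then recovers the max form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import WeightedGraph

__all__ = [
    "GameParameters",
    "upwind_gradient_norm",
    "upwind_gradient_norms_inf",
    "laplacian_2",
    "laplacian_2_all",
    "laplacian_inf",
    "game_p_laplacian",
    "nl_dilation",
    "nl_erosion",
    "nl_mean",
    "nl_average",
    "delta_abg",
]

SIMPLEX_TOL = 1e-10


@dataclass(frozen=True)
class GameParameters:
    """Tug-of-War move probabilities (alpha, beta, gamma).

    alpha/2 is the probability the maximizing player moves, beta/2 the
    minimizing player, gamma a random (weight-proportional) move; they must
    satisfy (alpha + beta)/2 + gamma = 1. Each entry may be a scalar or a
    per-vertex array. ``validate=False`` admits off-simplex triples such as
    the pure-erosion (eikonal) setting alpha=gamma=0, beta=1.
    """

    alpha: float | np.ndarray = 1.0
    beta: float | np.ndarray = 1.0
    gamma: float | np.ndarray = 0.0
    validate: bool = True

    def __post_init__(self) -> None:
        a, b, g = (np.asarray(v, dtype=float) for v in (self.alpha, self.beta, self.gamma))
        if np.any(a < 0) or np.any(b < 0) or np.any(g < 0):
            raise ValueError("alpha, beta, gamma must be nonnegative")
        if self.validate and np.any(np.abs((a + b) / 2 + g - 1.0) > SIMPLEX_TOL):
            raise ValueError("(alpha + beta)/2 + gamma must equal 1")

    @classmethod
    def from_p(cls, p: float) -> "GameParameters":
        """Game p-Laplacian row: alpha = beta = (p-2)/p, gamma = 2/p."""
        if p < 2:
            raise ValueError("p must be >= 2")
        if np.isinf(p):
            return cls(1.0, 1.0, 0.0)
        return cls((p - 2) / p, (p - 2) / p, 2 / p)

    def at(self, x: int):
        pick = lambda v: float(np.asarray(v).ravel()[x]) if np.ndim(v) else float(v)
        return pick(self.alpha), pick(self.beta), pick(self.gamma)

    def broadcast(self, n: int):
        """(alpha, beta, gamma) as length-n arrays."""
        return tuple(np.broadcast_to(np.asarray(v, dtype=float), (n,))
                     for v in (self.alpha, self.beta, self.gamma))


# ---------------------------------------------------------------------------
# per-vertex operators
# ---------------------------------------------------------------------------

def _signed_differences(graph: WeightedGraph, u: np.ndarray, x: int, sign: str) -> np.ndarray:
    nbrs = graph.neighbors(x)
    if nbrs.size == 0:
        raise ValueError(f"vertex {x} is isolated")
    diff = np.sqrt(graph.neighbor_weights(x)) * (u[nbrs] - u[x])
    if sign == "+":
        return np.maximum(diff, 0.0)
    if sign == "-":
        return np.maximum(-diff, 0.0)
    raise ValueError("sign must be '+' or '-'")


def upwind_gradient_norm(graph: WeightedGraph, u: np.ndarray, x: int,
                         sign: str, p: float = np.inf) -> float:
    """L_p norm of the upwind gradient of a single-channel signal at x."""
    if p < 1:
        raise ValueError("p must be >= 1")
    d = _signed_differences(graph, np.asarray(u, dtype=float), x, sign)
    if np.isinf(p):
        return float(d.max())
    return float((d ** p).sum() ** (1.0 / p))


def laplacian_2(graph: WeightedGraph, u: np.ndarray, x: int) -> float:
    """Weighted-mean Laplacian: (sum_y w u(y)) / (sum_y w) - u(x)."""
    nbrs = graph.neighbors(x)
    if nbrs.size == 0:
        raise ValueError(f"vertex {x} is isolated")
    w = graph.neighbor_weights(x)
    u = np.asarray(u, dtype=float)
    return float(w @ u[nbrs] / w.sum() - u[x])


def laplacian_inf(graph: WeightedGraph, u: np.ndarray, x: int) -> float:
    """Infinity-Laplacian: half the gap between upwind gradient norms."""
    d = _signed_differences(graph, np.asarray(u, dtype=float), x, "+")
    e = _signed_differences(graph, np.asarray(u, dtype=float), x, "-")
    return 0.5 * float(d.max() - e.max())


def game_p_laplacian(graph: WeightedGraph, u: np.ndarray, x: int, p: float) -> float:
    """Convex combination ((p-2)/p) * inf-Laplacian + (2/p) * 2-Laplacian."""
    if p < 2:
        raise ValueError("p must be >= 2")
    if np.isinf(p):
        return laplacian_inf(graph, u, x)
    return (p - 2) / p * laplacian_inf(graph, u, x) + 2 / p * laplacian_2(graph, u, x)


# ---------------------------------------------------------------------------
# vectorised whole-graph operators
# ---------------------------------------------------------------------------

def _require_no_isolated(graph: WeightedGraph) -> None:
    if graph.has_isolated_vertices():
        raise ValueError("graph has isolated vertices; neighbourhood "
                         "operators are undefined there")


def _as_channels(u: np.ndarray, n: int) -> tuple[np.ndarray, bool]:
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("signal must be finite")
    if u.ndim == 1:
        return u[:, None], True
    if u.ndim == 2 and u.shape[0] == n:
        return u, False
    raise ValueError(f"signal must have shape ({n},) or ({n}, C)")


def upwind_gradient_norms_inf(graph: WeightedGraph, u: np.ndarray):
    """(||grad+ u||_inf, ||grad- u||_inf) at every vertex, per channel."""
    _require_no_isolated(graph)
    n = graph.n_vertices
    uc, squeeze = _as_channels(u, n)
    adj = graph.adj
    src = np.repeat(np.arange(n), np.diff(adj.indptr))
    sw = np.sqrt(adj.data)[:, None]
    diff = sw * (uc[adj.indices] - uc[src])
    plus = np.maximum.reduceat(np.maximum(diff, 0.0), adj.indptr[:-1], axis=0)
    minus = np.maximum.reduceat(np.maximum(-diff, 0.0), adj.indptr[:-1], axis=0)
    if squeeze:
        plus, minus = plus[:, 0], minus[:, 0]
    return plus, minus


def laplacian_2_all(graph: WeightedGraph, u: np.ndarray) -> np.ndarray:
    _require_no_isolated(graph)
    n = graph.n_vertices
    uc, squeeze = _as_channels(u, n)
    deg = np.asarray(graph.adj.sum(axis=1)).ravel()
    out = (graph.adj @ uc) / deg[:, None] - uc
    return out[:, 0] if squeeze else out


def nl_dilation(graph: WeightedGraph, u: np.ndarray) -> np.ndarray:
    """NLD(u) = u + ||grad+ u||_inf (= neighbourhood max incl. x for w = 1)."""
    plus, _ = upwind_gradient_norms_inf(graph, u)
    return np.asarray(u, dtype=float) + plus


def nl_erosion(graph: WeightedGraph, u: np.ndarray) -> np.ndarray:
    """NLE(u) = u - ||grad- u||_inf (= neighbourhood min incl. x for w = 1)."""
    _, minus = upwind_gradient_norms_inf(graph, u)
    return np.asarray(u, dtype=float) - minus


def nl_mean(graph: WeightedGraph, u: np.ndarray) -> np.ndarray:
    """NLM(u) = u + Delta_2 u = weighted mean over I(x)."""
    return np.asarray(u, dtype=float) + laplacian_2_all(graph, u)


def _abg_fields(params: GameParameters, u: np.ndarray, n: int):
    a, b, g = params.broadcast(n)
    if np.ndim(u) == 2:
        a, b, g = a[:, None], b[:, None], g[:, None]
    return a, b, g


def nl_average(graph: WeightedGraph, u: np.ndarray, params: GameParameters) -> np.ndarray:
    """NLA(u) = (alpha/2) NLD(u) + (beta/2) NLE(u) + gamma NLM(u).

    A convex combination of averaging operators, hence itself averaging:
    it stays within [min, max] of u over I(x) and {x} and is nonexpansive.
    """
    a, b, g = _abg_fields(params, u, graph.n_vertices)
    return (a / 2 * nl_dilation(graph, u) + b / 2 * nl_erosion(graph, u)
            + g * nl_mean(graph, u))


def delta_abg(graph: WeightedGraph, u: np.ndarray, params: GameParameters) -> np.ndarray:
    """The (alpha, beta, gamma) operator; equals nl_average(u) - u.

    Recovers the named graph operators at the dictionary parameter points:
    (1,1,0) -> inf-Laplacian, (0,0,1) -> 2-Laplacian, from_p(p) -> game
    p-Laplacian, and (0,1,0) -> -(1/2) ||grad- u||_inf (pure erosion;
    proportional to the eikonal operator).
    """
    plus, minus = upwind_gradient_norms_inf(graph, u)
    a, b, g = _abg_fields(params, u, graph.n_vertices)
    return a / 2 * plus - b / 2 * minus + g * laplacian_2_all(graph, u)
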
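"""Elliptic and parabolic interpolation on weighted graphs.

Solves the Dirichlet problem

    -Delta_{a,b,g} u = h   in A,        u = g   on the boundary dA,

by the fixed-point iteration  u <- NLA(u) + h  on A with u clamped to g on
dA (the explicit Euler scheme for the associated evolution equation with
unit time step).  Because NLA is an averaging operator the iteration is a
sup-norm nonexpansive map, every iterate obeys the maximum principle for
h = 0, and the limit is the unique solution on solvable specs.

``inpaint`` and ``colorize`` are application front-ends: they build the
similarity graph, declare the pixels/points with missing data as the
interior A and everything known as dA, and run the solver with the
infinity-Laplacian parameters (alpha = beta = 1, gamma = 0) by default.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .graph import SimilarityConfig, WeightedGraph, build_grid_graph, build_knn_graph
from .operators import GameParameters, nl_average

__all__ = [
    "DirichletSpec",
    "SolveReport",
    "nla_step",
    "solve_dirichlet",
    "evolve_parabolic",
    "inpaint",
    "colorize",
]


@dataclass
class DirichletSpec:
    """Interior/boundary decomposition with boundary data.

    ``interior`` and ``boundary`` are disjoint vertex index arrays covering
    the graph; ``g`` holds boundary values (rows aligned with ``boundary``),
    ``h`` an optional source on the interior, ``u0`` an optional initial
    guess on the interior (default 0).
    """

    interior: np.ndarray
    boundary: np.ndarray
    g: np.ndarray
    h: np.ndarray | None = None
    u0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.interior = np.asarray(self.interior, dtype=int)
        self.boundary = np.asarray(self.boundary, dtype=int)
        self.g = np.asarray(self.g, dtype=float)
        if self.boundary.size == 0:
            raise ValueError("boundary set must be nonempty")
        if np.intersect1d(self.interior, self.boundary).size:
            raise ValueError("interior and boundary must be disjoint")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("boundary values must be finite")
        if self.g.shape[0] != self.boundary.size:
            raise ValueError("g must have one row per boundary vertex")

    @property
    def n_channels(self) -> int:
        return 1 if self.g.ndim == 1 else self.g.shape[1]

    def validate_against(self, graph: WeightedGraph) -> None:
        n = graph.n_vertices
        covered = np.union1d(self.interior, self.boundary)
        if covered.size != n or covered[0] != 0 or covered[-1] != n - 1:
            raise ValueError("interior and boundary must partition the vertex set")
        # solvability: each component of the graph must carry boundary data
        ncomp, labels = connected_components(graph.adj, directed=False)
        if set(labels[self.interior]) - set(labels[self.boundary]):
            raise ValueError("an interior component has no path to the boundary")

    def full_signal(self, graph: WeightedGraph) -> np.ndarray:
        """Initial full-length signal: u0 (default 0) on A, g on dA."""
        shape = (graph.n_vertices,) if self.g.ndim == 1 else (graph.n_vertices, self.g.shape[1])
        u = np.zeros(shape)
        if self.u0 is not None:
            u[self.interior] = self.u0
        u[self.boundary] = self.g
        return u


@dataclass
class SolveReport:
    iterations: int
    residual: float
    converged: bool
    wall_time: float
    final_update: float = np.nan

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be nonnegative")


def _apply_source(v: np.ndarray, spec: DirichletSpec) -> None:
    if spec.h is not None:
        v[spec.interior] += np.asarray(spec.h, dtype=float)


def nla_step(graph: WeightedGraph, u: np.ndarray, params: GameParameters,
             spec: DirichletSpec) -> np.ndarray:
    """One synchronous update: v = NLA(u) + h on A, v = g on dA."""
    v = nl_average(graph, u, params)
    _apply_source(v, spec)
    v[spec.boundary] = spec.g
    return v


def solve_dirichlet(graph: WeightedGraph, spec: DirichletSpec,
                    params: GameParameters, tol: float = 1e-6,
                    max_iter: int = 100_000,
                    u0: np.ndarray | None = None) -> tuple[np.ndarray, SolveReport]:
    """Iterate ``nla_step`` to a sup-norm fixed point.

    Convergence is declared when the sup-norm update falls at or below
    ``tol``; the report also carries the true fixed-point residual
    ``||u - NLA(u) - h||_inf`` on A. Non-convergence within ``max_iter`` is
    reported, not raised.
    """
    spec.validate_against(graph)
    t0 = time.perf_counter()
    u = spec.full_signal(graph) if u0 is None else np.array(u0, dtype=float)
    u[spec.boundary] = spec.g
    update = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        v = nla_step(graph, u, params, spec)
        update = float(np.max(np.abs(v - u))) if v.size else 0.0
        u = v
        if update <= tol:
            break
    resid_field = u - nla_step(graph, u, params, spec)
    residual = float(np.max(np.abs(resid_field[spec.interior]))) if spec.interior.size else 0.0
    return u, SolveReport(iterations=it, residual=residual,
                          converged=update <= tol,
                          wall_time=time.perf_counter() - t0,
                          final_update=update)


def evolve_parabolic(graph: WeightedGraph, u0: np.ndarray, params, h=None,
                     dt: float = 1.0, steps: int = 0,
                     boundary: np.ndarray | None = None,
                     boundary_values: np.ndarray | None = None) -> list[np.ndarray]:
    """Explicit Euler trajectory of du/dt = NLA(u) - u + h.

    ``params`` may be a :class:`GameParameters` or a callable ``step ->
    GameParameters`` (time-dependent game). ``dt`` must lie in (0, 1] so
    each step is a convex combination (monotone, stable). Returns the
    trajectory ``[u_0, u_1, ..., u_steps]``.
    """
    if not 0 < dt <= 1:
        raise ValueError("dt must lie in (0, 1]")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    u = np.array(u0, dtype=float)
    if boundary is not None:
        u[boundary] = boundary_values
    traj = [u.copy()]
    for k in range(steps):
        p = params(k) if callable(params) else params
        v = nl_average(graph, u, p)
        rhs = v - u if h is None else v - u + np.asarray(h, dtype=float)
        u = u + dt * rhs
        if boundary is not None:
            u[boundary] = boundary_values
        traj.append(u.copy())
    return traj


# ---------------------------------------------------------------------------
# applications
# ---------------------------------------------------------------------------

DEFAULT_GAME = GameParameters(alpha=1.0, beta=1.0, gamma=0.0)


def inpaint(image: np.ndarray, mask: np.ndarray,
            params: GameParameters = DEFAULT_GAME,
            cfg: SimilarityConfig | None = None,
            adjacency: int = 4, tol: float = 1e-6,
            max_iter: int = 100_000) -> tuple[np.ndarray, SolveReport]:
    """Fill masked pixels by graph interpolation from the unmasked ones.

    Builds a grid graph with patch-based photometric weights (patch
    distances ignore masked pixels), sets A = masked pixels and dA = all
    known pixels, and solves the Dirichlet problem. Returns the completed
    image and the solve report.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask must match the image grid")
    if not (~mask).any():
        raise ValueError("no known pixels to interpolate from")
    cfg = cfg or SimilarityConfig(kind="exponential", distance="sqeuclidean",
                                  patch_size=3)
    graph = build_grid_graph(img, adjacency=adjacency, cfg=cfg, mask=mask)
    flat = img.reshape(graph.n_vertices, -1)
    hole = np.flatnonzero(mask.ravel())
    known = np.flatnonzero(~mask.ravel())
    # warm start at the mean known value: constant regions are then an
    # exact fixed point, and gradients need fewer sweeps to relax
    u0 = np.broadcast_to(flat[known].mean(axis=0), (hole.size, flat.shape[1]))
    spec = DirichletSpec(interior=hole, boundary=known, g=flat[known],
                         u0=u0.copy())
    u, report = solve_dirichlet(graph, spec, params, tol=tol, max_iter=max_iter)
    out = img.copy().reshape(flat.shape)
    out[hole] = u[hole]
    return out.reshape(img.shape), report


def colorize(payload: np.ndarray, seed_vertices: np.ndarray,
             seed_colors: np.ndarray,
             params: GameParameters = DEFAULT_GAME,
             cfg: SimilarityConfig | None = None, k: int = 10,
             graph: WeightedGraph | None = None, tol: float = 1e-6,
             max_iter: int = 100_000) -> tuple[np.ndarray, SolveReport]:
    """Diffuse scribble colours over a k-NN graph on geometry/intensity.

    ``payload`` holds the per-vertex geometry or intensity the similarity
    weights are computed from (e.g. XYZ coordinates of a point cloud);
    ``seed_vertices`` index the scribbled vertices with colours
    ``seed_colors`` (rows aligned). Colour channels diffuse independently;
    the initial guess is the mean scribble colour.
    """
    seed_vertices = np.asarray(seed_vertices, dtype=int)
    seed_colors = np.atleast_2d(np.asarray(seed_colors, dtype=float))
    if seed_vertices.size == 0:
        raise ValueError("no scribbles given")
    if graph is None:
        graph = build_knn_graph(payload, k=k, cfg=cfg or SimilarityConfig())
    unknown = np.setdiff1d(np.arange(graph.n_vertices), seed_vertices)
    u0 = np.broadcast_to(seed_colors.mean(axis=0), (unknown.size, seed_colors.shape[1]))
    spec = DirichletSpec(interior=unknown, boundary=seed_vertices,
                         g=seed_colors, u0=u0.copy())
    u, report = solve_dirichlet(graph, spec, params, tol=tol, max_iter=max_iter)
    return u, report
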
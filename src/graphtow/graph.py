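"""Weighted-graph data model and graph construction.

A :class:`WeightedGraph` is a finite simple undirected graph with strictly
positive, symmetric edge weights, stored as a symmetric CSR adjacency matrix.
Vertices may carry a payload vector (pixel intensity, patch, 3D coordinates,
morphological features ...) used by the similarity weighting of the builders.

Builders cover the constructions used throughout the package: pixel grid
graphs (4- or 8-adjacency), k-nearest-neighbour and epsilon-ball graphs on
payload vectors, region adjacency graphs, and the k-NN extension of a RAG by
region mean payloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "WeightedGraph",
    "SimilarityConfig",
    "similarity_weight",
    "pairwise_payload_distance",
    "build_grid_graph",
    "extract_patches",
    "build_knn_graph",
    "build_epsilon_graph",
    "build_rag",
    "knn_extend",
]

#: weights below this are pruned so I(x) = {y : w(x,y) > 0} stays well defined
WEIGHT_PRUNE_THRESHOLD = 1e-12


@dataclass(frozen=True)
class SimilarityConfig:
    """Similarity map s(x,y) turning payload distances into edge weights.

    kind:
        ``constant`` -> s = 1; ``exponential`` -> s = exp(-d / sigma^2);
        ``inverse`` -> s = 1 / (d + 1).
    sigma:
        Scale of the exponential kind. ``None`` means "estimate globally"
        from the mean nonzero candidate distance at build time. May also be
        a per-vertex array (local scaling, geometric mean across the edge).
    distance:
        ``euclidean`` or ``sqeuclidean`` on payload vectors. Patch-based
        photometric weighting conventionally uses ``sqeuclidean``.
    patch_size:
        Odd window width for image patch payloads (1 = raw pixel value).
    """

    kind: str = "exponential"
    sigma: float | np.ndarray | None = None
    distance: str = "euclidean"
    patch_size: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "exponential", "inverse"):
            raise ValueError(f"unknown similarity kind: {self.kind!r}")
        if self.distance not in ("euclidean", "sqeuclidean"):
            raise ValueError(f"unknown distance: {self.distance!r}")
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be a positive odd integer")
        if self.sigma is not None and np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be positive")


def similarity_weight(d, cfg: SimilarityConfig, sigma=None):
    """Map a nonnegative distance to a similarity weight in (0, 1].

    ``sigma`` overrides ``cfg.sigma`` (used by builders after global
    estimation). Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    if cfg.kind == "constant":
        return np.ones_like(d) if d.ndim else 1.0
    if cfg.kind == "inverse":
        out = 1.0 / (d + 1.0)
    else:
        s = cfg.sigma if sigma is None else sigma
        if s is None:
            raise ValueError("exponential similarity needs a sigma")
        out = np.exp(-d / np.asarray(s, dtype=float) ** 2)
    return float(out) if out.ndim == 0 else out


class WeightedGraph:
    """Finite simple undirected graph with positive symmetric edge weights.

    Parameters
    ----------
    adjacency:
        Symmetric sparse (or dense) matrix of nonnegative weights with zero
        diagonal; zeros mean "no edge".
    payload:
        Optional per-vertex feature array of shape ``(n, d)`` (or ``(n,)``).
    shape:
        Optional lattice shape ``(H, W)`` when vertices are image pixels;
        pixel (r, c) is vertex ``r * W + c``.
    """

    def __init__(self, adjacency, payload: np.ndarray | None = None,
                 shape: tuple[int, int] | None = None) -> None:
        adj = sp.csr_matrix(adjacency, dtype=float)
        if adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        adj.setdiag(0.0)
        adj.eliminate_zeros()
        # prune numerically-zero weights, then enforce exact symmetry
        adj.data[adj.data < WEIGHT_PRUNE_THRESHOLD] = 0.0
        adj.eliminate_zeros()
        if (abs(adj - adj.T) > 1e-9 * max(1.0, abs(adj).max() if adj.nnz else 1.0)).nnz:
            raise ValueError("adjacency must be symmetric")
        adj = (adj + adj.T) / 2.0
        if adj.nnz and adj.data.min() <= 0:
            raise ValueError("edge weights must be positive")
        adj.sort_indices()
        self.adj: sp.csr_matrix = adj
        self.payload = None if payload is None else np.atleast_2d(
            np.asarray(payload, dtype=float).reshape(adj.shape[0], -1))
        self.shape = shape

    # -- basic queries ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.adj.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adj.nnz // 2

    def neighbors(self, x: int) -> np.ndarray:
        """I(x): indices of all y with w(x,y) > 0."""
        return self.adj.indices[self.adj.indptr[x]:self.adj.indptr[x + 1]]

    def neighbor_weights(self, x: int) -> np.ndarray:
        return self.adj.data[self.adj.indptr[x]:self.adj.indptr[x + 1]]

    def weight(self, x: int, y: int) -> float:
        return float(self.adj[x, y])

    def degrees(self) -> np.ndarray:
        return np.diff(self.adj.indptr)

    def edges(self) -> Iterator[tuple[int, int, float]]:
        """Iterate undirected edges (x, y, w) with x < y."""
        coo = sp.triu(self.adj, k=1).tocoo()
        for x, y, w in zip(coo.row, coo.col, coo.data):
            yield int(x), int(y), float(w)

    def is_connected(self) -> bool:
        if self.n_vertices <= 1:
            return True
        return connected_components(self.adj, directed=False, return_labels=False) == 1

    def has_isolated_vertices(self) -> bool:
        return bool(np.any(self.degrees() == 0))

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        adj = self.adj
        if adj.diagonal().any():
            raise ValueError("self-loops present")
        if (abs(adj - adj.T)).nnz:
            raise ValueError("weights not symmetric")
        if adj.nnz and adj.data.min() <= 0:
            raise ValueError("nonpositive edge weight")
        if self.payload is not None and self.payload.shape[0] != self.n_vertices:
            raise ValueError("payload size mismatch")

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedGraph(n_vertices={self.n_vertices}, n_edges={self.n_edges})"

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_edges(cls, n: int, edges: Sequence[tuple[int, int, float]],
                   payload=None, shape=None) -> "WeightedGraph":
        seen: dict[tuple[int, int], float] = {}
        for x, y, w in edges:
            x, y, w = int(x), int(y), float(w)
            if x == y:
                raise ValueError(f"self-loop at vertex {x}")
            if w <= 0:
                raise ValueError(f"nonpositive weight on edge ({x},{y})")
            if not (0 <= x < n and 0 <= y < n):
                raise ValueError(f"vertex out of range on edge ({x},{y})")
            key = (min(x, y), max(x, y))
            if key in seen and seen[key] != w:
                raise ValueError(f"conflicting weights for edge {key}")
            seen[key] = w
        if seen:
            xs, ys = np.array(list(seen)).T
            ws = np.fromiter(seen.values(), float, len(seen))
            adj = sp.coo_matrix((np.r_[ws, ws], (np.r_[xs, ys], np.r_[ys, xs])),
                                shape=(n, n))
        else:
            adj = sp.csr_matrix((n, n))
        return cls(adj, payload=payload, shape=shape)


# ---------------------------------------------------------------------------
# distances and patches
# ---------------------------------------------------------------------------

def pairwise_payload_distance(a: np.ndarray, b: np.ndarray, distance: str) -> np.ndarray:
    """Distance between rows of ``a`` and matching rows of ``b``."""
    d2 = np.sum((np.atleast_2d(a) - np.atleast_2d(b)) ** 2, axis=-1)
    return d2 if distance == "sqeuclidean" else np.sqrt(d2)


def extract_patches(image: np.ndarray, n: int) -> np.ndarray:
    """Per-pixel patch vectors P(x) from an (H, W[, C]) image.

    The n x n window centred at each pixel is read in row-major order and
    flattened (channels fastest); borders use replicate padding. Returns an
    array of shape ``(H * W, n * n * C)`` indexed by vertex ``r * W + c``.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError("patch size must be a positive odd integer")
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    H, W, C = img.shape
    r = n // 2
    padded = np.pad(img, ((r, r), (r, r), (0, 0)), mode="edge")
    out = np.empty((H * W, n * n * C))
    k = 0
    for dr in range(n):
        for dc in range(n):
            out[:, k * C:(k + 1) * C] = padded[dr:dr + H, dc:dc + W].reshape(H * W, C)
            k += 1
    return out


def _auto_sigma(distances: np.ndarray) -> float:
    """Global sigma: mean nonzero candidate distance (1.0 if all zero)."""
    nz = distances[distances > 0]
    return float(nz.mean()) if nz.size else 1.0


def _weights_from_distances(d: np.ndarray, cfg: SimilarityConfig,
                            rows=None, cols=None) -> np.ndarray:
    if cfg.kind == "exponential" and cfg.sigma is None:
        return similarity_weight(d, cfg, sigma=_auto_sigma(d))
    if cfg.kind == "exponential" and np.ndim(cfg.sigma) == 1 and rows is not None:
        s = np.asarray(cfg.sigma, dtype=float)
        return similarity_weight(d, cfg, sigma=np.sqrt(s[rows] * s[cols]))
    return similarity_weight(d, cfg)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _lattice_edges(H: int, W: int, adjacency: int) -> tuple[np.ndarray, np.ndarray]:
    offsets = [(0, 1), (1, 0)]
    if adjacency == 8:
        offsets += [(1, 1), (1, -1)]
    elif adjacency != 4:
        raise ValueError("adjacency must be 4 or 8")
    rr, cc = np.mgrid[0:H, 0:W]
    rows, cols = [], []
    for dr, dc in offsets:
        ok = (rr + dr >= 0) & (rr + dr < H) & (cc + dc >= 0) & (cc + dc < W)
        rows.append((rr[ok] * W + cc[ok]).ravel())
        cols.append(((rr[ok] + dr) * W + (cc[ok] + dc)).ravel())
    return np.concatenate(rows), np.concatenate(cols)


def build_grid_graph(image: np.ndarray, adjacency: int = 4,
                     cfg: SimilarityConfig | None = None,
                     mask: np.ndarray | None = None) -> WeightedGraph:
    """Pixel-lattice graph with photometric similarity weights.

    ``image`` is (H, W) or (H, W, C). Payloads are patch vectors of width
    ``cfg.patch_size`` (1 = raw value). ``mask`` optionally marks pixels with
    unreliable values (e.g. an inpainting hole); masked positions are ignored
    in patch distances (mean square over jointly known positions).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:
        img = img[:, :, None]
    H, W, C = img.shape
    cfg = cfg or SimilarityConfig(kind="constant")
    rows, cols = _lattice_edges(H, W, adjacency)
    payload = extract_patches(img, cfg.patch_size)
    if mask is not None and cfg.kind != "constant":
        known = extract_patches((~np.asarray(mask, bool)).astype(float)[:, :, None],
                                cfg.patch_size)
        known = np.repeat(known, C, axis=1) > 0.5
        both = known[rows] & known[cols]
        diff2 = (payload[rows] - payload[cols]) ** 2
        cnt = both.sum(axis=1)
        d = np.where(cnt > 0, (diff2 * both).sum(axis=1) / np.maximum(cnt, 1), 0.0)
        if cfg.distance == "euclidean":
            d = np.sqrt(d)
    else:
        d = pairwise_payload_distance(payload[rows], payload[cols], cfg.distance)
    w = _weights_from_distances(d, cfg, rows, cols)
    adj = sp.coo_matrix((np.broadcast_to(w, rows.shape), (rows, cols)), shape=(H * W, H * W))
    return WeightedGraph(adj + adj.T, payload=payload, shape=(H, W))


def build_knn_graph(features: np.ndarray, k: int,
                    cfg: SimilarityConfig | None = None,
                    mutual: bool = False) -> WeightedGraph:
    """k-nearest-neighbour graph on feature rows.

    The directed k-NN relation is symmetrised by union (edge if either
    endpoint selects the other); ``mutual=True`` keeps only reciprocal
    pairs. Ties in distance are broken by sample index.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop each point from its own neighbour list (handles exact duplicates)
    rows, cols, dists = [], [], []
    for i in range(n):
        others = idx[i] != i
        rows.extend([i] * k)
        cols.extend(idx[i][others][:k])
        dists.extend(dist[i][others][:k])
    rows, cols, dists = np.array(rows), np.array(cols), np.array(dists)
    directed = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    directed.data[:] = 1.0
    und = directed.minimum(directed.T) if mutual else directed.maximum(directed.T)
    und = sp.triu(und, k=1).tocoo()
    cfg = cfg or SimilarityConfig()
    d = pairwise_payload_distance(X[und.row], X[und.col],
                                  cfg.distance)
    w = _weights_from_distances(d, cfg, und.row, und.col)
    adj = sp.coo_matrix((np.broadcast_to(w, und.row.shape), (und.row, und.col)), shape=(n, n))
    return WeightedGraph(adj + adj.T, payload=X)


def build_epsilon_graph(points: np.ndarray, eps: float,
                        cfg: SimilarityConfig | None = None) -> WeightedGraph:
    """Connect every pair at payload distance <= eps."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    nn = NearestNeighbors(radius=eps).fit(X)
    dist_mat = nn.radius_neighbors_graph(X, mode="distance")
    conn = nn.radius_neighbors_graph(X, mode="connectivity")  # keeps d == 0 pairs
    coo = sp.triu(conn, k=1).tocoo()
    cfg = cfg or SimilarityConfig(kind="constant")
    d = (np.asarray(dist_mat[coo.row, coo.col]).ravel()
         if coo.nnz else np.zeros(0))
    if cfg.distance == "sqeuclidean":
        d = d ** 2
    w = _weights_from_distances(d, cfg, coo.row, coo.col)
    adj = sp.coo_matrix((np.broadcast_to(w, coo.row.shape), (coo.row, coo.col)), shape=(n, n))
    adj.setdiag(0)
    return WeightedGraph(adj + adj.T, payload=X)


def build_rag(region_map: np.ndarray, base: WeightedGraph,
              cfg: SimilarityConfig | None = None) -> WeightedGraph:
    """Region adjacency graph over a partition of ``base``'s vertices.

    ``region_map[x]`` gives the region id of base vertex x; ids must cover
    0..R-1. Region payload is the mean payload of its members; regions are
    adjacent iff some member pair is adjacent in ``base``.
    """
    labels = np.asarray(region_map)
    if labels.shape[0] != base.n_vertices:
        raise ValueError("region map must cover every vertex")
    uniq = np.unique(labels)
    if labels.min() < 0 or not np.array_equal(uniq, np.arange(uniq.size)):
        raise ValueError("region ids must be 0..R-1 with every id present")
    R = uniq.size
    coo = sp.triu(base.adj, k=1).tocoo()
    ra, rb = labels[coo.row], labels[coo.col]
    cross = ra != rb
    pairs = sp.coo_matrix((np.ones(cross.sum()),
                           (np.minimum(ra[cross], rb[cross]),
                            np.maximum(ra[cross], rb[cross]))), shape=(R, R)).tocsr()
    pairs.data[:] = 1.0
    means = None
    if base.payload is not None:
        means = np.zeros((R, base.payload.shape[1]))
        np.add.at(means, labels, base.payload)
        means /= np.bincount(labels, minlength=R)[:, None]
    up = sp.triu(pairs, k=1).tocoo()
    cfg = cfg or SimilarityConfig(kind="constant")
    if cfg.kind == "constant" or means is None:
        w = np.ones(up.nnz)
    else:
        d = pairwise_payload_distance(means[up.row], means[up.col], cfg.distance)
        w = _weights_from_distances(d, cfg, up.row, up.col)
    adj = sp.coo_matrix((w, (up.row, up.col)), shape=(R, R))
    return WeightedGraph(adj + adj.T, payload=means)


def knn_extend(graph: WeightedGraph, k: int,
               cfg: SimilarityConfig | None = None) -> WeightedGraph:
    """Union a RAG with the k-NN graph over region mean payloads.

    Lets fronts grow beyond spatial neighbours (e.g. between non-adjacent
    regions of similar mean colour). ``k = 0`` returns the graph unchanged.
    """
    if graph.payload is None:
        raise ValueError("knn_extend requires region payloads")
    if k == 0:
        return graph
    if k >= graph.n_vertices:
        raise ValueError("k must be smaller than the region count")
    knn = build_knn_graph(graph.payload, k, cfg)
    # union keeps the existing RAG weight where an edge is in both
    new_only = knn.adj - knn.adj.multiply(graph.adj.astype(bool).astype(float))
    return WeightedGraph(graph.adj + new_only, payload=graph.payload,
                         shape=graph.shape)
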
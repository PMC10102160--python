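"""File I/O: images, point clouds, feature tables, edge lists, seeds.

Images are exchanged as PNG/TIFF through imageio and live internally as
float arrays in [0, 1]. Point clouds use ASCII PLY (x, y, z + red, green,
blue vertex properties) or plain whitespace XYZRGB text. Tabular data
(features, edge lists, seed labels) go through pandas CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .graph import WeightedGraph

__all__ = [
    "load_image", "save_image", "load_mask",
    "load_pointcloud", "save_pointcloud",
    "load_features", "load_seeds", "save_labels",
    "load_edgelist", "save_edgelist",
]


def load_image(path) -> np.ndarray:
    """Read PNG/TIFF into a float array scaled to [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return arr


def save_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF."""
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (img * 255).round().astype(np.uint8))


def load_mask(path) -> np.ndarray:
    """Single-channel mask image; nonzero = selected."""
    arr = load_image(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


# -- point clouds -----------------------------------------------------------

_PLY_HEADER = """ply
format ascii 1.0
element vertex {n}
property float x
property float y
property float z
property uchar red
property uchar green
property uchar blue
end_header
"""


def save_pointcloud(path, xyz: np.ndarray, rgb: np.ndarray | None = None) -> None:
    """Write ASCII PLY (``.ply``) or whitespace XYZRGB text (anything else).

    ``rgb`` is float in [0, 1]; PLY stores it as uint8, the text format
    keeps full precision.
    """
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    if rgb is None:
        rgb = np.zeros_like(xyz)
    rgb = np.atleast_2d(np.asarray(rgb, dtype=float))
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".ply":
            fh.write(_PLY_HEADER.format(n=len(xyz)))
            c8 = np.clip(rgb * 255, 0, 255).round().astype(int)
            for p, c in zip(xyz, c8):
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {c[0]} {c[1]} {c[2]}\n")
        else:
            for p, c in zip(xyz, rgb):
                fh.write(" ".join(f"{v:.17g}" for v in (*p, *c)) + "\n")


def load_pointcloud(path) -> tuple[np.ndarray, np.ndarray]:
    """Read ASCII PLY or whitespace XYZRGB text; returns (xyz, rgb in [0,1])."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("ply"):
        lines = text.splitlines()
        try:
            n = next(int(l.split()[-1]) for l in lines if l.startswith("element vertex"))
            body_at = next(i for i, l in enumerate(lines) if l.strip() == "end_header") + 1
        except StopIteration:
            raise ValueError(f"{path}: malformed PLY header") from None
        if "format ascii" not in text:
            raise ValueError(f"{path}: only ASCII PLY is supported")
        rows = [l.split() for l in lines[body_at:body_at + n]]
        if len(rows) != n or any(len(r) < 6 for r in rows):
            raise ValueError(f"{path}: PLY body shorter than declared ({n} vertices)")
        data = np.array(rows, dtype=float)
        return data[:, :3], data[:, 3:6] / 255.0
    rows = [l.split() for l in text.splitlines() if l.strip()]
    if any(len(r) not in (3, 6) for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) not in (3, 6))
        raise ValueError(f"{path}: line {bad + 1} must have 3 or 6 columns")
    data = np.array(rows, dtype=float)
    rgb = data[:, 3:6] if data.shape[1] == 6 else np.zeros((len(data), 3))
    return data[:, :3], rgb


# -- tables -----------------------------------------------------------------

def load_features(path) -> tuple[np.ndarray, list[str]]:
    """CSV with header row, one sample per row -> (array, column names)."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), list(df.columns)


def load_seeds(path) -> tuple[np.ndarray, np.ndarray]:
    """CSV ``vertex,label`` -> (vertex ids, labels)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns vertex,label")
    return df.iloc[:, 0].to_numpy(dtype=int), df.iloc[:, 1].to_numpy()


def save_labels(path, vertices: np.ndarray, labels: np.ndarray) -> None:
    pd.DataFrame({"vertex": vertices, "label": labels}).to_csv(path, index=False)


def load_edgelist(path, n_vertices: int | None = None) -> WeightedGraph:
    """CSV ``x,y,w`` (undirected, each edge once) -> WeightedGraph."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns x,y,w")
    xs = df.iloc[:, 0].to_numpy(dtype=int)
    ys = df.iloc[:, 1].to_numpy(dtype=int)
    ws = df.iloc[:, 2].to_numpy(dtype=float)
    bad = np.flatnonzero(ws <= 0)
    if bad.size:
        raise ValueError(f"{path}: row {bad[0] + 2} has nonpositive weight")
    n = int(max(xs.max(), ys.max()) + 1) if n_vertices is None else n_vertices
    return WeightedGraph.from_edges(n, list(zip(xs, ys, ws)))


def save_edgelist(path, graph: WeightedGraph) -> None:
    rows = [(x, y, w) for x, y, w in graph.edges()]
    pd.DataFrame(rows, columns=["x", "y", "w"]).to_csv(path, index=False)
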
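"""End-to-end application pipelines and run manifests.

``run_pipeline(command, config)`` dispatches to the application solvers,
writes its artifacts next to the configured output path, and returns a
manifest (config hash, package version, seeds, solve reports). Pipelines
are pure functions of (config, seed): repeated runs are bit-identical up
to timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .eikonal import EikonalSpec, LabelSeeds, classify_semi_supervised, \
    propagate_labels, solve_eikonal, superpixels
from .graph import SimilarityConfig
from .interpolation import colorize, inpaint
from .io import load_edgelist, load_features, load_image, load_mask, \
    load_pointcloud, load_seeds, save_image, save_labels, save_pointcloud
from .game import GameSpec, simulate_game
from .operators import GameParameters
from .synthetic import FixtureConfig, generate_blob_features, \
    generate_point_cloud, generate_test_image

COMMANDS = ("inpaint", "colorize", "segment", "superpixels", "cluster",
            "solve-eikonal", "simulate", "generate", "demo")

#: fixed palette for label images (cycled beyond 12 labels)
LABEL_PALETTE = np.array([
    [0, 0, 0], [230, 25, 75], [60, 180, 75], [0, 130, 200], [255, 225, 25],
    [145, 30, 180], [70, 240, 240], [240, 50, 230], [210, 245, 60],
    [250, 190, 190], [0, 128, 128], [128, 128, 0],
]) / 255.0


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _similarity(config: dict) -> SimilarityConfig:
    return SimilarityConfig(
        kind=config.get("kind", "exponential"),
        sigma=config.get("sigma"),
        distance=config.get("distance", "sqeuclidean"),
        patch_size=int(config.get("patch", 3)),
    )


def _game(config: dict) -> GameParameters:
    return GameParameters(alpha=config.get("alpha", 1.0),
                          beta=config.get("beta", 1.0),
                          gamma=config.get("gamma", 0.0))


def labels_to_image(labels: np.ndarray) -> np.ndarray:
    return LABEL_PALETTE[(np.asarray(labels) % (len(LABEL_PALETTE) - 1)) + 1]


def run_pipeline(command: str, config: dict) -> dict:
    """Run one application pipeline; returns the manifest dict."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command: {command!r}")
    t0 = time.perf_counter()
    out = Path(config.get("out", "out"))
    manifest: dict = {
        "command": command,
        "config": dict(config),
        "config_hash": config_hash({"command": command, **config}),
        "version": __version__,
        "artifacts": [],
    }

    def emit(path, kind):
        manifest["artifacts"].append({"path": str(path), "kind": kind})

    if command == "inpaint":
        image = load_image(config["image"])
        mask = load_mask(config["mask"])
        result, report = inpaint(image, mask, params=_game(config),
                                 cfg=_similarity(config),
                                 tol=float(config.get("tol", 1e-6)))
        save_image(out, result)
        emit(out, "image")
        manifest["report"] = asdict(report)

    elif command == "colorize":
        xyz, rgb = load_pointcloud(config["input"])
        seed_v, seed_l = load_seeds(config["scribbles"])
        # scribble file may carry either a colour index or per-channel values
        colors = np.asarray(seed_l, dtype=float)
        if colors.ndim == 1:
            colors = labels_to_image(colors.astype(int))
        result, report = colorize(xyz, seed_v, colors, params=_game(config),
                                  k=int(config.get("knn", 10)),
                                  tol=float(config.get("tol", 1e-6)))
        save_pointcloud(out, xyz, result)
        emit(out, "pointcloud")
        manifest["report"] = asdict(report)

    elif command == "segment":
        image = load_image(config["image"])
        seed_img = load_image(config["seeds"])
        if seed_img.ndim == 3:
            seed_img = seed_img[..., 0]
        seed_labels = (seed_img * 255).round().astype(int).ravel()
        seeds = LabelSeeds.from_array(np.where(seed_labels > 0, seed_labels, -1))
        from .graph import build_grid_graph
        graph = build_grid_graph(image, adjacency=4, cfg=_similarity(config))
        p = float(config.get("p", np.inf)) if config.get("p") not in ("inf", None) else np.inf
        labels, _ = propagate_labels(graph, seeds, h=1.0, p=p)
        save_image(out, labels_to_image(labels.reshape(image.shape[:2])))
        save_labels(str(out) + ".csv", np.arange(labels.size), labels)
        emit(out, "label_image")

    elif command == "superpixels":
        image = load_image(config["image"])
        regions = superpixels(image, spacing=int(config.get("spacing", 8)),
                              cfg=_similarity(config))
        save_image(out, labels_to_image(regions))
        save_labels(str(out) + ".csv", np.arange(regions.size), regions.ravel())
        emit(out, "label_image")
        manifest["n_regions"] = int(regions.max() + 1)

    elif command == "cluster":
        X, _ = load_features(config["features"])
        seed_v, seed_l = load_seeds(config["labels"])
        y = np.full(X.shape[0], -1, dtype=int)
        y[seed_v] = seed_l.astype(int)
        from .estimators import EikonalClassifier
        clf = EikonalClassifier(n_neighbors=int(config.get("knn", 10)),
                                p=float(config.get("p", 1)))
        clf.fit(X, y)
        save_labels(out, np.arange(X.shape[0]), clf.transduction_)
        emit(out, "labels")

    elif command == "solve-eikonal":
        graph = load_edgelist(config["graph"])
        seed_v, _ = load_seeds(config["seeds"])
        p = np.inf if str(config.get("p", "inf")) == "inf" else float(config["p"])
        values = solve_eikonal(graph, EikonalSpec(seeds=seed_v,
                                                  h=float(config.get("h", 1.0)), p=p))
        save_labels(out, np.arange(values.size), values)
        emit(out, "values")

    elif command == "simulate":
        graph = load_edgelist(config["graph"])
        bnd_v, bnd_g = load_seeds(config["boundary"])
        spec = GameSpec(graph=graph, boundary=bnd_v,
                        g=np.asarray(bnd_g, dtype=float), params=_game(config),
                        seed=int(config.get("seed", 0)))
        est = simulate_game(spec, start=int(config["start"]),
                            n_playouts=int(config.get("n", 10_000)))
        result = {"mean": est.mean, "se": est.se, "n_playouts": est.n_playouts,
                  "capped": est.capped}
        Path(out).write_text(json.dumps(result, indent=2))
        emit(out, "json")
        manifest["estimate"] = result

    elif command == "generate":
        cfg = FixtureConfig(kind=config.get("fixture", "holed_image"),
                            seed=int(config.get("seed", 0)))
        outdir = Path(config.get("out", "fixtures"))
        outdir.mkdir(parents=True, exist_ok=True)
        if cfg.kind == "blob_features":
            X, y = generate_blob_features(cfg)
            np.savetxt(outdir / "features.csv", X, delimiter=",",
                       header=",".join(f"f{i}" for i in range(X.shape[1])), comments="")
            save_labels(outdir / "labels.csv", np.arange(y.size), y)
        elif cfg.kind == "point_cloud_clusters":
            xyz, rgb, sv, sc, _ = generate_point_cloud(cfg)
            save_pointcloud(outdir / "cloud.ply", xyz, rgb)
            save_labels(outdir / "scribbles.csv", sv, np.arange(sv.size) // 5)
        else:
            image, mask, truth = generate_test_image(cfg)
            save_image(outdir / "image.png", image)
            save_image(outdir / "mask.png", mask.astype(float))
            save_image(outdir / "truth.png", truth)
        emit(outdir, "fixtures")

    elif command == "demo":
        manifest["demo"] = _run_demo(int(config.get("seed", 0)))

    manifest["wall_time"] = time.perf_counter() - t0
    manifest_path = Path(str(out) + ".manifest.json")
    try:
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        manifest["manifest_path"] = str(manifest_path)
    except OSError:
        pass
    return manifest


def _run_demo(seed: int) -> dict:
    """Small end-to-end exercise of every solver on generated fixtures."""
    results = {}
    image, mask, truth = generate_test_image(FixtureConfig(kind="holed_image",
                                                           seed=seed, hole=6,
                                                           height=16, width=16))
    filled, report = inpaint(image, mask)
    results["inpaint_sup_error"] = float(np.max(np.abs(filled - truth)))
    xyz, rgb, sv, sc, prim = generate_point_cloud(FixtureConfig(
        kind="point_cloud_clusters", seed=seed, n_points=120))
    colors, _ = colorize(xyz, sv, sc, k=8)
    results["colorize_sup_error"] = float(np.max(np.abs(colors - rgb)))
    regions = superpixels(truth, spacing=8)
    results["n_superpixels"] = int(regions.max() + 1)
    X, y = generate_blob_features(FixtureConfig(kind="blob_features", seed=seed,
                                                n_samples=200))
    _, acc, _ = classify_semi_supervised(X, y, labeled_fraction=0.1, k=8, p=1,
                                         seed=seed)
    results["classification_accuracy"] = acc
    return results
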
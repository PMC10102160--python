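"""scikit-learn estimator front-end for eikonal label propagation."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted, check_X_y

from .eikonal import LabelSeeds, propagate_labels
from .graph import SimilarityConfig, build_knn_graph


class EikonalClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised classifier by eikonal front propagation.

    Builds a k-NN similarity graph over all samples (labelled and
    unlabelled) and propagates each class's front with unit potential; a
    sample takes the class of the first-arriving front. Unlabelled training
    samples are marked with ``y = -1``, mirroring
    ``sklearn.semi_supervised.LabelPropagation``.

    Parameters
    ----------
    n_neighbors : int
        k of the k-NN graph (symmetrised by union).
    p : {1, 2, inf}
        Norm index of the eikonal local solve.
    kind, sigma, metric : similarity weighting of graph edges; ``sigma=None``
        estimates a global scale from the candidate edge distances.

    Attributes
    ----------
    classes_ : ndarray of the distinct (non-negative) class labels.
    transduction_ : predicted label of every training sample.
    arrival_ : front arrival value of every training sample.
    """

    def __init__(self, n_neighbors: int = 10, p: float = 1,
                 kind: str = "exponential", sigma: float | None = None,
                 metric: str = "euclidean"):
        self.n_neighbors = n_neighbors
        self.p = p
        self.kind = kind
        self.sigma = sigma
        self.metric = metric

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = np.asarray(y, dtype=int)
        if not (y != -1).any():
            raise ValueError("at least one labelled sample is required")
        cfg = SimilarityConfig(kind=self.kind, sigma=self.sigma,
                               distance=self.metric)
        graph = build_knn_graph(X, k=self.n_neighbors, cfg=cfg)
        seeds = LabelSeeds.from_array(y, unlabeled=-1)
        label_idx, arrival = propagate_labels(graph, seeds, h=1.0, p=self.p)
        classes = np.asarray(seeds.labels)
        self.classes_ = classes
        self.X_ = X
        self.transduction_ = np.where(label_idx >= 0,
                                      classes[np.maximum(label_idx, 0)], -1)
        self.arrival_ = arrival
        return self

    def predict(self, X):
        """Labels for new points: the transduced label of the nearest
        training sample (inductive extension of a transductive method)."""
        check_is_fitted(self, "transduction_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        nn = NearestNeighbors(n_neighbors=1).fit(self.X_)
        _, idx = nn.kneighbors(X)
        return self.transduction_[idx[:, 0]]
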
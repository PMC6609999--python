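"""Classifiers: least-squares SVM (primary) and a k-means baseline.

The LS-SVM replaces the SVM's inequality constraints with equalities, so
training reduces to one linear (KKT) system

    [ 0   1^T          ] [ b     ]   [ 0 ]
    [ 1   K + I/gamma  ] [ alpha ] = [ y ]

with the RBF kernel K(x, z) = exp(-||x - z||^2 / (2 sigma^2)), ridge term
1/gamma, and targets y in {-1, +1}. The decision score of a new point is
f(x) = sum_i alpha_i K(x, x_i) + b. Default hyperparameters gamma = 10,
sigma = 1.

The k-means baseline is plain Lloyd iteration with seeded kmeans++-style
initialisation; its clusters are mapped to classes by majority vote against
the training truth when available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["LSSVMModel", "lssvm_fit", "lssvm_predict", "KMeansModel", "kmeans_fit_predict"]


def _rbf_kernel(X: np.ndarray, Z: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-cdist(X, Z, "sqeuclidean") / (2.0 * sigma**2))


@dataclass(frozen=True)
class LSSVMModel:
    """Fitted LS-SVM: every training point is a support point."""

    support_points: np.ndarray
    alphas: np.ndarray
    bias: float
    gamma: float
    sigma: float

    def to_dict(self) -> dict:
        return {
            "type": "lssvm",
            "support_points": self.support_points.tolist(),
            "alphas": self.alphas.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "sigma": self.sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMModel":
        return cls(
            support_points=np.asarray(d["support_points"], dtype=float),
            alphas=np.asarray(d["alphas"], dtype=float),
            bias=float(d["bias"]),
            gamma=float(d["gamma"]),
            sigma=float(d["sigma"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "LSSVMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def lssvm_fit(
    X: np.ndarray, y: np.ndarray, gamma: float = 10.0, sigma: float = 1.0
) -> LSSVMModel:
    """Train an LS-SVM by solving its KKT linear system.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Feature matrix; must be finite.
    y : ndarray
        Labels in {-1, +1}; both classes must be present.
    gamma : float
        Regularisation (larger = less ridge). Must be positive.
    sigma : float
        RBF kernel width. Must be positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    if len(X) < 2:
        raise ValueError("need at least 2 training points")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if gamma <= 0 or sigma <= 0:
        raise ValueError("gamma and sigma must be positive")

    n = len(X)
    K = _rbf_kernel(X, X, sigma)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"LS-SVM KKT system is singular: {exc}") from exc
    resid = np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"LS-SVM KKT solve inaccurate: relative residual {resid:.3e}"
        )
    return LSSVMModel(
        support_points=X.copy(), alphas=sol[1:], bias=float(sol[0]), gamma=gamma, sigma=sigma
    )


def lssvm_predict(model: LSSVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores and sign labels for new points.

    Returns ``(scores, labels)``; a score of exactly 0 maps to +1.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0), np.zeros(0, dtype=int)
    if X.ndim != 2 or X.shape[1] != model.support_points.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[-1]} does not match training "
            f"dimension {model.support_points.shape[1]}"
        )
    scores = _rbf_kernel(X, model.support_points, model.sigma) @ model.alphas + model.bias
    labels = np.where(scores >= 0, 1, -1)
    return scores, labels


@dataclass(frozen=True)
class KMeansModel:
    centers: np.ndarray
    k: int
    label_map: dict  # cluster index -> class label
    inertia_history: tuple = ()  # within-cluster SSE after each Lloyd sweep


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [X[rng.integers(len(X))]]
    for _ in range(1, k):
        d2 = np.min(cdist(X, np.array(centers), "sqeuclidean"), axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(len(X))])
        else:
            centers.append(X[rng.choice(len(X), p=d2 / total)])
    return np.array(centers)


def kmeans_fit_predict(
    X: np.ndarray,
    k: int = 2,
    seed: int = 0,
    truth_for_mapping: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> tuple[np.ndarray, KMeansModel]:
    """Cluster with Lloyd's algorithm and optionally map clusters to classes.

    Iterates until the largest centroid movement falls below `tol` or
    `max_iter` sweeps. Empty clusters keep their previous centre. When
    `truth_for_mapping` is given each cluster is assigned the majority class
    among its members and the returned labels are class labels; otherwise
    raw cluster indices are returned.
    """
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(X) < k:
        raise ValueError(f"need at least k={k} points, got {len(X)}")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(X, k, rng)
    assign = np.zeros(len(X), dtype=int)
    inertia_history: list[float] = []
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        assign = np.argmin(d2, axis=1)
        inertia_history.append(float(d2[np.arange(len(X)), assign].sum()))
        new_centers = centers.copy()
        for c in range(k):
            members = X[assign == c]
            if len(members):
                new_centers[c] = members.mean(axis=0)
        shift = np.max(np.linalg.norm(new_centers - centers, axis=1))
        centers = new_centers
        if shift < tol:
            break
    assign = np.argmin(cdist(X, centers, "sqeuclidean"), axis=1)

    label_map: dict = {c: c for c in range(k)}
    labels = assign
    if truth_for_mapping is not None:
        truth = np.asarray(truth_for_mapping)
        for c in range(k):
            members = truth[assign == c]
            if len(members):
                vals, counts = np.unique(members, return_counts=True)
                label_map[c] = vals[np.argmax(counts)]
        labels = np.array([label_map[c] for c in assign])
    return labels, KMeansModel(
        centers=centers, k=k, label_map=label_map,
        inertia_history=tuple(inertia_history),
    )


def kmeans_inertia(X: np.ndarray, centers: np.ndarray) -> float:
    """Within-cluster sum of squares for given centres (diagnostic)."""
    return float(np.min(cdist(X, centers, "sqeuclidean"), axis=1).sum())
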
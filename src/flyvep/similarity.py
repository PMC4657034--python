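"""Genotype-level response-similarity analysis.

Mean response vectors per genotype, pairwise distances between them,
2-D multidimensional scaling of the distance matrix, and a convex-hull
cluster-separation check of the embedding (are the control and
early-onset-PD clusters disjoint? does an outlier genotype fall outside
both hulls?).

The MDS embedding is nonmetric (Kruskal stress-1 minimization via SMACOF)
initialized from the classical-scaling solution, so it is deterministic;
orientation, reflection and scale of the axes are arbitrary, and any
comparison of embeddings must follow Procrustes alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.manifold import smacof

from .design import canonical_columns
from .exceptions import (
    ConfigurationError,
    LabellingError,
    UndefinedCorrelationError,
)


def genotype_means(features, labels=None) -> pd.DataFrame:
    """Arithmetic mean feature vector per genotype (K x 64 table)."""
    if isinstance(features, pd.DataFrame):
        cols = [c for c in canonical_columns() if c in features.columns]
        if not cols:
            cols = [c for c in features.columns if c not in ("fly_id", "genotype")]
        if labels is None:
            if "genotype" not in features.columns:
                raise LabellingError("no genotype column and no labels given")
            labels = features["genotype"].to_numpy()
        X = features[cols]
    else:
        X = pd.DataFrame(np.asarray(features, dtype=float),
                         columns=canonical_columns())
        if labels is None:
            raise LabellingError("labels are required when features is an array")
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise LabellingError(
            f"{len(labels)} labels for {len(X)} rows"
        )
    return X.groupby(labels, sort=False).mean()


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        K = len(self.labels)
        if self.d.shape != (K, K):
            raise ConfigurationError(
                f"distance matrix shape {self.d.shape} does not match "
                f"{K} labels"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def distance_matrix(means, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between genotype mean response vectors.

    ``euclidean``: plain Euclidean distance (the default);
    ``correlation``: 1 - Pearson r, an alternative for sensitivity checks.
    """
    if isinstance(means, pd.DataFrame):
        labels = list(means.index)
        M = means.to_numpy(dtype=float)
    else:
        M = np.asarray(means, dtype=float)
        labels = list(range(M.shape[0]))
    if M.shape[0] < 2:
        raise ConfigurationError("need at least 2 genotypes")

    if metric == "euclidean":
        diff = M[:, None, :] - M[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    elif metric == "correlation":
        sd = M.std(axis=1)
        if np.any(sd == 0):
            bad = [labels[i] for i in np.flatnonzero(sd == 0)]
            raise UndefinedCorrelationError(
                f"correlation distance undefined for constant mean vectors: {bad}"
            )
        r = np.corrcoef(M)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
    else:
        raise ConfigurationError(f"unknown metric {metric!r}")
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class Embedding2D:
    labels: list
    coords: np.ndarray
    stress: float
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.labels, columns=["x", "y"])


def classical_scaling(D: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson classical scaling: eigendecomposition of the
    double-centered squared distance matrix. Used as the deterministic
    initialization of the stress minimization."""
    K = D.shape[0]
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    w_top = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_top)


def mds_embed(
    D: DistanceMatrix,
    dims: int = 2,
    seed: Optional[int] = None,
    max_iter: int = 500,
    eps: float = 1e-6,
    n_restarts: int = 0,
) -> Embedding2D:
    """Nonmetric MDS (Kruskal stress-1) of a distance matrix.

    Initialized from the classical-scaling solution for determinism; the
    seed is only used when random restarts are requested. Non-convergence
    sets ``converged=False`` with a warning rather than failing silently.
    """
    K = len(D.labels)
    if K == 2:
        # exactly embeddable: two points on the x axis, d12 apart
        coords = np.array([[0.0, 0.0], [D.d[0, 1], 0.0]])[:, :dims]
        return Embedding2D(labels=list(D.labels), coords=coords,
                           stress=0.0, converged=True)
    if dims >= K:
        raise ConfigurationError(f"dims={dims} must be < number of points {K}")
    init = classical_scaling(D.d, dims)

    def run(init_coords, random_state):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, stress, n_iter = smacof(
                D.d,
                metric=False,
                n_components=dims,
                init=init_coords,
                n_init=1,
                max_iter=max_iter,
                eps=eps,
                random_state=random_state,
                normalized_stress=True,
                return_n_iter=True,
            )
        return coords, float(stress), n_iter

    coords, stress, n_iter = run(init, None)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        rand_init = rng.normal(size=(K, dims)) * (np.abs(init).mean() + 1.0)
        c2, s2, it2 = run(rand_init, None)
        if s2 < stress:
            coords, stress, n_iter = c2, s2, it2

    converged = n_iter < max_iter
    if not converged:
        warnings.warn(
            f"MDS did not converge within {max_iter} iterations "
            f"(stress-1 = {stress:.4g})",
            RuntimeWarning,
        )
    return Embedding2D(labels=list(D.labels), coords=np.asarray(coords),
                       stress=stress, converged=converged)


# ---------------------------------------------------------------------------
# Convex-hull separation
# ---------------------------------------------------------------------------

def _point_in_hull(point: np.ndarray, hull_points: np.ndarray,
                   tol: float = 1e-9) -> bool:
    """Containment in the convex hull of ``hull_points`` (2-D).

    Degenerate hulls are handled explicitly: a single point matches only
    itself (within tol), collinear points form a segment and containment
    on the segment counts as inside.
    """
    hp = np.asarray(hull_points, dtype=float)
    if len(hp) == 1:
        return bool(np.linalg.norm(point - hp[0]) <= tol)
    try:
        hull = ConvexHull(hp)
    except QhullError:
        # collinear: project onto the segment spanned by the extreme points
        center = hp.mean(axis=0)
        rel = hp - center
        # principal direction
        _, _, vt = np.linalg.svd(rel, full_matrices=False)
        u = vt[0]
        t = rel @ u
        tp = (point - center) @ u
        perp = np.linalg.norm((point - center) - tp * u)
        return bool(perp <= tol and t.min() - tol <= tp <= t.max() + tol)
    eqs = hull.equations  # A x + b <= 0 inside
    return bool(np.all(eqs[:, :-1] @ point + eqs[:, -1] <= tol))


def hull_separation(
    embedding: Embedding2D,
    class_map: Dict[str, str],
) -> dict:
    """Convex-hull cluster-separation report on a 2-D embedding.

    For every embedded point, reports which *foreign* class hulls contain
    it; a pair of classes is separated when no point of either lies inside
    the other's hull, and the overall embedding is separated when that
    holds for all pairs.
    """
    unknown = [g for g in embedding.labels if g not in class_map]
    if unknown:
        raise LabellingError(f"class_map is missing genotypes: {unknown}")
    classes = sorted(set(class_map[g] for g in embedding.labels))
    pts = {g: embedding.coords[i] for i, g in enumerate(embedding.labels)}
    class_points = {
        c: np.array([pts[g] for g in embedding.labels if class_map[g] == c])
        for c in classes
    }

    containment: Dict[str, list] = {}
    for g in embedding.labels:
        own = class_map[g]
        inside = [
            c for c in classes
            if c != own and _point_in_hull(pts[g], class_points[c])
        ]
        containment[g] = inside

    pair_sep = {}
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1:]:
            violated = any(
                c2 in containment[g] for g in embedding.labels if class_map[g] == c1
            ) or any(
                c1 in containment[g] for g in embedding.labels if class_map[g] == c2
            )
            pair_sep[(c1, c2)] = not violated

    return {
        "classes": classes,
        "containment": containment,
        "pair_separated": pair_sep,
        "separated": all(pair_sep.values()),
        "hull_vertices": {
            c: _hull_vertices(class_points[c]) for c in classes
        },
    }


def _hull_vertices(points: np.ndarray) -> list:
    if len(points) < 3:
        return points.tolist()
    try:
        hull = ConvexHull(points)
        return points[hull.vertices].tolist()
    except QhullError:
        return points.tolist()
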
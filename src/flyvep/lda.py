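"""Shrinkage-regularized linear discriminant analysis.

The classifier operates in the 64-dimensional space of per-fly 2F
amplitudes. Two regularization knobs follow the classical shrinkage-LDA
recipe:

* ``gamma`` in [0, 1] blends the pooled within-class covariance toward its
  diagonal: ``Sigma_gamma = (1 - gamma) Sigma + gamma diag(Sigma)``. Any
  gamma > 0 makes the covariance nonsingular even when n < p.
* ``delta`` >= 0 eliminates weak predictors: feature j is dropped when the
  largest absolute linear coefficient ``|C_kj|`` across classes, with
  ``C_k = Sigma_gamma^{-1} (mu_k - mu_bar)``, does not exceed delta. The
  number of surviving features is the "number of components" quoted in
  reports.

With n=40 flies and p=64 features the unregularized pooled covariance is
always singular (rank <= n - K); raw-data fits therefore require the
explicit ``singular='pinv'`` pseudo-inverse mode, and every model fitted
that way carries a rank warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import (
    DegenerateClassError,
    InvalidInputError,
    NoFeaturesRetainedError,
    OptimizationFailureError,
    SingularCovarianceError,
)

_RANK_RTOL = 1e-10


@dataclass
class _FittedArrays:
    """Plain-array fit result used by the fast CV/bootstrap loops."""

    classes: np.ndarray
    priors: np.ndarray
    mask: np.ndarray          # boolean over the original features
    means_r: np.ndarray       # (K, p_retained) class means on retained features
    icov_mu: np.ndarray       # (p_retained, K): Sigma_r^{-1} mu_k
    const: np.ndarray         # (K,): -1/2 mu' Sigma^-1 mu + log prior
    rank: int
    n_features_in: int

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.mask] @ self.icov_mu + self.const

    def predict_idx(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.decision(X), axis=1)


def _pooled_cov(X: np.ndarray, y_idx: np.ndarray, K: int) -> Tuple[np.ndarray, np.ndarray]:
    """Class means and pooled within-class covariance (denominator n - K)."""
    n, p = X.shape
    means = np.empty((K, p))
    S = np.zeros((p, p))
    for k in range(K):
        Xk = X[y_idx == k]
        means[k] = Xk.mean(axis=0)
        R = Xk - means[k]
        S += R.T @ R
    return means, S / (n - K)


def _solve_spd(A: np.ndarray, B: np.ndarray, singular: str) -> Tuple[np.ndarray, int]:
    """Solve A X = B for symmetric PSD A, reporting rank.

    ``singular='raise'`` raises on rank deficiency; ``'pinv'`` falls back to
    the Moore-Penrose pseudo-inverse (raw-data mode) with a rank warning.
    """
    p = A.shape[0]
    # eigendecomposition gives both the rank check and a stable (pseudo)inverse
    w, V = np.linalg.eigh(A)
    tol = _RANK_RTOL * max(w.max(), 0.0) * p if w.size else 0.0
    keep = w > tol
    rank = int(keep.sum())
    if rank < p:
        if singular == "raise":
            raise SingularCovarianceError(
                f"regularized covariance is singular (rank {rank} < {p}); "
                "increase gamma or fit with singular='pinv' (pseudo-inverse "
                "raw-data mode)"
            )
        warnings.warn(
            f"pooled covariance rank-deficient (rank {rank} of {p}); "
            "using pseudo-inverse",
            RuntimeWarning,
            stacklevel=3,
        )
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    X = V @ (winv[:, None] * (V.T @ B))
    return X, rank


def _fit_arrays(
    X: np.ndarray,
    y_idx: np.ndarray,
    K: int,
    gamma: float,
    delta: float,
    priors: Optional[np.ndarray],
    singular: str,
) -> _FittedArrays:
    n, p = X.shape
    counts = np.bincount(y_idx, minlength=K)
    if np.any(counts < 2):
        k_bad = int(np.argmin(counts))
        raise DegenerateClassError(
            f"class index {k_bad} has {counts[k_bad]} member(s); need >= 2"
        )
    means, S = _pooled_cov(X, y_idx, K)
    Sg = (1.0 - gamma) * S + gamma * np.diag(np.diag(S))

    grand = means.mean(axis=0)  # unweighted grand within-class mean
    # one decomposition solves for both the elimination coefficients and the
    # discriminant weights
    sol, rank = _solve_spd(Sg, np.hstack([(means - grand).T, means.T]), singular)
    C = sol[:, :K]
    coef_mag = np.abs(C).max(axis=1)
    mask = coef_mag > delta
    if not mask.any():
        raise NoFeaturesRetainedError(
            f"delta={delta} eliminates all {p} features "
            f"(max |coefficient| = {coef_mag.max():.6g})"
        )

    pr = counts / n if priors is None else np.asarray(priors, dtype=float)
    means_r = means[:, mask]
    if mask.all():
        icov_mu, rank_r = sol[:, K:], rank
    else:
        Sg_r = Sg[np.ix_(mask, mask)]
        icov_mu, rank_r = _solve_spd(Sg_r, means_r.T, singular)  # (p_r, K)
    const = -0.5 * np.einsum("kp,pk->k", means_r, icov_mu) + np.log(pr)
    return _FittedArrays(
        classes=np.arange(K),
        priors=pr,
        mask=mask,
        means_r=means_r,
        icov_mu=icov_mu,
        const=const,
        rank=min(rank, rank_r),
        n_features_in=p,
    )


class ShrinkageLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant classifier with covariance shrinkage (gamma) and
    coefficient-threshold feature elimination (delta).

    Parameters
    ----------
    gamma : float in [0, 1]
        Shrinkage weight toward the diagonal of the pooled covariance.
    delta : float >= 0
        Features whose largest absolute linear coefficient is <= delta are
        eliminated before scoring.
    priors : array-like of shape (n_classes,), optional
        Class priors; empirical frequencies when None.
    singular : {'raise', 'pinv'}
        Behaviour on a singular regularized covariance: raise (default) or
        use a pseudo-inverse with an explicit rank warning (raw-data mode).

    Attributes
    ----------
    classes_ : ndarray of class labels, sorted.
    means_ : ndarray (n_classes, n_features) class mean vectors.
    pooled_cov_ : ndarray, shrinkage-regularized pooled covariance.
    coef_magnitudes_ : ndarray (n_features,), max_k |C_kj| before elimination.
    retained_mask_ : boolean ndarray (n_features,).
    n_components_ : int, number of retained features.
    rank_ : int, numerical rank of the (retained) regularized covariance.
    priors_ : ndarray of class priors.

    Examples
    --------
    >>> clf = ShrinkageLDA(gamma=0.2, delta=0.0).fit(X, y)
    >>> clf.predict(X_new)
    """

    def __init__(
        self,
        gamma: float = 0.0,
        delta: float = 0.0,
        priors=None,
        singular: str = "raise",
    ):
        self.gamma = gamma
        self.delta = delta
        self.priors = priors
        self.singular = singular

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InvalidInputError(
                f"X ({X.shape}) and y ({y.shape}) have inconsistent shapes"
            )
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("X contains non-finite values")
        if not (0.0 <= self.gamma <= 1.0):
            raise InvalidInputError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.delta < 0:
            raise InvalidInputError(f"delta must be >= 0, got {self.delta}")
        if self.singular not in ("raise", "pinv"):
            raise InvalidInputError("singular must be 'raise' or 'pinv'")

        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        if K < 2:
            raise DegenerateClassError(f"need >= 2 classes, got {K}")

        n, p = X.shape
        counts = np.bincount(y_idx, minlength=K)
        if np.any(counts < 2):
            bad = self.classes_[counts < 2]
            raise DegenerateClassError(
                f"classes {list(bad)} have < 2 members"
            )
        means, S = _pooled_cov(X, y_idx, K)
        Sg = (1.0 - self.gamma) * S + self.gamma * np.diag(np.diag(S))
        self.means_ = means
        self.pooled_cov_ = Sg

        fitted = _fit_arrays(
            X, y_idx, K, self.gamma, self.delta,
            None if self.priors is None else np.asarray(self.priors, float),
            self.singular,
        )
        self._fitted = fitted
        self.coef_magnitudes_ = self._coef_magnitudes(means, Sg)
        self.retained_mask_ = fitted.mask
        self.n_components_ = int(fitted.mask.sum())
        self.rank_ = fitted.rank
        self.priors_ = fitted.priors
        self.n_features_in_ = p
        return self

    def _coef_magnitudes(self, means, Sg) -> np.ndarray:
        grand = means.mean(axis=0)
        C, _ = _solve_spd(Sg, (means - grand).T, "pinv")
        return np.abs(C).max(axis=1)

    def decision_function(self, X) -> np.ndarray:
        """Per-class discriminant scores s_k(x)."""
        X = self._validate_for_predict(X)
        return self._fitted.decision(X)

    def predict(self, X):
        """Assign each row to the class with the largest discriminant score;
        ties break deterministically toward the first class label."""
        X = self._validate_for_predict(X)
        idx = self._fitted.predict_idx(X)
        return self.classes_[idx]

    def _validate_for_predict(self, X) -> np.ndarray:
        if not hasattr(self, "_fitted"):
            raise InvalidInputError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("features contain non-finite values")
        return X


def fit_lda(
    X, y, gamma: float = 0.0, delta: float = 0.0,
    priors=None, singular: str = "raise",
) -> ShrinkageLDA:
    """Functional wrapper over :class:`ShrinkageLDA`."""
    return ShrinkageLDA(gamma=gamma, delta=delta, priors=priors,
                        singular=singular).fit(X, y)


def predict(model: ShrinkageLDA, x):
    """Classify a single feature vector."""
    return model.predict(np.atleast_2d(x))[0]


# ---------------------------------------------------------------------------
# Cross-validated losses
# ---------------------------------------------------------------------------

def _encode(y) -> Tuple[np.ndarray, np.ndarray]:
    classes, y_idx = np.unique(np.asarray(y), return_inverse=True)
    return classes, y_idx


def _grouped_folds(
    groups: np.ndarray, k_folds: Optional[int], rng: Optional[np.random.Generator]
) -> List[np.ndarray]:
    """Fold membership (boolean test masks) grouped by fly identity.

    ``k_folds=None`` gives leave-one-fly-out; smaller k chunks the unique
    groups (shuffled when an rng is supplied, else in first-appearance
    order) into k folds.
    """
    uniq = list(dict.fromkeys(groups.tolist()))
    if k_folds is None or k_folds >= len(uniq):
        parts = [[g] for g in uniq]
    else:
        if k_folds < 2:
            raise InvalidInputError("k_folds must be >= 2")
        order = list(uniq)
        if rng is not None:
            order = [order[i] for i in rng.permutation(len(order))]
        parts = [order[i::k_folds] for i in range(k_folds)]
    masks = []
    for part in parts:
        member = np.isin(groups, part)
        if member.any():
            masks.append(member)
    return masks


def stratified_group_folds(
    y_idx: np.ndarray,
    groups: np.ndarray,
    k_folds: Optional[int],
    rng: Optional[np.random.Generator] = None,
) -> List[List]:
    """Class-balanced, fly-grouped hold-out sets.

    Each fold holds out exactly one unique fly *per class* (classes with
    fewer distinct flies in a resample recycle some flies), so the training
    set always loses one fly from every class; an unbalanced hold-out makes
    cross-validated accuracy systematically pessimistic under weak effects.
    ``k_folds`` smaller than the natural fold count merges folds
    round-robin. Returns a list of folds, each a list of held-out group
    ids (one per class).
    """
    per_class: List[List] = []
    for k in np.unique(y_idx):
        uniq = list(dict.fromkeys(np.asarray(groups)[y_idx == k].tolist()))
        if rng is not None:
            uniq = [uniq[i] for i in rng.permutation(len(uniq))]
        per_class.append(uniq)
    L = max(len(u) for u in per_class)
    folds = [
        [u[j % len(u)] for u in per_class]
        for j in range(L)
    ]
    if k_folds is not None:
        if k_folds < 2:
            raise InvalidInputError("k_folds must be >= 2")
        if k_folds < L:
            merged: List[List] = [[] for _ in range(k_folds)]
            for j, f in enumerate(folds):
                merged[j % k_folds].extend(f)
            folds = merged
    return folds


def kfold_loss(
    X,
    y,
    gamma: float = 0.0,
    delta: float = 0.0,
    k_folds: Optional[int] = None,
    groups=None,
    singular: str = "raise",
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Misclassification rate under (grouped) k-fold cross-validation.

    ``k_folds=None`` is leave-one-out; when ``groups`` is given, all rows of
    a group (e.g. bootstrap copies of the same fly) are held out together so
    the test fly never leaks into training.
    """
    X = np.asarray(X, dtype=float)
    classes, y_idx = _encode(y)
    pred = cv_predictions(X, y_idx, len(classes), gamma, delta,
                          k_folds=k_folds, groups=groups,
                          singular=singular, rng=rng)
    return float(np.mean(pred != y_idx))


def cv_predictions(
    X: np.ndarray,
    y_idx: np.ndarray,
    K: int,
    gamma: float,
    delta: float,
    k_folds: Optional[int] = None,
    groups=None,
    singular: str = "raise",
    rng: Optional[np.random.Generator] = None,
    folds: Optional[List[np.ndarray]] = None,
) -> np.ndarray:
    """Cross-validated class-index predictions, one per row.

    ``folds`` (boolean test masks) overrides the built-in fold
    construction when given.
    """
    n = X.shape[0]
    if n < 3:
        raise DegenerateClassError("need at least 3 samples for cross-validation")
    groups = np.arange(n) if groups is None else np.asarray(groups)
    if folds is None:
        folds = _grouped_folds(groups, k_folds, rng)
    pred = np.empty(n, dtype=int)
    for fold_no, test in enumerate(folds):
        train = ~test
        try:
            fitted = _fit_arrays(
                X[train], y_idx[train], K, gamma, delta, None, singular
            )
        except (DegenerateClassError, SingularCovarianceError,
                NoFeaturesRetainedError) as exc:
            raise type(exc)(f"fold {fold_no}: {exc}") from exc
        pred[test] = fitted.predict_idx(X[test])
    return pred


def loo_accuracy(
    X, y, gamma: float = 0.0, delta: float = 0.0, singular: str = "raise"
) -> float:
    """Leave-one-out accuracy: n refits, each excluding one fly."""
    return 1.0 - kfold_loss(X, y, gamma=gamma, delta=delta,
                            k_folds=None, singular=singular)


# ---------------------------------------------------------------------------
# (gamma, delta) grid search
# ---------------------------------------------------------------------------

def _try_chol_solve(A: np.ndarray, B: np.ndarray):
    """Cholesky solve for the optimizer grid; None when A is not PD."""
    try:
        return cho_solve(cho_factor(A, lower=True), B)
    except (LinAlgError, ValueError):
        return None


def optimize_regularization(
    X,
    y,
    gamma_grid: Sequence[float] = tuple(np.linspace(0.0, 1.0, 11)),
    n_delta: int = 10,
    k_folds: Optional[int] = 10,
    seed: Optional[int] = None,
) -> Tuple[float, float, int, float]:
    """Grid search over (gamma, delta) minimizing cross-validated loss.

    For each gamma the delta candidates are quantiles of the full-data
    coefficient magnitudes, spanning 0 to their maximum (``n_delta`` of
    them). Ties break toward fewer retained components, then larger gamma.

    Returns ``(gamma, delta, n_components, cv_loss)``.
    """
    X = np.asarray(X, dtype=float)
    classes, y_idx = _encode(y)
    K = len(classes)
    gamma_grid = list(gamma_grid)
    if not gamma_grid or n_delta < 1:
        raise OptimizationFailureError("gamma_grid and n_delta must be non-empty")
    rng = np.random.default_rng(seed)

    try:
        means, S = _pooled_cov(X, y_idx, K)
    except Exception as exc:  # pragma: no cover - shape errors surface here
        raise OptimizationFailureError(str(exc)) from exc

    n = X.shape[0]
    counts = np.bincount(y_idx, minlength=K)
    if np.any(counts < 2):
        raise DegenerateClassError("every class needs >= 2 members")

    # class-balanced fly-grouped folds, fixed across the whole grid so
    # candidate losses are directly comparable
    folds = stratified_group_folds(
        y_idx, np.arange(n), k_folds,
        np.random.default_rng(rng.integers(2**31)),
    )
    fold_masks = [np.isin(np.arange(n), tg) for tg in folds]
    fold_cache = []
    for test in fold_masks:
        train = ~test
        ytr = y_idx[train]
        if len(np.unique(ytr)) < K or np.any(np.bincount(ytr, minlength=K) < 2):
            continue
        m_f, S_f = _pooled_cov(X[train], ytr, K)
        pri_f = np.log(np.bincount(ytr, minlength=K) / train.sum())
        fold_cache.append((train, test, m_f, S_f, pri_f))
    if not fold_cache:
        raise OptimizationFailureError("no usable cross-validation fold")

    best = None  # (loss, n_components, -gamma), gamma, delta
    for gamma in gamma_grid:
        Sg = (1.0 - gamma) * S + gamma * np.diag(np.diag(S))
        C = _try_chol_solve(Sg, (means - means.mean(axis=0)).T)
        if C is None:
            continue
        mags = np.abs(C).max(axis=1)
        deltas = np.quantile(mags, np.linspace(0.0, 1.0, n_delta))
        deltas[0] = 0.0

        # per-fold elimination coefficients, shared by all delta candidates
        per_fold = []
        ok = True
        for train, test, m_f, S_f, pri_f in fold_cache:
            Sg_f = (1.0 - gamma) * S_f + gamma * np.diag(np.diag(S_f))
            C_f = _try_chol_solve(Sg_f, (m_f - m_f.mean(axis=0)).T)
            if C_f is None:
                ok = False
                break
            per_fold.append((test, m_f, Sg_f, pri_f, np.abs(C_f).max(axis=1)))
        if not ok:
            continue

        for delta in np.unique(deltas):
            full_mask = mags > delta
            if not full_mask.any():
                continue
            errors = 0
            tested = 0
            failed = False
            for test, m_f, Sg_f, pri_f, mags_f in per_fold:
                mask = mags_f > delta
                if not mask.any():
                    failed = True
                    break
                m_r = m_f[:, mask]
                try:
                    icov_mu = np.linalg.solve(Sg_f[np.ix_(mask, mask)], m_r.T)
                except np.linalg.LinAlgError:
                    failed = True
                    break
                const = -0.5 * np.einsum("kp,pk->k", m_r, icov_mu) + pri_f
                pred = np.argmax(X[test][:, mask] @ icov_mu + const, axis=1)
                errors += int(np.sum(pred != y_idx[test]))
                tested += int(test.sum())
            if failed or tested == 0:
                continue
            loss = errors / tested
            key = (loss, int(full_mask.sum()), -gamma)
            if best is None or key < best[0]:
                best = (key, gamma, float(delta))
    if best is None:
        raise OptimizationFailureError(
            "no (gamma, delta) candidate produced a valid fit"
        )
    key, gamma, delta = best
    return gamma, delta, key[1], key[0]
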
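"""Bootstrap generalization estimates for the discriminant classifier.

Each bootstrap iteration resamples flies *with replacement, stratified
within class* (class sizes preserved), recomputes the cross-validated loss
of the resample, and records accuracy = 1 - loss. Cross-validation on a
resample is grouped by original fly identity: every copy of the held-out
fly leaves the training set together, so a duplicated test fly can never
leak into training.

Significance follows the 1% bootstrap criterion: a two-class result is
above chance when fewer than 1% of bootstrap accuracies are 0.5 or below;
a K-way result when fewer than 1% fall strictly below 1/K. The boundary
inclusion deliberately differs between the two criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .exceptions import (
    DegenerateClassError,
    NoFeaturesRetainedError,
    SingularCovarianceError,
)
from .lda import (
    _encode,
    _fit_arrays,
    kfold_loss,
    optimize_regularization,
    stratified_group_folds,
)
from .stats import DipTestResult, dip_test

_EPS = 1e-12
_MAX_RETRIES_PER_ITER = 20


@dataclass
class ClassificationReport:
    """Point accuracy, bootstrap accuracy distribution and significance."""

    accuracy_point: float
    boot_accuracies: np.ndarray
    chance: float
    p_at_or_below_chance: float
    significant: bool
    n_components: int
    class_labels: list
    per_class_accuracy: Optional[Dict[str, float]] = None
    per_class_boot: Optional[Dict[str, np.ndarray]] = None
    gamma: float = 0.0
    delta: float = 0.0
    n_retries: int = 0
    unstable: bool = False
    raw_mode: bool = False
    covariance_rank: Optional[int] = None
    n_events_median: Optional[int] = None
    notes: list = field(default_factory=list)

    @property
    def mean_boot_accuracy(self) -> float:
        return float(np.mean(self.boot_accuracies))

    def boot_quantiles(self, qs=(0.025, 0.25, 0.5, 0.75, 0.975)) -> Dict[str, float]:
        return {f"q{q:g}": float(np.quantile(self.boot_accuracies, q)) for q in qs}

    def unimodality(self, seed: Optional[int] = None, n_boot: int = 500) -> DipTestResult:
        """Hartigan dip test of the bootstrap accuracy distribution.

        Accuracies live on a ~1/n grid (n = test events per iteration), so
        seeded uniform jitter of half a grid step is applied before
        computing the dip; ties and micro-clusters would otherwise dominate
        the statistic regardless of the distribution's shape.
        """
        acc = np.asarray(self.boot_accuracies)
        if self.n_events_median:
            step = 1.0 / self.n_events_median
        else:
            uniq = np.unique(acc)
            step = float(np.min(np.diff(uniq))) if len(uniq) > 1 else 0.0
        return dip_test(acc, n_boot=n_boot, seed=seed, jitter=step / 2 or None)

    def to_dict(self) -> dict:
        d = {
            "accuracy_point": self.accuracy_point,
            "mean_boot_accuracy": self.mean_boot_accuracy,
            "boot_quantiles": self.boot_quantiles(),
            "chance": self.chance,
            "p_at_or_below_chance": self.p_at_or_below_chance,
            "significant": bool(self.significant),
            "n_components": self.n_components,
            "class_labels": [str(c) for c in self.class_labels],
            "gamma": self.gamma,
            "delta": self.delta,
            "n_retries": self.n_retries,
            "unstable": self.unstable,
            "raw_mode": self.raw_mode,
            "covariance_rank": self.covariance_rank,
            "notes": self.notes,
        }
        if self.per_class_accuracy is not None:
            d["per_class_accuracy"] = {
                str(k): v for k, v in self.per_class_accuracy.items()
            }
        if self.per_class_boot is not None:
            d["per_class_boot_quantiles"] = {
                str(k): {
                    f"q{q:g}": float(np.quantile(v, q))
                    for q in (0.025, 0.25, 0.5, 0.75, 0.975)
                }
                for k, v in self.per_class_boot.items()
            }
        return d


def bootstrap_accuracy(
    X,
    y,
    n_iter: int = 10_000,
    k_folds: Optional[int] = None,
    gamma: float = 0.0,
    delta: float = 0.0,
    seed: Optional[int] = None,
    chance: Optional[float] = None,
    singular: str = "raise",
) -> ClassificationReport:
    """Stratified bootstrap of the cross-validated classification accuracy.

    Parameters
    ----------
    n_iter : int
        Number of bootstrap iterations (>= 100). The headline analyses use
        10,000; reduced counts are appropriate for test suites.
    k_folds : int or None
        Folds for the within-iteration loss; None = leave-one-fly-out.
    gamma, delta : float
        Regularization parameters, fixed across iterations (select them
        beforehand with :func:`flyvep.lda.optimize_regularization`).
    chance : float, optional
        Baseline accuracy; defaults to 0.5 for two classes, 1/K otherwise.
    """
    if n_iter < 100:
        raise ValueError(f"n_iter must be >= 100, got {n_iter}")
    X = np.asarray(X, dtype=float)
    classes, y_idx = _encode(y)
    K = len(classes)
    n = X.shape[0]
    class_rows = [np.flatnonzero(y_idx == k) for k in range(K)]
    if any(len(r) < 2 for r in class_rows):
        raise DegenerateClassError("every class needs >= 2 members")
    if chance is None:
        chance = 0.5 if K == 2 else 1.0 / K

    rng = np.random.default_rng(seed)

    # point estimate: leave-one-out on the original sample
    accuracy_point = 1.0 - kfold_loss(
        X, y_idx, gamma=gamma, delta=delta, k_folds=None, singular=singular
    )
    full_fit = _fit_arrays(X, y_idx, K, gamma, delta, None, singular)

    boot = np.empty(n_iter)
    per_class_boot = {c: np.empty(n_iter) for c in classes}
    n_events = np.empty(n_iter)
    n_retries = 0
    for it in range(n_iter):
        for attempt in range(_MAX_RETRIES_PER_ITER + 1):
            idx = np.concatenate(
                [rows[rng.integers(0, len(rows), size=len(rows))]
                 for rows in class_rows]
            )
            fold_rng = np.random.default_rng(rng.integers(2**31))
            try:
                yb = y_idx[idx]
                folds = stratified_group_folds(yb, idx, k_folds, fold_rng)
                # one test event per (fold, held-out fly); a fly is scored on
                # its own feature row, never weighted by its copy count in
                # the resample (size-biased weighting is pessimistic)
                hits = np.zeros(K)
                events = np.zeros(K)
                for test_groups in folds:
                    train = ~np.isin(idx, test_groups)
                    fitted = _fit_arrays(
                        X[idx[train]], yb[train], K, gamma, delta, None, singular
                    )
                    tg = np.asarray(test_groups)
                    pred = fitted.predict_idx(X[tg])
                    truth = y_idx[tg]
                    events += np.bincount(truth, minlength=K)
                    hits += np.bincount(truth[pred == truth], minlength=K)
                break
            except (DegenerateClassError, SingularCovarianceError,
                    NoFeaturesRetainedError):
                n_retries += 1
                if attempt == _MAX_RETRIES_PER_ITER:
                    raise
        boot[it] = hits.sum() / events.sum()
        n_events[it] = events.sum()
        for k, c in enumerate(classes):
            per_class_boot[c][it] = hits[k] / events[k] if events[k] else np.nan

    if K == 2:
        p = float(np.mean(boot <= chance + _EPS))
    else:
        p = float(np.mean(boot < chance - _EPS))
    unstable = n_retries > 0.01 * n_iter
    if unstable:
        warnings.warn(
            f"bootstrap required {n_retries} resample retries over {n_iter} "
            "iterations (> 1%); estimates may be unstable",
            RuntimeWarning,
        )
    report = ClassificationReport(
        accuracy_point=accuracy_point,
        boot_accuracies=boot,
        chance=float(chance),
        p_at_or_below_chance=p,
        significant=bool(p < 0.01),
        n_components=int(full_fit.mask.sum()),
        class_labels=list(classes),
        per_class_accuracy={c: float(v.mean()) for c, v in per_class_boot.items()},
        per_class_boot=per_class_boot,
        gamma=gamma,
        delta=delta,
        n_retries=n_retries,
        unstable=unstable,
        raw_mode=(singular == "pinv"),
        covariance_rank=full_fit.rank,
        n_events_median=int(np.median(n_events)),
    )
    return report


def oob_bootstrap_accuracy(
    X,
    y,
    n_iter: int = 1000,
    seed: Optional[int] = None,
    chance: Optional[float] = None,
    gamma_grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_delta: int = 6,
    opt_k_folds: int = 5,
) -> ClassificationReport:
    """Out-of-bag bootstrap of the *whole* regularized pipeline.

    Each iteration resamples flies with replacement stratified within
    class, re-runs the (gamma, delta) grid search on the resample alone,
    trains on the full resample, and scores the flies left out of the
    resample entirely (the out-of-bag set). Because hyperparameter
    selection never sees the evaluated flies, this estimator is exactly
    calibrated at chance under a no-effect null — unlike re-using
    hyperparameters selected on the full sample, which leaks the
    evaluation flies into selection and inflates the null by a few
    percentage points. Accuracy is macro-averaged over classes.

    Use this for calibration experiments; :func:`bootstrap_accuracy`
    mirrors the classical fixed-hyperparameter procedure of the report
    layer.
    """
    if n_iter < 100:
        raise ValueError(f"n_iter must be >= 100, got {n_iter}")
    X = np.asarray(X, dtype=float)
    classes, y_idx = _encode(y)
    K = len(classes)
    class_rows = [np.flatnonzero(y_idx == k) for k in range(K)]
    if any(len(r) < 3 for r in class_rows):
        raise DegenerateClassError("every class needs >= 3 members")
    if chance is None:
        chance = 0.5 if K == 2 else 1.0 / K

    rng = np.random.default_rng(seed)
    boot = np.empty(n_iter)
    per_class_boot = {c: np.empty(n_iter) for c in classes}
    n_retries = 0
    n_comp_sum = 0
    for it in range(n_iter):
        for attempt in range(_MAX_RETRIES_PER_ITER + 1):
            idx = np.concatenate(
                [rows[rng.integers(0, len(rows), size=len(rows))]
                 for rows in class_rows]
            )
            oob = np.setdiff1d(np.arange(X.shape[0]), idx)
            it_seed = int(rng.integers(2**31))
            if len(oob) == 0 or len(np.unique(y_idx[oob])) < K:
                n_retries += 1
                continue
            try:
                gamma, delta, n_comp, _ = optimize_regularization(
                    X[idx], y_idx[idx], gamma_grid=gamma_grid,
                    n_delta=n_delta, k_folds=opt_k_folds, seed=it_seed,
                )
                fitted = _fit_arrays(
                    X[idx], y_idx[idx], K, gamma, delta, None, "raise"
                )
                break
            except (DegenerateClassError, SingularCovarianceError,
                    NoFeaturesRetainedError):
                n_retries += 1
                if attempt == _MAX_RETRIES_PER_ITER:
                    raise
        pred = fitted.predict_idx(X[oob])
        truth = y_idx[oob]
        per_class = np.empty(K)
        for k in range(K):
            sel = truth == k
            per_class[k] = np.mean(pred[sel] == k)
            per_class_boot[classes[k]][it] = per_class[k]
        boot[it] = per_class.mean()
        n_comp_sum += n_comp

    if K == 2:
        p = float(np.mean(boot <= chance + _EPS))
    else:
        p = float(np.mean(boot < chance - _EPS))
    unstable = n_retries > 0.01 * n_iter
    n_oob_typical = int(round(X.shape[0] * 0.368))
    return ClassificationReport(
        accuracy_point=float(boot.mean()),
        boot_accuracies=boot,
        chance=float(chance),
        p_at_or_below_chance=p,
        significant=bool(p < 0.01),
        n_components=int(round(n_comp_sum / n_iter)),
        class_labels=list(classes),
        per_class_accuracy={c: float(np.nanmean(v))
                            for c, v in per_class_boot.items()},
        per_class_boot=per_class_boot,
        gamma=float("nan"),
        delta=float("nan"),
        n_retries=n_retries,
        unstable=unstable,
        n_events_median=max(n_oob_typical, 1),
        notes=["out-of-bag bootstrap with per-resample (gamma, delta) "
               "selection; macro-averaged accuracy"],
    )
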
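"""Report layer: the three classification analyses.

* pairwise: one two-way report per unordered genotype pair;
* pooled: a single PD-vs-non-PD binary report after pooling genotypes;
* n-way: one multi-class report over all genotypes with per-class
  bootstrap accuracy distributions.

``regularized=True`` selects (gamma, delta) by cross-validated grid search
(per pair for the pairwise analysis, once over the whole ensemble for the
n-way analysis). ``regularized=False`` reproduces the raw-data analysis:
gamma = delta = 0 with a pseudo-inverse for the (always singular at
n < p) pooled covariance; such reports carry a ``raw_mode`` flag and the
covariance rank.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import canonical_columns
from .exceptions import ConfigurationError, DegenerateClassError
from .bootstrap import ClassificationReport, bootstrap_accuracy
from .lda import optimize_regularization

PairKey = Tuple[str, str]


def _as_xy(features, labels=None) -> Tuple[np.ndarray, np.ndarray]:
    """Accept a feature_matrix-style DataFrame or a plain array."""
    if isinstance(features, pd.DataFrame):
        cols = [c for c in canonical_columns() if c in features.columns]
        if not cols:
            cols = [c for c in features.columns if c not in ("fly_id", "genotype")]
        X = features[cols].to_numpy(dtype=float)
        if labels is None and "genotype" in features.columns:
            labels = features["genotype"].to_numpy()
    else:
        X = np.asarray(features, dtype=float)
    if labels is None:
        raise ConfigurationError("labels are required when features is an array")
    return X, np.asarray(labels)


def _single_report(
    X: np.ndarray,
    y: np.ndarray,
    regularized: bool,
    n_iter: int,
    k_folds: Optional[int],
    seed: Optional[int],
    chance: Optional[float] = None,
    opt_k_folds: Optional[int] = 10,
    gamma_grid: Optional[Sequence[float]] = None,
    n_delta: int = 10,
) -> ClassificationReport:
    if regularized:
        opt_kwargs = {} if gamma_grid is None else {"gamma_grid": gamma_grid}
        gamma, delta, n_comp, cv_loss = optimize_regularization(
            X, y, n_delta=n_delta, k_folds=opt_k_folds, seed=seed, **opt_kwargs
        )
        report = bootstrap_accuracy(
            X, y, n_iter=n_iter, k_folds=k_folds, gamma=gamma, delta=delta,
            seed=seed, chance=chance, singular="raise",
        )
        report.notes.append(
            f"regularized: gamma={gamma:g}, delta={delta:g}, "
            f"cv_loss={cv_loss:g}, n_components={n_comp}"
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            report = bootstrap_accuracy(
                X, y, n_iter=n_iter, k_folds=k_folds, gamma=0.0, delta=0.0,
                seed=seed, chance=chance, singular="pinv",
            )
        report.notes.append(
            "raw mode: gamma=delta=0, singular pooled covariance handled by "
            f"pseudo-inverse (rank {report.covariance_rank})"
        )
    return report


def pairwise_matrix(
    features,
    labels=None,
    regularized: bool = True,
    n_iter: int = 1000,
    k_folds: Optional[int] = None,
    seed: Optional[int] = None,
    **opt_kwargs,
) -> Dict[PairKey, ClassificationReport]:
    """Two-way classification report for every unordered genotype pair.

    Returns the upper triangle only (the analysis is symmetric in the pair).
    Per-pair failures are recorded as None without aborting other pairs.
    """
    X, y = _as_xy(features, labels)
    genotypes = list(pd.unique(y))
    if len(genotypes) < 2:
        raise DegenerateClassError("need >= 2 genotypes for pairwise analysis")

    out: Dict[PairKey, Optional[ClassificationReport]] = {}
    for i, (g1, g2) in enumerate(itertools.combinations(genotypes, 2)):
        sel = np.isin(y, (g1, g2))
        pair_seed = None if seed is None else seed + 7919 * i
        try:
            out[(g1, g2)] = _single_report(
                X[sel], y[sel], regularized, n_iter, k_folds, pair_seed,
                chance=0.5, **opt_kwargs,
            )
        except Exception as exc:  # noqa: BLE001 - propagate per-pair, not global
            warnings.warn(f"pair ({g1}, {g2}) failed: {exc}", RuntimeWarning)
            out[(g1, g2)] = None
    return out


def pairwise_table(reports: Dict[PairKey, ClassificationReport]) -> pd.DataFrame:
    """Upper-triangular table of mean bootstrap accuracies (percent);
    non-significant cells are left as NaN, mirroring the convention of
    printing only scores with bootstrapped p < .01."""
    genotypes = list(dict.fromkeys([g for pair in reports for g in pair]))
    tbl = pd.DataFrame(np.nan, index=genotypes, columns=genotypes)
    for (g1, g2), rep in reports.items():
        if rep is not None and rep.significant:
            tbl.loc[g1, g2] = 100.0 * rep.mean_boot_accuracy
    return tbl


def pooled_binary(
    features,
    labels=None,
    class_map: Optional[Dict[str, str]] = None,
    exclusions: Iterable[str] = (),
    regularized: bool = True,
    n_iter: int = 1000,
    k_folds: Optional[int] = None,
    seed: Optional[int] = None,
    **opt_kwargs,
) -> ClassificationReport:
    """PD-vs-non-PD style pooled two-class report.

    ``class_map`` sends each genotype to one of two pooled class names;
    genotypes in ``exclusions`` are dropped first. Chance is 0.5.
    """
    X, y = _as_xy(features, labels)
    if class_map is None:
        raise ConfigurationError("class_map is required")
    keep = ~np.isin(y, list(exclusions))
    X, y = X[keep], y[keep]
    unknown = set(y) - set(class_map)
    if unknown:
        raise ConfigurationError(
            f"class_map is missing genotypes: {sorted(unknown)}"
        )
    pooled = np.asarray([class_map[g] for g in y])
    if len(set(pooled)) != 2:
        raise ConfigurationError(
            f"class_map must produce exactly 2 non-empty pooled classes, "
            f"got {sorted(set(pooled))}"
        )
    return _single_report(X, pooled, regularized, n_iter, k_folds, seed,
                          chance=0.5, **opt_kwargs)


def nway_report(
    features,
    labels=None,
    regularized: bool = True,
    n_iter: int = 1000,
    k_folds: Optional[int] = None,
    seed: Optional[int] = None,
    **opt_kwargs,
) -> ClassificationReport:
    """Multi-class report over all genotypes; chance = 1/K.

    Regularization (when requested) is optimized once on the entire
    ensemble; per-class bootstrap accuracy distributions are collected for
    box-plot style summaries.
    """
    X, y = _as_xy(features, labels)
    K = len(set(y))
    if K < 3:
        raise DegenerateClassError(f"n-way report needs >= 3 classes, got {K}")
    return _single_report(
        X, y, regularized, n_iter, k_folds, seed, chance=1.0 / K, **opt_kwargs
    )
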
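"""Bolasso baselines and the held-out AUC comparison protocol.

Bolasso fits the Lasso on bootstrap replicates (drawn WITH replacement,
unlike the scoring loop's without-replacement subsamples) and keeps the
features present in every support; Bolasso-S relaxes "every" to a fraction
(0.9 by default).  ``compare_selectors`` runs repeated random train/test
splits and reports the mean held-out AUC per selection strategy, the
protocol used to compare the spline-thresholded scores against a plain
cross-validated Lasso and against Bolasso.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.metrics import roc_auc_score

from .data import FeatureMatrix
from .scoring import RunConfig, fealect_scores
from .segmentation import build_curve, fit_three_segment, select_informative

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 50


@dataclass(frozen=True)
class BolassoConfig:
    """Bolasso settings.

    selection_threshold : minimum selection frequency across replicates
        (1.0 = hard intersection; 0.9 = the customary soft variant).
    lambda_rule : per-replicate penalty choice — 5-fold cross-validation,
        or the theoretical decay lambda = mu0 / sqrt(n).
    """

    m: int = 100
    selection_threshold: float = 0.9
    lambda_rule: Literal["cross_validation", "root_n"] = "cross_validation"
    mu0: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.selection_threshold <= 1.0):
            raise ValueError("selection_threshold must lie in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be positive")


def _lasso_support(X: np.ndarray, y: np.ndarray, config: BolassoConfig) -> np.ndarray:
    if config.lambda_rule == "cross_validation":
        model = LassoCV(cv=5, alphas=30, max_iter=5000)
    else:
        model = Lasso(alpha=config.mu0 / np.sqrt(len(y)), max_iter=5000)
    model.fit(X, y)
    return np.abs(model.coef_) > 1e-10


def bolasso_frequencies(
    data: FeatureMatrix, config: BolassoConfig, seed: int
) -> np.ndarray:
    """Per-feature selection frequency over m bootstrap replicates."""
    data.require_min_samples()
    n, d = data.n_samples, data.n_features
    rng = np.random.default_rng(seed)
    counts = np.zeros(d)
    for _ in range(config.m):
        for _attempt in range(_MAX_REDRAWS):
            rows = rng.integers(0, n, size=n)
            y = data.response[rows]
            if np.ptp(y) > 0:
                break
        else:
            raise ValueError("could not draw a replicate with non-constant response")
        counts += _lasso_support(data.values[rows], y, config)
    return counts / config.m


def bolasso_select(
    data: FeatureMatrix, config: BolassoConfig, seed: int
) -> tuple[list[int], np.ndarray]:
    """Features whose bootstrap selection frequency reaches the threshold.

    Returns (selected indices, per-feature frequencies).
    """
    freq = bolasso_frequencies(data, config, seed)
    selected = [int(j) for j in np.flatnonzero(freq >= config.selection_threshold - 1e-12)]
    return selected, freq


def fit_and_score(
    data_train: FeatureMatrix,
    data_test: FeatureMatrix,
    feature_subset: Sequence[int],
) -> float:
    """AUC on held-out labels of a linear model restricted to a feature subset.

    A minimum-norm least-squares fit is used when the subset is small
    relative to the training size; otherwise a cross-validated Lasso.  Ties
    among predictions contribute 1/2 (midrank convention), so a constant
    predictor scores 0.5.
    """
    subset = list(feature_subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    y_test = data_test.response
    if len(np.unique(y_test)) < 2:
        raise ValueError("test labels are single-class; AUC undefined")
    Xtr = data_train.values[:, subset]
    Xte = data_test.values[:, subset]
    ytr = data_train.response
    if len(subset) <= data_train.n_samples // 2:
        A = np.column_stack([np.ones(len(Xtr)), Xtr])
        coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        preds = np.column_stack([np.ones(len(Xte)), Xte]) @ coef
    else:
        model = LassoCV(cv=5, alphas=30, max_iter=5000)
        model.fit(Xtr, ytr)
        preds = model.predict(Xte)
    return auc_score(y_test, preds)


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC with midrank tie handling (Mann–Whitney convention)."""
    y = np.asarray(y_true, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    if np.ptp(scores) == 0:
        return 0.5
    return float(roc_auc_score(y > np.mean(np.unique(y)), scores))


def _fealect_selector(
    train: FeatureMatrix, seed: int, m: int, top_k: int | None
) -> list[int]:
    table = fealect_scores(train, RunConfig(m=m, seed=seed))
    if top_k is not None:
        return table.top(top_k)
    try:
        fit = fit_three_segment(build_curve(table))
        sel = select_informative(table, fit)
        if sel.selected_ids:
            return list(sel.selected_ids)
    except ValueError as exc:
        logger.warning("spline selection unavailable (%s); falling back to top-5", exc)
    return table.top(5)


def compare_selectors(
    data: FeatureMatrix,
    n_train: int,
    repeats: int,
    seed: int,
    fealect_m: int = 100,
    top_k: int | None = None,
    bolasso: BolassoConfig | None = None,
) -> pd.DataFrame:
    """Repeated random-split AUC comparison of feature selectors.

    Per repeat, ``n_train`` samples are drawn uniformly at random for
    training; FeaLect (spline-thresholded, or top-k if given), a plain
    cross-validated Lasso on all features ("lars" row), and Bolasso are run
    on the training split only and evaluated by AUC on the remainder.

    Returns a tidy frame (selector, repeat, n_train, n_selected, auc).
    """
    if not (0 < n_train < data.n_samples):
        raise ValueError("n_train must be in (0, n)")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    bolasso = bolasso or BolassoConfig()
    children = np.random.SeedSequence(seed).spawn(repeats)
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng(children[rep])
        sub_seed = int(rng.integers(2**31 - 1))
        for _attempt in range(_MAX_REDRAWS):
            train_idx = np.sort(rng.choice(data.n_samples, n_train, replace=False))
            test_idx = np.setdiff1d(np.arange(data.n_samples), train_idx)
            if (
                len(np.unique(data.response[test_idx])) > 1
                and len(np.unique(data.response[train_idx])) > 1
            ):
                break
        else:
            raise ValueError("could not draw a split with both classes on each side")
        train, test = data.subset(train_idx), data.subset(test_idx)

        selections = {
            "fealect": _fealect_selector(train, sub_seed, fealect_m, top_k),
            "lars": list(range(data.n_features)),
            "bolasso": bolasso_select(train, bolasso, sub_seed)[0],
        }
        for name, subset in selections.items():
            if subset:
                auc = fit_and_score(train, test, subset)
            else:  # empty Bolasso intersection: uninformative constant model
                auc = 0.5
            rows.append(
                {
                    "selector": name,
                    "repeat": rep,
                    "n_train": n_train,
                    "n_selected": len(subset),
                    "auc": auc,
                }
            )
    return pd.DataFrame(rows)


def summarize_comparison(results: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC and its standard error per selector."""
    g = results.groupby("selector")["auc"]
    out = g.agg(["mean", "count"])
    out["sem"] = g.sem().fillna(0.0)
    return out.rename(columns={"mean": "mean_auc", "count": "repeats"})
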
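"""LARS regularization-path entry orders.

The scoring scheme needs, for each subsample B, the nested chain of active
sets F_1^B ⊂ F_2^B ⊂ … produced as the l1 penalty relaxes.  The pure LARS
(least-angle, no-drop) path is the variant whose active sets are nested by
construction, so F_k^B is simply the set of the first k features to enter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lars_path

from .data import FeatureMatrix

logger = logging.getLogger(__name__)

_STD_TOL = 1e-8


@dataclass(frozen=True)
class EntryOrder:
    """The order in which features enter the LARS path on one (sub)sample.

    ``ordered_features[:k]`` is exactly F_k^B for every k up to
    ``max_size_reached``; nesting holds by construction.
    """

    ordered_features: tuple[int, ...]
    max_size_reached: int

    def __post_init__(self) -> None:
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise ValueError("entry order contains a repeated feature")
        if self.max_size_reached != len(self.ordered_features):
            raise ValueError("max_size_reached must equal the sequence length")


def standardize(data: FeatureMatrix) -> FeatureMatrix:
    """Center each column to mean zero and scale to unit Euclidean norm.

    The response is centered.  Zero-variance columns can never enter a LARS
    path and are removed (with a warning) so the entry order is well defined.

    Raises
    ------
    ValueError
        If every column has zero variance.
    """
    X = data.values - data.values.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    keep = norms > _STD_TOL * max(1.0, float(np.abs(data.values).max(initial=1.0)))
    if not keep.any():
        raise ValueError("all feature columns have zero variance; matrix is unusable")
    if not keep.all():
        dropped = [data.feature_names[j] for j in np.flatnonzero(~keep)]
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
    X = X[:, keep] / norms[keep]
    y = data.response - data.response.mean()
    names = [nm for nm, k in zip(data.feature_names, keep) if k]
    out = FeatureMatrix(X, names, y)
    out.standardized = True
    return out


def is_standardized(data: FeatureMatrix, tol: float = 1e-6) -> bool:
    colmeans = data.values.mean(axis=0)
    norms = np.linalg.norm(data.values, axis=0)
    return bool(
        np.all(np.abs(colmeans) < tol)
        and np.all(np.abs(norms - 1.0) < tol)
        and abs(data.response.mean()) < tol * max(1.0, np.abs(data.response).max(initial=1.0))
    )


def entry_order(data: FeatureMatrix, max_features: int) -> EntryOrder:
    """Order in which features enter the no-drop LARS path.

    Parameters
    ----------
    data : FeatureMatrix
        Must be standardized (zero-mean unit-norm columns, centered response).
    max_features : int
        Upper bound K on the path length; the realized length is
        ``min(max_features, d, n - 1)`` or shorter if the residual is
        exhausted first.

    Notes
    -----
    Exact correlation ties are broken toward the lowest column index (the
    argmax convention of the underlying solver), which makes the order
    deterministic.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    if not is_standardized(data):
        raise ValueError("entry_order requires a standardized FeatureMatrix")
    n, d = data.values.shape
    cap = min(max_features, d, n - 1)
    with warnings.catch_warnings():
        # exact collinearity inside a subsample is expected in the n << d regime
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, active, _ = lars_path(
            data.values, data.response, method="lar", max_iter=cap
        )
    order = tuple(int(j) for j in active[:cap])
    return EntryOrder(ordered_features=order, max_size_reached=len(order))
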
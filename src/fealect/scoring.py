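"""FeaLect feature scoring.

Each of m subsamples B (a fraction γ of the samples, drawn without
replacement) yields a LARS entry order.  A feature active among the k
features of F_k^B earns 1/k at that path size, so a feature entering at rank
j accumulates H_{K_B} − H_{j−1} on that subsample, where H is the harmonic
number and K_B the realized path length.  The total score S(f) averages
these contributions over subsamples; summed over features it conserves the
mean path length exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .data import FeatureMatrix
from .path import EntryOrder, entry_order, standardize

logger = logging.getLogger(__name__)

#: signature of a path engine usable by the scoring loop: receives the
#: standardized subsample, the feature cap K and the drawn row indices,
#: returns an EntryOrder whose indices refer to the subsample's columns.
PathEngine = Callable[[FeatureMatrix, int, np.ndarray], EntryOrder]

_MAX_REDRAWS = 50


def harmonic(k: int) -> float:
    """H_k = sum_{i=1..k} 1/i (H_0 = 0)."""
    return float(np.sum(1.0 / np.arange(1, k + 1)))


@dataclass(frozen=True)
class RunConfig:
    """Scoring-loop settings.

    gamma : fraction of instances per subsample (default 3/4)
    m : number of subsamples (default 1000)
    max_features : path-length cap K (default min(d, 60), resolved at run time)
    seed : RNG seed; subsample t uses substream t, so increasing m extends a
        run without reshuffling earlier draws
    """

    gamma: float = 0.75
    m: int = 1000
    max_features: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1")

    def resolve_k(self, d: int) -> int:
        return min(d, 60) if self.max_features is None else self.max_features


@dataclass(frozen=True)
class ScoreTable:
    """Per-feature total scores S(f) plus run metadata."""

    scores: np.ndarray
    feature_names: tuple[str, ...]
    per_bootstrap_sizes: tuple[int, ...]
    config: RunConfig

    def top(self, k: int) -> list[int]:
        """Indices of the k highest-scoring features (ties to lower index)."""
        order = np.lexsort((np.arange(len(self.scores)), -self.scores))
        return [int(i) for i in order[:k]]


def draw_subsample(n: int, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw floor(gamma*n) distinct sample indices uniformly, without replacement."""
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must lie in (0, 1]")
    b = int(np.floor(gamma * n))
    if b < 2:
        raise ValueError(f"floor(gamma*n) = {b} < 2: subsample too small")
    return np.sort(rng.choice(n, size=b, replace=False))


def bootstrap_contribution(order: EntryOrder, d: int, K: int) -> np.ndarray:
    """Per-feature score earned from one subsample's entry order.

    The feature entering at rank j (1-based) receives
    sum_{k=j..K_B} 1/k = H_{K_B} - H_{j-1}; absent features receive 0.
    The vector sums to K_B exactly (k features each earn 1/k at size k).
    """
    if K < order.max_size_reached:
        raise ValueError("K must be at least the realized path length")
    out = np.zeros(d)
    kb = order.max_size_reached
    if kb == 0:
        return out
    # suffix sums of 1/k over k = 1..kb
    inv = 1.0 / np.arange(1, kb + 1)
    tail = np.cumsum(inv[::-1])[::-1]  # tail[j-1] = H_{kb} - H_{j-1}
    out[np.fromiter(order.ordered_features, dtype=int, count=kb)] = tail
    return out


def _default_engine(std_sub: FeatureMatrix, k: int, rows: np.ndarray) -> EntryOrder:
    return entry_order(std_sub, k)


def fealect_scores(
    data: FeatureMatrix,
    config: RunConfig,
    path_engine: PathEngine | None = None,
) -> ScoreTable:
    """Run the full scoring loop: m subsamples, path per subsample, 1/k scores.

    Scores are on the averaged scale, i.e. divided by m; downstream selection
    is invariant to this constant.  Fully reproducible from ``config.seed``.

    A subsample whose standardization fails (e.g. all drawn rows identical)
    is redrawn a bounded number of times, then an error is raised.
    """
    engine = _default_engine if path_engine is None else path_engine
    data.require_min_samples()
    n, d = data.n_samples, data.n_features
    K = config.resolve_k(d)
    if int(np.floor(config.gamma * n)) < 2:
        raise ValueError("floor(gamma*n) must be >= 2")
    name_to_col = {nm: j for j, nm in enumerate(data.feature_names)}
    totals = np.zeros(d)
    sizes: list[int] = []
    children = np.random.SeedSequence(config.seed).spawn(config.m)
    for t in range(config.m):
        rng = np.random.default_rng(children[t])
        for attempt in range(_MAX_REDRAWS):
            rows = draw_subsample(n, config.gamma, rng)
            try:
                std_sub = standardize(data.subset(rows))
            except ValueError as exc:
                logger.warning("subsample %d redrawn (%s)", t, exc)
                continue
            break
        else:
            raise ValueError(f"subsample {t}: no usable draw in {_MAX_REDRAWS} tries")
        order = engine(std_sub, K, rows)
        contrib = bootstrap_contribution(order, len(std_sub.feature_names), K)
        # standardization may drop columns inside the subsample; map back by name
        if len(std_sub.feature_names) != d or std_sub.feature_names != data.feature_names:
            cols = np.fromiter(
                (name_to_col[nm] for nm in std_sub.feature_names), dtype=int
            )
            totals[cols] += contrib
        else:
            totals += contrib
        sizes.append(order.max_size_reached)
    return ScoreTable(
        scores=totals / config.m,
        feature_names=tuple(data.feature_names),
        per_bootstrap_sizes=tuple(sizes),
        config=replace(config, max_features=K),
    )
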
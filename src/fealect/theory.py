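"""Combinatorics of subsample inclusion, the mock over-fit harness, and
synthetic sparse-regression data.

An *irrelevant* feature is one that over-fits on a fixed sample subset U of
size r: it enters the path if and only if U is contained in the drawn
subsample B.  Since B is drawn without replacement with |B| = floor(gamma*n),
Pr(U ⊆ B) is a hypergeometric ratio C(n-r, b-r)/C(n, b), which tends to
gamma^r as n grows.  The expected score of such a feature is therefore
geometric in r, so the sorted log-score curve is linear over the irrelevant
band — the fact the segmentation threshold exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
from scipy.special import gammaln

from .data import FeatureMatrix
from .path import EntryOrder
from .scoring import RunConfig, fealect_scores, harmonic

_EXACT_N = 500  # below this, use exact integer combinatorics


@dataclass(frozen=True)
class OverfitSpec:
    """A fixed over-fitting set U of sample indices, |U| = r."""

    U: frozenset[int]

    @property
    def r(self) -> int:
        return len(self.U)

    def validate(self, n: int) -> None:
        if any((i < 0 or i >= n) for i in self.U):
            raise ValueError("over-fit set contains indices outside [0, n)")


@dataclass(frozen=True)
class SyntheticDataset:
    """A sparse linear model draw: data plus ground truth."""

    data: FeatureMatrix
    true_support: tuple[int, ...]
    noise_sd: float
    effect_sizes: np.ndarray
    raw_response: np.ndarray


def inclusion_probability_exact(n: int, r: int, gamma: float) -> float:
    """Exact Pr(U ⊆ B) for |U| = r and B of size floor(gamma*n) drawn
    without replacement from n samples: C(n-r, b-r) / C(n, b).

    Exact rational arithmetic for moderate n; log-space gamma functions
    beyond.  Returns 0.0 when r exceeds the subsample size; r > n is an
    error.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must lie in (0, 1]")
    if r < 0:
        raise ValueError("r must be non-negative")
    if r > n:
        raise ValueError(f"r = {r} exceeds n = {n}")
    b = int(np.floor(gamma * n))
    if r > b:
        return 0.0
    if n <= _EXACT_N:
        return float(Fraction(comb(n - r, b - r), comb(n, b)))
    lg = (
        gammaln(n - r + 1)
        - gammaln(b - r + 1)
        - gammaln(n - b + 1)
        - (gammaln(n + 1) - gammaln(b + 1) - gammaln(n - b + 1))
    )
    return float(np.exp(lg))


def overfit_path_engine(spec: OverfitSpec, d: int, K: int):
    """A path engine realizing the over-fit definition exactly.

    Feature 0 over-fits on U: it enters at rank 1 (hence sits in every
    F_k^B) precisely when U ⊆ B, and never enters otherwise.  The other
    d-1 features fill the remaining ranks so the path always has length K.
    Requires d >= K + 1.
    """
    if d < K + 1:
        raise ValueError("need d >= K + 1 filler features")
    U = np.fromiter(spec.U, dtype=int)

    def engine(std_sub: FeatureMatrix, k: int, rows: np.ndarray) -> EntryOrder:
        contained = bool(np.isin(U, rows).all()) if len(U) else True
        if contained:
            order = (0,) + tuple(range(1, K))
        else:
            order = tuple(range(1, K + 1))
        return EntryOrder(ordered_features=order, max_size_reached=K)

    return engine


def mock_overfit_score(
    spec: OverfitSpec,
    n: int,
    gamma: float,
    m: int,
    K: int,
    seed: int,
) -> float:
    """Empirical FeaLect score of a feature over-fitting on U, |U| = r.

    Runs the real scoring loop with the mock path engine injected, on a
    placeholder Gaussian matrix (the mock ignores the values).  The score
    equals H_K times the empirical frequency of U ⊆ B, so its expectation
    is H_K * Pr(U ⊆ B) ≈ H_K * gamma^r.
    """
    spec.validate(n)
    d = K + 1
    rng = np.random.default_rng(seed)
    data = FeatureMatrix(
        rng.standard_normal((n, d)),
        [f"f{j}" for j in range(d)],
        rng.standard_normal(n),
    )
    cfg = RunConfig(gamma=gamma, m=m, max_features=K, seed=seed)
    table = fealect_scores(data, cfg, path_engine=overfit_path_engine(spec, d, K))
    return float(table.scores[0])


def generate_sparse_regression(
    n: int,
    d: int,
    s: int,
    snr: float,
    seed: int,
) -> SyntheticDataset:
    """Sparse linear model in the n ≪ d regime.

    Standard-normal design; the first s coefficients (support chosen at
    random) share a magnitude scaled so var(signal)/var(noise) = snr with
    unit noise.  The response is thresholded at its median into ±1 labels
    for classification use; the raw response is retained.
    """
    if s > d:
        raise ValueError("sparsity s cannot exceed d")
    if n < 4:
        raise ValueError("need n >= 4")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    support = np.sort(rng.choice(d, size=s, replace=False)) if s else np.array([], int)
    noise_sd = 1.0
    beta = np.zeros(d)
    if s:
        # independent unit-variance columns: var(signal) = sum beta_j^2
        beta[support] = np.sqrt(snr * noise_sd**2 / s)
    raw = X @ beta + rng.normal(0.0, noise_sd, size=n)
    labels = np.where(raw > np.median(raw), 1.0, -1.0)
    data = FeatureMatrix(X, [f"f{j}" for j in range(d)], labels)
    return SyntheticDataset(
        data=data,
        true_support=tuple(int(j) for j in support),
        noise_sd=noise_sd,
        effect_sizes=beta[support].copy(),
        raw_response=raw,
    )
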
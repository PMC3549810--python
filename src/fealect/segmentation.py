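"""Score-curve segmentation and the analytic selection threshold.

Sorting the positive feature scores and taking logs yields a curve whose
middle part is linear — those are the irrelevant features, whose scores
decay geometrically in the size of the sample subset they over-fit on — and
whose two ends bend away.  Fitting a continuous quadratic–linear–quadratic
3-segment model to the curve therefore separates, without any user-set
threshold, the low-score tail (g1), the irrelevant linear band (g2) and the
informative upper bend (g3).  Features strictly above the upper knot are
selected.

The knot pair minimizing the total squared error is found by exhaustive
search over all admissible pairs (each segment at least 3 points).  The
search is vectorized through prefix-sum normal equations: because the two
quadratic correction bases have disjoint supports, every 6×6 normal system
decomposes into per-knot blocks computable in O(1) from prefix sums, so the
whole grid is solved batched.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .scoring import ScoreTable

MIN_SEGMENT = 3  # points per segment
MIN_CURVE = 3 * MIN_SEGMENT


@dataclass(frozen=True)
class ScoreCurve:
    """Sorted log-score curve over the positive-score features.

    ``log_scores`` are natural logs sorted ascending (ties by feature
    index); ``feature_ids`` aligns original feature indices to curve
    positions 1..L; ``n_zero`` counts excluded zero-score features.
    """

    log_scores: np.ndarray
    feature_ids: np.ndarray
    n_zero: int

    def __len__(self) -> int:
        return len(self.log_scores)

    @property
    def ranks(self) -> np.ndarray:
        """Curve x-axis: rank positions 1..L."""
        return np.arange(1, len(self.log_scores) + 1, dtype=float)


@dataclass(frozen=True)
class SegmentFit:
    """A continuous quadratic–linear–quadratic fit to a score curve.

    ``knots`` are curve indices (k1, k2): segment g1 covers points 1..k1,
    g2 covers k1+1..k2, g3 covers k2+1..L; continuity is enforced at the
    half-integer rank positions k1+0.5 and k2+0.5 between segments.
    ``coefficients`` maps each segment to polynomial coefficients
    (intercept, slope[, curvature]) in the rank coordinate.
    ``threshold_score`` is the original-scale score at the upper knot point.
    """

    knots: tuple[int, int]
    coefficients: dict[str, tuple[float, ...]]
    sse: float
    threshold_score: float
    curve_length: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the fitted piecewise function at rank positions x."""
        x = np.asarray(x, dtype=float)
        k1, k2 = self.knots
        out = np.empty_like(x)
        for name, mask in (
            ("g1", x < k1 + 0.5),
            ("g2", (x >= k1 + 0.5) & (x <= k2 + 0.5)),
            ("g3", x > k2 + 0.5),
        ):
            c = self.coefficients[name]
            out[mask] = np.polyval(c[::-1], x[mask])
        return out

    @property
    def segment_counts(self) -> tuple[int, int, int]:
        k1, k2 = self.knots
        return (k1, k2 - k1, self.curve_length - k2)


@dataclass(frozen=True)
class SelectionResult:
    """Features declared informative: all curve points above the upper knot."""

    selected_ids: tuple[int, ...]
    selected_names: tuple[str, ...]
    threshold_score: float
    segment_counts: tuple[int, int, int]


def build_curve(table: ScoreTable) -> ScoreCurve:
    """Sorted log-score curve from a score table.

    Zero-score features cannot be plotted on the log scale (and were never
    selected on any path), so they are excluded and counted in ``n_zero``.
    At least 9 positive scores are required so each of the three segments
    can span 3 points.
    """
    scores = np.asarray(table.scores, dtype=float)
    pos = np.flatnonzero(scores > 0.0)
    if len(pos) < MIN_CURVE:
        raise ValueError(
            f"need at least {MIN_CURVE} features with positive score to fit "
            f"3 segments, got {len(pos)}"
        )
    order = pos[np.lexsort((pos, scores[pos]))]  # ascending score, ties by index
    return ScoreCurve(
        log_scores=np.log(scores[order]),
        feature_ids=order,
        n_zero=int(len(scores) - len(pos)),
    )


def _design(x: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Continuity-only piecewise basis: [1, x, (x-t1)_-, (x-t1)_-^2, (x-t2)_+, (x-t2)_+^2].

    The four correction columns vanish on the middle segment and at their
    own knot, so the fitted function is linear between t1 and t2, quadratic
    outside, and continuous at both knots by construction.
    """
    left = np.where(x < t1, x - t1, 0.0)
    right = np.where(x > t2, x - t2, 0.0)
    return np.column_stack([np.ones_like(x), x, left, left**2, right, right**2])


def _fit_pair(x: np.ndarray, y: np.ndarray, k1: int, k2: int):
    """Direct least-squares fit at one knot pair; returns (beta, sse)."""
    A = _design(x, k1 + 0.5, k2 + 0.5)
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid)


def _search_knots(y: np.ndarray) -> tuple[int, int]:
    """Exhaustive minimum-SSE knot search, batched over the whole grid.

    Works in the scaled coordinate u = rank/L for conditioning; knots and
    SSE ordering are invariant to the scaling.
    """
    L = len(y)
    u = np.arange(1, L + 1, dtype=float) / L
    # prefix sums of u^p and u^p * y
    P = np.vstack([np.concatenate([[0.0], np.cumsum(u**p)]) for p in range(5)])
    Q = np.vstack([np.concatenate([[0.0], np.cumsum((u**p) * y)]) for p in range(3)])
    k1s = np.arange(MIN_SEGMENT, L - 2 * MIN_SEGMENT + 1)  # left segment = 1..k1
    k2s = np.arange(2 * MIN_SEGMENT, L - MIN_SEGMENT + 1)  # right segment = k2+1..L
    t1 = (k1s + 0.5) / L
    t2 = (k2s + 0.5) / L

    def expand(ts, prefix_rows, pmax, shift=0):
        # sum over the block of u^shift (u - t)^p for p = 1..pmax, per knot
        return {
            p: sum(
                comb(p, j) * (-ts) ** (p - j) * prefix_rows[j + shift]
                for j in range(p + 1)
            )
            for p in range(1, pmax + 1)
        }

    # left-block sums (functions of k1 only), over i = 1..k1
    Pl = {p: P[p][k1s] for p in range(5)}
    Ql = {p: Q[p][k1s] for p in range(3)}
    A = expand(t1, Pl, 4)  # sum (u-t1)^p
    Acx = expand(t1, Pl, 2, shift=1)  # sum u (u-t1)^p
    Ay = expand(t1, Ql, 2)  # sum y (u-t1)^p
    # right-block sums (functions of k2 only), over i = k2+1..L
    Pt = {p: P[p][-1] - P[p][k2s] for p in range(5)}
    Qt = {p: Q[p][-1] - Q[p][k2s] for p in range(3)}
    R = expand(t2, Pt, 4)
    Rcx = expand(t2, Pt, 2, shift=1)
    Ry = expand(t2, Qt, 2)

    n1, n2 = len(k1s), len(k2s)
    M = np.zeros((n1, n2, 6, 6))
    b = np.zeros((n1, n2, 6))
    ones1 = np.ones((n1, 1))
    ones2 = np.ones((1, n2))

    def fill(i, j, val_k1=None, val_k2=None, const=None):
        if const is not None:
            M[:, :, i, j] = const
        elif val_k1 is not None:
            M[:, :, i, j] = val_k1[:, None]
        else:
            M[:, :, i, j] = val_k2[None, :]
        M[:, :, j, i] = M[:, :, i, j]

    fill(0, 0, const=float(L))
    fill(0, 1, const=P[1][-1])
    fill(1, 1, const=P[2][-1])
    fill(0, 2, val_k1=A[1])
    fill(0, 3, val_k1=A[2])
    fill(1, 2, val_k1=Acx[1])
    fill(1, 3, val_k1=Acx[2])
    fill(2, 2, val_k1=A[2])
    fill(2, 3, val_k1=A[3])
    fill(3, 3, val_k1=A[4])
    fill(0, 4, val_k2=R[1])
    fill(0, 5, val_k2=R[2])
    fill(1, 4, val_k2=Rcx[1])
    fill(1, 5, val_k2=Rcx[2])
    fill(4, 4, val_k2=R[2])
    fill(4, 5, val_k2=R[3])
    fill(5, 5, val_k2=R[4])
    # left/right cross terms are identically zero (disjoint supports)

    b[:, :, 0] = Q[0][-1]
    b[:, :, 1] = Q[1][-1]
    b[:, :, 2] = Ay[1][:, None] * ones2
    b[:, :, 3] = Ay[2][:, None] * ones2
    b[:, :, 4] = ones1 * Ry[1][None, :]
    b[:, :, 5] = ones1 * Ry[2][None, :]

    try:
        beta = np.linalg.solve(M, b[..., None])[..., 0]
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate grids
        beta = (np.linalg.pinv(M) @ b[..., None])[..., 0]
    yty = float(y @ y)
    sse = yty - np.einsum("ijk,ijk->ij", beta, b)
    # mask inadmissible pairs (middle segment shorter than MIN_SEGMENT)
    valid = (k2s[None, :] - k1s[:, None]) >= MIN_SEGMENT
    sse = np.where(valid, sse, np.inf)
    i, j = np.unravel_index(int(np.argmin(sse)), sse.shape)
    return int(k1s[i]), int(k2s[j])


def fit_three_segment(curve: ScoreCurve) -> SegmentFit:
    """Minimum-SSE continuous quadratic–linear–quadratic fit to the curve.

    Exhaustive over all knot pairs with every segment spanning at least 3
    points; deterministic (ties resolve to the lexicographically smallest
    pair scanned first).
    """
    y = curve.log_scores
    if len(y) < MIN_CURVE:
        raise ValueError(f"curve must have at least {MIN_CURVE} points")
    k1, k2 = _search_knots(y)
    x = curve.ranks
    beta, sse = _fit_pair(x, y, k1, k2)
    a, blin, dl, cl, dr, cr = beta
    t1, t2 = k1 + 0.5, k2 + 0.5
    coefficients = {
        # expand a + b x + d (x-t) + c (x-t)^2 into intercept/slope/curvature
        "g1": (a - dl * t1 + cl * t1**2, blin + dl - 2 * cl * t1, cl),
        "g2": (a, blin),
        "g3": (a - dr * t2 + cr * t2**2, blin + dr - 2 * cr * t2, cr),
    }
    return SegmentFit(
        knots=(k1, k2),
        coefficients={k: tuple(float(c) for c in v) for k, v in coefficients.items()},
        sse=sse,
        threshold_score=float(np.exp(y[k2 - 1])),
        curve_length=len(y),
    )


def select_informative(table: ScoreTable, fit: SegmentFit) -> SelectionResult:
    """Features on the upper quadratic segment g3: curve index > upper knot."""
    curve = build_curve(table)
    if fit.curve_length != len(curve):
        raise ValueError("fit does not correspond to this table's curve")
    _, k2 = fit.knots
    ids = curve.feature_ids[k2:]  # curve positions k2+1..L (1-based)
    return SelectionResult(
        selected_ids=tuple(int(i) for i in ids),
        selected_names=tuple(table.feature_names[i] for i in ids),
        threshold_score=fit.threshold_score,
        segment_counts=fit.segment_counts,
    )
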
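"""In-memory container for a samples × features matrix with a response."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeatureMatrix:
    """A numeric design matrix with named feature columns and a response.

    Parameters
    ----------
    values : ndarray of shape (n_samples, d_features)
        Feature values. Must be finite.
    feature_names : list of str
        Unique names, one per column.
    response : ndarray of shape (n_samples,)
        Real response. Binary class labels are encoded as -1/+1 so that
        classification reduces to least-squares regression on the labels.
    """

    values: np.ndarray
    feature_names: list[str]
    response: np.ndarray
    standardized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples × features matrix")
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError(f"{len(self.feature_names)} names for {d} feature columns")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if self.response.shape[0] != n:
            raise ValueError("response length must equal the number of samples")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at sample {bad[0]}, feature {bad[1]}")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite value in response")
        if n < 1:
            raise ValueError("matrix has no samples")

    def require_min_samples(self, minimum: int = 4) -> None:
        """Analysis entry points demand n >= 4; subsampling is degenerate below."""
        if self.n_samples < minimum:
            raise ValueError(
                f"need at least {minimum} samples, got {self.n_samples} "
                "(subsampling is degenerate)"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        """Row subset (e.g. a subsample B); feature columns are unchanged."""
        return FeatureMatrix(
            self.values[rows], list(self.feature_names), self.response[rows]
        )
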
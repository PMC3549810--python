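"""Reading datasets and serializing results.

Datasets are CSV/TSV tables with a header row, samples as rows (use
``transpose=True`` for gene-expression-style files with features as rows)
and one label column.  Binary labels are mapped to -1/+1 (lexicographically
smaller value to -1); numeric labels pass through as regression targets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureMatrix
from .scoring import RunConfig, ScoreTable

logger = logging.getLogger(__name__)


def read_dataset(
    path: str | Path,
    label_column: str,
    delimiter: str | None = None,
    transpose: bool = False,
) -> FeatureMatrix:
    """Load a FeatureMatrix from a delimited text file.

    The delimiter is inferred from the extension (.tsv → tab, else comma)
    unless given.  Exactly-two-valued label columns are encoded as -1/+1.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(names="sample")
        df = df.drop(columns=["sample"])
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")
    labels = df[label_column]
    feats = df.drop(columns=[label_column])
    values = feats.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in feats.columns:
            if not np.issubdtype(feats[col].dtype, np.number):
                raise ValueError(f"non-numeric feature column {col!r}")
    bad = np.argwhere(~np.isfinite(values.astype(float)))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-finite value at row {i}, column {feats.columns[j]!r}"
        )
    uniq = sorted(labels.unique().tolist(), key=str)
    if len(uniq) == 2:
        mapping = {uniq[0]: -1.0, uniq[1]: 1.0}
        logger.info("label mapping: %r -> -1, %r -> +1", uniq[0], uniq[1])
        response = labels.map(mapping).to_numpy(dtype=float)
    else:
        try:
            response = labels.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"label column has {len(uniq)} distinct non-numeric values"
            ) from exc
    if len(df) < 4:
        raise ValueError(f"need at least 4 samples, file has {len(df)}")
    return FeatureMatrix(values.astype(float), list(feats.columns), response)


def write_scores(table: ScoreTable, path: str | Path) -> None:
    """TSV of (feature, score) sorted descending, plus a sidecar meta JSON."""
    path = Path(path)
    order = np.argsort(-table.scores, kind="stable")
    pd.DataFrame(
        {
            "feature": [table.feature_names[i] for i in order],
            "score": [f"{table.scores[i]:.12g}" for i in order],
        }
    ).to_csv(path, sep="\t", index=False)
    sizes, counts = np.unique(table.per_bootstrap_sizes, return_counts=True)
    meta = {
        "config": asdict(table.config),
        "path_size_histogram": {int(s): int(c) for s, c in zip(sizes, counts)},
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_scores(path: str | Path) -> ScoreTable:
    """Re-load a score TSV written by :func:`write_scores`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        config = RunConfig(**json.loads(meta_path.read_text())["config"])
    else:
        config = RunConfig()
    return ScoreTable(
        scores=df["score"].to_numpy(dtype=float),
        feature_names=tuple(df["feature"].astype(str)),
        per_bootstrap_sizes=(),
        config=config,
    )
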
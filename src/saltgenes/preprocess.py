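"""Expression-matrix container, control-probe filtering and quantile normalization.

Input matrices are assumed to be log2-summarized per probe (one probe = one
gene on the motivating array); only the quantile-normalization slice of the
usual RMA pipeline is performed here. Background correction and probe-set
summarization are out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "filter_control_probes", "quantile_normalize"]


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 intensities with two-class sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
    labels
        Mapping ``sample_id -> class`` with classes in ``{+1, -1}``
        (+1 control, -1 stressed). Every sample column must be labeled.
    """

    values: pd.DataFrame
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = {str(k): int(v) for k, v in self.labels.items()}
        if not self.values.index.is_unique:
            raise ValueError("duplicate probe ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.labels]
        if self.labels and missing:
            raise ValueError(f"samples without a class label: {missing[:5]}")
        bad = set(self.labels.values()) - {1, -1}
        if bad:
            raise ValueError(f"class labels must be +1/-1, got {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_columns(self, cls: int) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == cls]

    def label_vector(self) -> np.ndarray:
        """Labels ordered like the sample columns."""
        return np.array([self.labels[s] for s in self.values.columns], dtype=int)

    # --- TSV dialect shared with the synthetic generators -------------------

    def to_tsv(self, expression_path: str | Path, labels_path: str | Path) -> None:
        self.values.rename_axis("probe_id").to_csv(expression_path, sep="\t")
        pd.Series(self.labels, name="class_label").rename_axis("sample_id").to_csv(
            labels_path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, expression_path: str | Path, labels_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)["class_label"].to_dict()
        return cls(values=values, labels={str(k): int(v) for k, v in labels.items()})


def filter_control_probes(matrix: ExpressionMatrix, control_ids: Iterable[str]) -> ExpressionMatrix:
    """Drop control probe sets, preserving probe order.

    Control ids absent from the matrix are ignored with a logged warning;
    removing every probe is an error.
    """
    control = set(map(str, control_ids))
    if matrix.n_probes == 0:
        raise ValueError("empty expression matrix")
    present = control & set(matrix.values.index)
    absent = control - present
    if absent:
        logger.warning("%d control ids not present in the matrix", len(absent))
    keep = [p for p in matrix.values.index if p not in control]
    if not keep:
        raise ValueError("control filter removed every probe")
    return ExpressionMatrix(values=matrix.values.loc[keep], labels=dict(matrix.labels))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common distribution of row-rank means.

    After normalization ``sorted(col_i) == sorted(col_j)`` for all columns.
    Tied values within a column receive the mean of the rank-means their tied
    ranks span (the usual mean-rank convention). Idempotent.
    """
    if matrix.values.isna().any().any():
        raise ValueError("missing values in expression matrix")
    X = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        warnings.warn("quantile normalization skipped: fewer than two samples")
        return ExpressionMatrix(values=matrix.values.copy(), labels=dict(matrix.labels))
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(p):
        col = X[:, j]
        ordinal = rankdata(col, method="ordinal") - 1
        vals = mean_sorted[ordinal]
        # k-way ties get the mean of the k rank-means they span
        dense = rankdata(col, method="dense") - 1
        group_sum = np.bincount(dense, weights=vals)
        group_n = np.bincount(dense)
        out[:, j] = group_sum[dense] / group_n[dense]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, labels=dict(matrix.labels))
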
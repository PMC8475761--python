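"""Pearson-correlation similarity analysis of trial feature vectors.

For one run and condition, every block-averaged trial is flattened to a
vector (rows major, frequency minor) and correlated with every other trial,
giving an (n_subjects x trials) square similarity matrix ordered by subject
then trial time. If the features carry an identity signal, within-subject
blocks along the diagonal are visibly more correlated than between-subject
blocks; ``intra_inter_summary`` turns that picture into per-subject numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedCorrelationError
from .spectral_features import FeatureTensor


@dataclass
class SimilarityMatrix:
    values: np.ndarray = field(repr=False)  # (n, n) Pearson correlations
    subjects: np.ndarray  # (n,) subject label per row
    feature_kind: str

    def __post_init__(self) -> None:
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.subjects) != n:
            raise ValueError("values must be square with one subject label per row")


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient cov(X,Y)/(sigma_X sigma_Y)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def similarity_matrix(t: FeatureTensor, order: np.ndarray | None = None) -> SimilarityMatrix:
    """Trial-by-trial correlation matrix for a single run and condition.

    Trials are ordered by subject (first appearance) then original trial
    order; ``order`` overrides with an explicit permutation of trial indices.
    """
    if t.transform_state != "transformed" or not t.block_averaged:
        raise ValueError("expected a transformed, block-averaged tensor")
    if len(set(t.runs)) != 1 or len(set(t.conditions)) != 1:
        raise ValueError("similarity matrix is per run and condition")
    if order is None:
        # stable sort by subject keeps trial time order within subjects
        order = np.argsort(t.subjects, kind="stable")
    vecs = t.data[order].reshape(len(order), -1)
    values = np.corrcoef(vecs)
    return SimilarityMatrix(
        values=values, subjects=t.subjects[order], feature_kind=t.kind
    )


def intra_inter_summary(m: SimilarityMatrix) -> pd.DataFrame:
    """Per-subject mean within-block vs between-block correlation.

    The diagonal (self-correlations) is excluded from the within-block mean.
    Columns: subject, intra_mean, inter_mean, separation.
    """
    subjects = np.asarray(m.subjects)
    uniq = list(dict.fromkeys(subjects.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects")
    n = len(subjects)
    offdiag = ~np.eye(n, dtype=bool)
    rows = []
    for s in uniq:
        mask = subjects == s
        intra = m.values[np.ix_(mask, mask)][offdiag[np.ix_(mask, mask)]]
        inter = m.values[np.ix_(mask, ~mask)]
        intra_mean = float(intra.mean()) if intra.size else 0.0
        inter_mean = float(inter.mean())
        rows.append(
            {
                "subject": s,
                "intra_mean": intra_mean,
                "inter_mean": inter_mean,
                "separation": intra_mean - inter_mean,
            }
        )
    return pd.DataFrame(rows)
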
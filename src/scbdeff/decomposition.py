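"""Total beta diversity and its species / site contributions.

Beta diversity is measured as the total variance of the community matrix
after Hellinger transformation: each site row is converted to square roots
of relative abundances, and the total sum of squares of deviations from
species (column) means is partitioned.  The per-species share of that sum
of squares is the species contribution to beta diversity (SCBD); the
per-site share is the local contribution (LCBD); the total sum of squares
divided by (n_sites - 1) is BDtotal, which lies in [0, 1] for
Hellinger-transformed data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NoBetaDiversityError",
    "hellinger_transform",
    "BetaDiversityPartition",
    "decompose",
]


class NoBetaDiversityError(ValueError):
    """All sites are identical after transformation: SS_total = 0."""


def _as_frame(Y, orientation: str = "sites-rows") -> pd.DataFrame:
    """Coerce input to a sites x species DataFrame."""
    if orientation not in ("sites-rows", "species-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if isinstance(Y, pd.DataFrame):
        df = Y.copy()
    else:
        arr = np.asarray(Y, dtype=float)
        if arr.ndim != 2:
            raise ValueError("community matrix must be 2-dimensional")
        df = pd.DataFrame(arr)
        df.index = [f"site{i}" for i in range(arr.shape[0])]
        df.columns = [f"sp{j}" for j in range(arr.shape[1])]
    if orientation == "species-rows":
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate site or species labels in community matrix")
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("community matrix contains non-finite values")
    if (vals < 0).any():
        raise ValueError("community matrix contains negative abundances")
    return df


def hellinger_transform(Y, orientation: str = "sites-rows") -> pd.DataFrame:
    """Hellinger-transform a community matrix.

    Each entry becomes sqrt(y_ij / row_sum_i), so every site row has unit
    Euclidean norm.  Sites with zero total abundance are not analyzable and
    raise a ``ValueError`` naming them.
    """
    df = _as_frame(Y, orientation)
    vals = df.to_numpy(dtype=float)
    row_sums = vals.sum(axis=1)
    empty = row_sums <= 0
    if empty.any():
        bad = list(df.index[empty])
        raise ValueError(f"empty sites (zero total abundance) cannot be Hellinger-transformed: {bad}")
    out = np.sqrt(vals / row_sums[:, None])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


class BetaDiversityPartition(TransformerMixin, BaseEstimator):
    """Sum-of-squares partition of beta diversity.

    Parameters
    ----------
    transform_method : {"hellinger", "none"}
        Pre-transformation applied to the abundance matrix. ``"none"``
        partitions the raw matrix (BDtotal is then not bounded by 1).
    orientation : {"sites-rows", "species-rows"}
        Orientation of the input matrix.

    Attributes
    ----------
    transformed_ : DataFrame
        The (Hellinger-)transformed sites x species matrix.
    ss_total_ : float
        Total sum of squares of deviations from column means.
    bd_total_ : float
        ``ss_total_ / (n_sites - 1)``.
    scbd_ : Series
        Per-species contribution, summing to 1.
    lcbd_ : Series
        Per-site contribution, summing to 1.

    Examples
    --------
    >>> part = BetaDiversityPartition().fit([[1, 0], [0, 1]])
    >>> part.bd_total_
    1.0
    """

    def __init__(self, transform_method: str = "hellinger", orientation: str = "sites-rows"):
        self.transform_method = transform_method
        self.orientation = orientation

    def fit(self, X, y=None):
        df = _as_frame(X, self.orientation)
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError("decomposition needs at least 2 sites and 2 species")
        if self.transform_method == "hellinger":
            t = hellinger_transform(df)
        elif self.transform_method == "none":
            t = df
        else:
            raise ValueError(f"unknown transform_method {self.transform_method!r}")
        vals = t.to_numpy(dtype=float)
        s = (vals - vals.mean(axis=0)) ** 2
        ss_total = float(s.sum())
        if ss_total <= 1e-300:
            raise NoBetaDiversityError(
                "no beta diversity: all sites identical after transformation (SS_total = 0)"
            )
        self.transformed_ = t
        self.ss_total_ = ss_total
        self.bd_total_ = ss_total / (df.shape[0] - 1)
        self.scbd_ = pd.Series(s.sum(axis=0) / ss_total, index=df.columns, name="scbd")
        self.lcbd_ = pd.Series(s.sum(axis=1) / ss_total, index=df.index, name="lcbd")
        self.n_sites_ = df.shape[0]
        self.n_species_ = df.shape[1]
        return self

    def transform(self, X):
        """Return the (Hellinger-)transformed matrix for new data."""
        df = _as_frame(X, self.orientation)
        if self.transform_method == "hellinger":
            return hellinger_transform(df)
        return df


def decompose(Y, orientation: str = "sites-rows") -> BetaDiversityPartition:
    """Convenience wrapper: fit a :class:`BetaDiversityPartition` on ``Y``."""
    return BetaDiversityPartition(orientation=orientation).fit(Y)
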
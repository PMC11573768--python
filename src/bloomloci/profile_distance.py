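"""Chi-squared distances between function profiles and classical MDS.

The distance between two profile rows is computed on row proportions,
weighted by inverse column mass and scaled by the square root of the
grand total — the convention used for correspondence-analysis style
ordination of community profiles.  Ordination is Torgerson double
centering with eigendecomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MdsResult", "chisq_distance", "classical_mds", "profiles_from_matrix"]


def chisq_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise chi-squared distances between rows of a profile matrix.

    d(i,j) = sqrt( N * sum_k (1/c_k) * (x_ik/r_i - x_jk/r_j)^2 ) with
    r the row sums, c the column sums and N the grand total.  All-zero
    columns are dropped with a warning; an all-zero row is an error.
    """
    x = profiles.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("profile values must be non-negative")
    row_sums = x.sum(axis=1)
    zero_rows = np.flatnonzero(row_sums == 0)
    if zero_rows.size:
        names = [str(profiles.index[i]) for i in zero_rows]
        raise ValueError(f"all-zero profile row(s): {names}")
    col_sums = x.sum(axis=0)
    keep = col_sums > 0
    if not keep.all():
        dropped = [str(c) for c in profiles.columns[~keep]]
        warnings.warn(f"dropping all-zero column(s): {dropped}", stacklevel=2)
        x = x[:, keep]
        col_sums = col_sums[keep]
    n_total = x.sum()
    props = x / row_sums[:, None]
    # squared distance via broadcasting over row pairs
    diff = props[:, None, :] - props[None, :, :]
    d2 = n_total * (diff * diff / col_sums).sum(axis=2)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class MdsResult:
    coordinates: pd.DataFrame  # rows x retained axes
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives included)
    explained_pct: np.ndarray  # percent of positive-eigenvalue mass, per retained axis

    @property
    def n_positive(self) -> int:
        return int((self.eigenvalues > 0).sum())


def classical_mds(distances: pd.DataFrame, k: int = 2) -> MdsResult:
    """Torgerson scaling of a symmetric zero-diagonal distance matrix.

    B = -1/2 * J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by sqrt of the positive eigenvalues.  Axis signs are fixed by
    forcing each axis's largest-magnitude loading positive.  Explained
    variance is relative to the positive eigenvalue total; negative
    eigenvalues are reported but never used.  ``k`` beyond the positive
    count is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix diagonal must be zero")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = max(n_pos, 0)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    pos_total = eigvals[:n_pos].sum() if n_pos else 1.0
    explained = 100.0 * eigvals[:k] / pos_total
    return MdsResult(
        coordinates=pd.DataFrame(
            coords,
            index=distances.index,
            columns=[f"axis{i + 1}" for i in range(k)],
        ),
        eigenvalues=eigvals,
        explained_pct=explained,
    )


def profiles_from_matrix(
    cn_table: pd.DataFrame,
    functions: list[str] | None = None,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Build a profile matrix from a long-form copy-number table.

    Rows are taxa (values averaged over the series) or taxon-sample
    pairs with ``per_sample``; columns are functions.  Undefined cells
    are excluded from averages; all-zero rows are rejected downstream.
    """
    t = cn_table[cn_table["defined"]]
    if functions is not None:
        t = t[t["function"].isin(functions)]
    if per_sample:
        t = t.assign(row=t["taxon"] + "|" + t["sample"])
        wide = t.pivot_table(index="row", columns="function", values="value")
    else:
        wide = t.pivot_table(index="taxon", columns="function", values="value")
    return wide.fillna(0.0)
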
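"""Spearman/FDR screening of function copy numbers against chlorophyll.

Rho is the Pearson correlation of average ranks.  Two-sided p-values
come from full permutation enumeration for n <= 8 (where the asymptotic
approximation is unreliable) and from the t approximation with n - 2
degrees of freedom otherwise.  Benjamini–Hochberg step-up controls the
FDR across the screened families.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st

from bloomloci.datamodel_io import (
    FunctionSets,
    OrfRecord,
    SampleSeries,
    ValidationError,
)
from bloomloci.copy_number import compute_matrix, families_of_class

__all__ = [
    "CorrelationResult",
    "spearman",
    "bh_fdr",
    "screen_families",
    "screen_matrix",
    "positive_table",
    "negative_table",
]

EXACT_MAX_N = 8


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Spearman rho and a two-sided p-value.

    ``method``: ``auto`` (exact enumeration for n <= 8, else t
    approximation), ``exact`` or ``approx``.  Constant input returns
    (nan, nan) so screens can flag rather than fail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 4:
        raise ValidationError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    rho = _rank_corr(rx, ry)

    if method not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown method {method!r}")
    exact = method == "exact" or (method == "auto" and n <= EXACT_MAX_N)
    if exact:
        if n > EXACT_MAX_N:
            raise ValidationError(f"exact enumeration limited to n <= {EXACT_MAX_N}")
        hits = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.asarray(perm))) >= target:
                hits += 1
        return rho, hits / total
    # t approximation, n - 2 df
    r = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(_st.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return [float(v) for v in q]


@dataclass
class CorrelationResult:
    function: str
    rho: float
    p_value: float
    q_value: float
    n: int
    significant: bool


def screen_families(
    orfs: Sequence[OrfRecord],
    samples: SampleSeries,
    taxon: str | None,
    cazy_class: str,
    sets: FunctionSets,
    alpha: float = 0.01,
    method: str = "auto",
) -> list[CorrelationResult]:
    """Correlate each family of a class against chlorophyll, BH-corrected.

    One result per family/subfamily of the class present in the taxon
    subset; all-zero or constant copy-number series are skipped.
    Results are sorted by q then |rho| descending.  Significance is
    q <= alpha.
    """
    families = families_of_class(orfs, cazy_class, taxon)
    matrix = compute_matrix(orfs, samples, [taxon], families, sets)
    label = taxon if taxon is not None else "community"
    return screen_matrix(matrix, samples, label, families, alpha=alpha, method=method)


def screen_matrix(
    matrix,
    samples: SampleSeries,
    taxon_label: str,
    families: Sequence[str],
    alpha: float = 0.01,
    method: str = "auto",
) -> list[CorrelationResult]:
    """Screen precomputed copy-number series against chlorophyll."""
    if len(samples) < 4:
        raise ValidationError("need at least 4 samples")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    chlorophyll = np.asarray(samples.chlorophyll, dtype=float)

    screened: list[tuple[str, float, float]] = []
    for family in families:
        values = matrix.series(taxon_label, family).to_numpy(dtype=float)
        if np.isnan(values).any():
            continue  # undefined denominator somewhere in the series
        if np.all(values == 0) or np.all(values == values[0]):
            continue
        rho, p = spearman(chlorophyll, values, method=method)
        if math.isnan(rho):
            continue
        screened.append((family, rho, p))
    if not screened:
        return []
    # underflowed approximate p-values are clamped to the smallest positive float
    tiny = math.ulp(0.0)
    qs = bh_fdr([p if p > 0 else tiny for _, _, p in screened])
    results = [
        CorrelationResult(
            function=fam,
            rho=rho,
            p_value=p,
            q_value=q,
            n=len(samples),
            significant=q <= alpha,
        )
        for (fam, rho, p), q in zip(screened, qs)
    ]
    results.sort(key=lambda r: (r.q_value, -abs(r.rho)))
    return results


def positive_table(results: Sequence[CorrelationResult]) -> list[CorrelationResult]:
    return [r for r in results if r.rho > 0]


def negative_table(results: Sequence[CorrelationResult]) -> list[CorrelationResult]:
    return [r for r in results if r.rho < 0]
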
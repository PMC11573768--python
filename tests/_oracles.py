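"""Independent reference implementations used only by the test suite.

Each oracle is deliberately brute-force (enumeration, explicit sorting,
closed forms) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as st


# --- rank statistics -------------------------------------------------------

def spearman_rho_oracle(x, y) -> float:
    """Pearson correlation of rank vectors via numpy.corrcoef."""
    return float(np.corrcoef(st.rankdata(x), st.rankdata(y))[0, 1])


def spearman_exact_p_oracle(x, y) -> float:
    """Two-sided p by enumerating every permutation of y."""
    obs = abs(spearman_rho_oracle(x, y))
    y = list(y)
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho_oracle(x, perm)) >= obs - 1e-12:
            hits += 1
    return hits / total


def bh_oracle(pvals):
    """Step-up BH applied literally to the definition, no vectorization."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    q = [None] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = indexed[pos]
        running_min = min(running_min, pvals[i] * m / (pos + 1))
        q[i] = min(running_min, 1.0)
    return q


# --- chi-squared distance --------------------------------------------------

def chisq_oracle(matrix) -> np.ndarray:
    """Element-wise loop transcription of the distance definition."""
    x = np.asarray(matrix, dtype=float)
    n_rows, n_cols = x.shape
    r = [sum(x[i]) for i in range(n_rows)]
    c = [sum(x[:, k]) for k in range(n_cols)]
    n = sum(r)
    d = np.zeros((n_rows, n_rows))
    for i in range(n_rows):
        for j in range(n_rows):
            acc = 0.0
            for k in range(n_cols):
                if c[k] == 0:
                    continue
                acc += (x[i, k] / r[i] - x[j, k] / r[j]) ** 2 / c[k]
            d[i, j] = math.sqrt(n * acc)
    return d


# --- median ----------------------------------------------------------------

def median_by_sort(values) -> float:
    vals = sorted(values)
    n = len(vals)
    if n % 2 == 1:
        return float(vals[n // 2])
    return (vals[n // 2 - 1] + vals[n // 2]) / 2.0


# --- PUL locus window oracle ----------------------------------------------

def gap_between(left, right) -> int:
    return max(right.start - left.end - 1, 0)


def locus_window_oracle(genes, susc_id, susd_id, strand, max_gap=102):
    """Largest coordinate window around the tandem satisfying the rules.

    Enumerates every [L, R] index window containing both tandem genes
    and checks the clustering predicate directly: every gene on the
    tandem strand, and every step away from the tandem either within
    the gap limit or onto a cazyme.  Returns the orf_ids of the widest
    valid window.
    """
    genes = sorted(genes, key=lambda g: (g.start, g.end, g.orf_id))
    idx = {g.orf_id: i for i, g in enumerate(genes)}
    t_lo, t_hi = sorted((idx[susc_id], idx[susd_id]))

    def valid(lo, hi):
        for g in genes[lo:hi + 1]:
            if g.strand != strand:
                return False
        for j in range(t_hi + 1, hi + 1):
            if gap_between(genes[j - 1], genes[j]) >= max_gap and not genes[j].cazy_families:
                return False
        for j in range(t_lo - 1, lo - 1, -1):
            if gap_between(genes[j], genes[j + 1]) >= max_gap and not genes[j].cazy_families:
                return False
        return True

    best = (t_lo, t_hi)
    for lo in range(0, t_lo + 1):
        for hi in range(t_hi, len(genes)):
            if hi - lo > best[1] - best[0] and valid(lo, hi):
                best = (lo, hi)
    # the oracle must itself verify the minimal window is legal
    assert valid(*best) or best == (t_lo, t_hi)
    return [g.orf_id for g in genes[best[0]:best[1] + 1]]
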
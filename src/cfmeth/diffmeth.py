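"""Per-site differential methylation statistics between two sample groups.

The workhorse test is the two-tailed Mann-Whitney U (MWW).  For small
pooled sizes (n_a + n_b <= 12) the U distribution is enumerated exactly
over all group assignments of the mid-ranked pooled values, which handles
ties correctly; larger inputs use the tie-corrected normal approximation
with continuity correction.  Multiplicity is controlled per call with
Benjamini-Hochberg, and effect size is a pseudocounted mean fold change
(MEPM means are frequently zero in plasma).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import MethylationMatrix

EXACT_MAX_N = 12


@dataclass(frozen=True)
class DiffMethResult:
    site_id: str
    mean_a: float
    mean_b: float
    fold_change: float
    p_value: float
    q_value: float
    direction: str  # "hyper" (a > b) or "hypo"


def _exact_mww_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact MWW p by enumerating all C(n, n_a) assignments."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - offset
    total = comb(n, n_a)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def mww_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact enumeration for n_a + n_b <= 12; otherwise the tie-corrected
    normal approximation with continuity correction.  Returns p in (0, 1].
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if pooled.min() == pooled.max():
        return 1.0
    if a.size + b.size <= EXACT_MAX_N:
        return _exact_mww_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(min(1.0, max(res.pvalue, np.nextafter(0, 1))))


def _mww_pvalues_matrix(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Column-wise two-tailed MWW p-values for two (samples x sites) blocks."""
    n_a, n_b = values_a.shape[0], values_b.shape[0]
    m = values_a.shape[1]
    if n_a + n_b <= EXACT_MAX_N:
        return np.array([_fast_small(values_a[:, j], values_b[:, j]) for j in range(m)])
    p = np.ones(m)
    lo = np.minimum(values_a.min(axis=0), values_b.min(axis=0))
    hi = np.maximum(values_a.max(axis=0), values_b.max(axis=0))
    varying = lo != hi
    if varying.any():
        res = stats.mannwhitneyu(
            values_a[:, varying], values_b[:, varying],
            alternative="two-sided", method="asymptotic", axis=0,
        )
        p[varying] = np.minimum(1.0, res.pvalue)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _fast_small(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if pooled.min() == pooled.max():
        return 1.0
    return _exact_mww_p(a, b)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.5) -> float:
    """Pseudocounted ratio of group means: (mean_a + c) / (mean_b + c)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return (mean_a + pseudocount) / (mean_b + pseudocount)


def differential_sites(
    matrix: MethylationMatrix,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    q_max: float = 0.05,
    fc_min: float = 2.0,
    pseudocount: float = 0.5,
) -> tuple[list[DiffMethResult], tuple[int, int]]:
    """Sites differentially methylated between groups A and B.

    Per site: MWW p-value, BH q-value (one family per call, across all
    sites tested), and pseudocounted mean fold change.  A site is kept when
    q < ``q_max`` and the fold change exceeds ``fc_min`` in either
    direction.  Returns the retained sites sorted by ascending p plus the
    (hyper, hypo) counts, where "hyper" means mean_a > mean_b.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if not a_ids or not b_ids:
        raise ValueError("both groups must be non-empty")
    overlap = set(a_ids) & set(b_ids)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")

    va = matrix.values.loc[a_ids].to_numpy()
    vb = matrix.values.loc[b_ids].to_numpy()
    p = _mww_pvalues_matrix(va, vb)
    q = bh_fdr(p)
    mean_a = va.mean(axis=0)
    mean_b = vb.mean(axis=0)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)

    keep = (q < q_max) & ((fc > fc_min) | (fc < 1.0 / fc_min))
    order = np.argsort(p[keep], kind="stable")
    idx = np.flatnonzero(keep)[order]
    site_ids = matrix.site_ids
    results = [
        DiffMethResult(
            site_id=site_ids[j],
            mean_a=float(mean_a[j]),
            mean_b=float(mean_b[j]),
            fold_change=float(fc[j]),
            p_value=float(p[j]),
            q_value=float(q[j]),
            direction="hyper" if mean_a[j] > mean_b[j] else "hypo",
        )
        for j in idx
    ]
    n_hyper = sum(1 for r in results if r.direction == "hyper")
    return results, (n_hyper, len(results) - n_hyper)
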
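"""Consensus clustering of tumor samples and CIMP subtype labeling.

Subsampled hierarchical clustering (Ward linkage, Euclidean distance on
log1p-transformed MEPM) is repeated over resampled subsets; the consensus
matrix entry (i, j) is the fraction of co-drawn resamples in which i and j
co-clustered.  The number of clusters k is judged from the empirical CDF
of consensus values; the default decision rule minimizes the proportion
of ambiguous clustering (PAC) — the CDF mass between 0.1 and 0.9 — which
behaves sensibly for imbalanced subgroups, with the classical relative
delta-area rule available and its curve always reported.  With
k = 2, the cluster whose samples have the larger median total methylation
over the diagnostic panel is labeled CIMP (CpG island methylator
phenotype).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .panel import MarkerPanel, panel_totals
from .types import MethylationMatrix


@dataclass
class ConsensusResult:
    consensus_matrices: dict[int, pd.DataFrame]
    cdf_per_k: dict[int, pd.DataFrame]
    delta_area: dict[int, float]
    optimal_k: int
    assignments: pd.Series  # sample -> cluster id at optimal_k

    def assignments_for(self, k: int) -> pd.Series:
        return _assign_from_consensus(self.consensus_matrices[k], k)


def _features(matrix: MethylationMatrix, sites) -> pd.DataFrame:
    values = matrix.values if sites is None else matrix.values[list(sites)]
    return np.log1p(values)


def _cluster_once(X: np.ndarray, k: int) -> np.ndarray:
    if len(X) == k:
        return np.arange(1, k + 1)
    return fcluster(linkage(X, method="ward"), t=k, criterion="maxclust")


def consensus_matrix(
    matrix: MethylationMatrix,
    k: int,
    n_resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    sites=None,
) -> pd.DataFrame:
    """Co-clustering frequencies over subsampled Ward clusterings.

    Entry (i, j) is (#resamples where i, j co-cluster) / (#resamples where
    both were drawn); the diagonal is 1.  Samples are processed in
    sample-id order internally, so permuting the input order permutes the
    result consistently.
    """
    n = matrix.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    order = sorted(matrix.sample_ids)
    feats = _features(matrix, sites).loc[order].to_numpy()
    if n == 1:
        return pd.DataFrame([[1.0]], index=order, columns=order)

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, k])
    size = max(k, int(np.ceil(subsample_frac * n)))
    together = np.zeros((n, n))
    drawn = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=size, replace=False)
        idx.sort()
        labels = _cluster_once(feats[idx], k)
        same = labels[:, None] == labels[None, :]
        drawn[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(drawn > 0, together / np.maximum(drawn, 1), 0.0)
    cons = (cons + cons.T) / 2.0
    np.fill_diagonal(cons, 1.0)
    return pd.DataFrame(cons, index=order, columns=order)


def _cdf_and_area(cons: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    n = cons.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.sort(cons.to_numpy()[iu])
    if vals.size == 0:
        return pd.DataFrame({"consensus": [0.0, 1.0], "cdf": [1.0, 1.0]}), 1.0
    f = np.arange(1, vals.size + 1) / vals.size
    area = float(np.sum(np.diff(vals) * f[:-1]) + (1.0 - vals[-1]) * 1.0 + vals[0] * 0.0)
    cdf = pd.DataFrame({"consensus": vals, "cdf": f})
    return cdf, area


def pac_score(cons: pd.DataFrame, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: consensus mass in (lower, upper).

    A crisp partition leaves pairwise consensus values near 0 or 1; mass in
    the middle of the unit interval signals unstable co-clustering.
    """
    n = cons.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = cons.to_numpy()[iu]
    if vals.size == 0:
        return 0.0
    return float(((vals > lower) & (vals < upper)).mean())


def optimal_k(
    consensus_by_k: dict[int, pd.DataFrame],
    delta_threshold: float = 0.1,
    method: str = "pac",
    pac_ambiguity_max: float = 0.2,
) -> tuple[int, dict[int, float], dict[int, pd.DataFrame]]:
    """Choose the number of clusters from the consensus CDFs.

    ``method="pac"`` (default) picks the k with the smallest proportion of
    ambiguous clustering (ties to the smallest k); when even the best k
    leaves more than ``pac_ambiguity_max`` of the pairs ambiguous the data
    are treated as structureless and k falls back to 2.  ``method="delta"``
    is the CDF delta-area rule (largest k whose relative area gain meets
    ``delta_threshold``; Delta(2) is the area itself); the delta-area curve
    is computed and returned either way.
    """
    ks = sorted(consensus_by_k)
    if not ks or ks[0] < 2:
        raise ValueError("consensus results must start at k=2")
    areas: dict[int, float] = {}
    cdfs: dict[int, pd.DataFrame] = {}
    for k in ks:
        cdfs[k], areas[k] = _cdf_and_area(consensus_by_k[k])
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    if method == "delta":
        passing = [k for k in ks if delta[k] >= delta_threshold]
        return (max(passing) if passing else 2), delta, cdfs
    if method != "pac":
        raise ValueError(f"unknown method {method!r}")
    pacs = {k: pac_score(consensus_by_k[k]) for k in ks}
    best = min(ks, key=lambda k: (pacs[k], k))
    if pacs[best] > pac_ambiguity_max:
        best = 2
    return best, delta, cdfs


def _assign_from_consensus(cons: pd.DataFrame, k: int) -> pd.Series:
    if cons.shape[0] == 1:
        return pd.Series([1], index=cons.index, name="cluster")
    dist = 1.0 - cons.to_numpy()
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                      t=k, criterion="maxclust")
    return pd.Series(labels, index=cons.index, name="cluster")


def consensus_cluster(
    matrix: MethylationMatrix,
    k_max: int = 6,
    n_resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    sites=None,
    delta_threshold: float = 0.1,
    method: str = "pac",
) -> ConsensusResult:
    """Full consensus-clustering run over k = 2..k_max."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    by_k = {
        k: consensus_matrix(matrix, k, n_resamples, subsample_frac, seed, sites)
        for k in range(2, k_max + 1)
    }
    best, delta, cdfs = optimal_k(by_k, delta_threshold, method=method)
    assignments = _assign_from_consensus(by_k[best], best)
    return ConsensusResult(
        consensus_matrices=by_k,
        cdf_per_k=cdfs,
        delta_area=delta,
        optimal_k=best,
        assignments=assignments,
    )


def assign_cimp(
    assignments: pd.Series,
    matrix: MethylationMatrix,
    panel: MarkerPanel,
) -> tuple[int, pd.DataFrame]:
    """Label the CIMP cluster of a two-cluster tumor partition.

    CIMP is the cluster with the larger median per-sample total
    methylation over the diagnostic panel.  Requires exactly two clusters;
    an exact median tie is reported as an error.
    """
    clusters = sorted(assignments.unique())
    if len(clusters) != 2:
        raise ValueError(f"CIMP labeling needs exactly 2 clusters, got {len(clusters)}")
    totals = panel_totals(matrix.select_samples(list(assignments.index)), panel)
    medians = {c: float(totals[assignments[assignments == c].index].median()) for c in clusters}
    summary = pd.DataFrame(
        {
            "n_samples": [int((assignments == c).sum()) for c in clusters],
            "median_total_methylation": [medians[c] for c in clusters],
        },
        index=pd.Index(clusters, name="cluster"),
    )
    if medians[clusters[0]] == medians[clusters[1]]:
        raise ValueError("cluster medians tie exactly; CIMP is undefined")
    cimp = max(clusters, key=lambda c: medians[c])
    return int(cimp), summary
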
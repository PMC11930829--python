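"""The positivity-counting diagnostic model.

A sample's statistic for a marker panel is the number of panel sites with
methylation strictly above the per-marker positivity threshold (default 0:
any fully methylated molecule observed).  Panel size is chosen by Monte
Carlo cross-validation of a count -> probability logistic model scored
with the Brier score; the panel-level count cut-off is calibrated on an
independent normal-plasma cohort and classification is positive when the
count strictly exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

from .types import MethylationMatrix


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered marker set with positivity thresholds and a count cut-off."""

    cancer: str
    marker_ids: tuple[str, ...]
    thresholds: tuple[float, ...] = ()
    count_cutoff: int | None = None
    selection_pvalues: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids in panel")
        if not self.thresholds:
            object.__setattr__(self, "thresholds", tuple(0.0 for _ in self.marker_ids))
        if len(self.thresholds) != len(self.marker_ids):
            raise ValueError("one threshold per marker required")
        if self.count_cutoff is not None:
            if self.count_cutoff < 0:
                raise ValueError("count_cutoff must be >= 0")
            if self.count_cutoff >= len(self.marker_ids):
                raise ValueError("count_cutoff must be smaller than the panel size")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def with_cutoff(self, cutoff: int) -> "MarkerPanel":
        return replace(self, count_cutoff=int(cutoff))

    def head(self, n: int) -> "MarkerPanel":
        return MarkerPanel(
            cancer=self.cancer,
            marker_ids=self.marker_ids[:n],
            thresholds=self.thresholds[:n],
            selection_pvalues=self.selection_pvalues[:n],
        )


@dataclass(frozen=True)
class PanelEvaluation:
    """Positive count, exact positive fraction and total methylation."""

    positive_count: int
    fraction_positive: Fraction
    total_methylation: float

    def __post_init__(self) -> None:
        if self.positive_count < 0:
            raise ValueError("positive_count must be >= 0")
        if self.total_methylation < 0:
            raise ValueError("total_methylation must be >= 0")


def _sample_panel_values(sample_values, panel: MarkerPanel) -> np.ndarray:
    if isinstance(sample_values, pd.Series):
        mapping = sample_values
    elif isinstance(sample_values, Mapping):
        mapping = pd.Series(sample_values)
    else:
        raise TypeError("sample_values must be a Series or mapping of site -> MEPM")
    missing = [m for m in panel.marker_ids if m not in mapping.index]
    if missing:
        raise KeyError(f"sample is missing panel markers: {missing[:5]}")
    return mapping[list(panel.marker_ids)].to_numpy(dtype=float)


def positive_count(sample_values, panel: MarkerPanel) -> int:
    """Number of panel markers with value strictly above their threshold."""
    vals = _sample_panel_values(sample_values, panel)
    return int((vals > np.asarray(panel.thresholds)).sum())


def total_methylation(sample_values, panel: MarkerPanel) -> float:
    """Sum of panel MEPM values, counting only positive markers."""
    vals = _sample_panel_values(sample_values, panel)
    pos = vals > np.asarray(panel.thresholds)
    return float(vals[pos].sum())


def evaluate_sample(sample_values, panel: MarkerPanel) -> PanelEvaluation:
    vals = _sample_panel_values(sample_values, panel)
    pos = vals > np.asarray(panel.thresholds)
    denom = max(len(panel), 1)  # empty panel counts nothing
    return PanelEvaluation(
        positive_count=int(pos.sum()),
        fraction_positive=Fraction(int(pos.sum()), denom),
        total_methylation=float(vals[pos].sum()),
    )


def panel_counts(matrix: MethylationMatrix, panel: MarkerPanel) -> pd.Series:
    """Positive counts for every sample in a matrix (vectorized)."""
    missing = [m for m in panel.marker_ids if m not in matrix.values.columns]
    if missing:
        raise KeyError(f"matrix is missing panel markers: {missing[:5]}")
    vals = matrix.values[list(panel.marker_ids)].to_numpy()
    counts = (vals > np.asarray(panel.thresholds)).sum(axis=1)
    return pd.Series(counts, index=matrix.values.index, name="positive_count")


def panel_totals(matrix: MethylationMatrix, panel: MarkerPanel) -> pd.Series:
    """Per-sample total methylation over positive panel markers."""
    missing = [m for m in panel.marker_ids if m not in matrix.values.columns]
    if missing:
        raise KeyError(f"matrix is missing panel markers: {missing[:5]}")
    vals = matrix.values[list(panel.marker_ids)].to_numpy()
    pos = vals > np.asarray(panel.thresholds)
    return pd.Series((vals * pos).sum(axis=1), index=matrix.values.index, name="total_methylation")


def calibrate_count_cutoff(
    normal_plasma_matrix: MethylationMatrix,
    panel: MarkerPanel,
    policy: str = "max",
    quantile: float = 0.95,
    min_normals: int = 10,
) -> int:
    """Panel-level count cut-off from an independent normal-plasma cohort.

    ``policy="max"`` sets the cut-off to the largest positive count seen in
    the calibration normals, guaranteeing 100% specificity on that cohort
    (downstream classification is positive iff count > cutoff, strictly).
    ``policy="quantile"`` returns the smallest integer c whose empirical
    exceedance probability P(count > c) is at most 1 - quantile.
    """
    counts = panel_counts(normal_plasma_matrix, panel).to_numpy()
    if counts.size < min_normals:
        raise ValueError(
            f"need at least {min_normals} calibration normals, got {counts.size}"
        )
    if policy == "max":
        return int(counts.max())
    if policy == "quantile":
        if not 0 < quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        for c in range(int(counts.max()) + 1):
            if (counts > c).mean() <= 1.0 - quantile:
                return c
        return int(counts.max())
    raise ValueError(f"unknown policy {policy!r}")


def classify_by_count(sample_values, panel: MarkerPanel) -> tuple[str, PanelEvaluation]:
    """"positive" iff the positive count strictly exceeds the panel cut-off."""
    if panel.count_cutoff is None:
        raise ValueError("panel has no calibrated count_cutoff")
    evaluation = evaluate_sample(sample_values, panel)
    label = "positive" if evaluation.positive_count > panel.count_cutoff else "negative"
    return label, evaluation


def brier_score(predicted_probs: Sequence[float], outcomes: Sequence[int]) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predicted_probs and outcomes must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    return float(np.mean((p - y) ** 2))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, pd.DataFrame]:
    """AUC via the rank (Mann-Whitney U) formulation, plus ROC points.

    AUC = U / (n_case * n_control) with tied scores contributing 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int(y.sum())
    n0 = int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    fpr, tpr, thr = roc_curve(y, s)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, points


def monte_carlo_panel_size(
    plasma_matrix: MethylationMatrix,
    candidate_markers_ranked: Sequence[str],
    size_grid: Sequence[int] | None = None,
    n_splits: int = 1000,
    seed: int = 0,
    positivity_threshold: float = 0.0,
    train_fraction: float = 0.5,
) -> tuple[int, pd.Series]:
    """Choose the panel size minimizing the Monte Carlo mean Brier score.

    For each random stratified train/test split and each candidate size s,
    the positive count over the top-s ranked candidates is mapped to a
    case probability by a univariate logistic model (standardized count,
    fitted on the training half) and scored on the test half with the
    Brier score.  Returns the size with the smallest mean Brier (ties go
    to the smallest size) and the per-size mean Brier curve.
    """
    ranked = list(candidate_markers_ranked)
    if not ranked:
        raise ValueError("no candidate markers supplied")
    if size_grid is None:
        size_grid = _default_size_grid(len(ranked))
    sizes = sorted(set(int(s) for s in size_grid))
    if sizes[0] < 1 or sizes[-1] > len(ranked):
        raise ValueError("size_grid must lie within [1, number of candidates]")

    missing = [m for m in ranked if m not in plasma_matrix.values.columns]
    if missing:
        raise KeyError(f"matrix is missing candidates: {missing[:5]}")
    y = np.array([1 if s.is_cancer else 0 for s in plasma_matrix.samples])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("cohort must contain both cases and controls")

    positives = (plasma_matrix.values[ranked].to_numpy() > positivity_threshold)
    cum = positives.cumsum(axis=1)
    counts_by_size = {s: cum[:, s - 1].astype(float) for s in sizes}

    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, random_state=seed & 0x7FFFFFFF
    )
    briers = np.zeros((n_splits, len(sizes)))
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    for i, (train, test) in enumerate(splitter.split(np.zeros_like(y), y)):
        y_tr, y_te = y[train], y[test]
        for j, s in enumerate(sizes):
            x = counts_by_size[s]
            mu, sd = x[train].mean(), x[train].std()
            sd = sd if sd > 0 else 1.0
            clf.fit(((x[train] - mu) / sd).reshape(-1, 1), y_tr)
            probs = clf.predict_proba(((x[test] - mu) / sd).reshape(-1, 1))[:, 1]
            briers[i, j] = np.mean((probs - y_te) ** 2)

    mean_brier = pd.Series(briers.mean(axis=0), index=pd.Index(sizes, name="panel_size"))
    best = int(mean_brier.index[int(np.argmin(mean_brier.to_numpy()))])
    return best, mean_brier


def _default_size_grid(n_candidates: int) -> list[int]:
    grid = [10, 25, 50, 75, 100, 110, 120, 130, 140, 150, 175, 200, 250, 300]
    out = [s for s in grid if s <= n_candidates]
    return out or [n_candidates]
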
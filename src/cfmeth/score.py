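"""The LASSO-logistic methylation score.

Feature selection runs an L1-penalized logistic path over candidate
markers with 10-fold cross-validation and the one-standard-error rule
(the strongest penalty whose mean validation deviance is within one
standard error of the minimum).  The surviving markers are refit without
penalty and the score of a sample is

    score = Coef_0 + sum_i Coef_i * A_i

where A_i is the raw MEPM value of marker i.  Samples with score > 0 are
called patients (waterfall classification); a score of exactly 0 is
called negative, favoring specificity.

Candidates are standardized internally during penalty selection and the
coefficients are transformed back to the raw MEPM scale, so the stored
model applies directly to unstandardized values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .panel import PanelEvaluation
from .types import MethylationMatrix


@dataclass(frozen=True)
class ScoreModel:
    """Selected markers with logistic coefficients defining the score."""

    marker_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.marker_ids) != len(self.coefficients):
            raise ValueError("one coefficient per marker required")
        vals = list(self.coefficients) + [self.intercept]
        if not np.isfinite(vals).all():
            raise ValueError("coefficients must be finite")


def _labels_from(matrix: MethylationMatrix, labels) -> np.ndarray:
    if labels is None:
        return np.array([1 if s.is_cancer else 0 for s in matrix.samples])
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != matrix.shape[0]:
        raise ValueError("labels length must match number of samples")
    return y


def lasso_select_features(
    plasma_matrix: MethylationMatrix,
    labels: Sequence[int] | None,
    candidate_markers: Sequence[str],
    seed: int = 0,
    cv_folds: int = 10,
    n_penalties: int = 40,
    penalty_override: float | None = None,
) -> list[str]:
    """Markers with nonzero L1-logistic coefficients at the 1-SE penalty.

    ``penalty_override`` forces a specific inverse-regularization strength
    C (C -> 0 is full shrinkage and returns an empty selection).
    Deterministic for a fixed seed.
    """
    candidates = list(candidate_markers)
    if not candidates:
        return []
    y = _labels_from(plasma_matrix, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = plasma_matrix.values[candidates].to_numpy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    def _fit(C: float) -> LogisticRegression:
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=5000, random_state=0
        )
        clf.fit(Xs, y)
        return clf

    if penalty_override is not None:
        chosen_c = float(penalty_override)
    else:
        Cs = np.logspace(-2.5, 1.5, n_penalties)
        folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed & 0x7FFFFFFF)
        losses = np.zeros((len(Cs), cv_folds))
        for f, (tr, va) in enumerate(folds.split(Xs, y)):
            for i, C in enumerate(Cs):
                clf = LogisticRegression(
                    l1_ratio=1.0, C=C, solver="liblinear", max_iter=5000, random_state=0
                )
                clf.fit(Xs[tr], y[tr])
                probs = clf.predict_proba(Xs[va])[:, 1]
                losses[i, f] = log_loss(y[va], probs, labels=[0, 1])
        mean = losses.mean(axis=1)
        se = losses.std(axis=1, ddof=1) / np.sqrt(cv_folds)
        best = int(np.argmin(mean))
        within = np.flatnonzero(mean <= mean[best] + se[best])
        chosen_c = float(Cs[within.min()])  # smallest C = strongest penalty

    coefs = _fit(chosen_c).coef_.ravel()
    return [m for m, c in zip(candidates, coefs) if c != 0.0]


def fit_score_model(
    plasma_matrix: MethylationMatrix,
    labels: Sequence[int] | None,
    selected_markers: Sequence[str],
    seed: int = 0,
) -> ScoreModel:
    """Unpenalized logistic refit of the selected markers (raw MEPM scale).

    Perfect separation - routine for strongly hypermethylated panels - is
    handled by a ridge-stabilized fit (small L2 penalty), flagged in
    ``training_meta['ridge_stabilized']``.
    """
    selected = list(selected_markers)
    if not selected:
        raise ValueError("selected_markers must be non-empty")
    y = _labels_from(plasma_matrix, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = plasma_matrix.values[selected].to_numpy()

    meta = {"seed": seed, "n_samples": len(y), "ridge_stabilized": False}
    bse = None
    pvalues = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0, maxiter=200)
        params = res.params
        if not np.isfinite(params).all() or np.abs(params).max() > 1e4:
            raise RuntimeError("unstable maximum-likelihood fit")
        intercept = float(params[0])
        coefs = np.asarray(params[1:], dtype=float)
        bse = tuple(float(v) for v in res.bse)
        pvalues = tuple(float(v) for v in res.pvalues)
    except Exception:
        # ridge-stabilized fallback on (quasi-)separation
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(l1_ratio=0.0, C=1000.0, solver="lbfgs", max_iter=10_000)
        clf.fit((X - mu) / sd, y)
        coefs = clf.coef_.ravel() / sd
        intercept = float(clf.intercept_[0] - np.sum(clf.coef_.ravel() * mu / sd))
        meta["ridge_stabilized"] = True

    model = ScoreModel(
        marker_ids=tuple(selected),
        coefficients=tuple(float(c) for c in coefs),
        intercept=intercept,
        training_meta=meta,
    )
    model.training_meta["bse"] = bse
    model.training_meta["pvalues"] = pvalues
    return model


def methylation_score(sample_values, model: ScoreModel) -> float:
    """score = intercept + sum_i Coef_i * A_i over the model's markers."""
    if isinstance(sample_values, pd.Series):
        mapping = sample_values
    elif isinstance(sample_values, Mapping):
        mapping = pd.Series(sample_values)
    else:
        raise TypeError("sample_values must be a Series or mapping of site -> MEPM")
    missing = [m for m in model.marker_ids if m not in mapping.index]
    if missing:
        raise KeyError(f"sample is missing model markers: {missing[:5]}")
    vals = mapping[list(model.marker_ids)].to_numpy(dtype=float)
    return float(model.intercept + np.dot(vals, model.coefficients))


def score_matrix(matrix: MethylationMatrix, model: ScoreModel) -> pd.Series:
    missing = [m for m in model.marker_ids if m not in matrix.values.columns]
    if missing:
        raise KeyError(f"matrix is missing model markers: {missing[:5]}")
    vals = matrix.values[list(model.marker_ids)].to_numpy()
    scores = model.intercept + vals @ np.asarray(model.coefficients)
    return pd.Series(scores, index=matrix.values.index, name="methylation_score")


def waterfall_classify(scores) -> tuple[np.ndarray, pd.Series]:
    """Sign rule: positive iff score > 0 (0 is negative).

    Returns labels in the input order and the scores sorted descending for
    waterfall display.
    """
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
    labels = np.where(s.to_numpy() > 0, "positive", "negative")
    ordered = s.sort_values(ascending=False)
    return labels, ordered


def stage_flag(panel_evaluation: PanelEvaluation) -> str:
    """Late-stage compatibility flag from the full diagnostic panel.

    A patient can be concluded to be in stage III/IV only when the positive
    count exceeds 8 or the total positive methylation exceeds 150 MEPM;
    anything else is indeterminate (early- and late-stage ranges overlap).
    """
    if panel_evaluation.positive_count > 8 or panel_evaluation.total_methylation > 150:
        return "late_stage_compatible"
    return "indeterminate"


# ---------------------------------------------------------------------------
# model/results facade
# ---------------------------------------------------------------------------


class MethylationScoreModel:
    """LASSO-selected logistic methylation score, statsmodels-style.

    Parameters
    ----------
    matrix
        Plasma cohort (samples x sites).
    labels
        Binary case labels; defaults to ``condition != "normal"``.
    candidate_markers
        Candidate marker ids (e.g. a selected diagnostic panel); defaults
        to every site in the matrix.

    Examples
    --------
    >>> model = MethylationScoreModel(cohort, candidate_markers=panel.marker_ids)
    >>> results = model.fit(seed=1)
    >>> results.params  # doctest: +SKIP
    >>> calls, display = waterfall_classify(results.scores)
    """

    def __init__(
        self,
        matrix: MethylationMatrix,
        labels: Sequence[int] | None = None,
        candidate_markers: Sequence[str] | None = None,
    ) -> None:
        self.matrix = matrix
        self.labels = _labels_from(matrix, labels)
        self.candidate_markers = list(
            candidate_markers if candidate_markers is not None else matrix.site_ids
        )

    @classmethod
    def from_panel(cls, matrix: MethylationMatrix, panel, labels=None) -> "MethylationScoreModel":
        return cls(matrix, labels=labels, candidate_markers=list(panel.marker_ids))

    def fit(self, seed: int = 0, cv_folds: int = 10, penalty_override: float | None = None) -> "MethylationScoreResults":
        selected = lasso_select_features(
            self.matrix, self.labels, self.candidate_markers,
            seed=seed, cv_folds=cv_folds, penalty_override=penalty_override,
        )
        if not selected:
            raise ValueError("LASSO selected no features; weaken the penalty")
        model = fit_score_model(self.matrix, self.labels, selected, seed=seed)
        return MethylationScoreResults(self, model)


class MethylationScoreResults:
    """Fitted methylation score: coefficients, diagnostics and predictions."""

    def __init__(self, model: MethylationScoreModel, score_model: ScoreModel) -> None:
        self.model = model
        self.score_model = score_model

    @property
    def params(self) -> pd.Series:
        idx = ["intercept", *self.score_model.marker_ids]
        return pd.Series([self.score_model.intercept, *self.score_model.coefficients], index=idx)

    @property
    def bse(self) -> pd.Series | None:
        bse = self.score_model.training_meta.get("bse")
        if bse is None:
            return None
        idx = ["intercept", *self.score_model.marker_ids]
        return pd.Series(bse, index=idx)

    @property
    def scores(self) -> pd.Series:
        return score_matrix(self.model.matrix, self.score_model)

    def predict(self, matrix: MethylationMatrix | None = None) -> pd.Series:
        return score_matrix(matrix or self.model.matrix, self.score_model)

    def classify(self, matrix: MethylationMatrix | None = None) -> pd.Series:
        scores = self.predict(matrix)
        labels, _ = waterfall_classify(scores)
        return pd.Series(labels, index=scores.index, name="call")

    def accuracy(self) -> float:
        """In-sample fraction of correct sign-rule calls."""
        calls = self.classify() == "positive"
        return float((calls.to_numpy() == self.model.labels.astype(bool)).mean())

    def summary(self) -> str:
        meta = self.score_model.training_meta
        lines = [
            "Methylation score (LASSO-selected logistic model)",
            "=" * 50,
            f"samples: {meta.get('n_samples')}   markers: {len(self.score_model.marker_ids)}"
            f"   ridge-stabilized: {meta.get('ridge_stabilized')}",
            "-" * 50,
            f"{'term':<24}{'coef':>12}",
        ]
        for term, coef in self.params.items():
            lines.append(f"{term:<24}{coef:>12.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Model file layout: marker_id/coefficient rows plus intercept row."""
        rows = [("__intercept__", self.score_model.intercept)] + list(
            zip(self.score_model.marker_ids, self.score_model.coefficients)
        )
        return pd.DataFrame(rows, columns=["marker_id", "coefficient"])


def score_model_to_tsv(model: ScoreModel, path) -> None:
    rows = [("__intercept__", model.intercept)] + list(zip(model.marker_ids, model.coefficients))
    pd.DataFrame(rows, columns=["marker_id", "coefficient"]).to_csv(path, sep="\t", index=False)


def score_model_from_tsv(path) -> ScoreModel:
    df = pd.read_csv(path, sep="\t")
    inter = df[df["marker_id"] == "__intercept__"]
    if len(inter) != 1:
        raise ValueError("model file must contain exactly one intercept row")
    rest = df[df["marker_id"] != "__intercept__"]
    return ScoreModel(
        marker_ids=tuple(rest["marker_id"]),
        coefficients=tuple(float(c) for c in rest["coefficient"]),
        intercept=float(inter["coefficient"].iloc[0]),
    )
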
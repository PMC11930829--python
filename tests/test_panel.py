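from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cfmeth as cf

from conftest import mk_plasma


def _panel(n=5, thresholds=None, cutoff=None):
    return cf.MarkerPanel(
        "PAC",
        tuple(f"g{j}" for j in range(n)),
        thresholds=tuple(thresholds) if thresholds else (),
        count_cutoff=cutoff,
    )


def _values(vals):
    return pd.Series(vals, index=[f"g{j}" for j in range(len(vals))])


# ----------------------------------------------------- counting primitives


def test_positive_count_examples():
    assert cf.positive_count(_values([0, 0, 2.5, 0.1, 0]), _panel()) == 2
    assert cf.positive_count(_values([0, 0, 0, 0, 0]), _panel()) == 0
    panel = _panel(thresholds=[1, 1, 1, 1, 1])
    assert cf.positive_count(_values([0.5, 2, 1, 3, 0]), panel) == 2  # 1 is not > 1


def test_positive_count_missing_marker():
    with pytest.raises(KeyError):
        cf.positive_count(_values([1.0, 2.0])[:1], _panel(2))


def test_total_methylation_examples():
    panel = _panel(3)
    assert cf.total_methylation(_values([0, 30, 120]), panel) == 150.0
    empty = cf.MarkerPanel("PAC", ())
    assert cf.total_methylation(_values([1.0]), empty) == 0.0
    at_threshold = _panel(1, thresholds=[5.0])
    assert cf.total_methylation(_values([5.0]), at_threshold) == 0.0


@given(
    vals=st.lists(st.floats(0, 100), min_size=4, max_size=4),
    bump=st.floats(0.1, 50),
    idx=st.integers(0, 3),
)
def test_positive_count_monotonicity(vals, bump, idx):
    panel = _panel(4, thresholds=[1.0, 2.0, 0.0, 5.0])
    base = cf.positive_count(_values(vals), panel)
    raised = list(vals)
    raised[idx] += bump
    assert cf.positive_count(_values(raised), panel) >= base
    tighter = cf.MarkerPanel(
        "PAC", panel.marker_ids, thresholds=tuple(t + bump for t in panel.thresholds)
    )
    assert cf.positive_count(_values(vals), tighter) <= base


# ----------------------------------------------------------- cutoff + calls


def _matrix_with_counts(counts, n_sites=12):
    """Sample i is positive at exactly counts[i] sites."""
    values = np.zeros((len(counts), n_sites))
    for i, c in enumerate(counts):
        values[i, :c] = 7.0
    return mk_plasma(values, [0] * len(counts))


def test_calibrate_cutoff_policy_max():
    matrix = _matrix_with_counts([0, 0, 1, 2, 3, 5] + [0] * 6)
    panel = cf.MarkerPanel("PAC", tuple(matrix.site_ids))
    assert cf.calibrate_count_cutoff(matrix, panel, policy="max") == 5


def test_calibrate_cutoff_all_zero_normals():
    matrix = _matrix_with_counts([0] * 12)
    panel = cf.MarkerPanel("PAC", tuple(matrix.site_ids))
    assert cf.calibrate_count_cutoff(matrix, panel, policy="max") == 0


def test_calibrate_cutoff_quantile_matches_brute_force():
    counts = list(range(11))
    matrix = _matrix_with_counts(counts)
    panel = cf.MarkerPanel("PAC", tuple(matrix.site_ids))
    got = cf.calibrate_count_cutoff(matrix, panel, policy="quantile", quantile=0.95)
    counts_arr = np.array(counts)
    brute = next(
        c for c in range(12) if (counts_arr > c).mean() <= 0.05
    )
    assert got == brute


def test_calibrate_cutoff_needs_enough_normals():
    matrix = _matrix_with_counts([0] * 5)
    panel = cf.MarkerPanel("PAC", tuple(matrix.site_ids))
    with pytest.raises(ValueError, match="calibration normals"):
        cf.calibrate_count_cutoff(matrix, panel)


def test_classify_by_count_strict_rule():
    panel = cf.MarkerPanel("PAC", tuple(f"g{j}" for j in range(12)), count_cutoff=5)
    six = _values([9.0] * 6 + [0.0] * 6)
    five = _values([9.0] * 5 + [0.0] * 7)
    assert cf.classify_by_count(six, panel)[0] == "positive"
    assert cf.classify_by_count(five, panel)[0] == "negative"
    assert cf.classify_by_count(_values([0.0] * 12), panel)[0] == "negative"
    with pytest.raises(ValueError, match="cutoff"):
        cf.classify_by_count(six, cf.MarkerPanel("PAC", panel.marker_ids))


def test_evaluation_fraction_is_exact_rational():
    panel = cf.MarkerPanel("PAC", tuple(f"g{j}" for j in range(12)))
    evaluation = cf.evaluate_sample(_values([9.0] * 3 + [0.0] * 9), panel)
    assert evaluation.fraction_positive == Fraction(1, 4)


# ----------------------------------------------------------------- Brier


@pytest.mark.parametrize(
    "p,y,expected",
    [([1, 0], [1, 0], 0.0), ([0.5, 0.5], [1, 0], 0.25), ([0.8, 0.4], [1, 0], 0.1)],
)
def test_brier_examples(p, y, expected):
    assert cf.brier_score(p, y) == pytest.approx(expected)


def test_brier_validation():
    with pytest.raises(ValueError):
        cf.brier_score([0.5], [1, 0])
    with pytest.raises(ValueError):
        cf.brier_score([1.5], [1])


@given(st.integers(1, 30), st.integers(0, 30))
def test_brier_of_prevalence_predictor(n_pos, n_neg):
    n = n_pos + n_neg
    y = [1] * n_pos + [0] * n_neg
    prev = n_pos / n
    assert cf.brier_score([prev] * n, y) == pytest.approx(prev * (1 - prev))


# -------------------------------------------------------------------- AUC


def test_roc_auc_examples():
    assert cf.roc_auc([1, 2, 3, 4], [0, 0, 1, 1])[0] == 1.0
    assert cf.roc_auc([1, 2, 3, 4], [0, 1, 0, 1])[0] == 0.75
    assert cf.roc_auc([3, 3, 3, 3], [0, 1, 0, 1])[0] == 0.5
    with pytest.raises(ValueError):
        cf.roc_auc([1, 2], [1, 1])


def pairwise_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s in pos:
        for t in neg:
            total += (s > t) + 0.5 * (s == t)
    return total / (len(pos) * len(neg))


def test_roc_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = rng.integers(4, 40)
        scores = rng.integers(0, 8, n).astype(float)  # many ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, rng.integers(1, n), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        auc, points = cf.roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels))
        assert {"fpr", "tpr"} <= set(points.columns)


# ------------------------------------------------- Monte Carlo panel sizing


def test_panel_size_single_perfect_candidate():
    rng = np.random.default_rng(3)
    n = 40
    y = np.array([1] * 20 + [0] * 20)
    values = np.zeros((n, 1))
    values[y == 1, 0] = rng.uniform(20, 40, 20)
    matrix = mk_plasma(values, y)
    best, curve = cf.monte_carlo_panel_size(
        matrix, ["g0"], size_grid=[1], n_splits=50, seed=0
    )
    assert best == 1
    assert curve.loc[1] < 0.05


def test_panel_size_all_noise_brier_near_quarter():
    rng = np.random.default_rng(4)
    n = 60
    y = np.array([1] * 30 + [0] * 30)
    values = (rng.random((n, 40)) < 0.3) * rng.lognormal(1, 0.5, (n, 40))
    matrix = mk_plasma(values, y)
    best, curve = cf.monte_carlo_panel_size(
        matrix, [f"g{j}" for j in range(40)], size_grid=[5, 10, 20, 40],
        n_splits=100, seed=0,
    )
    assert ((curve > 0.15) & (curve < 0.40)).all()


def test_panel_size_tie_breaks_to_smallest():
    """A marker that is never positive leaves the count unchanged, so the
    Brier curves for sizes 2 and 3 tie exactly and the smaller size wins."""
    rng = np.random.default_rng(5)
    n = 40
    y = np.array([1] * 20 + [0] * 20)
    values = np.zeros((n, 3))
    values[y == 1, 0] = rng.uniform(10, 30, 20)
    values[y == 1, 1] = rng.uniform(10, 30, 20)
    matrix = mk_plasma(values, y)
    best, curve = cf.monte_carlo_panel_size(
        matrix, ["g0", "g1", "g2"], size_grid=[2, 3], n_splits=30, seed=1
    )
    assert curve.loc[2] == curve.loc[3]
    assert best == 2


def test_panel_size_grid_validation(discovery_cohort):
    matrix, truth = discovery_cohort
    with pytest.raises(ValueError):
        cf.monte_carlo_panel_size(matrix, ["nope"], size_grid=[2], n_splits=2, seed=0)
    with pytest.raises(KeyError):
        cf.monte_carlo_panel_size(matrix, ["nope"], size_grid=[1], n_splits=2, seed=0)
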
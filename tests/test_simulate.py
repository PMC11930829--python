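import numpy as np
import pytest
from scipy import stats

import cfmeth as cf


def small_config(seed=0, **kw):
    base = dict(
        n_sites=400,
        markers_per_cancer={"PAC": 30, "HCC": 10, "CRC": 15, "GC": 20},
    )
    base.update(kw)
    return cf.default_config(seed=seed, **base)


# ------------------------------------------------------------------- catalog


def test_catalog_deterministic_and_unique(config):
    a = cf.simulate_site_catalog(config)
    b = cf.simulate_site_catalog(config)
    assert a == b
    assert len(a) == config.n_sites
    assert len({s.site_id for s in a}) == config.n_sites


def test_planted_marker_bookkeeping(config):
    panels, pan = cf.planted_markers(config)
    assert {c: len(v) for c, v in panels.items()} == dict(config.markers_per_cancer)
    # pan-cancer subset: round(fraction * panel size) per cancer
    expected_pan = sum(
        round(config.shared_marker_fraction * m) for m in config.markers_per_cancer.values()
    )
    assert len(pan) == expected_pan
    catalog = {s.site_id: s for s in cf.simulate_site_catalog(config)}
    for markers in panels.values():
        assert all(catalog[m].motif_distance_bp < 60 for m in markers)


def test_decoy_far_motif_fraction_within_binomial_ci(config):
    catalog = cf.simulate_site_catalog(config)
    panels, _ = cf.planted_markers(config)
    marker_ids = {m for ms in panels.values() for m in ms}
    decoys = [s for s in catalog if s.site_id not in marker_ids]
    far = sum(1 for s in decoys if s.motif_distance_bp >= 60)
    lo, hi = stats.binom.interval(0.99, len(decoys), config.decoy_motif_far_fraction)
    assert lo <= far <= hi


# -------------------------------------------------------------------- tissue


def test_tissue_cohort_pairing_and_cimp(tissue_cohort):
    matrix, truth = tissue_cohort
    assert matrix.shape[0] == 66
    tumors = [s for s in matrix.samples if s.is_cancer]
    assert len(tumors) == 33
    by_id = {s.sample_id: s for s in matrix.samples}
    for t in tumors:
        assert by_id[t.paired_id].paired_id == t.sample_id
        assert by_id[t.paired_id].condition == "normal"
    assert len(truth.cimp_samples()) == 2  # round(2/33 * 33)


def test_tissue_hypermethylation_effect(tissue_cohort, config):
    matrix, truth = tissue_cohort
    planted = sorted(truth.fired_markers("PAC"))
    cancer_ids = [s.sample_id for s in matrix.samples if s.is_cancer]
    adj_ids = matrix.ids_where(condition="normal")
    mean_c = matrix.values.loc[cancer_ids, planted].mean(axis=0)
    mean_a = matrix.values.loc[adj_ids, planted].mean(axis=0)
    fold = (mean_c + 0.5) / (mean_a + 0.5)
    assert (fold > 2).mean() >= 0.95
    assert (mean_c >= 10).mean() >= 0.95  # high-methylation criterion holds at defaults


def test_tissue_reproducible_bit_exact(config):
    a, _ = cf.simulate_tissue_cohort(config, n_pairs=5)
    b, _ = cf.simulate_tissue_cohort(config, n_pairs=5)
    assert a.values.equals(b.values)
    assert a.samples == b.samples


# -------------------------------------------------------------------- plasma


def test_control_background_positivity_matches_config():
    cfg = small_config(seed=3)
    matrix, truth = cf.simulate_plasma_cohort(cfg, n_cases_by_stage={}, n_controls=300)
    rate = (matrix.values.to_numpy() > 0).mean()
    n_draws = matrix.values.size
    lo, hi = stats.binom.interval(0.999, n_draws, cfg.background_pos_freq)
    assert lo <= rate * n_draws <= hi
    # per-site frequencies stay in the binomial envelope for nearly all sites
    per_site = (matrix.values.to_numpy() > 0).sum(axis=0)
    lo_s, hi_s = stats.binom.interval(0.99, 300, cfg.background_pos_freq)
    assert ((per_site >= lo_s) & (per_site <= hi_s)).mean() >= 0.97


def test_null_tumor_signal_indistinguishable_from_controls():
    cfg = small_config(
        seed=4, tumor_signal_by_stage={"I": 0.0, "II": 0.0, "III": 0.0, "IV": 0.0}
    )
    matrix, truth = cf.simulate_plasma_cohort(
        cfg, n_cases_by_stage={"I": 15, "IV": 15}, n_controls=30
    )
    panel = cf.MarkerPanel("PAC", tuple(truth.planted_markers["PAC"]))
    counts = cf.panel_counts(matrix, panel)
    y = np.array([1 if s.is_cancer else 0 for s in matrix.samples])
    ks = stats.ks_2samp(counts[y == 1], counts[y == 0])
    assert ks.pvalue > 0.01
    results, _ = cf.differential_sites(
        matrix,
        [s.sample_id for s in matrix.samples if s.is_cancer],
        matrix.ids_where(condition="normal"),
    )
    assert results == []


def test_stage_multiplier_monotonicity():
    """Mean positive count for stage IV cases >= stage I over replicates."""
    means = {"I": [], "IV": []}
    for seed in range(200):
        cfg = small_config(seed=seed)
        matrix, truth = cf.simulate_plasma_cohort(
            cfg, n_cases_by_stage={"I": 2, "IV": 2}, n_controls=0
        )
        panel = cf.MarkerPanel("PAC", tuple(truth.planted_markers["PAC"]))
        counts = cf.panel_counts(matrix, panel)
        for s in matrix.samples:
            means[s.stage].append(counts[s.sample_id])
    assert np.mean(means["IV"]) >= np.mean(means["I"])


def test_plasma_reproducible_bit_exact(config):
    a, _ = cf.simulate_plasma_cohort(config, n_cases_by_stage={"I": 3}, n_controls=4)
    b, _ = cf.simulate_plasma_cohort(config, n_cases_by_stage={"I": 3}, n_controls=4)
    assert a.values.equals(b.values)


# --------------------------------------------------------------- multicancer


def test_multicancer_label_groups():
    cfg = small_config(seed=6)
    matrix, truth = cf.simulate_multicancer_plasma(
        cfg, n_per_cancer={"PAC": 3, "HCC": 3, "CRC": 3, "GC": 3}, n_controls=3
    )
    conditions = {s.condition for s in matrix.samples}
    assert conditions == {"PAC", "HCC", "CRC", "GC", "normal"}
    assert matrix.shape[0] == 15


def test_private_markers_stay_private_without_sharing():
    cfg = small_config(seed=7, shared_marker_fraction=0.0)
    matrix, truth = cf.simulate_multicancer_plasma(
        cfg, n_per_cancer={"PAC": 0, "HCC": 20}, n_controls=0
    )
    pac_private = sorted(set(truth.planted_markers["PAC"]) - set(truth.pan_cancer_markers))
    rate = (matrix.values[pac_private].to_numpy() > 0).mean()
    assert rate < 3 * cfg.background_pos_freq  # background-level only


def test_shared_markers_fire_across_cancers():
    cfg = small_config(seed=8, shared_marker_fraction=0.5, markers_per_cancer={"PAC": 40, "HCC": 20})
    matrix, truth = cf.simulate_multicancer_plasma(
        cfg, n_per_cancer={"PAC": 0, "HCC": 20}, n_controls=0
    )
    pac_panel = list(truth.planted_markers["PAC"])
    pan = set(truth.pan_cancer_markers)
    pac_pan = [m for m in pac_panel if m in pan]
    pac_private = [m for m in pac_panel if m not in pan]
    assert len(pac_pan) == 20  # half of the PAC panel is pan-cancer
    hit_pan = (matrix.values[pac_pan].to_numpy() > 0).mean()
    hit_private = (matrix.values[pac_private].to_numpy() > 0).mean()
    assert hit_pan > 5 * hit_private  # other-cancer signal concentrates on the shared part


# -------------------------------------------------------------------- config


def test_config_validation():
    with pytest.raises(ValueError):
        cf.default_config(background_pos_freq=0.05)
    with pytest.raises(ValueError):
        cf.default_config(cimp_boost=1.0)
    with pytest.raises(ValueError):
        cf.default_config(n_sites=100)  # planted markers exceed sites
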
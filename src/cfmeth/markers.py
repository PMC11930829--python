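"""Hypermethylated CpG-island marker selection.

Tumor-vs-normal panels require, per site, the conjunction of four criteria:

1. significant hypermethylation in cancer vs adjacent tissue
   (two-tailed MWW p < 0.01, cancer mean above adjacent mean);
2. distance to the nearest CGCGCGG motif strictly below 60 bp;
3. mean cancer-tissue methylation of at least 10 MEPM;
4. background positivity frequency in normal plasma strictly below 5%.

Cross-cancer (pairwise discriminative) panels replace (1) with a
between-tumor comparison at fold change > 2, relax (3) to 5 MEPM, and keep
the normal-plasma background criterion.  All inequality boundaries follow
the strict/inclusive wording above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffmeth import _mww_pvalues_matrix
from .panel import MarkerPanel
from .types import CpGSite, MethylationMatrix


@dataclass(frozen=True)
class SelectionCriteria:
    p_max: float = 0.01
    motif_max_bp: int = 60
    min_mepm: float = 10.0
    max_normal_freq: float = 0.05
    fc_min: float = 2.0  # used by pairwise selection only
    positivity_threshold: float = 0.0

    def __post_init__(self) -> None:
        if min(self.p_max, self.motif_max_bp, self.min_mepm, self.fc_min) <= 0:
            raise ValueError("criteria thresholds must be positive")
        if not 0 < self.max_normal_freq <= 1:
            raise ValueError("max_normal_freq must be in (0, 1]")

    @classmethod
    def tumor_vs_normal(cls) -> "SelectionCriteria":
        return cls()

    @classmethod
    def cross_cancer(cls) -> "SelectionCriteria":
        return cls(min_mepm=5.0)


def background_frequency(
    plasma_matrix: MethylationMatrix,
    site_id: str,
    positivity_threshold: float = 0.0,
) -> float:
    """Fraction of normal plasma samples positive (value > threshold) at a site."""
    freqs = background_frequencies(plasma_matrix, [site_id], positivity_threshold)
    return float(freqs[site_id])


def background_frequencies(
    plasma_matrix: MethylationMatrix,
    site_ids=None,
    positivity_threshold: float = 0.0,
) -> pd.Series:
    """Per-site positivity frequency across the normal plasma samples."""
    normals = plasma_matrix.ids_where(condition="normal")
    if not normals:
        raise ValueError("no normal plasma samples in matrix")
    sub = plasma_matrix.values.loc[normals]
    if site_ids is not None:
        missing = [s for s in site_ids if s not in sub.columns]
        if missing:
            raise KeyError(f"sites not in matrix: {missing[:5]}")
        sub = sub[list(site_ids)]
    return (sub > positivity_threshold).mean(axis=0)


def _catalog_motif(catalog: list[CpGSite], site_ids) -> np.ndarray:
    by_id = {s.site_id: s for s in catalog}
    missing = [s for s in site_ids if s not in by_id]
    if missing:
        raise KeyError(f"matrix sites missing from catalog: {missing[:5]}")
    return np.array([by_id[s].motif_distance_bp for s in site_ids])


def select_cancer_markers(
    tissue_matrix: MethylationMatrix,
    plasma_matrix: MethylationMatrix,
    catalog: list[CpGSite] | None = None,
    criteria: SelectionCriteria | None = None,
    cancer: str | None = None,
) -> MarkerPanel:
    """Apply the four tumor-vs-normal criteria; returns an unsized panel.

    The tissue matrix must contain the cancer group and the adjacent
    ("normal"-condition) group; pairing is kept only as metadata, and the
    test is the unpaired MWW.  Markers are ordered by ascending p-value.
    """
    criteria = criteria or SelectionCriteria.tumor_vs_normal()
    if catalog is None:
        if tissue_matrix.sites is None:
            raise ValueError("no site catalog provided")
        catalog = tissue_matrix.sites
    cancer_ids = [s.sample_id for s in tissue_matrix.samples if s.is_cancer]
    adjacent_ids = tissue_matrix.ids_where(condition="normal")
    if not cancer_ids or not adjacent_ids:
        raise ValueError("tissue matrix must contain cancer and adjacent samples")
    if cancer is None:
        cancer = tissue_matrix.meta_for(cancer_ids[0]).condition

    site_ids = tissue_matrix.site_ids
    vc = tissue_matrix.values.loc[cancer_ids].to_numpy()
    va = tissue_matrix.values.loc[adjacent_ids].to_numpy()
    p = _mww_pvalues_matrix(vc, va)
    mean_c = vc.mean(axis=0)
    mean_a = va.mean(axis=0)
    motif = _catalog_motif(list(catalog), site_ids)
    bg = background_frequencies(
        plasma_matrix, site_ids, criteria.positivity_threshold
    ).to_numpy()

    passing = (
        (p < criteria.p_max)
        & (mean_c > mean_a)
        & (motif < criteria.motif_max_bp)
        & (mean_c >= criteria.min_mepm)
        & (bg < criteria.max_normal_freq)
    )
    idx = np.flatnonzero(passing)
    idx = idx[np.argsort(p[idx], kind="stable")]
    return MarkerPanel(
        cancer=cancer,
        marker_ids=tuple(site_ids[j] for j in idx),
        selection_pvalues=tuple(float(p[j]) for j in idx),
    )


def rank_candidates_by_selection_p(
    tissue_matrix: MethylationMatrix,
) -> tuple[list[str], np.ndarray]:
    """All sites ranked by ascending cancer-vs-adjacent MWW p-value.

    Used to grow candidate panels for Monte-Carlo size selection; the
    four-criteria panel is a prefix-like subset of this ordering.
    """
    cancer_ids = [s.sample_id for s in tissue_matrix.samples if s.is_cancer]
    adjacent_ids = tissue_matrix.ids_where(condition="normal")
    vc = tissue_matrix.values.loc[cancer_ids].to_numpy()
    va = tissue_matrix.values.loc[adjacent_ids].to_numpy()
    p = _mww_pvalues_matrix(vc, va)
    hyper = vc.mean(axis=0) > va.mean(axis=0)
    # hypermethylated sites first (by p), then the rest
    key = np.where(hyper, p, 1.0 + p)
    order = np.argsort(key, kind="stable")
    site_ids = tissue_matrix.site_ids
    return [site_ids[j] for j in order], p[order]


def select_pairwise_discriminative_markers(
    tumor_a_tissue: MethylationMatrix,
    tumor_b_tissue: MethylationMatrix,
    normal_plasma: MethylationMatrix,
    criteria: SelectionCriteria | None = None,
    cancers: tuple[str, str] | None = None,
) -> tuple[MarkerPanel, MarkerPanel]:
    """Markers separating two tumor types in tissue, quiet in normal plasma.

    A-specific sites satisfy p < p_max (MWW A vs B), fold change (A/B) >
    fc_min, mean MEPM in A >= min_mepm and normal-plasma positivity
    frequency < max_normal_freq; B-specific sites are symmetric.  The two
    panels are disjoint by construction of the fold-change criterion.
    """
    criteria = criteria or SelectionCriteria.cross_cancer()
    a_ids = [s.sample_id for s in tumor_a_tissue.samples if s.is_cancer]
    b_ids = [s.sample_id for s in tumor_b_tissue.samples if s.is_cancer]
    if not a_ids or not b_ids:
        raise ValueError("both tumor groups must be non-empty")
    overlap = set(a_ids) & set(b_ids)
    if overlap:
        raise ValueError(f"tumor cohorts share sample ids: {sorted(overlap)[:5]}")
    if list(tumor_a_tissue.site_ids) != list(tumor_b_tissue.site_ids):
        raise ValueError("tumor matrices cover different site sets")
    if cancers is None:
        cancers = (
            tumor_a_tissue.meta_for(a_ids[0]).condition,
            tumor_b_tissue.meta_for(b_ids[0]).condition,
        )

    site_ids = tumor_a_tissue.site_ids
    va = tumor_a_tissue.values.loc[a_ids].to_numpy()
    vb = tumor_b_tissue.values.loc[b_ids].to_numpy()
    p = _mww_pvalues_matrix(va, vb)
    mean_a = va.mean(axis=0)
    mean_b = vb.mean(axis=0)
    fc = (mean_a + 0.5) / (mean_b + 0.5)
    bg = background_frequencies(
        normal_plasma, site_ids, criteria.positivity_threshold
    ).to_numpy()

    quiet = bg < criteria.max_normal_freq
    sig = p < criteria.p_max
    a_mask = sig & (fc > criteria.fc_min) & (mean_a >= criteria.min_mepm) & quiet
    b_mask = sig & (fc < 1.0 / criteria.fc_min) & (mean_b >= criteria.min_mepm) & quiet

    def _panel(mask: np.ndarray, cancer: str) -> MarkerPanel:
        idx = np.flatnonzero(mask)
        idx = idx[np.argsort(p[idx], kind="stable")]
        return MarkerPanel(
            cancer=cancer,
            marker_ids=tuple(site_ids[j] for j in idx),
            selection_pvalues=tuple(float(p[j]) for j in idx),
        )

    return _panel(a_mask, cancers[0]), _panel(b_mask, cancers[1])
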
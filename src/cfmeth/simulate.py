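"""Ground-truthed synthetic MCTA-Seq-like cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, on the MEPM scale:

* a CpG-site catalog in which planted marker sites sit < 60 bp from a
  CGCGCGG amplification anchor while a configurable fraction of decoy sites
  violate that rule;
* paired cancer/adjacent tissue cohorts in which planted markers are
  hypermethylated in tumors by a configurable fold change, with a small
  CIMP subgroup receiving a global boost;
* plasma cohorts in which normal samples show sparse low-level background
  positivity (Bernoulli occupancy x log-normal magnitude) and cancer
  samples add a tumor signal channel scaled by stage;
* multi-cancer plasma cohorts for PAC/HCC/CRC/GC in which a fraction of
  each cancer's panel is "pan-cancer" (fires in every tumor type) and the
  remainder is type-private.

Everything is bit-reproducible for a fixed seed and configuration.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .types import CANCER_TYPES, CpGSite, MethylationMatrix, SampleMeta

DEFAULT_SEED = 42

_DEFAULT_PANEL_SIZES = {"PAC": 120, "HCC": 38, "CRC": 80, "GC": 153}
_DEFAULT_STAGE_MULTIPLIERS = {"I": 1.0, "II": 1.0, "III": 1.5, "IV": 3.0}
_DEFAULT_CASES_BY_STAGE = {"I": 7, "II": 8, "III": 8, "IV": 7}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the operating regime of the assay this package
    models: 120 PAC markers among 3000 assayed sites, per-marker background
    positivity of 1% in normal plasma with low magnitudes (median positive
    count ~1-2 of 120 in controls), tumor plasma signal firing ~30% of the
    panel at stage I and scaling up with stage, and an 8-fold tissue
    hypermethylation effect at planted markers.
    """

    n_sites: int = 3000
    markers_per_cancer: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PANEL_SIZES)
    )
    shared_marker_fraction: float = 0.25
    background_pos_freq: float = 0.01
    background_magnitude_mean: float = 5.0
    tumor_signal_by_stage: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STAGE_MULTIPLIERS)
    )
    tissue_hyper_effect: float = 8.0
    dispersion: float = 0.8
    cimp_fraction: float = 2 / 33
    cimp_boost: float = 3.0
    seed: int = DEFAULT_SEED
    # secondary knobs (documented in docs/methods.md)
    tumor_occupancy: float = 0.30
    tumor_magnitude_mean: float = 30.0
    tissue_background_occupancy: float = 0.40
    tissue_background_magnitude: float = 5.0
    tissue_tumor_occupancy: float = 0.90
    decoy_motif_far_fraction: float = 0.5
    max_occupancy: float = 0.95

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if sum(self.markers_per_cancer.values()) > self.n_sites:
            raise ValueError("total planted markers exceed n_sites")
        if any(m <= 0 for m in self.markers_per_cancer.values()):
            raise ValueError("markers_per_cancer values must be positive")
        if not 0.0 <= self.shared_marker_fraction <= 1.0:
            raise ValueError("shared_marker_fraction must be in [0, 1]")
        if not 0.0 <= self.background_pos_freq < 0.05:
            raise ValueError("background_pos_freq must be in [0, 0.05)")
        if self.tissue_hyper_effect <= 2.0:
            raise ValueError("tissue_hyper_effect must be > 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.cimp_fraction <= 1.0:
            raise ValueError("cimp_fraction must be in [0, 1]")
        if self.cimp_boost <= 1.0:
            raise ValueError("cimp_boost must be > 1")
        if any(m < 0 for m in self.tumor_signal_by_stage.values()):
            raise ValueError("stage multipliers must be >= 0")
        if not 0.0 < self.tumor_occupancy <= 1.0:
            raise ValueError("tumor_occupancy must be in (0, 1]")
        if not 0.0 <= self.decoy_motif_far_fraction <= 1.0:
            raise ValueError("decoy_motif_far_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: marker panels and per-sample labels."""

    planted_markers: dict[str, tuple[str, ...]]
    pan_cancer_markers: tuple[str, ...]
    sample_labels: dict[str, tuple[str, str, bool]]  # condition, stage, cimp flag

    def cimp_samples(self) -> list[str]:
        return [s for s, (_, _, flag) in self.sample_labels.items() if flag]

    def fired_markers(self, cancer: str) -> set[str]:
        """All sites that carry tumor signal in the given cancer type.

        A tumor emits signal at its own planted panel plus every
        pan-cancer marker (including those belonging to other panels).
        """
        return set(self.planted_markers[cancer]) | set(self.pan_cancer_markers)


def default_config(seed: int = DEFAULT_SEED, **overrides) -> SimulationConfig:
    return replace(SimulationConfig(seed=seed), **overrides) if overrides else SimulationConfig(seed=seed)


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    entries = [int(config.seed) & 0x7FFFFFFF]
    for item in stream:
        if isinstance(item, str):
            entries.append(zlib.crc32(item.encode()))
        else:
            entries.append(int(item))
    return np.random.default_rng(entries)


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean."""
    mu = np.log(mean) - sigma * sigma / 2.0
    return rng.lognormal(mu, sigma, size)


# ---------------------------------------------------------------------------
# catalog and planted panels
# ---------------------------------------------------------------------------


def _plant(config: SimulationConfig):
    """Deterministically assign marker sites to panels.

    Returns (marker_indices_by_cancer, pan_marker_indices).  Each cancer's
    panel has ``round(shared_marker_fraction * size)`` pan-cancer sites
    (which fire in every tumor type) listed first, then type-private sites.
    """
    rng = _rng(config, "catalog")
    cancers = [c for c in CANCER_TYPES if c in config.markers_per_cancer]
    total = sum(config.markers_per_cancer[c] for c in cancers)
    chosen = rng.choice(config.n_sites, size=total, replace=False)
    panels: dict[str, np.ndarray] = {}
    pan: list[int] = []
    offset = 0
    for cancer in cancers:
        m = config.markers_per_cancer[cancer]
        panel = np.sort(chosen[offset : offset + m])
        offset += m
        n_pan = int(round(config.shared_marker_fraction * m))
        panels[cancer] = panel
        pan.extend(panel[:n_pan].tolist())
    return panels, np.array(sorted(pan), dtype=int)


def simulate_site_catalog(config: SimulationConfig) -> list[CpGSite]:
    """Generate the CpG-site catalog with motif-distance annotations.

    Planted marker sites receive a motif distance < 60 bp; decoy sites fall
    beyond 60 bp with probability ``decoy_motif_far_fraction``.
    """
    rng = _rng(config, "catalog-annotation")
    panels, _ = _plant(config)
    marker_idx = np.zeros(config.n_sites, dtype=bool)
    for panel in panels.values():
        marker_idx[panel] = True

    motif = rng.integers(0, 60, size=config.n_sites)
    far = (~marker_idx) & (rng.random(config.n_sites) < config.decoy_motif_far_fraction)
    motif[far] = rng.integers(60, 500, size=int(far.sum()))

    chroms = [f"chr{(i % 22) + 1}" for i in range(config.n_sites)]
    sites = []
    for i in range(config.n_sites):
        gene = f"GENE{i:04d}"
        start = 10_000 + 5_000 * i
        sites.append(
            CpGSite(
                site_id=f"{gene}-{start}_1_1",
                chrom=chroms[i],
                start=start,
                end=start + 150,
                motif_distance_bp=int(motif[i]),
                gene_label=gene,
            )
        )
    return sites


def planted_markers(config: SimulationConfig) -> tuple[dict[str, tuple[str, ...]], tuple[str, ...]]:
    """Site ids of each cancer's planted panel and of the pan-cancer subset."""
    catalog = simulate_site_catalog(config)
    ids = np.array([s.site_id for s in catalog])
    panels, pan = _plant(config)
    by_cancer = {c: tuple(ids[idx]) for c, idx in panels.items()}
    return by_cancer, tuple(ids[pan])


def _fire_indices(config: SimulationConfig, cancer: str) -> np.ndarray:
    """Catalog indices at which a tumor of type ``cancer`` emits signal."""
    panels, pan = _plant(config)
    return np.union1d(panels[cancer], pan)


# ---------------------------------------------------------------------------
# value channels
# ---------------------------------------------------------------------------


def _background(rng, n, m, occ, mag_mean, sigma) -> np.ndarray:
    occupied = rng.random((n, m)) < occ
    values = np.zeros((n, m))
    if occupied.any():
        values[occupied] = _lognormal(rng, mag_mean, sigma, int(occupied.sum()))
    return values


def _add_tumor_channel(rng, values, row, cols, occ, mag_mean, sigma) -> None:
    if mag_mean <= 0 or occ <= 0 or len(cols) == 0:
        return
    occupied = rng.random(len(cols)) < occ
    k = int(occupied.sum())
    if k:
        values[row, cols[occupied]] += _lognormal(rng, mag_mean, sigma, k)


# ---------------------------------------------------------------------------
# cohort generators
# ---------------------------------------------------------------------------


def simulate_tissue_cohort(
    config: SimulationConfig,
    n_pairs: int = 33,
    cancer: str = "PAC",
    cohort_label: str = "tissue",
) -> tuple[MethylationMatrix, GroundTruth]:
    """Paired cancer / adjacent-noncancerous tissue samples.

    At planted markers the expected cancer-tissue MEPM exceeds the adjacent
    mean by ``tissue_hyper_effect``-fold; a ``cimp_fraction`` of tumors get
    every planted-marker signal magnified by ``cimp_boost``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    catalog = simulate_site_catalog(config)
    site_ids = [s.site_id for s in catalog]
    fire = _fire_indices(config, cancer)
    rng = _rng(config, "tissue", cohort_label, cancer, n_pairs)

    n = 2 * n_pairs
    base_mean = config.tissue_background_occupancy * config.tissue_background_magnitude
    tumor_mag = (config.tissue_hyper_effect - 1.0) * base_mean / config.tissue_tumor_occupancy
    values = _background(
        rng,
        n,
        config.n_sites,
        config.tissue_background_occupancy,
        config.tissue_background_magnitude,
        config.dispersion,
    )

    n_cimp = int(round(config.cimp_fraction * n_pairs))
    cimp_rows = set(rng.choice(n_pairs, size=n_cimp, replace=False).tolist()) if n_cimp else set()

    stages = ["I", "II", "III", "IV"]
    metas: list[SampleMeta] = []
    labels: dict[str, tuple[str, str, bool]] = {}
    for i in range(n_pairs):
        boost = config.cimp_boost if i in cimp_rows else 1.0
        _add_tumor_channel(
            rng, values, i, fire, config.tissue_tumor_occupancy, tumor_mag * boost, config.dispersion
        )
    for i in range(n_pairs):
        t_id = f"{cancer}_tumor_{i:03d}"
        a_id = f"{cancer}_adj_{i:03d}"
        stage = stages[i % 4]
        cimp = i in cimp_rows
        metas.append(
            SampleMeta(t_id, "tissue", cancer, stage, paired_id=a_id,
                       total_molecules=int(rng.integers(20_000, 200_000)))
        )
        labels[t_id] = (cancer, stage, cimp)
    for i in range(n_pairs):
        a_id = f"{cancer}_adj_{i:03d}"
        metas.append(
            SampleMeta(a_id, "tissue", "normal", "NA", paired_id=f"{cancer}_tumor_{i:03d}",
                       total_molecules=int(rng.integers(20_000, 200_000)))
        )
        labels[a_id] = ("normal", "NA", False)

    matrix = MethylationMatrix(values, metas, sites=catalog, site_ids=site_ids)
    panels, pan = planted_markers(config)
    return matrix, GroundTruth(dict(panels), pan, labels)


def simulate_plasma_cohort(
    config: SimulationConfig,
    n_cases_by_stage: Mapping[str, int] | None = None,
    n_controls: int = 31,
    cancer: str = "PAC",
    cohort_label: str = "discovery",
) -> tuple[MethylationMatrix, GroundTruth]:
    """Plasma cohort: stage-scaled tumor signal plus sparse background.

    ``n_cases_by_stage=None`` uses the default 30-case stage mix; pass an
    empty mapping for a pure normal-plasma set (e.g. a calibration cohort).
    """
    if n_cases_by_stage is None:
        n_cases_by_stage = dict(_DEFAULT_CASES_BY_STAGE)
    if n_controls < 0 or any(v < 0 for v in n_cases_by_stage.values()):
        raise ValueError("sample counts must be >= 0")
    catalog = simulate_site_catalog(config)
    site_ids = [s.site_id for s in catalog]
    fire = _fire_indices(config, cancer)
    rng = _rng(config, "plasma", cohort_label, cancer, n_controls,
               *[f"{k}:{v}" for k, v in sorted(n_cases_by_stage.items())])

    case_stages = [s for s in ("I", "II", "III", "IV") for _ in range(n_cases_by_stage.get(s, 0))]
    n_cases = len(case_stages)
    n = n_cases + n_controls
    values = _background(
        rng, n, config.n_sites, config.background_pos_freq,
        config.background_magnitude_mean, config.dispersion,
    )

    metas: list[SampleMeta] = []
    labels: dict[str, tuple[str, str, bool]] = {}
    for i, stage in enumerate(case_stages):
        mult = float(config.tumor_signal_by_stage.get(stage, 1.0))
        occ = min(config.max_occupancy, config.tumor_occupancy * mult)
        _add_tumor_channel(
            rng, values, i, fire, occ if mult > 0 else 0.0,
            config.tumor_magnitude_mean * mult, config.dispersion,
        )
        sid = f"{cohort_label}_{cancer}_case_{i:03d}"
        metas.append(SampleMeta(sid, "plasma", cancer, stage,
                                total_molecules=int(rng.integers(20_000, 200_000))))
        labels[sid] = (cancer, stage, False)
    for i in range(n_controls):
        sid = f"{cohort_label}_ctrl_{i:03d}"
        metas.append(SampleMeta(sid, "plasma", "normal", "NA",
                                total_molecules=int(rng.integers(20_000, 200_000))))
        labels[sid] = ("normal", "NA", False)

    matrix = MethylationMatrix(values, metas, sites=catalog, site_ids=site_ids)
    panels, pan = planted_markers(config)
    return matrix, GroundTruth(dict(panels), pan, labels)


def simulate_multicancer_plasma(
    config: SimulationConfig,
    n_per_cancer: Mapping[str, int] | None = None,
    n_controls: int = 31,
    cohort_label: str = "multicancer",
) -> tuple[MethylationMatrix, GroundTruth]:
    """Plasma cohort mixing PAC/HCC/CRC/GC cases and normal controls.

    Each case fires at its own cancer's planted panel plus every pan-cancer
    marker; stages cycle I-IV within each cancer type.
    """
    if n_per_cancer is None:
        n_per_cancer = {c: 25 for c in CANCER_TYPES}
    unknown = [c for c in n_per_cancer if c not in config.markers_per_cancer]
    if unknown:
        raise ValueError(f"no planted panel for cancers: {unknown}")
    catalog = simulate_site_catalog(config)
    site_ids = [s.site_id for s in catalog]
    rng = _rng(config, "multicancer", cohort_label, n_controls,
               *[f"{k}:{v}" for k, v in sorted(n_per_cancer.items())])

    stages = ["I", "II", "III", "IV"]
    plan: list[tuple[str, str]] = []
    for cancer in sorted(n_per_cancer):
        for i in range(n_per_cancer[cancer]):
            plan.append((cancer, stages[i % 4]))
    n = len(plan) + n_controls
    values = _background(
        rng, n, config.n_sites, config.background_pos_freq,
        config.background_magnitude_mean, config.dispersion,
    )

    metas: list[SampleMeta] = []
    labels: dict[str, tuple[str, str, bool]] = {}
    for i, (cancer, stage) in enumerate(plan):
        mult = float(config.tumor_signal_by_stage.get(stage, 1.0))
        occ = min(config.max_occupancy, config.tumor_occupancy * mult)
        fire = _fire_indices(config, cancer)
        _add_tumor_channel(
            rng, values, i, fire, occ if mult > 0 else 0.0,
            config.tumor_magnitude_mean * mult, config.dispersion,
        )
        sid = f"{cohort_label}_{cancer}_case_{i:03d}"
        metas.append(SampleMeta(sid, "plasma", cancer, stage,
                                total_molecules=int(rng.integers(20_000, 200_000))))
        labels[sid] = (cancer, stage, False)
    for i in range(n_controls):
        sid = f"{cohort_label}_ctrl_{i:03d}"
        metas.append(SampleMeta(sid, "plasma", "normal", "NA",
                                total_molecules=int(rng.integers(20_000, 200_000))))
        labels[sid] = ("normal", "NA", False)

    matrix = MethylationMatrix(values, metas, sites=catalog, site_ids=site_ids)
    panels, pan = planted_markers(config)
    return matrix, GroundTruth(dict(panels), pan, labels)
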
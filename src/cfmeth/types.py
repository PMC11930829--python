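"""Core data containers for MCTA-Seq-style cfDNA methylation analysis.

The central object is :class:`MethylationMatrix`, a samples x CpG-sites grid
of MEPM values (methylated alleles per million mapped molecules) together
with per-sample metadata and, optionally, the CpG-site catalog.  All
downstream statistics (differential methylation, marker selection, the
positivity-counting classifier, the methylation score) operate on this
container.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CANCER_TYPES = ("PAC", "HCC", "CRC", "GC")
CONDITIONS = CANCER_TYPES + ("normal",)
SPECIMENS = ("tissue", "plasma")
STAGES = ("I", "II", "III", "IV", "NA")


class ParseError(ValueError):
    """A file violated the expected on-disk format."""


class EmptyCohortError(ValueError):
    """An operation left no samples to work with."""


@dataclass(frozen=True)
class CpGSite:
    """One CpG-island site assayed by MCTA-Seq.

    Coordinates are 0-based, half-open (BED convention).
    ``motif_distance_bp`` is the distance in bp to the nearest CGCGCGG
    amplification anchor; marker selection requires it to be < 60 bp.
    """

    site_id: str
    chrom: str
    start: int
    end: int
    motif_distance_bp: int
    gene_label: str = ""

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"site {self.site_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.motif_distance_bp < 0:
            raise ValueError(
                f"site {self.site_id!r}: motif_distance_bp must be >= 0"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one specimen (tissue or plasma sample)."""

    sample_id: str
    specimen: str
    condition: str
    stage: str = "NA"
    paired_id: str | None = None
    total_molecules: int = 0

    def __post_init__(self) -> None:
        if self.specimen not in SPECIMENS:
            raise ValueError(
                f"sample {self.sample_id!r}: specimen {self.specimen!r} not in {SPECIMENS}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id!r}: condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.stage not in STAGES:
            raise ValueError(
                f"sample {self.sample_id!r}: stage {self.stage!r} not in {STAGES}"
            )
        if self.condition == "normal" and self.stage != "NA":
            raise ValueError(
                f"sample {self.sample_id!r}: stage must be NA for normal samples"
            )
        if self.total_molecules < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: total_molecules must be >= 0"
            )

    @property
    def is_cancer(self) -> bool:
        return self.condition != "normal"


class MethylationMatrix:
    """Samples x CpG-sites matrix of non-negative MEPM values.

    Parameters
    ----------
    values
        DataFrame with sample ids as index and site ids as columns.  A plain
        array is accepted when ``samples``/``site_ids`` fully define the axes.
    samples
        One :class:`SampleMeta` per row, in row order.
    sites
        Optional site catalog (one :class:`CpGSite` per column, in column
        order).  Most operations only need site ids; the catalog is required
        for motif-distance criteria.

    Absent measurements are true zeros in this assay (no fully methylated
    molecule observed), so missing values are rejected.
    """

    def __init__(
        self,
        values: pd.DataFrame | np.ndarray,
        samples: Sequence[SampleMeta],
        sites: Sequence[CpGSite] | None = None,
        site_ids: Sequence[str] | None = None,
    ) -> None:
        samples = list(samples)
        sample_ids = [s.sample_id for s in samples]
        if not isinstance(values, pd.DataFrame):
            if site_ids is None and sites is None:
                raise ValueError("array input requires site_ids or sites")
            cols = list(site_ids) if site_ids is not None else [s.site_id for s in sites]
            values = pd.DataFrame(np.asarray(values, dtype=float), index=sample_ids, columns=cols)
        values = values.astype(float)

        if len(samples) != values.shape[0]:
            raise ValueError(
                f"{len(samples)} sample metadata rows for {values.shape[0]} matrix rows"
            )
        if list(values.index) != sample_ids:
            raise ValueError("matrix row index does not match sample metadata order")
        if len(set(sample_ids)) != len(sample_ids):
            dup = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate site_id {dup!r}")
        arr = values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at sample {values.index[bad[0]]!r}, site {values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative MEPM at sample {values.index[bad[0]]!r}, site {values.columns[bad[1]]!r}"
            )
        if sites is not None:
            sites = list(sites)
            if [s.site_id for s in sites] != list(values.columns):
                raise ValueError("site catalog does not match matrix columns")
        known = set(sample_ids)
        for s in samples:
            if s.paired_id is not None and s.paired_id not in known:
                raise ValueError(
                    f"sample {s.sample_id!r}: paired_id {s.paired_id!r} not in cohort"
                )

        self.values = values
        self.samples = samples
        self.sites = sites

    # -- basic introspection ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def meta(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "specimen": [s.specimen for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "stage": [s.stage for s in self.samples],
                "paired_id": [s.paired_id or "" for s in self.samples],
                "total_molecules": [s.total_molecules for s in self.samples],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def meta_for(self, sample_id: str) -> SampleMeta:
        return self.samples[self.values.index.get_loc(sample_id)]

    def ids_where(self, condition: str | None = None, specimen: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if condition is not None and s.condition != condition:
                continue
            if specimen is not None and s.specimen != specimen:
                continue
            out.append(s.sample_id)
        return out

    # -- subsetting ----------------------------------------------------------

    def select_samples(self, sample_ids: Iterable[str]) -> "MethylationMatrix":
        """Subset to the given samples (in the given order).

        A ``paired_id`` whose partner is not retained is cleared, keeping the
        pairing invariant intact within the subset.
        """
        ids = list(sample_ids)
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        kept = set(ids)
        by_id = {s.sample_id: s for s in self.samples}
        metas = []
        for i in ids:
            m = by_id[i]
            if m.paired_id is not None and m.paired_id not in kept:
                m = replace(m, paired_id=None)
            metas.append(m)
        # columns are untouched, so the site catalog carries over as-is
        return MethylationMatrix(self.values.loc[ids], metas, sites=self.sites)

    def select_sites(self, site_ids: Iterable[str]) -> "MethylationMatrix":
        ids = list(site_ids)
        missing = [i for i in ids if i not in self.values.columns]
        if missing:
            raise KeyError(f"unknown site ids: {missing[:5]}")
        sites = None
        if self.sites is not None:
            by_id = {s.site_id: s for s in self.sites}
            sites = [by_id[i] for i in ids]
        return MethylationMatrix(self.values[ids], list(self.samples), sites=sites)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_t = sum(1 for s in self.samples if s.is_cancer)
        return (
            f"<MethylationMatrix {self.shape[0]} samples x {self.shape[1]} sites"
            f" ({n_t} cancer / {self.shape[0] - n_t} normal)>"
        )


@dataclass(frozen=True)
class CohortSplit:
    """A discovery/validation partition of a plasma cohort."""

    discovery_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.discovery_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"discovery and validation overlap: {sorted(overlap)[:5]}")
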
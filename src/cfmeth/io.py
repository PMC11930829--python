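"""Readers/writers, QC filtering, MEPM computation and cohort partitioning.

On-disk formats (all TSV, UTF-8):

* MEPM matrix: first column ``sample_id``, header row of site ids, float
  values formatted to 12 significant digits.
* sample sheet: columns ``sample_id specimen condition stage paired_id
  total_molecules``; empty ``paired_id`` means unpaired.
* site catalog: header-less 6-column BED-like file ``chrom start end
  site_id motif_distance_bp gene_label`` (0-based half-open coordinates).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    CohortSplit,
    CpGSite,
    EmptyCohortError,
    MethylationMatrix,
    ParseError,
    SampleMeta,
)

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "specimen",
    "condition",
    "stage",
    "paired_id",
    "total_molecules",
]

_CATALOG_COLUMNS = ["chrom", "start", "end", "site_id", "motif_distance_bp", "gene_label"]


def compute_mepm(methylated_count, total_molecules):
    """MEPM = methylated molecule count / total molecules x 1e6.

    Accepts scalars or arrays; linear in the numerator and invariant under a
    common rescaling of numerator and denominator.
    """
    count = np.asarray(methylated_count, dtype=float)
    total = np.asarray(total_molecules, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_molecules must be > 0")
    if np.any(count < 0):
        raise ValueError("methylated_count must be >= 0")
    out = count / total * 1e6
    return float(out) if out.ndim == 0 else out


def qc_filter_samples(
    matrix: MethylationMatrix, min_molecules: int = 10_000
) -> tuple[MethylationMatrix, list[str]]:
    """Drop samples with a total molecular count below ``min_molecules``.

    The threshold is a strict less-than rule: a sample with exactly
    ``min_molecules`` molecules is retained.  Returns the filtered matrix
    (sample order preserved) and the list of excluded sample ids.
    """
    keep = [s.sample_id for s in matrix.samples if s.total_molecules >= min_molecules]
    excluded = [s.sample_id for s in matrix.samples if s.total_molecules < min_molecules]
    if not keep:
        raise EmptyCohortError("QC filter excluded every sample")
    if not excluded:
        return matrix, []
    return matrix.select_samples(keep), excluded


def split_cohort(
    samples: Sequence[SampleMeta],
    ratio: tuple[int, int] = (6, 4),
    stratify_by: str = "condition",
    seed: int = 0,
) -> CohortSplit:
    """Randomly partition a cohort into discovery/validation sets.

    The split is stratified (default: by condition) and per-stratum the
    discovery side receives ``round(frac * n)`` samples, where ``frac`` is
    the discovery share of ``ratio``.  A 6:4 split of 50 cases + 52 controls
    therefore yields 30+31 discovery and 20+21 validation samples.
    Deterministic for a fixed seed.
    """
    if stratify_by != "condition":
        raise ValueError("only stratification by condition is supported")
    samples = list(samples)
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in cohort")
    frac = ratio[0] / (ratio[0] + ratio[1])
    strata: dict[str, list[str]] = {}
    for s in samples:
        strata.setdefault(s.condition, []).append(s.sample_id)
    rng = np.random.default_rng(seed)
    discovery: list[str] = []
    validation: list[str] = []
    for condition in sorted(strata):
        members = strata[condition]
        if len(members) < 2:
            raise EmptyCohortError(
                f"stratum {condition!r} has {len(members)} sample(s); need at least 2"
            )
        order = rng.permutation(len(members))
        n_disc = int(round(frac * len(members)))
        chosen = {members[i] for i in order[:n_disc]}
        discovery.extend(m for m in members if m in chosen)
        validation.extend(m for m in members if m not in chosen)
    # report in original cohort order
    disc_set = set(discovery)
    return CohortSplit(
        discovery_ids=tuple(i for i in ids if i in disc_set),
        validation_ids=tuple(i for i in ids if i not in disc_set),
    )


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------


def _default_sheet_path(matrix_path: Path) -> Path:
    return matrix_path.with_name(matrix_path.stem + ".samples.tsv")


def write_sample_sheet(samples: Sequence[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "specimen": s.specimen,
            "condition": s.condition,
            "stage": s.stage,
            "paired_id": s.paired_id or "",
            "total_molecules": s.total_molecules,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"sample sheet {path}: missing columns {missing}")
    metas = []
    for _, row in df.iterrows():
        try:
            metas.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    specimen=row["specimen"],
                    condition=row["condition"],
                    stage=row["stage"] or "NA",
                    paired_id=row["paired_id"] or None,
                    total_molecules=int(row["total_molecules"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"sample sheet {path}: {exc}") from exc
    return metas


def write_mepm_matrix(matrix: MethylationMatrix, path, sample_sheet_path=None) -> None:
    """Write a matrix TSV plus its companion sample sheet.

    Values are formatted to 12 significant digits, which makes
    write-then-read an identity for practical purposes.
    """
    path = Path(path)
    sheet = Path(sample_sheet_path) if sample_sheet_path else _default_sheet_path(path)
    matrix.values.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")
    write_sample_sheet(matrix.samples, sheet)


def read_mepm_matrix(path, sample_sheet_path=None, catalog: Sequence[CpGSite] | None = None) -> MethylationMatrix:
    """Read a matrix TSV and its companion sample sheet.

    Raises :class:`ParseError` naming the offending row/column on negative
    values, duplicate ids, or matrix/sample-sheet mismatches.
    """
    path = Path(path)
    sheet = Path(sample_sheet_path) if sample_sheet_path else _default_sheet_path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate site_id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric matrix entry ({exc})") from exc
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ParseError(f"{path}: missing value in column {col!r}")
    arr = df.to_numpy()
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"{path}: negative MEPM at sample {df.index[i]!r}, site {df.columns[j]!r}"
        )

    metas = read_sample_sheet(sheet)
    by_id = {m.sample_id: m for m in metas}
    extra = [i for i in df.index if i not in by_id]
    if extra:
        raise ParseError(f"{path}: samples missing from sample sheet: {extra[:5]}")
    absent = [m.sample_id for m in metas if m.sample_id not in set(df.index)]
    if absent:
        raise ParseError(f"{sheet}: samples missing from matrix: {absent[:5]}")
    ordered = [by_id[i] for i in df.index]

    if catalog is not None:
        cat_ids = [s.site_id for s in catalog]
        if cat_ids != list(df.columns):
            if set(cat_ids) != set(df.columns):
                missing_sites = sorted(set(df.columns) - set(cat_ids))[:5]
                raise ParseError(f"{path}: sites missing from catalog: {missing_sites}")
            by_site = {s.site_id: s for s in catalog}
            catalog = [by_site[c] for c in df.columns]
    try:
        return MethylationMatrix(df, ordered, sites=None if catalog is None else list(catalog))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_site_catalog(sites: Sequence[CpGSite], path) -> None:
    rows = [
        (s.chrom, s.start, s.end, s.site_id, s.motif_distance_bp, s.gene_label)
        for s in sites
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_site_catalog(path) -> list[CpGSite]:
    """Read a 6-column BED-like site catalog (no header, stable order)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_CATALOG_COLUMNS, dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        return []
    sites: list[CpGSite] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        try:
            site = CpGSite(
                site_id=row["site_id"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                motif_distance_bp=int(row["motif_distance_bp"]),
                gene_label=row["gene_label"],
            )
        except ValueError as exc:
            raise ParseError(f"{path} line {idx + 1}: {exc}") from exc
        if site.site_id in seen:
            raise ParseError(f"{path} line {idx + 1}: duplicate site_id {site.site_id!r}")
        seen.add(site.site_id)
        sites.append(site)
    return sites
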
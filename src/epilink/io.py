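"""Readers, writers and core containers for the pipeline's external formats.

All genomic coordinates are BED-style: 0-based, half-open ``[start, end)``.
Tabular files are UTF-8, tab-delimited, with ``#`` comment lines skipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXCLUDED_CHROMS = frozenset({"chrY", "chrM", "Y", "M", "MT", "chrMT"})

PROMOTER_HALF_WINDOW = 500  # bp either side of the TSS


class ParseError(ValueError):
    """A malformed line in an input file (message names the line number)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with a unique id."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.start < 0:
            raise ValueError(f"negative start in interval {self.id!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PromoterAnnotation:
    """A gene's promoter: the TSS and its symmetric +/-500 bp window.

    The window is strand-agnostic; strand is retained as metadata only.
    ``gene_start``/``gene_end`` optionally carry the gene body, used for
    proximal SNP assignment.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_start: int | None = None
    gene_end: int | None = None
    window: GenomicInterval = field(init=False)

    def __post_init__(self):
        start = self.tss - PROMOTER_HALF_WINDOW
        if start < 0:
            warnings.warn(
                f"promoter window of {self.gene_id} clipped at chromosome start",
                stacklevel=2,
            )
            start = 0
        object.__setattr__(
            self,
            "window",
            GenomicInterval(self.chrom, start, self.tss + PROMOTER_HALF_WINDOW, self.gene_id),
        )


class ActivityMatrix:
    """Elements x samples CAGE activity (TPM) as a dense pandas DataFrame.

    TPM here means reads coverage per million mapped reads over the element.
    Values must be finite and non-negative; element and sample ids unique.
    """

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("activity matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("activity matrix contains negative values")
        if data.index.duplicated().any():
            raise ValueError("duplicate element ids in activity matrix")
        if data.columns.duplicated().any():
            raise ValueError("duplicate sample ids in activity matrix")
        self.data = data.astype(float)

    @property
    def element_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def row(self, element_id: str) -> np.ndarray:
        return self.data.loc[element_id].to_numpy()

    def __eq__(self, other) -> bool:
        return isinstance(other, ActivityMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"ActivityMatrix({self.data.shape[0]} elements x {self.data.shape[1]} samples)"


class UsageMatrix:
    """Boolean in-usage flags on the same axes as an :class:`ActivityMatrix`."""

    def __init__(self, data: pd.DataFrame):
        self.data = data.astype(bool)

    def is_in_usage(self, element_id: str, sample_id: str) -> bool:
        try:
            return bool(self.data.at[element_id, sample_id])
        except KeyError as exc:
            raise KeyError(f"unknown element or sample id: {exc}") from exc


@dataclass
class SampleTable:
    """Maps each sample to its cell/tissue state, coarse group and life stage."""

    data: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "state", "group", "life_stage"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")

    @property
    def states(self) -> list[str]:
        return sorted(self.data["state"].unique())

    def samples_of(self, state: str) -> list[str]:
        hits = self.data.loc[self.data["state"] == state, "sample_id"].tolist()
        if not hits:
            raise KeyError(f"state {state!r} has no samples")
        return hits

    def state_of(self, sample_id: str) -> str:
        row = self.data.loc[self.data["sample_id"] == sample_id, "state"]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return row.iloc[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_enhancers(path) -> list[GenomicInterval]:
    """Read enhancer regions from a BED file (>= 3 columns).

    The 4th column, when present, is the enhancer id; otherwise the id
    defaults to ``chrom:start-end``.
    """
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
        name = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
        try:
            interval = GenomicInterval(chrom, start, end, name)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        if name in seen:
            raise ValueError(f"{path}: line {lineno}: duplicate enhancer id {name!r}")
        seen.add(name)
        intervals.append(interval)
    return intervals


def write_enhancers(enhancers: Sequence[GenomicInterval], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for e in enhancers:
            handle.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.id}\n")


def read_promoters(path) -> list[PromoterAnnotation]:
    """Read a promoter/TSS table (gene_id, chrom, tss, strand [, gene_start, gene_end]).

    Genes on chrY/chrM are dropped (the count is logged); duplicate gene ids
    are an error -- multi-TSS genes must be collapsed upstream.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: promoter table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene_id values: {dups[:5]}")
    excluded = df["chrom"].isin(EXCLUDED_CHROMS)
    if excluded.any():
        logger.info("dropped %d promoters on chrY/chrM", int(excluded.sum()))
    df = df.loc[~excluded]
    has_body = {"gene_start", "gene_end"} <= set(df.columns)
    promoters = []
    for row in df.itertuples(index=False):
        promoters.append(
            PromoterAnnotation(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                tss=int(row.tss),
                strand=str(row.strand),
                gene_start=int(row.gene_start) if has_body else None,
                gene_end=int(row.gene_end) if has_body else None,
            )
        )
    return promoters


def write_promoters(promoters: Sequence[PromoterAnnotation], path) -> None:
    rows = []
    has_body = any(p.gene_start is not None for p in promoters)
    for p in promoters:
        row = {"gene_id": p.gene_id, "chrom": p.chrom, "tss": p.tss, "strand": p.strand}
        if has_body:
            row["gene_start"] = p.gene_start
            row["gene_end"] = p.gene_end
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_activity(path) -> ActivityMatrix:
    """Read a dense TPM matrix: header row of sample ids, first column element ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return ActivityMatrix(df)


def write_activity(matrix: ActivityMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="element_id", float_format="%.10g")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph coverage track into (chrom, start, end, value)."""
    rows = []
    for lineno, line in _data_lines(path):
        if line.startswith(("track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 bedGraph columns")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def promoter_tpm_from_coverage(
    track: pd.DataFrame,
    promoters: Sequence[PromoterAnnotation],
    total_mapped_reads: int,
    mode: str = "any",
) -> pd.Series:
    """Quantify promoter activity (TPM) from a read-count coverage track.

    Each track record carries a read count; a record contributes its full
    count to a promoter when it overlaps the +/-500 bp window by >=1 bp
    (``mode="any"``, default) or when its start (the 5' position) lies inside
    the window (``mode="five_prime"``).

    TPM = (summed counts in window) / (total_mapped_reads / 1e6), so the
    result is linear in coverage and inversely linear in library size.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    if mode not in {"any", "five_prime"}:
        raise ValueError(f"unknown counting mode {mode!r}")
    scale = total_mapped_reads / 1e6
    track_chroms = set(track["chrom"]) if len(track) else set()
    out = {}
    by_chrom = {c: g.sort_values("start") for c, g in track.groupby("chrom")} if len(track) else {}
    for p in promoters:
        if p.chrom not in track_chroms:
            if track_chroms:
                warnings.warn(f"chromosome {p.chrom} absent from track; activity set to 0")
            out[p.gene_id] = 0.0
            continue
        g = by_chrom[p.chrom]
        w = p.window
        if mode == "any":
            hit = (g["start"] < w.end) & (g["end"] > w.start)
        else:
            hit = (g["start"] >= w.start) & (g["start"] < w.end)
        out[p.gene_id] = float(g.loc[hit, "value"].sum()) / scale
    return pd.Series(out, name="tpm")


def usage_from_activity(matrix: ActivityMatrix, threshold: float = 1.0) -> UsageMatrix:
    """Call elements in usage per sample: TPM strictly greater than ``threshold``.

    The default threshold of 1 TPM follows the convention for calling CAGE
    elements active; an element at exactly the threshold is *not* in usage.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return UsageMatrix(matrix.data > threshold)


def read_validation_pairs(path) -> pd.DataFrame:
    """Read a validation link set: (enhancer_id, gene_id [, source])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"enhancer_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: validation table needs columns {sorted(required)}")
    return df


def read_variants(path) -> pd.DataFrame:
    """Read a variant table: (snp_id, chrom, pos, maf [, p, gene, pp])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"snp_id", "chrom", "pos", "maf"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: variant table needs columns {sorted(required)}")
    if df["snp_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate snp_id")
    return df
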
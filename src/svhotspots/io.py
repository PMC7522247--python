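"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are 0-based half-open (BED native) throughout the package.
Inputs using 1-based conventions must be converted by the caller.
Chromosome names are taken verbatim; no "chr" prefix normalisation is done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SV_TYPES = ("DUP", "DEL", "INS", "INV", "BND")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant call for one sample: a pair of breakend intervals.

    For DUP/DEL/INS/INV both breakends are on the same chromosome; BND
    (translocation) breakends may differ. ``svtype`` is one of DUP, DEL,
    INS, INV, BND.
    """

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    sample: str
    svtype: str

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ParseError(f"unknown SV type {self.svtype!r}")
        if self.start1 > self.end1 or self.start2 > self.end2:
            raise ParseError(
                f"breakend interval reversed in {self.sample}: "
                f"{self.start1}-{self.end1} / {self.start2}-{self.end2}"
            )
        if self.svtype != "BND" and self.chrom1 != self.chrom2:
            raise ParseError(
                f"{self.svtype} record spans chromosomes "
                f"{self.chrom1}/{self.chrom2}; only BND may"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Full affected region [min start, max end) for DUP/DEL semantics."""
        return (min(self.start1, self.start2), max(self.end1, self.end2))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with an optional name and strand."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if not self.name:
            object.__setattr__(self, "name", f"{self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Closest-edge distance; 0 when overlapping; None-like inf across chromosomes."""
        if self.chrom != other.chrom:
            return int(1e18)
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end, other.start - self.end)


@dataclass(frozen=True)
class CopyNumberSegment:
    """A copy-number segment for one sample, linear scale (diploid = 2)."""

    chrom: str
    start: int
    end: int
    sample: str
    cn: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"CN segment {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.cn < 0:
            raise ParseError(f"negative copy number {self.cn} for {self.sample}")


class ExpressionMatrix:
    """Gene-by-sample abundance matrix in TPM, backed by a pandas DataFrame."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ParseError(f"duplicate gene symbol {dup!r}")
        if values.columns.duplicated().any():
            raise ParseError("duplicate sample identifier")
        if (values.values < 0).any():
            raise ParseError("negative expression value")
        self._df = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        return self._df

    def gene_values(self, gene: str, samples: Sequence[str] | None = None) -> np.ndarray:
        row = self._df.loc[gene]
        if samples is not None:
            row = row.loc[list(samples)]
        return row.to_numpy(dtype=float)

    def __contains__(self, gene: str) -> bool:
        return gene in self._df.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self._df.equals(other._df)


# ---------------------------------------------------------------------------
# readers

def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split("\t")


def read_bedpe(path) -> list[SVRecord]:
    """Read SV calls from a BEDPE file.

    Column mapping: 1-6 = the two breakend coordinate triples, 7 = sample
    identifier, 8 = score (ignored), 9-10 = strands (ignored), 11 = SV type.
    When only 8 columns are present, column 8 is taken as the SV type.
    """
    records: list[SVRecord] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 8:
            raise ParseError(f"{path}:{lineno}: expected >= 8 BEDPE columns, got {len(cols)}")
        try:
            s1, e1, s2, e2 = int(cols[1]), int(cols[2]), int(cols[4]), int(cols[5])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed coordinate ({exc})") from None
        svtype = cols[10] if len(cols) >= 11 else cols[7]
        try:
            records.append(
                SVRecord(cols[0], s1, e1, cols[3], s2, e2, cols[6], svtype)
            )
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not records:
        warnings.warn(f"{path}: no SV records parsed", stacklevel=2)
    return records


def write_bedpe(records: Iterable[SVRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom1}\t{r.start1}\t{r.end1}\t{r.chrom2}\t{r.start2}\t{r.end2}"
                f"\t{r.sample}\t.\t+\t-\t{r.svtype}\n"
            )


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED6 intervals in file order.

    A missing name column defaults to "chrom:start-end".
    """
    out: list[GenomicInterval] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed coordinate ({exc})") from None
        name = cols[3] if len(cols) >= 4 and cols[3] not in ("", ".") else ""
        strand = cols[5] if len(cols) >= 6 else "."
        try:
            out.append(GenomicInterval(cols[0], start, end, name, strand))
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_cn_segments(path) -> list[CopyNumberSegment]:
    """Read copy-number segments (TSV: chrom, start, end, sample, cn).

    Segments belonging to one sample must not overlap.
    """
    segs: list[CopyNumberSegment] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns (chrom,start,end,sample,cn)")
        try:
            seg = CopyNumberSegment(cols[0], int(cols[1]), int(cols[2]), cols[3], float(cols[4]))
        except (ValueError, ParseError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        segs.append(seg)
    validate_cn_segments(segs)
    return segs


def validate_cn_segments(segs: Sequence[CopyNumberSegment]) -> None:
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for s in segs:
        by_key.setdefault((s.sample, s.chrom), []).append(s)
    for (sample, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ParseError(
                    f"overlapping CN segments for sample {sample} on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def write_cn_segments(segs: Iterable[CopyNumberSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segs:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sample}\t{s.cn:g}\n")


def cn_by_sample(segs: Sequence[CopyNumberSegment]) -> dict[str, list[CopyNumberSegment]]:
    out: dict[str, list[CopyNumberSegment]] = {}
    for s in segs:
        out.setdefault(s.sample, []).append(s)
    return out


def read_expression(path) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene symbol) into an ExpressionMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.isna()
    if bad.values.any():
        gi, si = np.argwhere(bad.values)[0]
        raise ParseError(
            f"{path}: missing/non-numeric value at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path}: non-numeric column {col!r}")
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_chrom_sizes(path) -> dict[str, int]:
    """UCSC-style chrom.sizes: chromosome name and length per line."""
    out: dict[str, int] = {}
    for lineno, cols in _data_lines(path):
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: expected chrom and length")
        out[cols[0]] = int(cols[1])
    return out


def read_gene_list(path) -> set[str]:
    """One gene symbol per line (used for cancer-census gene lists)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def check_chromosome_vocabulary(*collections: Iterable) -> None:
    """Warn when inputs use disjoint chromosome name sets (e.g. chr1 vs 1)."""
    vocabs = []
    for coll in collections:
        chroms: set[str] = set()
        for item in coll:
            if isinstance(item, SVRecord):
                chroms.update((item.chrom1, item.chrom2))
            else:
                chroms.add(item.chrom)
        if chroms:
            vocabs.append(chroms)
    for i, a in enumerate(vocabs):
        for b in vocabs[i + 1:]:
            if not (a & b):
                warnings.warn(
                    f"disjoint chromosome vocabularies between inputs: "
                    f"{sorted(a)[:3]}... vs {sorted(b)[:3]}...",
                    stacklevel=2,
                )
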
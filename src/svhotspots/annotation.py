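"""Attach nearby genes and overlapping regulatory elements to hotspot peaks.

"Nearby" means within ``gene_flank`` bases of either peak edge (closest-edge
distance, overlap = 0); recurrent SVs can act on a gene through regulatory
elements hundreds of kilobases away, so the default flank is 1 Mb. Strand is
ignored for proximity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .detection import Peak
from .io import GenomicInterval


@dataclass
class AnnotationConfig:
    gene_flank: int = 1_000_000

    def __post_init__(self) -> None:
        if self.gene_flank < 0:
            raise ValueError("gene_flank must be >= 0")


@dataclass
class AnnotatedPeak:
    """A peak plus the genes and regulatory elements in its neighbourhood.

    ``overlapping_genes`` intersect the peak; ``nearby_genes`` (a superset)
    lie within the configured flank, ordered by distance then coordinate.
    """

    peak: Peak
    overlapping_genes: list[GenomicInterval]
    nearby_genes: list[GenomicInterval]
    regulatory_hits: list[GenomicInterval]


def _build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GenomicInterval],
    regulatory: Sequence[GenomicInterval] = (),
    cfg: AnnotationConfig | None = None,
) -> list[AnnotatedPeak]:
    """Annotate each peak with overlapping/nearby genes and overlapping elements."""
    cfg = cfg or AnnotationConfig()
    gene_trees = _build_trees(genes)
    reg_trees = _build_trees(regulatory)
    out: list[AnnotatedPeak] = []
    for peak in peaks:
        piv = peak.interval
        gtree = gene_trees.get(peak.chrom, IntervalTree())
        near = [hit.data for hit in gtree.overlap(peak.start - cfg.gene_flank,
                                                  peak.end + cfg.gene_flank)]
        near.sort(key=lambda g: (piv.distance_to(g), g.start, g.end, g.name))
        overlapping = [g for g in near if piv.distance_to(g) == 0]
        rtree = reg_trees.get(peak.chrom, IntervalTree())
        regs = sorted(
            (hit.data for hit in rtree.overlap(peak.start, peak.end)),
            key=lambda r: (r.start, r.end, r.name),
        )
        out.append(AnnotatedPeak(peak, overlapping, near, regs))
    return out


def annotated_peaks_bed(annotated: Sequence[AnnotatedPeak]) -> list[GenomicInterval]:
    """Peak intervals (named by peak id) for BED output."""
    return [ap.peak.interval for ap in annotated]


def annotation_table(annotated: Sequence[AnnotatedPeak]):
    """Summary table with pipe-joined gene and element lists."""
    import pandas as pd

    rows = []
    for ap in annotated:
        p = ap.peak
        rows.append(
            {
                "peak_id": p.peak_id,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "n_samples": p.count,
                "pct_samples": p.pct_samples,
                "overlapping_genes": "|".join(g.name for g in ap.overlapping_genes),
                "nearby_genes": "|".join(g.name for g in ap.nearby_genes),
                "regulatory_elements": "|".join(r.name for r in ap.regulatory_hits),
            }
        )
    return pd.DataFrame(rows)
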
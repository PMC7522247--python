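"""Synthetic cancer-cohort generator with known ground truth.

Emulates the statistical structure the pipeline assumes: a cohort of tumor
samples with background SVs scattered uniformly along the genome, one or
more implanted hotspot loci recurrently hit by a chosen SV type, expression
of a linked gene shifted in the hit samples, and per-sample copy-number
segments. Everything is reproducible from an integer seed, and the
generator emits the exact on-disk formats the pipeline consumes.

Expression is modeled log-normally: log-TPM for gene g in sample s is
N(mu_g, sigma_g); an implanted effect of ``e`` SD units shifts the log-mean
of hit samples by e * sigma_g in the stated direction. Background SV counts
per sample are Poisson(background_rate * genome Mb); the default rate of
0.03 SVs/sample/Mb corresponds to on the order of 100 SVs per whole cancer
genome. DUP/DEL hotspot events get start/end jitter within 20% of the
hotspot length (staying inside the interval) so merged peaks must aggregate
genuinely heterogeneous events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CopyNumberSegment,
    ExpressionMatrix,
    GenomicInterval,
    SVRecord,
    SV_TYPES,
)


@dataclass
class HotspotSpec:
    chrom: str
    start: int
    end: int
    svtype: str = "DUP"
    penetrance: float = 0.4
    linked_gene: str | None = None
    expression_effect: float = 0.0   # shift in SD units of log-TPM
    direction: str = "up"

    def __post_init__(self) -> None:
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must be in [0,1]")
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype}")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass
class GeneSpec:
    name: str
    chrom: str
    start: int
    end: int
    mean_log_tpm: float = np.log(30.0)
    sd_log_tpm: float = 0.5


@dataclass
class CNEventSpec:
    chrom: str
    start: int
    end: int
    kind: str = "gain"     # gain or loss
    penetrance: float = 0.2
    cn: float | None = None  # default 4.0 for gain, 1.0 for loss


@dataclass
class SimulationSpec:
    n_samples: int = 100
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 6_000_000})
    background_rate: float = 0.03     # expected background SVs per sample per Mb
    hotspots: list[HotspotSpec] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)
    elements: list[GenomicInterval] = field(default_factory=list)
    cn_events: list[CNEventSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for h in self.hotspots:
            L = self.chrom_lengths.get(h.chrom)
            if L is None or not (0 <= h.start < h.end <= L):
                raise ValueError(
                    f"hotspot {h.chrom}:{h.start}-{h.end} outside the genome"
                )
        for g in self.genes:
            L = self.chrom_lengths.get(g.chrom)
            if L is None or not (0 <= g.start < g.end <= L):
                raise ValueError(f"gene {g.name} outside the genome")


@dataclass
class SimulatedCohort:
    svs: list[SVRecord]
    cn: list[CopyNumberSegment]
    expr: ExpressionMatrix
    genes: list[GenomicInterval]
    elements: list[GenomicInterval]
    truth: pd.DataFrame
    samples: list[str]


def _background_sv(rng: np.random.Generator, sample: str, chroms: list[str],
                   lengths: dict[str, int]) -> SVRecord:
    svtype = SV_TYPES[rng.integers(len(SV_TYPES))]
    chrom = chroms[rng.integers(len(chroms))]
    L = lengths[chrom]
    if svtype in ("DUP", "DEL"):
        size = int(np.exp(rng.uniform(np.log(10_000), np.log(100_000))))
        start = int(rng.integers(0, max(1, L - size)))
        end = min(start + size, L - 1)
        return SVRecord(chrom, start, start + 1, chrom, end, end + 1, sample, svtype)
    if svtype == "BND":
        chrom2 = chroms[rng.integers(len(chroms))]
        p1 = int(rng.integers(0, L - 1))
        p2 = int(rng.integers(0, lengths[chrom2] - 1))
        return SVRecord(chrom, p1, p1 + 1, chrom2, p2, p2 + 1, sample, "BND")
    # INS / INV: two nearby breakends on one chromosome
    size = int(np.exp(rng.uniform(np.log(1_000), np.log(50_000))))
    start = int(rng.integers(0, max(1, L - size)))
    end = min(start + size, L - 1)
    return SVRecord(chrom, start, start + 1, chrom, end, end + 1, sample, svtype)


def simulate(spec: SimulationSpec) -> SimulatedCohort:
    """Generate a cohort with the given background, hotspots, and effects.

    Each hotspot hits exactly round(penetrance * n_samples) samples, drawn
    without replacement; the truth table records the implanted intervals,
    hit sample sets, and effects.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    chroms = sorted(spec.chrom_lengths)
    genome_mb = sum(spec.chrom_lengths.values()) / 1e6

    svs: list[SVRecord] = []
    for s in samples:
        for _ in range(rng.poisson(spec.background_rate * genome_mb)):
            svs.append(_background_sv(rng, s, chroms, spec.chrom_lengths))

    truth_rows = []
    hotspot_hits: list[set[str]] = []
    for hi, h in enumerate(spec.hotspots):
        n_hit = int(round(h.penetrance * spec.n_samples))
        hits = set(rng.choice(samples, size=n_hit, replace=False))
        hotspot_hits.append(hits)
        L = h.end - h.start
        jitter = int(0.2 * L)
        for s in sorted(hits):
            if h.svtype in ("DUP", "DEL"):
                a = int(rng.integers(h.start, h.start + max(1, jitter)))
                b = int(rng.integers(h.end - max(1, jitter), h.end))
                svs.append(SVRecord(h.chrom, a, a + 1, h.chrom, b, b + 1, s, h.svtype))
            elif h.svtype == "BND":
                p1 = int(rng.integers(h.start, h.end - 1))
                other = chroms[rng.integers(len(chroms))]
                p2 = int(rng.integers(0, spec.chrom_lengths[other] - 1))
                svs.append(SVRecord(h.chrom, p1, p1 + 1, other, p2, p2 + 1, s, "BND"))
            else:
                p1 = int(rng.integers(h.start, h.end - 1))
                p2 = min(p1 + int(rng.integers(100, max(200, jitter + 200))), h.end - 1)
                svs.append(SVRecord(h.chrom, p1, p1 + 1, h.chrom, p2, p2 + 1, s, h.svtype))
        truth_rows.append(
            {
                "hotspot": f"hs{hi}",
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "svtype": h.svtype,
                "n_hit": n_hit,
                "hit_samples": "|".join(sorted(hits)),
                "linked_gene": h.linked_gene or "",
                "expression_effect": h.expression_effect,
                "direction": h.direction,
            }
        )

    # copy number: diploid genome, then implanted gain/loss events
    cn: list[CopyNumberSegment] = []
    cn_hits: dict[int, set[str]] = {}
    for ei, ev in enumerate(spec.cn_events):
        n_hit = int(round(ev.penetrance * spec.n_samples))
        cn_hits[ei] = set(rng.choice(samples, size=n_hit, replace=False))
    for s in samples:
        for chrom in chroms:
            L = spec.chrom_lengths[chrom]
            breaks = {0, L}
            events_here = [
                (ei, ev) for ei, ev in enumerate(spec.cn_events)
                if ev.chrom == chrom and s in cn_hits[ei]
            ]
            for _, ev in events_here:
                breaks.update((ev.start, ev.end))
            pts = sorted(breaks)
            for a, b in zip(pts, pts[1:]):
                value = 2.0
                for _, ev in events_here:
                    if ev.start <= a and b <= ev.end:
                        value = ev.cn if ev.cn is not None else (4.0 if ev.kind == "gain" else 1.0)
                cn.append(CopyNumberSegment(chrom, a, b, s, value))

    # expression: log-normal baseline, hit samples shifted for linked genes
    expr_rows = {}
    for g in spec.genes:
        log_tpm = rng.normal(g.mean_log_tpm, g.sd_log_tpm, size=spec.n_samples)
        for hi, h in enumerate(spec.hotspots):
            if h.linked_gene == g.name and h.expression_effect != 0:
                shift = h.expression_effect * g.sd_log_tpm
                if h.direction == "down":
                    shift = -shift
                mask = np.array([s in hotspot_hits[hi] for s in samples])
                log_tpm[mask] += shift
        expr_rows[g.name] = np.exp(log_tpm)
    expr = ExpressionMatrix(
        pd.DataFrame(expr_rows, index=samples).T if expr_rows
        else pd.DataFrame(index=pd.Index([], name="gene"), columns=samples, dtype=float)
    )

    gene_ivs = [GenomicInterval(g.chrom, g.start, g.end, g.name) for g in spec.genes]
    return SimulatedCohort(
        svs=svs,
        cn=cn,
        expr=expr,
        genes=gene_ivs,
        elements=list(spec.elements),
        truth=pd.DataFrame(truth_rows),
        samples=samples,
    )


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write every cohort component in the formats the pipeline reads."""
    import os

    from . import io as gio

    paths = {
        "svs": os.path.join(out_dir, "svs.bedpe"),
        "cn": os.path.join(out_dir, "cn_segments.tsv"),
        "expr": os.path.join(out_dir, "expression.tsv"),
        "genes": os.path.join(out_dir, "genes.bed"),
        "elements": os.path.join(out_dir, "elements.bed"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    gio.write_bedpe(cohort.svs, paths["svs"])
    gio.write_cn_segments(cohort.cn, paths["cn"])
    gio.write_expression(cohort.expr, paths["expr"])
    gio.write_bed(cohort.genes, paths["genes"])
    gio.write_bed(cohort.elements, paths["elements"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def recovery_spec(seed: int = 0, expression_effect: float = 2.0) -> SimulationSpec:
    """The standard single-hotspot benchmark cohort.

    100 samples on a 6-Mb chromosome; one 120-kb DUP hotspot at 40%
    penetrance whose hit samples get an expression shift (default +2 SD) on
    a gene starting 300 kb downstream; uniform background at 0.03
    SVs/sample/Mb (an expected 0.3 background SVs per 100-kb window across
    the cohort); three unlinked bystander genes.
    """
    hs = HotspotSpec(
        "chr1", 3_000_000, 3_120_000, svtype="DUP", penetrance=0.4,
        linked_gene="GENE_T", expression_effect=expression_effect, direction="up",
    )
    genes = [
        GeneSpec("GENE_T", "chr1", 3_420_000, 3_470_000),
        GeneSpec("GENE_A", "chr1", 800_000, 850_000),
        GeneSpec("GENE_B", "chr1", 2_300_000, 2_350_000),
        GeneSpec("GENE_C", "chr1", 4_600_000, 4_650_000),
    ]
    elements = [GenomicInterval("chr1", 3_040_000, 3_060_000, "ENH_T")]
    return SimulationSpec(
        n_samples=100,
        chrom_lengths={"chr1": 6_000_000},
        background_rate=0.03,
        hotspots=[hs],
        genes=genes,
        elements=elements,
        seed=seed,
    )
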
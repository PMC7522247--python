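"""Region multi-track figures, expression panels, and genome summaries.

Figures are deliberately schematic rather than publication-styled; every
number drawn (group sizes, p-values, counts) is read from the same result
objects that feed the tabular reports.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .annotation import AnnotatedPeak
from .association import AssociationResult
from .detection import SV_TYPES, Peak, sv_target_intervals
from .io import CopyNumberSegment, ExpressionMatrix, GenomicInterval, SVRecord


def _region_around(peak: Peak, chrom_length: int, flank_factor: float = 5.0) -> tuple[int, int]:
    flank = int(flank_factor * len(peak) / 2)
    return max(0, peak.start - flank), min(chrom_length, peak.end + flank)


def _fraction_track(ax, xs, values, label):
    ax.fill_between(xs, values, step="mid", alpha=0.6)
    ax.set_ylabel(label, fontsize=7)


def plot_region(
    annotated_peak: AnnotatedPeak,
    svs: Sequence[SVRecord],
    cn_segments: Sequence[CopyNumberSegment],
    chrom_length: int,
    out: str,
    coverage: Sequence[tuple[int, float]] | None = None,
    gain_threshold: float = 2.5,
    loss_threshold: float = 1.5,
) -> str:
    """Multi-track view of a hotspot region.

    Tracks, top to bottom: fraction of samples with copy-number gain/loss
    per position; per-sample DUP/DEL segment pileup; per-position DUP/DEL
    sample aggregation; per-position aggregation per SV type; optional
    coverage; regulatory elements and genes. Dashed vertical lines mark the
    peak bounds.
    """
    peak = annotated_peak.peak
    chrom = peak.chrom
    lo, hi = _region_around(peak, chrom_length)
    n_tracks = 6 if coverage is not None else 5
    fig, axes = plt.subplots(
        n_tracks, 1, figsize=(8, 1.3 * n_tracks + 1), sharex=True,
        gridspec_kw={"hspace": 0.45},
    )
    xs = np.linspace(lo, hi, 400).astype(int)

    samples = sorted({s.sample for s in svs})
    n = max(len(samples), 1)

    # 1: CN gain/loss fraction
    gain = np.zeros(xs.size)
    loss = np.zeros(xs.size)
    for seg in cn_segments:
        if seg.chrom != chrom:
            continue
        mask = (xs >= seg.start) & (xs < seg.end)
        if seg.cn >= gain_threshold:
            gain[mask] += 1
        elif seg.cn <= loss_threshold:
            loss[mask] += 1
    axes[0].fill_between(xs, gain / n, step="mid", alpha=0.6, label="gain")
    axes[0].fill_between(xs, -loss / n, step="mid", alpha=0.6, label="loss")
    axes[0].set_ylabel("CN frac", fontsize=7)
    axes[0].legend(fontsize=6, loc="upper right")

    # 2: DUP/DEL per-sample pileup
    row = 0
    for sv in svs:
        if sv.svtype not in ("DUP", "DEL") or sv.chrom1 != chrom:
            continue
        a, b = sv.span
        if b < lo or a > hi:
            continue
        color = "tab:red" if sv.svtype == "DUP" else "tab:blue"
        axes[1].hlines(row, max(a, lo), min(b, hi), color=color, lw=1.2)
        row += 1
    axes[1].set_ylabel("DUP/DEL\npileup", fontsize=7)

    # 3: DUP/DEL aggregation; 4: per-type aggregation
    agg = {t: np.zeros(xs.size) for t in SV_TYPES}
    for sv in svs:
        for s0, s1 in sv_target_intervals(sv, chrom):
            mask = (xs >= s0) & (xs < max(s1, s0 + 1))
            agg[sv.svtype][mask] += 1
    axes[2].fill_between(xs, agg["DUP"] + agg["DEL"], step="mid", alpha=0.6)
    axes[2].set_ylabel("DUP+DEL\nsamples", fontsize=7)
    for t in SV_TYPES:
        axes[3].plot(xs, agg[t], lw=1, label=t)
    axes[3].set_ylabel("by type", fontsize=7)
    axes[3].legend(fontsize=6, ncol=5, loc="upper right")

    next_ax = 4
    if coverage is not None:
        pos = np.array([p for p, _ in coverage])
        val = np.array([v for _, v in coverage])
        axes[next_ax].plot(pos, val, lw=0.8, color="black")
        axes[next_ax].set_ylabel("coverage", fontsize=7)
        next_ax += 1

    # last: annotation track
    ann = axes[next_ax]
    for el in annotated_peak.regulatory_hits:
        ann.hlines(1.0, el.start, el.end, color="tab:green", lw=6)
        ann.text((el.start + el.end) / 2, 1.15, el.name, fontsize=6, ha="center")
    for g in annotated_peak.nearby_genes:
        ann.hlines(0.4, g.start, g.end, color="tab:purple", lw=6)
        ann.text((g.start + g.end) / 2, 0.12, g.name, fontsize=6, ha="center")
    ann.set_ylim(0, 1.5)
    ann.set_yticks([])
    ann.set_ylabel("genes /\nelements", fontsize=7)
    ann.set_xlabel(f"{chrom} position (bp)")

    for ax in axes:
        ax.axvline(peak.start, ls="--", color="grey", lw=0.8)
        ax.axvline(peak.end, ls="--", color="grey", lw=0.8)
        ax.set_xlim(lo, hi)
    fig.suptitle(f"{peak.peak_id}: {peak.count} samples ({peak.pct_samples:.0%})",
                 fontsize=9)
    fig.savefig(out, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return out


def _fmt_p(p: float | None) -> str:
    return "n/a" if p is None else f"p={p:.2g}"


def plot_expression_panels(
    association: AssociationResult,
    expr: ExpressionMatrix,
    peak: Peak,
    cn_status: Mapping[str, str],
    out: str,
) -> str:
    """Three boxplot panels for one (peak, gene) pair.

    (1) SV vs no-SV samples; (2) by SV type; (3) by copy-number status of
    the gene. Group sizes and the p-values from the association report are
    annotated verbatim.
    """
    gene = association.gene
    cohort = expr.samples
    sv_samples = sorted(peak.samples & set(cohort))
    ctrl = [s for s in cohort if s not in peak.samples]

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))

    overall = association.comparison("all_sv")
    axes[0].boxplot(
        [expr.gene_values(gene, sv_samples), expr.gene_values(gene, ctrl)],
        tick_labels=[f"SV\nn={len(sv_samples)}", f"no SV\nn={len(ctrl)}"],
    )
    axes[0].set_title(f"{gene}: all SVs ({_fmt_p(overall.p_value)})", fontsize=8)
    axes[0].set_ylabel("TPM")

    groups, labels, ann = [], [], []
    for t in SV_TYPES:
        members = sorted(peak.type_samples.get(t, set()) & set(cohort))
        if not members:
            continue
        comp = association.comparison(t)
        groups.append(expr.gene_values(gene, members))
        labels.append(f"{t}\nn={len(members)}")
        ann.append(_fmt_p(comp.p_value))
    groups.append(expr.gene_values(gene, ctrl))
    labels.append(f"no SV\nn={len(ctrl)}")
    ann.append("")
    axes[1].boxplot(groups, tick_labels=labels)
    for i, a in enumerate(ann, start=1):
        axes[1].annotate(a, (i, 1.0), xycoords=("data", "axes fraction"),
                         ha="center", fontsize=6)
    axes[1].set_title("by SV type", fontsize=8)

    by_status: dict[str, list[str]] = {"gain": [], "loss": [], "neutral": []}
    for s in cohort:
        by_status[cn_status.get(s, "neutral")].append(s)
    groups = [expr.gene_values(gene, v) if v else np.array([]) for v in by_status.values()]
    axes[2].boxplot(groups, tick_labels=[f"{k}\nn={len(v)}" for k, v in by_status.items()])
    neutral_comp = association.comparison("all_sv", "cn_neutral")
    axes[2].set_title(f"by gene CN status (neutral stratum {_fmt_p(neutral_comp.p_value)})",
                      fontsize=8)

    fig.suptitle(f"{association.peak_id} / {gene}  combined "
                 f"{_fmt_p(association.combined_p)}  FDR="
                 f"{'n/a' if association.fdr is None else format(association.fdr, '.2g')}",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out


def plot_genome_summary(
    peaks: Sequence[Peak],
    gene_counts: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    out: str,
) -> str:
    """Per-chromosome bar chart of hotspot and associated-gene counts."""
    chroms = sorted(chrom_lengths)
    peak_counts = [sum(1 for p in peaks if p.chrom == c) for c in chroms]
    gcounts = [gene_counts.get(c, 0) for c in chroms]
    x = np.arange(len(chroms))
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(chroms) + 2), 3))
    ax.bar(x - 0.2, peak_counts, width=0.4, label="hotspots")
    ax.bar(x + 0.2, gcounts, width=0.4, label="associated genes")
    ax.set_xticks(x, chroms, rotation=45, fontsize=7)
    ax.set_ylabel("count")
    ax.legend(fontsize=7)
    ax.set_title(
        f"{sum(peak_counts)} hotspots, {sum(gcounts)} associated genes", fontsize=9
    )
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out
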
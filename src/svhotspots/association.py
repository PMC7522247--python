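"""Peak-gene expression association: the 12-comparison battery.

For every (peak, nearby gene) pair the expression of the gene is compared
between samples harboring hotspot SVs and samples without any SV targeting
the hotspot — overall, per SV type (five types), and each of those six
again restricted to samples copy-neutral for the gene, for twelve
comparisons in total. Per-comparison two-sided p-values are combined with
Fisher's method (undefined comparisons are dropped and the degrees of
freedom adapt), and the combined p-values are adjusted by Benjamini-
Hochberg across all (peak, gene) pairs.

The twelve tests on one pair share samples and are positively correlated,
so the Fisher combination is anticonservative; it is applied regardless
because it is the procedure this pipeline defines, and the inflation is
documented rather than corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotatedPeak
from .detection import SV_TYPES
from .io import CopyNumberSegment, ExpressionMatrix, GenomicInterval

COMPARISON_LABELS: tuple[tuple[str, str], ...] = tuple(
    (group, stratum)
    for stratum in ("unstratified", "cn_neutral")
    for group in ("all_sv",) + SV_TYPES
)


@dataclass
class AssociationConfig:
    method: str = "wilcoxon"  # or "ttest"
    min_group: int = 3
    gain_threshold: float = 2.5
    loss_threshold: float = 1.5
    log2_ratio_mode: bool = False
    log2_gain: float = 0.3
    log2_loss: float = -0.3

    def __post_init__(self) -> None:
        if self.method not in ("wilcoxon", "ttest"):
            raise ValueError("method must be 'wilcoxon' or 'ttest'")
        if not self.log2_ratio_mode and self.gain_threshold <= self.loss_threshold:
            raise ValueError("gain_threshold must exceed loss_threshold")


@dataclass
class ComparisonResult:
    group: str            # all_sv or one SV type
    stratum: str          # unstratified or cn_neutral
    n_sv: int
    n_ctrl: int
    mean_sv: float        # nan when the group is empty
    mean_ctrl: float
    p_value: float | None  # None when either group is below min_group

    @property
    def label(self) -> str:
        return f"{self.group}.{self.stratum}"


@dataclass
class AssociationResult:
    peak_id: str
    gene: str
    comparisons: list[ComparisonResult]
    combined_p: float | None = None
    fdr: float | None = None
    direction: str = "na"  # up/down from the all_sv unstratified means

    def comparison(self, group: str, stratum: str = "unstratified") -> ComparisonResult:
        for c in self.comparisons:
            if c.group == group and c.stratum == stratum:
                return c
        raise KeyError((group, stratum))


def classify_cn_status(
    segments: Sequence[CopyNumberSegment],
    gene: GenomicInterval,
    samples: Sequence[str],
    cfg: AssociationConfig | None = None,
) -> dict[str, str]:
    """Gain/loss/neutral call per sample from length-weighted mean copy number.

    A sample's gene-level copy number is the overlap-length-weighted mean of
    its segments intersecting the gene body; gain when >= gain_threshold,
    loss when <= loss_threshold, else neutral. Samples with no overlapping
    segment are treated as neutral (no evidence of alteration).
    """
    cfg = cfg or AssociationConfig()
    weights: dict[str, float] = {}
    acc: dict[str, float] = {}
    for seg in segments:
        if seg.chrom != gene.chrom:
            continue
        ov = min(seg.end, gene.end) - max(seg.start, gene.start)
        if ov <= 0:
            continue
        weights[seg.sample] = weights.get(seg.sample, 0.0) + ov
        acc[seg.sample] = acc.get(seg.sample, 0.0) + ov * seg.cn
    status: dict[str, str] = {}
    gain = cfg.log2_gain if cfg.log2_ratio_mode else cfg.gain_threshold
    loss = cfg.log2_loss if cfg.log2_ratio_mode else cfg.loss_threshold
    for sample in samples:
        if sample not in weights:
            status[sample] = "neutral"
            continue
        cn = acc[sample] / weights[sample]
        if cn >= gain:
            status[sample] = "gain"
        elif cn <= loss:
            status[sample] = "loss"
        else:
            status[sample] = "neutral"
    return status


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    # exact null when the pooled sample is small and untied; otherwise the
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_groups(
    expr_sv: Sequence[float],
    expr_ctrl: Sequence[float],
    method: str = "wilcoxon",
    min_group: int = 3,
) -> tuple[int, int, float, float, float | None]:
    """Two-sided comparison of two expression groups.

    Returns (n_sv, n_ctrl, mean_sv, mean_ctrl, p). p is None when either
    group has fewer than ``min_group`` samples; the group sizes and means are
    reported regardless.
    """
    a = np.asarray(expr_sv, dtype=float)
    b = np.asarray(expr_ctrl, dtype=float)
    mean_a = float(a.mean()) if a.size else float("nan")
    mean_b = float(b.mean()) if b.size else float("nan")
    if a.size < min_group or b.size < min_group:
        return a.size, b.size, mean_a, mean_b, None
    if method == "wilcoxon":
        p = _wilcoxon_p(a, b)
    else:
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
    return a.size, b.size, mean_a, mean_b, max(min(p, 1.0), np.nextafter(0, 1))


def run_comparison_battery(
    annotated_peak: AnnotatedPeak,
    gene: str,
    expr: ExpressionMatrix,
    cn_status: Mapping[str, str],
    cfg: AssociationConfig | None = None,
) -> AssociationResult | None:
    """Run all twelve comparisons for one (peak, gene) pair.

    The SV group is the peak's supporting sample set (per-type groups use
    samples with that SV type targeting the peak; a sample with several
    types enters each of its type groups); the control group is every
    expression-profiled sample without any SV targeting the peak.
    Copy-neutral strata intersect both groups with samples whose gene-level
    copy number is neutral. All twelve slots are always emitted; a slot's p
    is undefined when a group falls below ``min_group``.
    """
    cfg = cfg or AssociationConfig()
    if gene not in expr:
        warnings.warn(f"gene {gene!r} absent from expression matrix; pair skipped",
                      stacklevel=2)
        return None
    peak = annotated_peak.peak
    cohort = [s for s in expr.samples]
    sv_all = peak.samples & set(cohort)
    ctrl = [s for s in cohort if s not in peak.samples]
    neutral = {s for s in cohort if cn_status.get(s, "neutral") == "neutral"}

    def values(samples: Sequence[str]) -> np.ndarray:
        return expr.gene_values(gene, list(samples))

    comparisons: list[ComparisonResult] = []
    for group, stratum in COMPARISON_LABELS:
        sv_set = sv_all if group == "all_sv" else (peak.type_samples.get(group, set()) & set(cohort))
        ctrl_set: Sequence[str] = ctrl
        if stratum == "cn_neutral":
            sv_set = sv_set & neutral
            ctrl_set = [s for s in ctrl if s in neutral]
        n_sv, n_ctrl, m_sv, m_ctrl, p = compare_groups(
            values(sorted(sv_set)), values(ctrl_set), cfg.method, cfg.min_group
        )
        comparisons.append(ComparisonResult(group, stratum, n_sv, n_ctrl, m_sv, m_ctrl, p))

    result = AssociationResult(peak.peak_id, gene, comparisons)
    defined = [c.p_value for c in comparisons if c.p_value is not None]
    result.combined_p = fisher_combine(defined) if defined else None
    overall = result.comparison("all_sv")
    if np.isfinite(overall.mean_sv) and np.isfinite(overall.mean_ctrl):
        result.direction = "up" if overall.mean_sv >= overall.mean_ctrl else "down"
    return result


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: X2 = -2 sum(ln p) ~ chi-square(2k)."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if (ps <= 0).any():
        warnings.warn("p-value of 0 clamped to smallest positive float", stacklevel=2)
        ps = np.clip(ps, np.nextafter(0, 1), 1.0)
    x2 = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(x2, df=2 * ps.size))


def bh_fdr(p_values: Sequence[float | None]) -> list[float | None]:
    """Benjamini-Hochberg step-up q-values; None entries stay None and are
    excluded from the number of tests."""
    idx = [i for i, p in enumerate(p_values) if p is not None]
    out: list[float | None] = [None] * len(p_values)
    if not idx:
        return out
    ps = np.array([p_values[i] for i in idx], dtype=float)
    q = multipletests(ps, method="fdr_bh")[1]
    for i, qi in zip(idx, q):
        out[i] = float(qi)
    return out


def associate(
    annotated_peaks: Sequence[AnnotatedPeak],
    expr: ExpressionMatrix,
    cn_segments: Sequence[CopyNumberSegment],
    genes: Sequence[GenomicInterval],
    cfg: AssociationConfig | None = None,
) -> list[AssociationResult]:
    """Run the battery for every (peak, nearby gene) pair and attach global FDR."""
    cfg = cfg or AssociationConfig()
    gene_by_name = {g.name: g for g in genes}
    results: list[AssociationResult] = []
    for ap in annotated_peaks:
        for g in ap.nearby_genes:
            gene_iv = gene_by_name.get(g.name, g)
            status = classify_cn_status(cn_segments, gene_iv, expr.samples, cfg)
            res = run_comparison_battery(ap, g.name, expr, status, cfg)
            if res is not None:
                results.append(res)
    qs = bh_fdr([r.combined_p for r in results])
    for r, q in zip(results, qs):
        r.fdr = q
    return results


def association_table(results: Sequence[AssociationResult]):
    """Flat report table: one row per (peak, gene) pair with all statistics."""
    import pandas as pd

    rows = []
    for r in results:
        row: dict = {"peak_id": r.peak_id, "gene": r.gene}
        for c in r.comparisons:
            row[f"p.{c.label}"] = c.p_value
            row[f"n_sv.{c.label}"] = c.n_sv
            row[f"n_ctrl.{c.label}"] = c.n_ctrl
            row[f"mean_sv.{c.label}"] = c.mean_sv
            row[f"mean_ctrl.{c.label}"] = c.mean_ctrl
        row["combined_p"] = r.combined_p
        row["fdr"] = r.fdr
        row["direction"] = r.direction
        rows.append(row)
    return pd.DataFrame(rows)
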
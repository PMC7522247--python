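"""Final retention rules, peak ranking, and genome-browser track output.

A (peak, gene) pair survives when the peak is smaller than 500 kb (unless
the gene is on the supplied cancer-census list), recurs in at least 15% of
SV-harboring samples, reaches FDR < 0.05 on the Fisher-combined p, has at
least one of the twelve comparisons individually significant at p < 0.05,
and at least one group mean in a significant comparison exceeds 10 TPM.
All thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .association import AssociationResult
from .detection import SV_TYPES, Peak, WindowTrack
from .io import GenomicInterval


@dataclass
class FilterConfig:
    max_peak_size: int = 500_000
    census_genes: frozenset[str] = frozenset()
    min_pct_samples: float = 0.15
    max_fdr: float = 0.05
    min_comparison_p: float = 0.05
    min_tpm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("max_peak_size", "max_fdr", "min_comparison_p", "min_tpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "census_genes", frozenset(self.census_genes))


def _pair_passes(peak: Peak, assoc: AssociationResult, cfg: FilterConfig) -> bool:
    if len(peak) >= cfg.max_peak_size and assoc.gene not in cfg.census_genes:
        return False
    if peak.pct_samples < cfg.min_pct_samples:
        return False
    if assoc.fdr is None or not assoc.fdr < cfg.max_fdr:
        return False
    significant = [
        c for c in assoc.comparisons
        if c.p_value is not None and c.p_value < cfg.min_comparison_p
    ]
    if not significant:
        return False
    # expression floor: some group of some significant comparison is expressed
    return any(
        (c.n_sv > 0 and c.mean_sv > cfg.min_tpm) or (c.n_ctrl > 0 and c.mean_ctrl > cfg.min_tpm)
        for c in significant
    )


def apply_filters(
    peaks: Mapping[str, Peak],
    associations: Sequence[AssociationResult],
    cfg: FilterConfig | None = None,
) -> list[AssociationResult]:
    """Return the (peak, gene) association results passing every retention rule."""
    cfg = cfg or FilterConfig()
    return [a for a in associations if _pair_passes(peaks[a.peak_id], a, cfg)]


def rank_peaks(
    retained: Sequence[AssociationResult], peaks: Mapping[str, Peak]
) -> pd.DataFrame:
    """Ranked final report: sample count desc, then FDR asc, then coordinate.

    The rank is per peak; every retained gene of a peak shares its rank.
    """
    rows = []
    for a in retained:
        p = peaks[a.peak_id]
        rows.append(
            {
                "peak_id": a.peak_id,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "length": len(p),
                "n_samples": p.count,
                "pct_samples": p.pct_samples,
                "gene": a.gene,
                "combined_p": a.combined_p,
                "fdr": a.fdr,
                "direction": a.direction,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(
        by=["n_samples", "fdr", "chrom", "start", "gene"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    order = df.drop_duplicates("peak_id")["peak_id"].tolist()
    rank_of = {pid: i + 1 for i, pid in enumerate(order)}
    df.insert(0, "rank", df["peak_id"].map(rank_of))
    return df


def write_ucsc_tracks(
    peaks: Sequence[Peak],
    tracks: Mapping[str, WindowTrack],
    out_dir,
) -> list[str]:
    """One UCSC custom-track file per chromosome.

    Each file holds a BED block with the final peaks on that chromosome
    followed by BedGraph blocks of the per-window sample counts (total and
    per SV type, binned at the step size so records do not overlap).
    """
    import os

    paths = []
    for chrom in sorted(tracks):
        track = tracks[chrom]
        path = os.path.join(out_dir, f"ucsc_track.{chrom}.txt")
        step = (
            track.windows[1].start - track.windows[0].start
            if len(track.windows) > 1
            else len(track.windows[0])
        )
        with open(path, "w") as fh:
            fh.write(f'track name="hotspot peaks {chrom}" description="final merged hotspots"\n')
            for p in peaks:
                if p.chrom == chrom:
                    fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")
            series = {"total": track.count_total}
            for t in SV_TYPES:
                series[t] = track.count_by_type(t)
            for label, counts in series.items():
                fh.write(f'track type=bedGraph name="sample counts {label} {chrom}"\n')
                for w, c in zip(track.windows, counts):
                    fh.write(f"{chrom}\t{w.start}\t{min(w.start + step, w.end)}\t{c:g}\n")
        paths.append(path)
    return paths


def peaks_bed_intervals(peaks: Sequence[Peak]) -> list[GenomicInterval]:
    return [p.interval for p in peaks]
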
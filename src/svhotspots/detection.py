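"""Sliding-window sample counting, candidate peak calling, and peak merging.

The detector counts, for each overlapping window tiled along a chromosome,
how many distinct samples harbor a structural variant targeting the window:
the entire event region for duplications and deletions (these change copy
number of everything they contain), and only the breakend positions for
insertions, inversions, and translocations. Windows whose counts stand
significantly above their local surroundings and exceed a recurrence
threshold become candidate peaks; adjacent candidates with similar counts
are then merged into final hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SV_TYPES, GenomicInterval, SVRecord


@dataclass
class DetectionConfig:
    """Tuning parameters for hotspot detection.

    window_size / step_size define the sliding windows (bases); merge_distance
    is the maximum gap between adjacent candidate peaks grouped into one
    cluster; min_pct_samples is the candidate recurrence threshold as a
    fraction of SV-harboring samples; k and delta govern the merge walk
    (stop a direction after k consecutive peaks whose count differs from the
    top peak's by at least delta, relative); stdlim and neighborhood set the
    local significance test; smoothing_span is the moving-average width.
    """

    window_size: int = 100_000
    step_size: int = 30_000
    min_pct_samples: float = 0.15
    merge_distance: int = 50_000
    k: int = 1
    delta: float = 0.05
    stdlim: float = 3.0
    neighborhood: int = 10
    smoothing_span: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.step_size <= self.window_size):
            raise ValueError("require 0 < step_size <= window_size")
        if not (0 <= self.min_pct_samples <= 1):
            raise ValueError("min_pct_samples must be in [0,1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.neighborhood < 2:
            raise ValueError("neighborhood must be >= 2")
        if self.smoothing_span < 1 or self.smoothing_span % 2 == 0:
            raise ValueError("smoothing_span must be odd and >= 1")


@dataclass
class WindowTrack:
    """Per-chromosome window sample-count track.

    ``sample_sets[i]`` is the set of samples with any SV targeting window i;
    ``type_sample_sets[t][i]`` restricts to SV type t. ``smoothed`` holds the
    moving-average counts once :func:`smooth_counts` has run (raw counts are
    always retained for thresholds and reporting).
    """

    chrom: str
    windows: list[GenomicInterval]
    sample_sets: list[set[str]]
    type_sample_sets: dict[str, list[set[str]]]
    smoothed: np.ndarray | None = None
    skipped_svs: int = 0

    @property
    def count_total(self) -> np.ndarray:
        return np.array([len(s) for s in self.sample_sets], dtype=float)

    def count_by_type(self, svtype: str) -> np.ndarray:
        return np.array([len(s) for s in self.type_sample_sets[svtype]], dtype=float)


@dataclass
class Peak:
    """A (candidate or merged) hotspot interval with its supporting samples."""

    chrom: str
    start: int
    end: int
    samples: set[str]
    type_samples: dict[str, set[str]]
    n_sv_samples: int
    source_windows: tuple[int, ...] = ()
    peak_id: str = ""

    def __post_init__(self) -> None:
        if not self.peak_id:
            self.peak_id = f"peak_{self.chrom}_{self.start}_{self.end}"

    @property
    def count(self) -> int:
        return len(self.samples)

    @property
    def pct_samples(self) -> float:
        return self.count / self.n_sv_samples if self.n_sv_samples else 0.0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.peak_id)

    def __len__(self) -> int:
        return self.end - self.start


def make_windows(chrom: str, chrom_length: int, cfg: DetectionConfig) -> list[GenomicInterval]:
    """Tile [0, chrom_length) with windows starting at 0, s, 2s, ...

    Each window ends at min(start + window_size, chrom_length).
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    starts = range(0, chrom_length, cfg.step_size)
    return [
        GenomicInterval(chrom, s, min(s + cfg.window_size, chrom_length), f"w{i}")
        for i, s in enumerate(starts)
    ]


def sv_target_intervals(sv: SVRecord, chrom: str) -> list[tuple[int, int]]:
    """Intervals of ``chrom`` targeted by one SV under the counting semantics.

    DUP/DEL target their whole span; INS/INV/BND target each breakend
    interval that lies on ``chrom``.
    """
    if sv.svtype in ("DUP", "DEL"):
        return [sv.span] if sv.chrom1 == chrom else []
    out = []
    if sv.chrom1 == chrom:
        out.append((sv.start1, sv.end1))
    if sv.chrom2 == chrom:
        out.append((sv.start2, sv.end2))
    return out


def _overlapping_window_range(
    starts: np.ndarray, ends: np.ndarray, lo: int, hi: int
) -> tuple[int, int]:
    # window i overlaps [lo, hi) iff starts[i] < hi and ends[i] > lo;
    # both arrays are monotone so the hit set is a contiguous index range
    i_hi = int(np.searchsorted(starts, hi, side="left"))
    i_lo = int(np.searchsorted(ends, lo, side="right"))
    return i_lo, i_hi


def count_samples(
    svs: Iterable[SVRecord], windows: Sequence[GenomicInterval], cfg: DetectionConfig
) -> WindowTrack:
    """Build the per-window distinct-sample count track for one chromosome.

    A sample is counted at most once per window overall and at most once per
    (window, SV type), no matter how many of its SVs hit the window. A
    zero-length breakend interval is widened to one base so a breakpoint at
    position p counts in every window containing p.
    """
    if not windows:
        raise ValueError("empty window list")
    chrom = windows[0].chrom
    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    n = len(windows)
    sample_sets: list[set[str]] = [set() for _ in range(n)]
    type_sets: dict[str, list[set[str]]] = {t: [set() for _ in range(n)] for t in SV_TYPES}
    skipped = 0
    for sv in svs:
        ivs = sv_target_intervals(sv, chrom)
        if not ivs:
            skipped += 1
            continue
        for lo, hi in ivs:
            if hi == lo:
                hi = lo + 1
            i0, i1 = _overlapping_window_range(starts, ends, lo, hi)
            for i in range(i0, i1):
                sample_sets[i].add(sv.sample)
                type_sets[sv.svtype][i].add(sv.sample)
    return WindowTrack(chrom, list(windows), sample_sets, type_sets, skipped_svs=skipped)


def smooth_counts(track: WindowTrack, cfg: DetectionConfig) -> WindowTrack:
    """Centered moving average of the raw counts over ``smoothing_span`` windows.

    The averaging window shrinks symmetrically at the track edges. Raw counts
    stay available on the track for thresholding and reporting.
    """
    raw = track.count_total
    span = cfg.smoothing_span
    half = span // 2
    n = len(raw)
    sm = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        sm[i] = raw[lo:hi].mean()
    track.smoothed = sm
    return track


def _robust_flank_stats(values: np.ndarray, i: int, m: int) -> tuple[float, float]:
    """Median and MAD-based sd of the up-to-2m windows flanking i (i excluded)."""
    lo = max(0, i - m)
    hi = min(len(values), i + m + 1)
    flank = np.concatenate([values[lo:i], values[i + 1:hi]])
    if flank.size == 0:
        return 0.0, 1.0
    med = float(np.median(flank))
    sd = 1.4826 * float(np.median(np.abs(flank - med)))
    return med, max(sd, 1.0)


def call_candidate_peaks(
    track: WindowTrack, n_sv_samples: int, cfg: DetectionConfig
) -> list[Peak]:
    """Flag windows whose counts rise significantly above their surroundings.

    Window i is a candidate iff its smoothed count is at least
    ``median + stdlim * sd`` of its 2m flanking windows, where sd is the
    scaled median absolute deviation floored at 1 (robust statistics keep a
    wide hotspot from masking itself through its own shoulder windows), and
    its raw distinct-sample count reaches ``min_pct_samples`` of the
    SV-harboring cohort. Each candidate is a single-window Peak carrying its
    raw sample sets.
    """
    if n_sv_samples < 1:
        raise ValueError("n_sv_samples must be >= 1")
    if track.smoothed is None:
        smooth_counts(track, cfg)
    sm = track.smoothed
    raw = track.count_total
    peaks: list[Peak] = []
    for i, w in enumerate(track.windows):
        med, sd = _robust_flank_stats(sm, i, cfg.neighborhood)
        if sm[i] < med + cfg.stdlim * sd:
            continue
        if raw[i] / n_sv_samples < cfg.min_pct_samples:
            continue
        peaks.append(
            Peak(
                chrom=track.chrom,
                start=w.start,
                end=w.end,
                samples=set(track.sample_sets[i]),
                type_samples={t: set(track.type_sample_sets[t][i]) for t in SV_TYPES},
                n_sv_samples=n_sv_samples,
                source_windows=(i,),
            )
        )
    return peaks


def _cluster_by_gap(peaks: Sequence[Peak], max_gap: int) -> list[list[int]]:
    """Single-linkage clusters of peak indices where consecutive gaps <= max_gap."""
    clusters: list[list[int]] = []
    for idx in range(len(peaks)):
        if clusters:
            prev = peaks[clusters[-1][-1]]
            cur = peaks[idx]
            if cur.chrom == prev.chrom and cur.start - prev.end <= max_gap:
                clusters[-1].append(idx)
                continue
        clusters.append([idx])
    return clusters


def _merge_members(members: Sequence[Peak], n_sv_samples: int) -> Peak:
    start = min(p.start for p in members)
    end = max(p.end for p in members)
    samples: set[str] = set()
    type_samples: dict[str, set[str]] = {t: set() for t in SV_TYPES}
    windows: set[int] = set()
    for p in members:
        samples |= p.samples
        for t in SV_TYPES:
            type_samples[t] |= p.type_samples.get(t, set())
        windows.update(p.source_windows)
    return Peak(
        chrom=members[0].chrom,
        start=start,
        end=end,
        samples=samples,
        type_samples=type_samples,
        n_sv_samples=n_sv_samples,
        source_windows=tuple(sorted(windows)),
    )


def merge_peaks(candidates: Sequence[Peak], cfg: DetectionConfig) -> list[Peak]:
    """Merge adjacent candidate peaks with similar sample counts into hotspots.

    Candidates are clustered by single linkage with gap <= merge_distance.
    Within each cluster, repeatedly: take the unconsumed peak with the
    highest count (ties to the leftmost) and walk outward, upstream then
    downstream, over the cluster's unconsumed peaks in coordinate order,
    merging each whose count differs from the top count by less than delta
    (relative); a direction stops after k consecutive violations or upon
    reaching an already-consumed peak. The walk repeats until every peak in
    the cluster is consumed. Finally, any resulting peaks whose intervals
    overlap (sliding windows overlap, so walk products can) are unioned so
    the output is disjoint.
    """
    if not candidates:
        return []
    cand = sorted(candidates, key=lambda p: (p.chrom, p.start, p.end))
    n_sv = cand[0].n_sv_samples
    merged: list[Peak] = []
    for cluster in _cluster_by_gap(cand, cfg.merge_distance):
        consumed = [False] * len(cluster)
        while not all(consumed):
            open_idx = [j for j in range(len(cluster)) if not consumed[j]]
            top = max(open_idx, key=lambda j: (cand[cluster[j]].count, -cand[cluster[j]].start))
            top_count = cand[cluster[top]].count
            members = [top]
            for direction in (-1, +1):
                violations = 0
                j = top + direction
                while 0 <= j < len(cluster) and violations < cfg.k:
                    if consumed[j]:
                        break
                    c = cand[cluster[j]].count
                    if abs(top_count - c) / top_count < cfg.delta:
                        members.append(j)
                        violations = 0
                    else:
                        violations += 1
                    j += direction
            for j in members:
                consumed[j] = True
            merged.append(_merge_members([cand[cluster[j]] for j in sorted(members)], n_sv))
    merged.sort(key=lambda p: (p.chrom, p.start, p.end))
    # union overlapping walk products so output peaks are disjoint
    out: list[Peak] = []
    for p in merged:
        if out and p.chrom == out[-1].chrom and p.start < out[-1].end:
            out[-1] = _merge_members([out[-1], p], n_sv)
        else:
            out.append(p)
    return out


def n_sv_samples(svs: Iterable[SVRecord]) -> int:
    """Number of distinct samples with at least one SV anywhere in the input."""
    return len({sv.sample for sv in svs})


def detect_hotspots(
    svs: Sequence[SVRecord],
    chrom_lengths: Mapping[str, int],
    cfg: DetectionConfig | None = None,
) -> tuple[list[Peak], dict[str, WindowTrack]]:
    """Run counting, candidate calling, and merging over every chromosome.

    Returns the merged hotspot peaks (sorted by coordinate) and the
    per-chromosome window tracks for reporting and browser output.
    """
    cfg = cfg or DetectionConfig()
    n_sv = n_sv_samples(svs)
    peaks: list[Peak] = []
    tracks: dict[str, WindowTrack] = {}
    for chrom in sorted(chrom_lengths):
        windows = make_windows(chrom, chrom_lengths[chrom], cfg)
        track = count_samples(svs, windows, cfg)
        smooth_counts(track, cfg)
        tracks[chrom] = track
        if n_sv == 0:
            continue
        cand = call_candidate_peaks(track, n_sv, cfg)
        peaks.extend(merge_peaks(cand, cfg))
    return peaks, tracks


def samples_targeting(
    svs: Iterable[SVRecord], chrom: str, start: int, end: int
) -> tuple[set[str], dict[str, set[str]]]:
    """Samples (overall and per SV type) with an SV targeting [start, end).

    Uses the same region-vs-breakpoint semantics as :func:`count_samples`.
    """
    overall: set[str] = set()
    by_type: dict[str, set[str]] = {t: set() for t in SV_TYPES}
    for sv in svs:
        for lo, hi in sv_target_intervals(sv, chrom):
            if hi == lo:
                hi = lo + 1
            if lo < end and start < hi:
                overall.add(sv.sample)
                by_type[sv.svtype].add(sv.sample)
    return overall, by_type


def write_bedgraph_tracks(track: WindowTrack, out_dir, prefix: str = "counts") -> list[str]:
    """Write per-window counts as BedGraph, one file for the total and one per SV type.

    Overlapping sliding windows are resolved to step-sized bins (each bin
    takes the count of the window starting at it) so the BedGraph is valid.
    """
    import os

    paths = []
    series = {"total": track.count_total}
    for t in SV_TYPES:
        series[t] = track.count_by_type(t)
    for label, counts in series.items():
        path = os.path.join(out_dir, f"{prefix}.{track.chrom}.{label}.bedgraph")
        with open(path, "w") as fh:
            fh.write(
                f'track type=bedGraph name="{prefix} {label} {track.chrom}"\n'
            )
            for w, c in zip(track.windows, counts):
                step_end = min(w.start + (track.windows[1].start - track.windows[0].start
                                          if len(track.windows) > 1 else len(w)), w.end)
                fh.write(f"{track.chrom}\t{w.start}\t{step_end}\t{c:g}\n")
        paths.append(path)
    return paths
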
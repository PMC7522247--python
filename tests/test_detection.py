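import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svhotspots.detection import (
    SV_TYPES,
    DetectionConfig,
    call_candidate_peaks,
    count_samples,
    detect_hotspots,
    make_windows,
    merge_peaks,
    samples_targeting,
    smooth_counts,
)
from svhotspots.io import GenomicInterval, SVRecord

from conftest import make_peak, make_track


# --- independent oracles -----------------------------------------------------

def brute_force_counts(svs, windows):
    """Literal (sample x window) overlap enumeration of the counting rules."""
    totals, by_type = [], []
    for w in windows:
        tot = set()
        per_type = {t: set() for t in SV_TYPES}
        for sv in svs:
            targets = []
            if sv.svtype in ("DUP", "DEL"):
                if sv.chrom1 == w.chrom:
                    targets = [(min(sv.start1, sv.start2), max(sv.end1, sv.end2))]
            else:
                if sv.chrom1 == w.chrom:
                    targets.append((sv.start1, sv.end1))
                if sv.chrom2 == w.chrom:
                    targets.append((sv.start2, sv.end2))
            for lo, hi in targets:
                hi = max(hi, lo + 1)
                if lo < w.end and w.start < hi:
                    tot.add(sv.sample)
                    per_type[sv.svtype].add(sv.sample)
        totals.append(tot)
        by_type.append(per_type)
    return totals, by_type


def merge_oracle(cands, d, k, delta):
    """Literal simulation of cluster / top-peak / k-delta merge procedure."""
    cands = sorted(cands, key=lambda p: (p.chrom, p.start, p.end))
    clusters, cur = [], []
    for p in cands:
        if cur and p.chrom == cur[-1].chrom and p.start - cur[-1].end <= d:
            cur.append(p)
        else:
            if cur:
                clusters.append(cur)
            cur = [p]
    if cur:
        clusters.append(cur)

    raw_out = []
    for cluster in clusters:
        consumed = [False] * len(cluster)
        while not all(consumed):
            best = None
            for j, p in enumerate(cluster):
                if consumed[j]:
                    continue
                if best is None or len(p.samples) > len(cluster[best].samples):
                    best = j
            top = len(cluster[best].samples)
            members = {best}
            for step in (-1, 1):
                viol, j = 0, best + step
                while 0 <= j < len(cluster) and not consumed[j]:
                    if abs(top - len(cluster[j].samples)) / top < delta:
                        members.add(j)
                        viol = 0
                    else:
                        viol += 1
                        if viol >= k:
                            break
                    j += step
            for j in members:
                consumed[j] = True
            raw_out.append(
                (
                    min(cluster[j].start for j in members),
                    max(cluster[j].end for j in members),
                    set().union(*(cluster[j].samples for j in members)),
                )
            )
    raw_out.sort()
    final = []
    for start, end, samples in raw_out:
        if final and start < final[-1][1]:
            ps, pe, psam = final[-1]
            final[-1] = (ps, max(pe, end), psam | samples)
        else:
            final.append((start, end, samples))
    return final


def random_sv(rng, chroms, length):
    svtype = SV_TYPES[rng.integers(len(SV_TYPES))]
    sample = f"S{rng.integers(8)}"
    c1 = chroms[rng.integers(len(chroms))]
    c2 = chroms[rng.integers(len(chroms))] if svtype == "BND" else c1
    a = int(rng.integers(0, length))
    b = int(rng.integers(0, length))
    return SVRecord(c1, a, a + int(rng.integers(0, 3)), c2, b,
                    b + int(rng.integers(0, 3)), sample, svtype)


# --- windows -----------------------------------------------------------------

@pytest.mark.parametrize(
    "length,w,s,expected_n,last",
    [
        (250_000, 100_000, 30_000, 9, (240_000, 250_000)),
        (300_000, 100_000, 100_000, 3, (200_000, 300_000)),
        (50_000, 100_000, 30_000, 2, (30_000, 50_000)),
    ],
)
def test_make_windows_tiling(length, w, s, expected_n, last):
    cfg = DetectionConfig(window_size=w, step_size=s)
    windows = make_windows("chr1", length, cfg)
    assert len(windows) == expected_n
    assert [win.start for win in windows] == list(range(0, length, s))
    assert (windows[-1].start, windows[-1].end) == last
    assert all(win.end == min(win.start + w, length) for win in windows)


def test_make_windows_single_window_short_chrom():
    cfg = DetectionConfig(window_size=100_000, step_size=100_000)
    (only,) = make_windows("chr1", 50_000, cfg)
    assert (only.start, only.end) == (0, 50_000)


# --- counting ----------------------------------------------------------------

def _tiling_cfg(w):
    return DetectionConfig(window_size=w, step_size=w)


def test_del_region_counts_in_every_spanned_window():
    cfg = _tiling_cfg(100_000)
    windows = make_windows("chr1", 300_000, cfg)
    sv = SVRecord("chr1", 50_000, 50_001, "chr1", 249_999, 250_000, "S1", "DEL")
    track = count_samples([sv], windows, cfg)
    assert list(track.count_total) == [1, 1, 1]


def test_bnd_counts_only_breakend_windows():
    cfg = _tiling_cfg(100_000)
    windows = make_windows("chr1", 300_000, cfg)
    sv = SVRecord("chr1", 150_000, 150_001, "chr2", 0, 1, "S1", "BND")
    track = count_samples([sv], windows, cfg)
    assert list(track.count_total) == [0, 1, 0]
    assert track.skipped_svs == 0


def test_same_sample_deduplicated_within_window():
    cfg = _tiling_cfg(100_000)
    windows = make_windows("chr1", 100_000, cfg)
    svs = [
        SVRecord("chr1", 10_000, 10_001, "chr1", 20_000, 20_001, "S1", "DUP"),
        SVRecord("chr1", 30_000, 30_001, "chr1", 40_000, 40_001, "S1", "DUP"),
    ]
    track = count_samples(svs, windows, cfg)
    assert list(track.count_total) == [1]
    assert len(track.type_sample_sets["DUP"][0]) == 1


def test_count_samples_matches_brute_force(rng):
    cfg = DetectionConfig(window_size=10_000, step_size=3_000)
    for _ in range(30):
        windows = make_windows("chr1", 100_000, cfg)
        svs = [random_sv(rng, ["chr1", "chr2"], 100_000) for _ in range(25)]
        track = count_samples(svs, windows, cfg)
        totals, by_type = brute_force_counts(svs, windows)
        assert track.sample_sets == totals
        for i, per_type in enumerate(by_type):
            for t in SV_TYPES:
                assert track.type_sample_sets[t][i] == per_type[t]


def test_samples_targeting_matches_counting_semantics(rng):
    svs = [random_sv(rng, ["chr1"], 50_000) for _ in range(40)]
    window = GenomicInterval("chr1", 10_000, 30_000)
    totals, by_type = brute_force_counts(svs, [window])
    overall, per_type = samples_targeting(svs, "chr1", 10_000, 30_000)
    assert overall == totals[0]
    assert per_type == by_type[0]


# --- smoothing ---------------------------------------------------------------

def test_smoothing_examples(cfg):
    track = make_track([0, 0, 9, 0, 0])
    smooth_counts(track, DetectionConfig(smoothing_span=3))
    assert list(track.smoothed) == [0, 3, 3, 3, 0]

    ident = make_track([1, 5, 2])
    smooth_counts(ident, DetectionConfig(smoothing_span=1))
    assert list(ident.smoothed) == [1, 5, 2]

    const = make_track([4] * 7)
    smooth_counts(const, DetectionConfig(smoothing_span=3))
    assert list(const.smoothed) == [4] * 7


# --- candidate calling -------------------------------------------------------

def test_constant_track_yields_no_candidates():
    cfg = DetectionConfig(neighborhood=3)
    track = make_track([5] * 15)
    assert call_candidate_peaks(track, 100, cfg) == []


def test_isolated_spike_is_candidate():
    cfg = DetectionConfig(neighborhood=3, smoothing_span=1, min_pct_samples=0.15)
    track = make_track([2, 2, 2, 20, 2, 2, 2])
    (peak,) = call_candidate_peaks(track, 100, cfg)
    assert peak.source_windows == (3,)
    assert peak.count == 20
    assert peak.pct_samples == pytest.approx(0.20)


def test_spike_below_recurrence_threshold_rejected():
    cfg = DetectionConfig(neighborhood=3, smoothing_span=1, min_pct_samples=0.15)
    track = make_track([2, 2, 2, 10, 2, 2, 2])
    assert call_candidate_peaks(track, 100, cfg) == []


def test_short_track_flanks_truncated_without_error():
    cfg = DetectionConfig(neighborhood=10, smoothing_span=1)
    track = make_track([0, 30, 0])
    (peak,) = call_candidate_peaks(track, 100, cfg)
    assert peak.source_windows == (1,)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=50), min_size=5, max_size=40),
    t1=st.floats(min_value=0, max_value=1),
    t2=st.floats(min_value=0, max_value=1),
)
def test_raising_recurrence_threshold_never_adds_candidates(counts, t1, t2):
    lo, hi = sorted([t1, t2])
    track_lo = make_track(counts)
    track_hi = make_track(counts)
    n_lo = len(call_candidate_peaks(track_lo, 50, DetectionConfig(min_pct_samples=lo)))
    n_hi = len(call_candidate_peaks(track_hi, 50, DetectionConfig(min_pct_samples=hi)))
    assert n_hi <= n_lo


# --- merging -----------------------------------------------------------------

def test_merge_similar_adjacent_peaks():
    p1 = make_peak(100_000, 200_000, [f"a{i}" for i in range(30)])
    p2 = make_peak(230_000, 330_000, [f"b{i}" for i in range(29)])
    cfg = DetectionConfig(merge_distance=50_000, k=1, delta=0.05)
    (merged,) = merge_peaks([p1, p2], cfg)
    assert (merged.start, merged.end) == (100_000, 330_000)
    assert merged.count == 59


def test_distant_peaks_stay_separate():
    p1 = make_peak(100_000, 200_000, [f"a{i}" for i in range(30)])
    p2 = make_peak(260_000, 360_000, [f"b{i}" for i in range(29)])
    cfg = DetectionConfig(merge_distance=50_000)
    assert len(merge_peaks([p1, p2], cfg)) == 2


def test_dissimilar_counts_stop_the_walk():
    p1 = make_peak(100_000, 200_000, [f"a{i}" for i in range(30)])
    p2 = make_peak(230_000, 330_000, [f"b{i}" for i in range(20)])
    cfg = DetectionConfig(merge_distance=50_000, k=1, delta=0.05)
    out = merge_peaks([p1, p2], cfg)
    assert [(p.start, p.end) for p in out] == [(100_000, 200_000), (230_000, 330_000)]


def _random_cluster(rng, n):
    peaks, pos = [], 0
    for i in range(n):
        pos += int(rng.integers(0, 60_000))
        count = int(rng.integers(1, 40))
        peaks.append(
            make_peak(pos, pos + 100_000, {f"p{i}_s{j}" for j in range(count)})
        )
        pos += 100_000
    return peaks


def test_merge_matches_exhaustive_simulation(rng):
    cfg = DetectionConfig(merge_distance=50_000, k=1, delta=0.05)
    for _ in range(200):
        cands = _random_cluster(rng, int(rng.integers(1, 7)))
        got = merge_peaks(cands, cfg)
        want = merge_oracle(cands, cfg.merge_distance, cfg.k, cfg.delta)
        assert [(p.start, p.end, p.samples) for p in got] == want


def test_merge_conserves_samples(rng):
    cfg = DetectionConfig()
    cands = _random_cluster(rng, 6)
    out = merge_peaks(cands, cfg)
    assert set().union(*(p.samples for p in out)) == set().union(
        *(p.samples for p in cands)
    )


def test_merged_peaks_are_disjoint(rng):
    cfg = DetectionConfig()
    for _ in range(50):
        cands = _random_cluster(rng, int(rng.integers(2, 7)))
        out = merge_peaks(cands, cfg)
        for a, b in zip(out, out[1:]):
            assert a.end <= b.start


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    gaps=st.lists(st.integers(min_value=0, max_value=120_000), min_size=2, max_size=8),
    d1=st.integers(min_value=0, max_value=150_000),
    d2=st.integers(min_value=0, max_value=150_000),
)
def test_larger_merge_distance_never_adds_clusters(gaps, d1, d2):
    lo, hi = sorted([d1, d2])
    peaks, pos = [], 0
    for i, g in enumerate(gaps):
        pos += g
        peaks.append(make_peak(pos, pos + 10_000, {f"s{i}"}))
        pos += 10_000

    def n_clusters(d):
        n, prev_end = 0, None
        for p in peaks:
            if prev_end is None or p.start - prev_end > d:
                n += 1
            prev_end = p.end
        return n

    assert n_clusters(hi) <= n_clusters(lo)


# --- end to end detection ----------------------------------------------------

def test_detect_hotspots_empty_input_is_empty():
    peaks, tracks = detect_hotspots([], {"chr1": 500_000})
    assert peaks == []
    assert set(tracks) == {"chr1"}
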
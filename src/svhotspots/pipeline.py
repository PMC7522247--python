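"""End-to-end driver: detect -> annotate -> associate -> family -> filter -> report."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import io as gio
from .annotation import AnnotationConfig, annotate_peaks, annotation_table
from .association import AssociationConfig, associate, association_table
from .detection import DetectionConfig, Peak, detect_hotspots, write_bedgraph_tracks
from .families import build_families, families_table
from .filters import FilterConfig, apply_filters, rank_peaks, write_ucsc_tracks
from .io import CopyNumberSegment, ExpressionMatrix, GenomicInterval, SVRecord

log = logging.getLogger("svhotspots")


@dataclass
class RunConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    alpha_dep: float = 0.05


@dataclass
class PipelineResult:
    peaks: dict[str, Peak]
    tracks: dict
    annotated: list
    associations: list
    retained: list
    families: list
    report: object  # ranked pandas DataFrame
    manifest: dict


def run_pipeline(
    svs: Sequence[SVRecord],
    chrom_lengths: Mapping[str, int],
    genes: Sequence[GenomicInterval],
    regulatory: Sequence[GenomicInterval],
    cn_segments: Sequence[CopyNumberSegment],
    expr: ExpressionMatrix,
    cfg: RunConfig | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; write reports when out_dir is given."""
    cfg = cfg or RunConfig()
    gio.check_chromosome_vocabulary(svs, genes, cn_segments)

    peaks_list, tracks = detect_hotspots(svs, chrom_lengths, cfg.detection)
    log.info("detection: %d merged peaks", len(peaks_list))
    peaks = {p.peak_id: p for p in peaks_list}

    annotated = annotate_peaks(peaks_list, genes, regulatory, cfg.annotation)
    associations = associate(annotated, expr, cn_segments, genes, cfg.association)
    log.info("association: %d (peak, gene) pairs", len(associations))

    retained = apply_filters(peaks, associations, cfg.filters)
    log.info("filters: %d retained pairs", len(retained))

    cohort = set(expr.samples)
    families = build_families(
        [(a.peak_id, a.gene) for a in retained], peaks, cohort, cfg.alpha_dep
    )
    report = rank_peaks(retained, peaks)

    manifest = {
        "n_svs": len(svs),
        "n_sv_samples": len({sv.sample for sv in svs}),
        "n_merged_peaks": len(peaks),
        "n_pairs_tested": len(associations),
        "n_pairs_retained": len(retained),
        "n_families": len(families),
        "parameters": {
            "window_size": cfg.detection.window_size,
            "step_size": cfg.detection.step_size,
            "merge_distance": cfg.detection.merge_distance,
            "k": cfg.detection.k,
            "delta": cfg.detection.delta,
            "min_pct_samples": cfg.detection.min_pct_samples,
            "stdlim": cfg.detection.stdlim,
            "neighborhood": cfg.detection.neighborhood,
            "smoothing_span": cfg.detection.smoothing_span,
            "gene_flank": cfg.annotation.gene_flank,
            "test": cfg.association.method,
            "max_fdr": cfg.filters.max_fdr,
            "min_tpm": cfg.filters.min_tpm,
            "max_peak_size": cfg.filters.max_peak_size,
            "alpha_dep": cfg.alpha_dep,
        },
    }

    result = PipelineResult(
        peaks, tracks, annotated, associations, retained, families, report, manifest
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    peaks_list = sorted(result.peaks.values(), key=lambda p: (p.chrom, p.start))
    gio.write_bed([p.interval for p in peaks_list], os.path.join(out_dir, "peaks.bed"))
    annotation_table(result.annotated).to_csv(
        os.path.join(out_dir, "annotated_peaks.tsv"), sep="\t", index=False
    )
    association_table(result.associations).to_csv(
        os.path.join(out_dir, "associations.tsv"), sep="\t", index=False
    )
    result.report.to_csv(os.path.join(out_dir, "final_report.tsv"), sep="\t", index=False)
    families_table(result.families, result.peaks).to_csv(
        os.path.join(out_dir, "peak_families.tsv"), sep="\t", index=False
    )
    track_dir = os.path.join(out_dir, "tracks")
    os.makedirs(track_dir, exist_ok=True)
    write_ucsc_tracks(peaks_list, result.tracks, track_dir)
    for track in result.tracks.values():
        write_bedgraph_tracks(track, track_dir)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
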
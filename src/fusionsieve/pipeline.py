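"""End-to-end fusion detection: read -> assemble -> score -> filter ->
annotate -> write."""

from __future__ import annotations

import logging
import os
import sys
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import pyfaidx

from . import noise as noise_model
from .alignments import (
    MODE_SEPARATE,
    MODE_WITHIN_MAIN,
    count_mapped_reads,
    detect_boundary_spanning,
    mark_duplicates,
    read_chimeric_alignments,
)
from .annotation import AnnotationIndex, read_gene_annotation
from .candidates import FusionCandidate, assemble_candidates
from .constants import FilterThresholds, NoiseConstants, load_config
from .filters import FilterResources, run_filters
from .io import (
    FusionCall,
    read_breakpoint_lists,
    read_structural_variants,
    write_fusion_calls,
)
from .sequence import junction_flanking_sequence, predict_peptide

logger = logging.getLogger("fusionsieve")


class ConfigurationError(RuntimeError):
    """Missing or inconsistent pipeline configuration (usage error)."""


@dataclass
class PipelineConfig:
    gtf: str
    chimeric_sam: str | None = None
    main_sam: str | None = None
    genome: str | None = None
    blacklist: str | None = None
    whitelist: str | None = None
    sv_bedpe: str | None = None
    output: str | None = None  # None: stdout
    mapped_reads: int | None = None  # overrides counting from main_sam
    flank: int = 200
    config_file: str | None = None
    constants: NoiseConstants = field(default_factory=NoiseConstants)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)

    def validate(self) -> None:
        if self.chimeric_sam is None and self.main_sam is None:
            raise ConfigurationError(
                "either a chimeric or a main alignment file is required"
            )
        for label in ("gtf", "chimeric_sam", "main_sam", "genome",
                      "blacklist", "whitelist", "sv_bedpe", "config_file"):
            path = getattr(self, label)
            if path is not None and not os.path.exists(path):
                raise ConfigurationError(f"missing input file: {path}")


def _intergenic_counter(candidates: list[FusionCandidate]):
    """Count intergenic breakpoints near a position (pseudo-gene rate).

    Intergenic breakpoints have no annotated gene to normalize noise
    by; they borrow a fixed window centered on the breakpoint, with the
    number of intergenic candidate breakpoints inside the window
    standing in for the per-gene candidate count.
    """
    positions: dict[str, list[int]] = {}
    for cand in candidates:
        for bp in (cand.breakpoint5, cand.breakpoint3):
            if bp.gene_id is None:
                positions.setdefault(bp.chromosome, []).append(bp.position)
    for vals in positions.values():
        vals.sort()
    half = noise_model.INTERGENIC_WINDOW // 2

    def count(cand: FusionCandidate) -> int:
        best = 1
        for bp in (cand.breakpoint5, cand.breakpoint3):
            if bp.gene_id is not None:
                continue
            vals = positions.get(bp.chromosome, [])
            n = bisect_right(vals, bp.position + half) - bisect_left(
                vals, bp.position - half
            )
            best = max(best, n)
        return best

    return count


def run_pipeline(config: PipelineConfig) -> tuple[list[FusionCall], dict]:
    """Execute the full detection pipeline.

    Returns the kept calls (already written to the configured output)
    and a dictionary of stage counts.  Identical inputs and
    configuration produce byte-identical output.
    """
    config.validate()
    if config.config_file:
        with open(config.config_file) as handle:
            config.constants, config.thresholds = load_config(
                handle, config.constants, config.thresholds
            )

    annotation = read_gene_annotation(config.gtf)
    logger.info("annotation: %d genes", len(annotation.genes))

    if config.chimeric_sam is not None:
        alignments = list(
            read_chimeric_alignments(config.chimeric_sam, MODE_SEPARATE)
        )
    else:
        alignments = list(
            read_chimeric_alignments(config.main_sam, MODE_WITHIN_MAIN)
        )
    if config.main_sam is not None:
        alignments.extend(
            detect_boundary_spanning(config.main_sam, annotation)
        )
    alignments = mark_duplicates(alignments)
    logger.info("chimeric alignments: %d", len(alignments))

    if config.mapped_reads is not None:
        mapped = config.mapped_reads
    elif config.main_sam is not None:
        mapped = count_mapped_reads(config.main_sam)
    else:
        mapped = count_mapped_reads(config.chimeric_sam)
    logger.info("mapped reads: %d", mapped)

    candidates, stats = assemble_candidates(
        alignments, annotation, mapped, config.thresholds.mate_window
    )
    logger.info("candidates assembled: %d", len(candidates))

    intergenic_count = _intergenic_counter(candidates)
    for cand in candidates:
        noise_model.evalue(
            cand, stats, annotation, config.constants,
            intergenic_candidates=intergenic_count(cand),
        )

    blacklist, whitelist = [], set()
    if config.blacklist or config.whitelist:
        bl_stream = open(config.blacklist) if config.blacklist else None
        wl_stream = open(config.whitelist) if config.whitelist else None
        try:
            blacklist, whitelist = read_breakpoint_lists(
                bl_stream, wl_stream, config.thresholds.blacklist_tolerance
            )
        finally:
            for stream in (bl_stream, wl_stream):
                if stream is not None:
                    stream.close()
    svs = (
        read_structural_variants(config.sv_bedpe) if config.sv_bedpe else []
    )
    genome = pyfaidx.Fasta(config.genome) if config.genome else None

    resources = FilterResources(
        annotation=annotation,
        thresholds=config.thresholds,
        blacklist=blacklist,
        whitelist=whitelist,
        structural_variants=svs,
        genome=genome,
    )
    kept, discarded = run_filters(candidates, resources)
    counts = _stage_counts(candidates, kept, discarded)
    for line in _format_counts(counts):
        logger.info("%s", line)

    calls = [
        _annotate_call(cand, genome, annotation, config.flank)
        for cand in kept
    ]
    if config.output is None:
        write_fusion_calls(calls, sys.stdout)
    else:
        with open(config.output, "w") as handle:
            write_fusion_calls(calls, handle)
    return calls, counts


def _annotate_call(
    cand: FusionCandidate,
    genome,
    annotation: AnnotationIndex,
    flank: int,
) -> FusionCall:
    call = FusionCall(candidate=cand)
    for attr, bp in (("gene5", cand.breakpoint5), ("gene3", cand.breakpoint3)):
        if bp.gene_id is not None:
            setattr(call, attr, annotation.genes[bp.gene_id].gene_name)
    if genome is not None:
        transcript = junction_flanking_sequence(cand, genome, annotation, flank)
        call.fusion_transcript_sequence = transcript.marked
        peptide = predict_peptide(cand, genome, annotation)
        call.peptide_sequence = peptide.peptide or "."
        call.reading_frame = peptide.frame_status
    return call


def _stage_counts(candidates, kept, discarded) -> dict:
    counts = {
        "candidates": len(candidates),
        "kept": len(kept),
        "discarded": len(discarded),
    }
    for cand in discarded:
        for decision in cand.filter_history:
            if decision.action == "discard":
                key = f"discarded_{decision.filter_name}"
                counts[key] = counts.get(key, 0) + 1
    for cand in kept:
        for decision in cand.filter_history:
            if decision.action == "rescue":
                key = f"rescued_{decision.filter_name}"
                counts[key] = counts.get(key, 0) + 1
        key = f"kept_{cand.confidence}"
        counts[key] = counts.get(key, 0) + 1
    return counts


def _format_counts(counts: dict) -> list[str]:
    return [f"{key}: {value}" for key, value in sorted(counts.items())]
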
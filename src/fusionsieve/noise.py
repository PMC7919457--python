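"""Polynomial background-noise model (e-value) for fusion candidates.

The expected level of background noise for a candidate — its e-value —
is the product of five factors:

    e_value = base_level_bg_noise * depth_penalty * distance_penalty
              * inv_to_dup_ratio * intron_to_exon_ratio

``base_level_bg_noise`` is a per-gene rate that grows linearly with the
number of candidates observed in the gene and decays polynomially with
the number of supporting reads.  ``depth_penalty`` grows linearly with
sequencing depth with a slope that shrinks geometrically in the number
of supporting reads.  ``distance_penalty`` penalizes breakpoints in
close genomic proximity (artifacts cluster at short distances) using
two polynomial regimes split at 400 bp; it is not applied at all to
breakpoints 400 kb or further apart or on different chromosomes.  The
two ratio factors penalize event types (inversions, duplications) and
breakpoint site classes (intron/exon/splice site) in proportion to
their observed frequency among all candidates.

Note the two distance regimes, evaluated with the calibrated constants,
do not meet continuously at the 400 bp boundary; the model is applied
exactly as calibrated, without smoothing.

A candidate is kept only if it has *more supporting reads than its
e-value* (plus an absolute detection limit, see the filter engine).
"""

from __future__ import annotations

from .annotation import SITE_EXONIC, SITE_INTERGENIC, SITE_INTRONIC, SITE_SPLICE
from .candidates import (
    EVENT_DUPLICATION,
    EVENT_INVERSION,
    FusionCandidate,
    GeneStats,
)
from .constants import NoiseConstants

#: width of the pseudo-gene window used to derive a per-"gene" noise
#: rate for intergenic breakpoints, which have no annotated exon length
INTERGENIC_WINDOW = 10_000


def base_level_bg_noise(
    total_candidates_of_gene: int,
    sum_of_exon_lengths_of_gene: int,
    supporting_reads: int,
    constants: NoiseConstants = NoiseConstants(),
) -> float:
    """Per-gene base noise level.

    Linear in the gene's candidate count, normalized by the gene's exon
    union length, with polynomial decay in the supporting-read count.
    """
    if sum_of_exon_lengths_of_gene <= 0:
        raise ValueError("sum_of_exon_lengths_of_gene must be positive")
    if supporting_reads <= constants.shift_noise:
        raise ValueError("supporting_reads must exceed the noise shift")
    return (
        total_candidates_of_gene
        / sum_of_exon_lengths_of_gene
        * (supporting_reads - constants.shift_noise) ** constants.slope_noise
        * constants.intercept_noise
    )


def depth_penalty(
    supporting_reads: int,
    mapped_reads: int,
    constants: NoiseConstants = NoiseConstants(),
) -> float:
    """Sequencing-depth penalty.

    Linear in the total number of mapped reads; each additional
    supporting read attenuates the slope by ``slope_modifier``.
    """
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be non-negative")
    return (
        constants.slope_depth
        * constants.slope_modifier ** supporting_reads
        * mapped_reads
    )


def distance_penalty(
    distance: int | None, constants: NoiseConstants = NoiseConstants()
) -> float:
    """Breakpoint-distance penalty.

    ``None`` (translocation) and distances at or above the 400 kb
    ceiling yield exactly 1 (no penalty).  Below the ceiling two
    polynomial fits apply, split at 400 bp.
    """
    if distance is None:
        return 1.0
    if distance <= 0:
        raise ValueError("distance must be positive")
    if distance >= constants.distance_penalty_ceiling:
        return 1.0
    if distance < constants.distance_regime_boundary:
        return (
            distance ** constants.slope_distance_near
            * constants.intercept_distance_near
        )
    return (
        distance ** constants.slope_distance_far
        * constants.intercept_distance_far
    )


def inv_to_dup_ratio(
    event_type: str,
    stats: GeneStats,
    constants: NoiseConstants = NoiseConstants(),
) -> float:
    """Event-composition penalty.

    Inversions and duplications are penalized in proportion to their
    relative frequency among all candidates; deletions and
    translocations are not penalized (factor 1).
    """
    if stats.total_candidates <= 0:
        return 1.0
    if event_type == EVENT_INVERSION:
        return stats.total_inversions / stats.total_candidates
    if event_type == EVENT_DUPLICATION:
        return stats.total_duplications / stats.total_candidates
    return 1.0


def intron_to_exon_ratio(
    site_classes: tuple[str, ...] | list[str],
    stats: GeneStats,
    constants: NoiseConstants = NoiseConstants(),
) -> float:
    """Breakpoint-location penalty.

    Each classified breakpoint contributes the observed frequency of its
    site class (intron/exon/splice site) among all classified
    breakpoints; the candidate-level factor is the product over its
    breakpoints.  Intergenic breakpoints contribute factor 1.
    """
    total = stats.total_classified_breakpoints
    if total <= 0:
        return 1.0
    factor = 1.0
    for site in site_classes:
        if site == SITE_INTRONIC:
            factor *= stats.total_intronic_candidates / total
        elif site == SITE_EXONIC:
            factor *= stats.total_exonic_candidates / total
        elif site == SITE_SPLICE:
            factor *= stats.total_spliced_candidates / total
        elif site == SITE_INTERGENIC:
            factor *= 1.0
        else:
            raise ValueError(f"unknown site class: {site}")
    return factor


def candidate_base_level(
    candidate: FusionCandidate,
    stats: GeneStats,
    annotation,
    constants: NoiseConstants = NoiseConstants(),
    intergenic_candidates: int = 1,
) -> float:
    """Base noise level of a candidate.

    The per-gene base level is defined per gene; for a two-gene
    candidate the maximum (most conservative) of the two genes' levels
    is used.  An intergenic breakpoint contributes a pseudo-gene window
    of ``INTERGENIC_WINDOW`` bp with the window length standing in for
    the exon length and ``intergenic_candidates`` for the candidate
    count observed in that window.
    """
    reads = candidate.supporting_reads
    levels = []
    for bp in (candidate.breakpoint5, candidate.breakpoint3):
        if bp.gene_id is not None:
            gene = annotation.genes[bp.gene_id]
            levels.append(
                base_level_bg_noise(
                    stats.total_candidates_of_gene[bp.gene_id],
                    gene.sum_of_exon_lengths,
                    reads,
                    constants,
                )
            )
        else:
            levels.append(
                base_level_bg_noise(
                    intergenic_candidates, INTERGENIC_WINDOW, reads, constants
                )
            )
    return max(levels)


def evalue(
    candidate: FusionCandidate,
    stats: GeneStats,
    annotation,
    constants: NoiseConstants = NoiseConstants(),
    mapped_reads: int | None = None,
    intergenic_candidates: int = 1,
) -> float:
    """Expected background-noise level (e-value) of a candidate.

    The product of the five model factors; stored on the candidate.
    """
    if mapped_reads is None:
        mapped_reads = stats.mapped_reads
    reads = candidate.supporting_reads
    value = (
        candidate_base_level(
            candidate, stats, annotation, constants, intergenic_candidates
        )
        * depth_penalty(reads, mapped_reads, constants)
        * distance_penalty(candidate.distance, constants)
        * inv_to_dup_ratio(candidate.event_type, stats, constants)
        * intron_to_exon_ratio(
            (candidate.breakpoint5.site, candidate.breakpoint3.site),
            stats,
            constants,
        )
    )
    candidate.evalue = value
    return value
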
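"""Assembly of chimeric alignments into fusion candidates.

Split reads with identical junction coordinates merge into one
candidate; discordant mates attach to a split-read candidate when their
orientations match and they fall within the insert-size window of the
junction, otherwise they form mate-only candidates.  Candidates are
classified by event type (deletion/duplication/inversion/translocation)
and by the site class of each breakpoint, and the covariate tallies
consumed by the background-noise model are collected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .annotation import (
    DIRECTION_LEFT,
    DIRECTION_RIGHT,
    SITE_EXONIC,
    SITE_INTERGENIC,
    SITE_INTRONIC,
    SITE_SPLICE,
    AnnotationIndex,
    GeneModel,
)
from .alignments import KIND_DISCORDANT, KIND_SPLIT, ChimericAlignment

EVENT_DELETION = "deletion"
EVENT_DUPLICATION = "duplication"
EVENT_INVERSION = "inversion"
EVENT_TRANSLOCATION = "translocation"


@dataclass
class Breakpoint:
    chromosome: str
    position: int  # 0-based internal
    direction: str  # left | right: side on which the partner attaches
    gene_id: str | None = None
    site: str = SITE_INTERGENIC

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.direction)


@dataclass
class FilterDecision:
    filter_name: str
    action: str  # pass | discard | rescue
    detail: str = ""


@dataclass
class FusionCandidate:
    breakpoint5: Breakpoint
    breakpoint3: Breakpoint
    split_reads5: int = 0
    split_reads3: int = 0
    discordant_mates: int = 0
    event_type: str = EVENT_TRANSLOCATION
    evalue: float | None = None
    filter_history: list[FilterDecision] = field(default_factory=list)
    confidence: str | None = None
    reads: list[ChimericAlignment] = field(default_factory=list)

    @property
    def supporting_reads(self) -> int:
        return self.split_reads5 + self.split_reads3 + self.discordant_mates

    @property
    def distance(self) -> int | None:
        if self.breakpoint5.chromosome != self.breakpoint3.chromosome:
            return None
        return abs(self.breakpoint5.position - self.breakpoint3.position)

    @property
    def discarded(self) -> bool:
        actions = [d.action for d in self.filter_history]
        return "discard" in actions and "rescue" not in actions

    @property
    def key(self) -> tuple:
        return self.breakpoint5.key + self.breakpoint3.key

    def gene_ids(self) -> list[str]:
        return [
            bp.gene_id
            for bp in (self.breakpoint5, self.breakpoint3)
            if bp.gene_id is not None
        ]


@dataclass
class GeneStats:
    """Covariate tallies consumed by the background-noise model."""

    total_candidates_of_gene: Counter = field(default_factory=Counter)
    total_candidates: int = 0
    total_inversions: int = 0
    total_duplications: int = 0
    total_intronic_candidates: int = 0
    total_exonic_candidates: int = 0
    total_spliced_candidates: int = 0
    mapped_reads: int = 0

    @property
    def total_classified_breakpoints(self) -> int:
        return (
            self.total_intronic_candidates
            + self.total_exonic_candidates
            + self.total_spliced_candidates
        )


def classify_site(breakpoint: Breakpoint, annotation: AnnotationIndex) -> str:
    """Site class of a breakpoint (splice/exonic/intronic/intergenic)."""
    gene = (
        annotation.genes.get(breakpoint.gene_id)
        if breakpoint.gene_id is not None
        else None
    )
    return annotation.classify_site(
        breakpoint.chromosome, breakpoint.position, breakpoint.direction, gene
    )


def classify_event_type(bp5: Breakpoint, bp3: Breakpoint) -> str:
    """Event type from breakpoint geometry.

    Different chromosomes give a translocation.  Equal directions give
    an inversion (one partner is joined in reversed orientation).  For
    opposite directions, the genomic segment between the breakpoints is
    lost when the left-directed breakpoint sits at the higher coordinate
    (deletion); otherwise the segment between them is traversed twice
    (duplication).
    """
    if bp5.chromosome != bp3.chromosome:
        return EVENT_TRANSLOCATION
    if bp5.direction == bp3.direction:
        return EVENT_INVERSION
    left_directed = bp5 if bp5.direction == DIRECTION_LEFT else bp3
    right_directed = bp3 if left_directed is bp5 else bp5
    if left_directed.position > right_directed.position:
        return EVENT_DELETION
    return EVENT_DUPLICATION


def _is_five_prime_compatible(bp: Breakpoint, gene: GeneModel | None) -> bool | None:
    """Whether the retained side of ``bp`` is its gene's 5' region.

    Returns ``None`` for intergenic breakpoints (no strand available).
    """
    if gene is None:
        return None
    if gene.strand == "+":
        return bp.direction == DIRECTION_RIGHT
    return bp.direction == DIRECTION_LEFT


def orient_breakpoints(
    bp_a: Breakpoint, bp_b: Breakpoint, annotation: AnnotationIndex
) -> tuple[Breakpoint, Breakpoint]:
    """Order two breakpoints as (5', 3') of the fused transcript.

    The 5' partner donates its transcription start: on the plus strand
    its retained side is to the left of the break (partner attaches
    right), mirrored on the minus strand.  When gene strands leave the
    order unresolved, the (chromosome, position) order is used.
    """
    gene_a = annotation.genes.get(bp_a.gene_id) if bp_a.gene_id else None
    gene_b = annotation.genes.get(bp_b.gene_id) if bp_b.gene_id else None
    five_a = _is_five_prime_compatible(bp_a, gene_a)
    five_b = _is_five_prime_compatible(bp_b, gene_b)
    if five_a is True and five_b is not True:
        return bp_a, bp_b
    if five_b is True and five_a is not True:
        return bp_b, bp_a
    if five_a is False and five_b is None:
        return bp_b, bp_a
    if five_b is False and five_a is None:
        return bp_a, bp_b
    if (bp_a.chromosome, bp_a.position) <= (bp_b.chromosome, bp_b.position):
        return bp_a, bp_b
    return bp_b, bp_a


def _make_breakpoint(
    chromosome: str, position: int, direction: str, annotation: AnnotationIndex
) -> Breakpoint:
    gene = annotation.assign_gene(chromosome, position)
    bp = Breakpoint(
        chromosome=chromosome,
        position=position,
        direction=direction,
        gene_id=gene.gene_id if gene else None,
    )
    bp.site = annotation.classify_site(chromosome, position, direction, gene)
    return bp


def _oriented_breakpoints(
    aln: ChimericAlignment, annotation: AnnotationIndex
) -> tuple[Breakpoint, Breakpoint, bool]:
    """Breakpoints of one alignment in (5', 3') order.

    The boolean reports whether the alignment's own segment order was
    swapped, which matters for anchor bookkeeping.
    """
    bp_a = _make_breakpoint(
        aln.segment5.chromosome, aln.junction5, aln.direction5, annotation
    )
    bp_b = _make_breakpoint(
        aln.segment3.chromosome, aln.junction3, aln.direction3, annotation
    )
    bp5, bp3 = orient_breakpoints(bp_a, bp_b, annotation)
    return bp5, bp3, bp5 is bp_b


def assemble_candidates(
    alignments: Iterable[ChimericAlignment],
    annotation: AnnotationIndex,
    mapped_reads: int = 0,
    mate_window: int = 500,
) -> tuple[list[FusionCandidate], GeneStats]:
    """Group chimeric alignments into fusion candidates and tally stats.

    Duplicate-flagged alignments are excluded from support.  The result
    is independent of the input order: candidates are keyed by exact
    junction coordinates (split reads) or by gene pair and directions
    (mate-only candidates) and returned sorted by breakpoint key.
    """
    split: list[tuple[Breakpoint, Breakpoint, ChimericAlignment, bool]] = []
    mates: list[tuple[Breakpoint, Breakpoint, ChimericAlignment]] = []
    for aln in alignments:
        if aln.duplicate_flag:
            continue
        if aln.kind == KIND_SPLIT:
            bp5, bp3, swapped = _oriented_breakpoints(aln, annotation)
            split.append((bp5, bp3, aln, swapped))
        else:
            bp5, bp3, _ = _oriented_breakpoints(aln, annotation)
            mates.append((bp5, bp3, aln))

    candidates: dict[tuple, FusionCandidate] = {}
    for bp5, bp3, aln, swapped in sorted(
        split, key=lambda t: (t[0].key, t[1].key, t[2].segment5.read_id)
    ):
        key = bp5.key + bp3.key
        cand = candidates.get(key)
        if cand is None:
            cand = FusionCandidate(breakpoint5=bp5, breakpoint3=bp3)
            cand.event_type = classify_event_type(bp5, bp3)
            candidates[key] = cand
        anchor5 = aln.anchor3 if swapped else aln.anchor5
        anchor3 = aln.anchor5 if swapped else aln.anchor3
        if anchor5 >= anchor3:
            cand.split_reads5 += 1
        else:
            cand.split_reads3 += 1
        cand.reads.append(aln.swapped() if swapped else aln)

    ordered = [candidates[k] for k in sorted(candidates)]

    unattached: list[tuple[Breakpoint, Breakpoint, ChimericAlignment]] = []
    for bp5, bp3, aln in sorted(
        mates, key=lambda t: (t[0].key, t[1].key, t[2].segment5.read_id)
    ):
        best = None
        for cand in ordered:
            gap = _mate_attachment_gap(bp5, bp3, cand, mate_window)
            if gap is not None and (best is None or gap < best[0]):
                best = (gap, cand)
        if best is not None:
            best[1].discordant_mates += 1
            best[1].reads.append(aln)
        else:
            unattached.append((bp5, bp3, aln))

    mate_only: dict[tuple, FusionCandidate] = {}
    for bp5, bp3, aln in unattached:
        key = (
            bp5.gene_id or bp5.chromosome,
            bp3.gene_id or bp3.chromosome,
            bp5.direction,
            bp3.direction,
        )
        cand = mate_only.get(key)
        if cand is None:
            cand = FusionCandidate(breakpoint5=bp5, breakpoint3=bp3)
            mate_only[key] = cand
        else:
            cand.breakpoint5 = _extreme_breakpoint(cand.breakpoint5, bp5)
            cand.breakpoint3 = _extreme_breakpoint(cand.breakpoint3, bp3)
        cand.discordant_mates += 1
        cand.reads.append(aln)
    for cand in mate_only.values():
        for bp in (cand.breakpoint5, cand.breakpoint3):
            bp.site = classify_site(bp, annotation)
        cand.event_type = classify_event_type(cand.breakpoint5, cand.breakpoint3)

    ordered.extend(mate_only[k] for k in sorted(mate_only))
    ordered.sort(key=lambda c: c.key)
    stats = tally_gene_stats(ordered, annotation, mapped_reads)
    return ordered, stats


def _extreme_breakpoint(current: Breakpoint, new: Breakpoint) -> Breakpoint:
    """Innermost junction estimate from a set of discordant mates.

    Mates stop short of the junction, so the mate alignment reaching
    furthest toward the attachment side gives the tightest bound: the
    maximum position for direction ``right``, the minimum for ``left``.
    """
    if current.direction == DIRECTION_RIGHT:
        return new if new.position > current.position else current
    return new if new.position < current.position else current


def _mate_attachment_gap(
    bp5: Breakpoint, bp3: Breakpoint, cand: FusionCandidate, window: int
) -> int | None:
    """Total breakpoint distance of a mate pair to a candidate, or None
    when the pair does not support the candidate's junction.

    Both end pairings are tried (with equal directions, as in an
    inversion, either mate may flank either junction); the smaller
    matching gap wins.  A candidate is matched when, for one pairing,
    both mates agree in chromosome and direction and lie within the
    insert-size window of the respective junctions.
    """
    best: int | None = None
    for pair in ((bp5, bp3), (bp3, bp5)):
        gap = 0
        for bp, cbp in zip(pair, (cand.breakpoint5, cand.breakpoint3)):
            if bp.chromosome != cbp.chromosome or bp.direction != cbp.direction:
                gap = None
                break
            delta = abs(bp.position - cbp.position)
            if delta > window:
                gap = None
                break
            gap += delta
        if gap is not None and (best is None or gap < best):
            best = gap
    return best


def tally_gene_stats(
    candidates: Iterable[FusionCandidate],
    annotation: AnnotationIndex,
    mapped_reads: int = 0,
) -> GeneStats:
    """Recount all noise-model covariates from a candidate list.

    Every candidate increments the grand total once and the
    inversion/duplication tallies by event type; every genic breakpoint
    increments its gene's candidate count and exactly one of the
    intron/exon/splice tallies.  Intergenic breakpoints contribute to no
    per-gene or site tally.
    """
    stats = GeneStats(mapped_reads=mapped_reads)
    for cand in candidates:
        stats.total_candidates += 1
        if cand.event_type == EVENT_INVERSION:
            stats.total_inversions += 1
        elif cand.event_type == EVENT_DUPLICATION:
            stats.total_duplications += 1
        for bp in (cand.breakpoint5, cand.breakpoint3):
            if bp.gene_id is None:
                continue
            stats.total_candidates_of_gene[bp.gene_id] += 1
            if bp.site == SITE_SPLICE:
                stats.total_spliced_candidates += 1
            elif bp.site == SITE_EXONIC:
                stats.total_exonic_candidates += 1
            elif bp.site == SITE_INTRONIC:
                stats.total_intronic_candidates += 1
    return stats
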
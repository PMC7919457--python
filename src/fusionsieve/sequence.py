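"""Fused transcript sequence and peptide prediction.

For each kept fusion the junction-flanking transcript sequence is
assembled — spliced across the retained exons of the highest-priority
annotated transcript when the breakpoint sits on a splice site, plain
genomic sequence otherwise — with both sides oriented so that the
output reads 5'->3' across the junction.  The fusion peptide is
translated from the 5' partner's annotated start codon through the
junction into the retained 3' sequence; the reading frame is called
in-frame when the 3' partner's annotated coding frame is preserved at
the junction.  The flanking sequence supports primer design for
validation; the peptide is a basis for neoepitope prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import Seq

from .annotation import (
    DIRECTION_RIGHT,
    SITE_SPLICE,
    AnnotationIndex,
    GeneModel,
    Transcript,
)
from .candidates import Breakpoint, FusionCandidate

FRAME_IN = "in-frame"
FRAME_OUT = "out-of-frame"
FRAME_UNKNOWN = "unknown"


@dataclass
class FusionTranscript:
    """Junction-flanking sequence, both halves in fusion orientation."""

    sequence5: str
    sequence3: str
    transcript5: str | None = None
    transcript3: str | None = None

    @property
    def marked(self) -> str:
        return f"{self.sequence5}|{self.sequence3}"


@dataclass
class PeptidePrediction:
    peptide: str
    frame_status: str
    #: index of the stop codon in amino acids downstream of the
    #: junction (negative: stop upstream of the junction); None if
    #: translation runs through
    stop_relative_to_junction: int | None = None


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def pick_transcript(
    gene: GeneModel, position: int, require_cds: bool = False
) -> Transcript | None:
    """Deterministic transcript choice at a breakpoint.

    Transcripts whose span contains the position are preferred; among
    those, the longest coding sequence wins, then the longest transcript,
    then the lexicographically smallest identifier.
    """
    candidates = list(gene.transcripts.values())
    if require_cds:
        candidates = [tx for tx in candidates if tx.cds]
    if not candidates:
        return None
    candidates.sort(
        key=lambda tx: (
            not (tx.exons and tx.exons[0][0] <= position < tx.exons[-1][1]),
            -tx.cds_length,
            -tx.exonic_length,
            tx.transcript_id,
        )
    )
    return candidates[0]


def _chrom_seq(genome: Mapping, chromosome: str) -> str:
    return str(genome[chromosome]).upper()


def _spliced_retained(
    tx: Transcript, chrom_seq: str, position: int, retained: str, flank: int
) -> str:
    """Spliced sequence on the retained side of a breakpoint, in
    genomic orientation, crossing as many exons as the flank needs."""
    pieces: list[str] = []
    remaining = flank
    if retained == "left":
        for start, end in reversed(tx.exons):
            if start > position:
                continue
            hi = min(end, position + 1)
            lo = max(start, hi - remaining)
            pieces.append(chrom_seq[lo:hi])
            remaining -= hi - lo
            if remaining <= 0:
                break
        return "".join(reversed(pieces))
    for start, end in tx.exons:
        if end <= position:
            continue
        lo = max(start, position)
        hi = min(end, lo + remaining)
        pieces.append(chrom_seq[lo:hi])
        remaining -= hi - lo
        if remaining <= 0:
            break
    return "".join(pieces)


def _side_sequence(
    bp: Breakpoint,
    annotation: AnnotationIndex,
    genome: Mapping,
    flank: int,
    is_five_prime: bool,
) -> tuple[str, str | None]:
    chrom_seq = _chrom_seq(genome, bp.chromosome)
    if not 0 <= bp.position < len(chrom_seq):
        raise IndexError(
            f"breakpoint {bp.chromosome}:{bp.position + 1} outside genome"
        )
    retained = "left" if bp.direction == DIRECTION_RIGHT else "right"
    tx_id = None
    if bp.site == SITE_SPLICE and bp.gene_id is not None:
        tx = pick_transcript(annotation.genes[bp.gene_id], bp.position)
        if tx is not None:
            seq = _spliced_retained(tx, chrom_seq, bp.position, retained, flank)
            tx_id = tx.transcript_id
        else:
            seq = _genomic_retained(chrom_seq, bp.position, retained, flank)
    else:
        seq = _genomic_retained(chrom_seq, bp.position, retained, flank)
    # orient: the 5' half must end at the junction, the 3' half start at it
    if is_five_prime:
        return (seq if retained == "left" else _revcomp(seq)), tx_id
    return (seq if retained == "right" else _revcomp(seq)), tx_id


def _genomic_retained(
    chrom_seq: str, position: int, retained: str, flank: int
) -> str:
    if retained == "left":
        return chrom_seq[max(0, position + 1 - flank): position + 1]
    return chrom_seq[position: position + flank]


def junction_flanking_sequence(
    candidate: FusionCandidate,
    genome: Mapping,
    annotation: AnnotationIndex,
    flank: int = 200,
) -> FusionTranscript:
    """Transcript sequence flanking the junction, 5'->3' across it."""
    seq5, tx5 = _side_sequence(
        candidate.breakpoint5, annotation, genome, flank, True
    )
    seq3, tx3 = _side_sequence(
        candidate.breakpoint3, annotation, genome, flank, False
    )
    return FusionTranscript(
        sequence5=seq5, sequence3=seq3, transcript5=tx5, transcript3=tx3
    )


def _coding_before_junction(
    tx: Transcript, chrom_seq: str, strand: str, position: int
) -> str:
    """Coding sequence of a transcript from its start codon up to and
    including the junction base, in transcript orientation."""
    if strand == "+":
        pieces = [
            chrom_seq[s: min(e, position + 1)]
            for s, e in tx.cds
            if s <= position
        ]
        return "".join(pieces)
    pieces = [
        chrom_seq[max(s, position): e]
        for s, e in reversed(tx.cds)
        if e > position
    ]
    return "".join(_revcomp(p) for p in pieces)


def _coding_length_strictly_before(
    tx: Transcript, strand: str, position: int
) -> int | None:
    """Number of coding bases preceding ``position`` in transcript
    orientation, or None when the position is not inside the CDS."""
    inside = any(s <= position < e for s, e in tx.cds)
    if not inside:
        return None
    if strand == "+":
        return sum(min(e, position) - s for s, e in tx.cds if s < position)
    return sum(e - max(s, position + 1) for s, e in tx.cds if e > position)


def _retained_transcript_tail(
    tx: Transcript, chrom_seq: str, strand: str, position: int
) -> str:
    """Spliced exonic sequence of the 3' partner from the junction to
    the transcript end, in transcript orientation."""
    if strand == "+":
        pieces = [
            chrom_seq[max(s, position): e] for s, e in tx.exons if e > position
        ]
        return "".join(pieces)
    pieces = [
        chrom_seq[s: min(e, position + 1)]
        for s, e in reversed(tx.exons)
        if s <= position
    ]
    return "".join(_revcomp(p) for p in pieces)


def predict_peptide(
    candidate: FusionCandidate,
    genome: Mapping,
    annotation: AnnotationIndex,
) -> PeptidePrediction:
    """Translate the fused transcript from the 5' partner's start codon.

    Standard-code translation stops at the first stop codon.  The frame
    is in-frame when the number of 5'-partner coding bases modulo 3
    equals the 3' partner's annotated codon phase at the junction,
    out-of-frame when it does not, and unknown when either partner
    lacks a usable annotated coding sequence at its breakpoint.
    """
    bp5, bp3 = candidate.breakpoint5, candidate.breakpoint3
    if bp5.gene_id is None:
        return PeptidePrediction("", FRAME_UNKNOWN)
    gene5 = annotation.genes[bp5.gene_id]
    tx5 = pick_transcript(gene5, bp5.position, require_cds=True)
    if tx5 is None:
        return PeptidePrediction("", FRAME_UNKNOWN)
    chrom5 = _chrom_seq(genome, bp5.chromosome)
    coding5 = _coding_before_junction(tx5, chrom5, gene5.strand, bp5.position)
    if not coding5:
        return PeptidePrediction("", FRAME_UNKNOWN)

    tail3 = ""
    frame_status = FRAME_UNKNOWN
    if bp3.gene_id is not None:
        gene3 = annotation.genes[bp3.gene_id]
        tx3 = pick_transcript(gene3, bp3.position, require_cds=True)
        chrom3 = _chrom_seq(genome, bp3.chromosome)
        if tx3 is not None:
            tail3 = _retained_transcript_tail(
                tx3, chrom3, gene3.strand, bp3.position
            )
            phase3 = _coding_length_strictly_before(
                tx3, gene3.strand, bp3.position
            )
            if phase3 is not None:
                frame_status = (
                    FRAME_IN
                    if len(coding5) % 3 == phase3 % 3
                    else FRAME_OUT
                )

    full = coding5 + tail3
    usable = full[: len(full) - len(full) % 3]
    translated = str(Seq(usable).translate())
    junction_aa = (len(coding5) + 2) // 3  # codon index containing the junction
    stop_index = translated.find("*")
    if stop_index >= 0:
        peptide = translated[:stop_index]
        stop_rel = stop_index - junction_aa
    else:
        peptide = translated
        stop_rel = None
    return PeptidePrediction(
        peptide=peptide,
        frame_status=frame_status,
        stop_relative_to_junction=stop_rel,
    )
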
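"""Extraction of chimeric alignments from SAM streams.

Two kinds of fusion evidence are collected: split reads (one read with
two noncontiguously aligned segments, written by the aligner as a
primary plus a supplementary record) and discordant mates (read pairs
whose mates align in a nonlinear configuration).  Additionally, gapped
alignments whose gap crosses a gene boundary are converted into
synthetic split reads so that fusions caused by focal deletions — which
the aligner encodes as intron-like gaps — are not missed.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from .annotation import DIRECTION_LEFT, DIRECTION_RIGHT, AnnotationIndex

KIND_SPLIT = "split_read"
KIND_DISCORDANT = "discordant_mates"

MODE_SEPARATE = "separate_file"
MODE_WITHIN_MAIN = "within_main"

#: minimum inner distance for a same-chromosome, properly oriented pair
#: to count as discordant when scanning a full alignment stream
DISCORDANT_MIN_DISTANCE = 2000


@dataclass
class AlignmentSegment:
    """One aligned segment of a (possibly chimeric) read."""

    read_id: str
    chromosome: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'
    aligned_length: int  # reference span of match/deletion operators
    left_clip: int
    right_clip: int
    mismatches: int
    sequence: str = ""  # SAM orientation; may be empty for hard clips

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty segment {self.chromosome}:{self.start}")
        if self.left_clip < 0 or self.right_clip < 0:
            raise ValueError("negative clip length")

    @property
    def read_start(self) -> int:
        """Offset of the aligned part within the original read."""
        return self.left_clip if self.strand == "+" else self.right_clip


@dataclass
class ChimericAlignment:
    """One read (or read pair) supporting a putative fusion junction."""

    kind: str  # split_read | discordant_mates
    segment5: AlignmentSegment
    segment3: AlignmentSegment
    junction5: int  # 0-based position where the 5' segment ends
    junction3: int  # 0-based position where the 3' segment begins
    direction5: str  # side on which the fused partner attaches
    direction3: str
    anchor5: int
    anchor3: int
    duplicate_flag: bool = False

    def swapped(self) -> "ChimericAlignment":
        return ChimericAlignment(
            kind=self.kind,
            segment5=self.segment3,
            segment3=self.segment5,
            junction5=self.junction3,
            junction3=self.junction5,
            direction5=self.direction3,
            direction3=self.direction5,
            anchor5=self.anchor3,
            anchor3=self.anchor5,
            duplicate_flag=self.duplicate_flag,
        )


def _segment_from_record(rec: pysam.AlignedSegment) -> AlignmentSegment:
    cig = rec.cigartuples or []
    left_clip = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    right_clip = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    try:
        nm = int(rec.get_tag("NM"))
    except KeyError:
        nm = 0
    return AlignmentSegment(
        read_id=rec.query_name,
        chromosome=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        aligned_length=rec.reference_end - rec.reference_start,
        left_clip=left_clip,
        right_clip=right_clip,
        mismatches=nm,
        sequence=rec.query_sequence or "",
    )


def _split_read_from_segments(
    seg_a: AlignmentSegment, seg_b: AlignmentSegment, duplicate: bool
) -> ChimericAlignment:
    """Order two segments of one read along the read and derive the
    junction coordinates.

    The segment covering the earlier part of the read forms the 5' side
    of the fused transcript as sequenced.  The fused partner attaches
    where the read continues past a segment: to the right of a
    plus-strand 5' segment, to the left of a minus-strand one, and
    conversely for the 3' segment.
    """
    first, second = (
        (seg_a, seg_b) if seg_a.read_start <= seg_b.read_start else (seg_b, seg_a)
    )
    if first.strand == "+":
        junction5, direction5 = first.end - 1, DIRECTION_RIGHT
    else:
        junction5, direction5 = first.start, DIRECTION_LEFT
    if second.strand == "+":
        junction3, direction3 = second.start, DIRECTION_LEFT
    else:
        junction3, direction3 = second.end - 1, DIRECTION_RIGHT
    return ChimericAlignment(
        kind=KIND_SPLIT,
        segment5=first,
        segment3=second,
        junction5=junction5,
        junction3=junction3,
        direction5=direction5,
        direction3=direction3,
        anchor5=first.aligned_length,
        anchor3=second.aligned_length,
        duplicate_flag=duplicate,
    )


def _discordant_from_mates(
    mate1: pysam.AlignedSegment, mate2: pysam.AlignedSegment
) -> ChimericAlignment:
    """Build a discordant-mate record.

    Each mate points toward the junction with its 3' end: the junction
    lies to the right of a plus-strand mate and to the left of a
    minus-strand mate.
    """
    segs = []
    for rec in (mate1, mate2):
        seg = _segment_from_record(rec)
        if rec.is_reverse:
            junction, direction = seg.start, DIRECTION_LEFT
        else:
            junction, direction = seg.end - 1, DIRECTION_RIGHT
        segs.append((seg, junction, direction))
    segs.sort(key=lambda t: (t[0].chromosome, t[1]))
    (seg5, j5, d5), (seg3, j3, d3) = segs
    return ChimericAlignment(
        kind=KIND_DISCORDANT,
        segment5=seg5,
        segment3=seg3,
        junction5=j5,
        junction3=j3,
        direction5=d5,
        direction3=d3,
        anchor5=seg5.aligned_length,
        anchor3=seg3.aligned_length,
        duplicate_flag=mate1.is_duplicate or mate2.is_duplicate,
    )


def _pair_is_discordant(
    mate1: pysam.AlignedSegment, mate2: pysam.AlignedSegment, mode: str
) -> bool:
    if mate1.reference_name != mate2.reference_name:
        return True
    if mate1.is_reverse == mate2.is_reverse:
        return True
    if mode == MODE_SEPARATE:
        # a dedicated chimeric stream contains only chimeric records
        return True
    if mate1.is_proper_pair:
        return False
    distance = max(mate1.reference_start, mate2.reference_start) - min(
        mate1.reference_end, mate2.reference_end
    )
    return distance > DISCORDANT_MIN_DISTANCE


def read_chimeric_alignments(
    sam_path: str | os.PathLike, mode: str = MODE_SEPARATE
) -> Iterator[ChimericAlignment]:
    """Yield one :class:`ChimericAlignment` per supporting read or pair.

    ``mode`` selects between a dedicated chimeric-alignment file (every
    record is part of a chimeric read) and a full alignment stream in
    which chimeric records are recognized by supplementary-alignment
    flags and improper pair geometry.  PCR/optical duplicate flags are
    propagated; non-chimeric records are skipped silently.
    """
    if mode not in (MODE_SEPARATE, MODE_WITHIN_MAIN):
        raise ValueError(f"unknown mode: {mode}")
    groups: dict[str, list[pysam.AlignedSegment]] = {}
    try:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary:
                    continue
                groups.setdefault(rec.query_name, []).append(rec)
    except (NotImplementedError, OSError) as exc:
        raise ValueError(f"malformed SAM {sam_path}: {exc}") from exc

    for name in sorted(groups):
        records = groups[name]
        # split reads: primary + supplementary of the same mate
        for mate_bit in (None, True, False):
            prim = [
                r
                for r in records
                if not r.is_supplementary
                and (mate_bit is None and not r.is_paired
                     or mate_bit is True and r.is_paired and r.is_read1
                     or mate_bit is False and r.is_paired and r.is_read2)
            ]
            supp = [
                r
                for r in records
                if r.is_supplementary
                and (mate_bit is None and not r.is_paired
                     or mate_bit is True and r.is_paired and r.is_read1
                     or mate_bit is False and r.is_paired and r.is_read2)
            ]
            if supp and not prim:
                warnings.warn(
                    f"supplementary alignment of {name} without primary; dropped"
                )
                continue
            if prim and supp:
                dup = prim[0].is_duplicate or supp[0].is_duplicate
                yield _split_read_from_segments(
                    _segment_from_record(prim[0]),
                    _segment_from_record(supp[0]),
                    dup,
                )
        # discordant mates: both primaries present, no supplementary
        if any(r.is_supplementary for r in records):
            continue
        mates1 = [r for r in records if r.is_paired and r.is_read1]
        mates2 = [r for r in records if r.is_paired and r.is_read2]
        if mates1 and mates2:
            m1, m2 = mates1[0], mates2[0]
            if _pair_is_discordant(m1, m2, mode):
                yield _discordant_from_mates(m1, m2)


def mark_duplicates(
    alignments: Iterable[ChimericAlignment],
) -> list[ChimericAlignment]:
    """Flag unmarked PCR duplicates.

    Alignments with identical segment coordinates, strands and clipping
    are copies of the same original fragment; all but the first are
    flagged as duplicates.
    """
    seen: set[tuple] = set()
    out = []
    for aln in alignments:
        key = (
            aln.kind,
            aln.segment5.chromosome, aln.segment5.start, aln.segment5.end,
            aln.segment5.strand, aln.segment5.left_clip,
            aln.segment3.chromosome, aln.segment3.start, aln.segment3.end,
            aln.segment3.strand, aln.segment3.left_clip,
        )
        if not aln.duplicate_flag and key in seen:
            aln.duplicate_flag = True
        seen.add(key)
        out.append(aln)
    return out


def count_mapped_reads(sam_path: str | os.PathLike) -> int:
    """Number of mapped, primary, non-duplicate records.

    Mate pairs count as two reads; supplementary and secondary records
    are not counted.
    """
    count = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_duplicate:
                continue
            count += 1
    return count


@dataclass
class _CigarSide:
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int


def detect_boundary_spanning(
    sam_path: str | os.PathLike,
    annotation: AnnotationIndex,
    max_intron: int | None = None,
) -> list[ChimericAlignment]:
    """Convert gene-boundary-spanning gapped alignments into synthetic
    split reads.

    Aligners encode small focal deletions as intron-like gaps (``N``
    operators) because the decision between "intron" and "chimeric" is
    made purely on gap size.  A gap whose two flanks are assigned to
    different genes is fusion evidence and is re-emitted here as a
    split-read chimeric alignment with junctions at the gap edges; gaps
    within a single gene are normal splicing and are ignored.
    """
    out: list[ChimericAlignment] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cig = rec.cigartuples or []
            if not any(op == 3 for op, _ in cig):
                continue
            for aln in _split_gapped_record(rec, cig, annotation, max_intron):
                out.append(aln)
    return out


def _split_gapped_record(
    rec: pysam.AlignedSegment,
    cig: list[tuple[int, int]],
    annotation: AnnotationIndex,
    max_intron: int | None,
) -> Iterator[ChimericAlignment]:
    chrom = rec.reference_name
    ref = rec.reference_start
    read = 0
    sides: list[_CigarSide] = [_CigarSide(ref, ref, read, read)]
    gaps: list[int] = []
    for op, length in cig:
        if op == 3:  # N: start a new side after the gap
            if max_intron is not None and length > max_intron:
                pass  # oversized gaps would be chimeric already
            ref += length
            gaps.append(length)
            sides.append(_CigarSide(ref, ref, read, read))
            continue
        consumes_ref = op in (0, 2, 7, 8)
        consumes_read = op in (0, 1, 4, 7, 8)
        if consumes_ref:
            sides[-1].ref_end = ref + length
            ref += length
        if consumes_read:
            if op != 4:
                sides[-1].read_end = read + length
            read += length
    seq = rec.query_sequence or ""
    strand = "-" if rec.is_reverse else "+"
    for left, right in zip(sides, sides[1:]):
        gene_left = annotation.assign_gene(chrom, left.ref_end - 1)
        gene_right = annotation.assign_gene(chrom, right.ref_start)
        if (
            gene_left is None
            or gene_right is None
            or gene_left.gene_id == gene_right.gene_id
        ):
            continue
        seg5 = AlignmentSegment(
            read_id=rec.query_name,
            chromosome=chrom,
            start=left.ref_start,
            end=left.ref_end,
            strand=strand,
            aligned_length=left.ref_end - left.ref_start,
            left_clip=left.read_start,
            right_clip=max(0, len(seq) - left.read_end) if seq else 0,
            mismatches=0,
            sequence=seq,
        )
        seg3 = AlignmentSegment(
            read_id=rec.query_name,
            chromosome=chrom,
            start=right.ref_start,
            end=right.ref_end,
            strand=strand,
            aligned_length=right.ref_end - right.ref_start,
            left_clip=right.read_start,
            right_clip=max(0, len(seq) - right.read_end) if seq else 0,
            mismatches=0,
            sequence=seq,
        )
        yield ChimericAlignment(
            kind=KIND_SPLIT,
            segment5=seg5,
            segment3=seg3,
            junction5=left.ref_end - 1,
            junction3=right.ref_start,
            direction5=DIRECTION_RIGHT,
            direction3=DIRECTION_LEFT,
            anchor5=seg5.aligned_length,
            anchor3=seg3.aligned_length,
            duplicate_flag=rec.is_duplicate,
        )
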
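"""Tabular input/output: structural variants (BEDPE), blacklist and
whitelist TSVs, and the fusion-call result table."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

import pandas as pd

from .annotation import DIRECTION_LEFT, DIRECTION_RIGHT
from .candidates import FusionCandidate

CONFIDENCE_ORDER = {"high": 0, "medium": 1, "low": 2}

FUSION_CALL_COLUMNS = [
    "gene5", "gene3", "breakpoint5", "breakpoint3",
    "direction5", "direction3", "event_type", "site5", "site3",
    "split_reads5", "split_reads3", "discordant_mates",
    "evalue", "confidence", "filters",
    "fusion_transcript_sequence", "peptide_sequence", "reading_frame",
]


@dataclass
class StructuralVariant:
    """One genomic rearrangement call used for corroboration."""

    chrom1: str
    pos1: int  # 1-based
    orientation1: str  # left | right: side on which the partner attaches
    chrom2: str
    pos2: int
    orientation2: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError("structural-variant positions are 1-based")
        if self.orientation1 not in (DIRECTION_LEFT, DIRECTION_RIGHT):
            raise ValueError(f"bad orientation: {self.orientation1}")
        if self.orientation2 not in (DIRECTION_LEFT, DIRECTION_RIGHT):
            raise ValueError(f"bad orientation: {self.orientation2}")


@dataclass
class BlacklistEntry:
    """One recurrent-artifact pattern.

    ``position_pair`` entries match candidates whose two breakpoints
    both lie within ``tolerance`` bp of the listed positions (in either
    order); ``gene_pair`` entries match by unordered gene names;
    ``region`` entries match any candidate with a breakpoint inside the
    region.
    """

    kind: str  # position_pair | gene_pair | region
    chrom1: str | None = None
    pos1: int | None = None  # 0-based internally
    chrom2: str | None = None
    pos2: int | None = None
    gene1: str | None = None
    gene2: str | None = None
    region_start: int | None = None
    region_end: int | None = None
    tolerance: int = 100

    def matches(
        self, cand: FusionCandidate, gene_names: Iterable[str] = ()
    ) -> bool:
        """``gene_names``: identifiers and display names of the
        candidate's two genes (gene-pair entries may list either)."""
        bp5, bp3 = cand.breakpoint5, cand.breakpoint3
        if self.kind == "gene_pair":
            names = {bp.gene_id for bp in (bp5, bp3) if bp.gene_id}
            names.update(gene_names)
            return {self.gene1, self.gene2} <= names
        if self.kind == "position_pair":
            return _pair_hit(self, bp5, bp3) or _pair_hit(self, bp3, bp5)
        if self.kind == "region":
            for bp in (bp5, bp3):
                if (
                    bp.chromosome == self.chrom1
                    and self.region_start <= bp.position < self.region_end
                ):
                    return True
            return False
        raise ValueError(f"unknown blacklist entry kind: {self.kind}")


def _pair_hit(entry: BlacklistEntry, bp_a, bp_b) -> bool:
    return (
        bp_a.chromosome == entry.chrom1
        and abs(bp_a.position - entry.pos1) <= entry.tolerance
        and bp_b.chromosome == entry.chrom2
        and abs(bp_b.position - entry.pos2) <= entry.tolerance
    )


def read_structural_variants(
    source: str | os.PathLike | IO[str],
) -> list[StructuralVariant]:
    """Read BEDPE rows into structural variants.

    Each interval collapses to its midpoint (1-based).  Strand ``+`` at
    an end means the partner attaches to the right of the position,
    ``-`` to the left.
    """
    lines = _as_lines(source)
    out: list[StructuralVariant] = []
    for number, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 10:
            raise ValueError(
                f"BEDPE row {number} has {len(parts)} columns, expected >= 10"
            )
        chrom1, start1, end1, chrom2, start2, end2, name, _score, s1, s2 = parts[:10]
        pos1 = (int(start1) + int(end1) + 1) // 2  # midpoint, 1-based
        pos2 = (int(start2) + int(end2) + 1) // 2
        out.append(
            StructuralVariant(
                chrom1=chrom1,
                pos1=max(1, pos1),
                orientation1=DIRECTION_RIGHT if s1 == "+" else DIRECTION_LEFT,
                chrom2=chrom2,
                pos2=max(1, pos2),
                orientation2=DIRECTION_RIGHT if s2 == "+" else DIRECTION_LEFT,
                source=name,
            )
        )
    return out


def write_structural_variants(
    svs: Iterable[StructuralVariant], stream: IO[str]
) -> None:
    for sv in svs:
        stream.write(
            "\t".join(
                [
                    sv.chrom1, str(sv.pos1 - 1), str(sv.pos1),
                    sv.chrom2, str(sv.pos2 - 1), str(sv.pos2),
                    sv.source or ".", ".",
                    "+" if sv.orientation1 == DIRECTION_RIGHT else "-",
                    "+" if sv.orientation2 == DIRECTION_RIGHT else "-",
                ]
            )
            + "\n"
        )


def _parse_position(token: str) -> tuple[str, int]:
    chrom, pos = token.rsplit(":", 1)
    return chrom, int(pos) - 1  # to 0-based


def read_breakpoint_lists(
    blacklist_stream: IO[str] | None,
    whitelist_stream: IO[str] | None,
    default_tolerance: int = 100,
) -> tuple[list[BlacklistEntry], set[frozenset]]:
    """Parse the blacklist and whitelist TSVs.

    Blacklist rows are either two ``chrom:pos`` tokens (position pair,
    optional third column = tolerance in bp), two gene names (gene
    pair), or a single ``chrom:start-end`` region.  Whitelist rows are
    two gene names; matching is symmetric in gene order.  Unparseable
    rows are skipped with a warning.
    """
    blacklist: list[BlacklistEntry] = []
    if blacklist_stream is not None:
        for number, raw in enumerate(_as_lines(blacklist_stream), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                blacklist.append(_parse_blacklist_row(line, default_tolerance))
            except (ValueError, IndexError) as exc:
                warnings.warn(f"blacklist row {number} skipped: {exc}")
    whitelist: set[frozenset] = set()
    if whitelist_stream is not None:
        for raw in _as_lines(whitelist_stream):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) >= 2:
                whitelist.add(frozenset(parts[:2]))
    return blacklist, whitelist


def _parse_blacklist_row(line: str, default_tolerance: int) -> BlacklistEntry:
    parts = line.split("\t")
    if len(parts) == 1:
        chrom, span = parts[0].rsplit(":", 1)
        start, end = span.split("-")
        return BlacklistEntry(
            kind="region",
            chrom1=chrom,
            region_start=int(start) - 1,
            region_end=int(end),
        )
    first, second = parts[0], parts[1]
    if ":" in first and ":" in second:
        chrom1, pos1 = _parse_position(first)
        chrom2, pos2 = _parse_position(second)
        tolerance = int(parts[2]) if len(parts) > 2 else default_tolerance
        return BlacklistEntry(
            kind="position_pair",
            chrom1=chrom1, pos1=pos1,
            chrom2=chrom2, pos2=pos2,
            tolerance=tolerance,
        )
    return BlacklistEntry(kind="gene_pair", gene1=first, gene2=second)


@dataclass
class FusionCall:
    """A kept fusion candidate with its final annotation fields."""

    candidate: FusionCandidate
    gene5: str = "."
    gene3: str = "."
    fusion_transcript_sequence: str = "."
    peptide_sequence: str = "."
    reading_frame: str = "unknown"

    def row(self) -> list[str]:
        cand = self.candidate
        bp5, bp3 = cand.breakpoint5, cand.breakpoint3
        return [
            self.gene5,
            self.gene3,
            f"{bp5.chromosome}:{bp5.position + 1}",
            f"{bp3.chromosome}:{bp3.position + 1}",
            bp5.direction,
            bp3.direction,
            cand.event_type,
            bp5.site,
            bp3.site,
            str(cand.split_reads5),
            str(cand.split_reads3),
            str(cand.discordant_mates),
            repr(cand.evalue) if cand.evalue is not None else ".",
            cand.confidence or ".",
            ",".join(
                f"{d.filter_name}:{d.action}" for d in cand.filter_history
            )
            or ".",
            self.fusion_transcript_sequence,
            self.peptide_sequence,
            self.reading_frame,
        ]


def sort_fusion_calls(calls: list[FusionCall]) -> list[FusionCall]:
    return sorted(
        calls,
        key=lambda call: (
            CONFIDENCE_ORDER.get(call.candidate.confidence or "low", 3),
            -call.candidate.supporting_reads,
            call.gene5,
            call.gene3,
            call.candidate.key,
        ),
    )


def write_fusion_calls(calls: Iterable[FusionCall], stream: IO[str]) -> None:
    """Write the result TSV, sorted by confidence, support, gene names."""
    stream.write("\t".join(FUSION_CALL_COLUMNS) + "\n")
    for call in sort_fusion_calls(list(calls)):
        stream.write("\t".join(call.row()) + "\n")


def read_fusion_calls(source: str | os.PathLike | IO[str]) -> pd.DataFrame:
    """Re-parse a fusion-call TSV (all columns as strings)."""
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)


def _as_lines(source) -> Iterable[str]:
    if hasattr(source, "read"):
        return source
    with open(source) as handle:
        return handle.readlines()
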
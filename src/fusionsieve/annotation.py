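"""Gene-model index built from a GTF annotation.

Coordinates are converted to 0-based half-open intervals on read; all
printed output elsewhere in the package converts back to the 1-based
convention of GTF/SAM.  Splice-site sets record *internal* exon
boundaries only (a transcript's outermost ends are not donor/acceptor
sites).
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

import gffutils
from intervaltree import IntervalTree

SITE_SPLICE = "splice_site"
SITE_EXONIC = "exonic"
SITE_INTRONIC = "intronic"
SITE_INTERGENIC = "intergenic"

DIRECTION_LEFT = "left"
DIRECTION_RIGHT = "right"


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into their union."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def sort(self) -> None:
        self.exons.sort()
        self.cds.sort()


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chromosome: str
    strand: str
    start: int
    end: int
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    #: union of all transcripts' exons (merged, disjoint, sorted)
    exons: list[tuple[int, int]] = field(default_factory=list)
    #: length of the exon union (not the per-transcript sum)
    sum_of_exon_lengths: int = 0
    #: internal exon start positions (breaks with direction ``left``
    #: at these positions sit on a splice site)
    exon_left_edges: set[int] = field(default_factory=set)
    #: internal exon final bases (direction ``right``)
    exon_right_edges: set[int] = field(default_factory=set)

    def finalize(self) -> None:
        for tx in self.transcripts.values():
            tx.sort()
            if len(tx.exons) > 1:
                for s, _ in tx.exons[1:]:
                    self.exon_left_edges.add(s)
                for _, e in tx.exons[:-1]:
                    self.exon_right_edges.add(e - 1)
        self.exons = merge_intervals(
            (s, e) for tx in self.transcripts.values() for s, e in tx.exons
        )
        self.sum_of_exon_lengths = sum(e - s for s, e in self.exons)
        if self.exons:
            self.start = min(self.start, self.exons[0][0])
            self.end = max(self.end, self.exons[-1][1])

    def contains_exonic(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.exons)

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


class AnnotationIndex:
    """Interval-indexed gene models with splice-site lookups."""

    def __init__(self, genes: dict[str, GeneModel]):
        self.genes = genes
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes.values():
            tree = self._trees.setdefault(gene.chromosome, IntervalTree())
            if gene.end > gene.start:
                tree.addi(gene.start, gene.end, gene.gene_id)
        self._by_name: dict[str, list[GeneModel]] = {}
        for gene in genes.values():
            self._by_name.setdefault(gene.gene_name, []).append(gene)

    def genes_at(self, chromosome: str, position: int) -> list[GeneModel]:
        """All genes whose span contains ``position`` (0-based)."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.at(position)]
        return sorted(hits, key=lambda g: g.gene_id)

    def assign_gene(self, chromosome: str, position: int) -> GeneModel | None:
        """Deterministically pick one gene for a breakpoint position.

        Exon containment beats span containment; ties go to the gene
        with the longest exon union, then to the lexicographically
        smallest id.
        """
        hits = self.genes_at(chromosome, position)
        if not hits:
            return None
        hits.sort(
            key=lambda g: (
                not g.contains_exonic(position),
                -g.sum_of_exon_lengths,
                g.gene_id,
            )
        )
        return hits[0]

    def classify_site(
        self, chromosome: str, position: int, direction: str,
        gene: GeneModel | None = None,
    ) -> str:
        """Site class of a breakpoint: splice/exonic/intronic/intergenic.

        A breakpoint is on a splice site when its position coincides
        with an internal exon edge on the side matching its direction
        (direction ``right``: exon final base, i.e. a donor on the plus
        strand and an acceptor on the minus strand; direction ``left``:
        exon first base).
        """
        if gene is None:
            gene = self.assign_gene(chromosome, position)
        if gene is None or gene.chromosome != chromosome:
            return SITE_INTERGENIC
        if direction == DIRECTION_RIGHT and position in gene.exon_right_edges:
            return SITE_SPLICE
        if direction == DIRECTION_LEFT and position in gene.exon_left_edges:
            return SITE_SPLICE
        if gene.contains_exonic(position):
            return SITE_EXONIC
        if gene.contains(position):
            return SITE_INTRONIC
        return SITE_INTERGENIC

    def genes_by_name(self, name: str) -> list[GeneModel]:
        return self._by_name.get(name, [])


def _first_attr(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            values = feature.attributes[key]
            if values:
                return values[0]
    return None


def read_gene_annotation(source: str | os.PathLike | IO[str]) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GTF file or stream.

    Understands the GENCODE dialect (``gene``/``transcript``/``exon``/
    ``CDS`` features with ``gene_id``, ``gene_name``, ``transcript_id``
    attributes).  Records without a ``gene_id`` are skipped with a
    warning; exons reaching outside their transcript's span are clamped
    with a warning.
    """
    if hasattr(source, "read"):
        text = source.read()
        db = _create_db(text, from_string=True)
    else:
        db = _create_db(str(source), from_string=False)

    genes: dict[str, GeneModel] = {}

    def get_gene(feature) -> GeneModel | None:
        gene_id = _first_attr(feature, "gene_id")
        if gene_id is None:
            warnings.warn(
                f"record without gene_id skipped: {feature.featuretype} "
                f"{feature.seqid}:{feature.start}-{feature.end}"
            )
            return None
        if gene_id not in genes:
            genes[gene_id] = GeneModel(
                gene_id=gene_id,
                gene_name=_first_attr(feature, "gene_name") or gene_id,
                chromosome=feature.seqid,
                strand=feature.strand if feature.strand in "+-" else "+",
                start=feature.start - 1,
                end=feature.end,
            )
        return genes[gene_id]

    tx_spans: dict[str, tuple[int, int]] = {}
    for feature in db.all_features():
        kind = feature.featuretype
        if kind not in {"gene", "transcript", "exon", "CDS"}:
            continue
        gene = get_gene(feature)
        if gene is None:
            continue
        start, end = feature.start - 1, feature.end
        if kind == "gene":
            gene.start = min(gene.start, start)
            gene.end = max(gene.end, end)
            if _first_attr(feature, "gene_name"):
                gene.gene_name = _first_attr(feature, "gene_name")
            continue
        tx_id = _first_attr(feature, "transcript_id")
        if tx_id is None:
            warnings.warn(f"{kind} without transcript_id skipped")
            continue
        if kind == "transcript":
            tx_spans[tx_id] = (start, end)
            gene.transcripts.setdefault(tx_id, Transcript(tx_id))
            continue
        tx = gene.transcripts.setdefault(tx_id, Transcript(tx_id))
        if tx_id in tx_spans:
            lo, hi = tx_spans[tx_id]
            if start < lo or end > hi:
                warnings.warn(
                    f"{kind} {feature.seqid}:{feature.start}-{feature.end} "
                    f"outside transcript {tx_id}; clamped"
                )
                start, end = max(start, lo), min(end, hi)
        if end <= start:
            continue
        if kind == "exon":
            tx.exons.append((start, end))
        else:
            tx.cds.append((start, end))

    for gene in genes.values():
        gene.finalize()
    return AnnotationIndex(genes)


def _create_db(data: str, from_string: bool):
    # gffutils needs a real file for its sqlite import when the input is
    # a path; in-memory db keeps everything transient.
    if from_string:
        with tempfile.NamedTemporaryFile(
            "w", suffix=".gtf", delete=False
        ) as handle:
            handle.write(data)
            path = handle.name
        try:
            return gffutils.create_db(
                path,
                ":memory:",
                force=True,
                keep_order=True,
                merge_strategy="create_unique",
                disable_infer_genes=True,
                disable_infer_transcripts=True,
            )
        finally:
            os.unlink(path)
    return gffutils.create_db(
        data,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
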
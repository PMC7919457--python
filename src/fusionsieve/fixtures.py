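"""Self-contained synthetic test data: toy genome, annotation, chimeric
reads for planted fusions, and background-noise candidates.

Everything is a pure function of a :class:`FixtureSpec` and its seed, so
generated bundles are byte-reproducible.  The generator emulates the
aligner conventions the detector consumes: split reads as primary plus
supplementary SAM records with complementary soft clips, discordant
mates as improper pairs facing the junction, focal deletions optionally
encoded as intron-like gapped alignments, and background noise as
low-support split-read candidates whose per-gene counts, support
distribution (geometric, heavy at one or two reads, mirroring the steep
low-support noise curve of real data) and breakpoint site mixture are
configurable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}
_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass(frozen=True)
class PlantedFusion:
    gene5: str
    gene3: str
    split_reads: int = 4
    discordant_pairs: int = 2
    at_splice_sites: bool = True
    #: transcript-order exon whose far boundary carries the 5' break
    exon5: int = 1
    #: transcript-order exon whose near boundary carries the 3' break
    exon3: int = 1
    #: shift into the exon when not at splice sites (bp)
    offset5: int = 37
    offset3: int = 23
    #: encode support as chimeric records or as gapped alignments
    #: (focal-deletion style; requires a same-chromosome deletion)
    encoding: str = "chimeric"
    with_sv: bool = False
    #: distance of the corroborating SV ends from the breakpoints (bp)
    sv_offset: int = 500
    name: str = ""


@dataclass(frozen=True)
class NoiseConfig:
    #: Poisson mean of candidates per gene (ignored when total is set)
    rate_per_gene: float = 0.0
    #: exact total number of noise candidates
    total: int | None = None
    #: mean of the geometric support distribution on {1, 2, ...}
    support_mean: float = 1.3
    #: optional hard cap on support per candidate
    support_cap: int | None = None
    #: breakpoint site-class mixture: (intron, exon, splice site)
    site_mix: tuple[float, float, float] = (0.45, 0.45, 0.10)
    #: probabilities of 0/1/2 mismatches per aligned segment
    mismatch_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 200
    intergenic_gap: int = 1000
    n_chromosomes: int = 2
    read_length: int = 100
    #: concordant (non-chimeric) read pairs per gene in the main stream
    background_pairs_per_gene: int = 5
    fusions: tuple[PlantedFusion, ...] = ()
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        if (self.exons_per_gene * self.exon_length) % 3:
            raise ValueError("total exon length per gene must be a codon multiple")
        if self.exon_length < self.read_length:
            raise ValueError("exons must be at least one read long")
        if self.n_genes < 2:
            raise ValueError("need at least two genes")


@dataclass
class _Gene:
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, genomic order

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class _Layout:
    spec: FixtureSpec
    genes: dict[str, _Gene]
    chrom_seqs: dict[str, str]
    mapped_reads_main: int = 0


_BASE_STR = "ACGT"


def _violates_complexity(seq: list[str]) -> bool:
    """Whether the sequence tail ends in a low-complexity motif (a
    homopolymer run of 6 or a tandem repeat of unit <= 4 spanning 12
    bases) — the motifs the read-artifact filter screens for."""
    if len(seq) >= 6 and len(set(seq[-6:])) == 1:
        return True
    if len(seq) >= 12:
        tail = seq[-12:]
        for unit in (2, 3, 4):
            if all(tail[i] == tail[i + unit] for i in range(12 - unit)):
                return True
    return False


def _random_seq(rng: np.random.Generator, length: int) -> str:
    """Random sequence free of low-complexity motifs.

    Keeping the toy genome free of homopolymers and short tandem
    repeats makes the artifact filter's behavior a function of what the
    fixture plants rather than of chance genome content.  (Real genomes
    do contain such tracts; fusions there are deliberately subject to
    the low-complexity filter.)
    """
    seq: list[str] = []
    pool = rng.integers(0, 4, size=length + 64).tolist()
    index = 0
    attempts = 0
    while len(seq) < length:
        if index >= len(pool):
            pool = rng.integers(0, 4, size=1024).tolist()
            index = 0
        seq.append(_BASE_STR[pool[index]])
        index += 1
        if _violates_complexity(seq):
            seq.pop()
            attempts += 1
            if attempts > 8:  # pathological corner: back out one base
                seq.pop()
                attempts = 0
        else:
            attempts = 0
    return "".join(seq)


def _coding_sequence(rng: np.random.Generator, length: int) -> str:
    """Random coding sequence: ATG start, no internal stops, TAA end."""
    seq = list(_random_seq(rng, length))
    seq[0:3] = "ATG"
    for i in range(3, length - 3, 3):
        while "".join(seq[i: i + 3]) in STOPS:
            seq[i: i + 3] = _random_seq(rng, 3)
    seq[length - 3:] = "TAA"
    return "".join(seq)


def build_layout(spec: FixtureSpec) -> _Layout:
    """Deterministic genome layout: non-overlapping genes on alternating
    strands, round-robin over chromosomes, coding along every exon."""
    rng = np.random.default_rng([spec.seed, 0])
    per_chrom: dict[str, list[str]] = {
        f"chr{c + 1}": [] for c in range(spec.n_chromosomes)
    }
    gene_order = [f"GENE{i + 1:03d}" for i in range(spec.n_genes)]
    for i, gene_id in enumerate(gene_order):
        per_chrom[f"chr{i % spec.n_chromosomes + 1}"].append(gene_id)

    genes: dict[str, _Gene] = {}
    chrom_seqs: dict[str, str] = {}
    for chrom, gene_ids in per_chrom.items():
        parts: list[str] = []
        cursor = 0

        def fill(length: int) -> None:
            nonlocal cursor
            parts.append(_random_seq(rng, length))
            cursor += length

        fill(spec.intergenic_gap)
        for gene_id in gene_ids:
            strand = "+" if int(gene_id[4:]) % 2 else "-"
            tx_seq = _coding_sequence(
                rng, spec.exons_per_gene * spec.exon_length
            )
            chunks = [
                tx_seq[k * spec.exon_length: (k + 1) * spec.exon_length]
                for k in range(spec.exons_per_gene)
            ]
            exons: list[tuple[int, int]] = []
            for k in range(spec.exons_per_gene):
                if k > 0:
                    fill(spec.intron_length)
                start = cursor
                chunk = (
                    chunks[k]
                    if strand == "+"
                    else revcomp(chunks[spec.exons_per_gene - 1 - k])
                )
                parts.append(chunk)
                cursor += len(chunk)
                exons.append((start, cursor))
            genes[gene_id] = _Gene(gene_id, chrom, strand, exons)
            fill(spec.intergenic_gap)
        chrom_seqs[chrom] = "".join(parts)
    return _Layout(spec=spec, genes=genes, chrom_seqs=chrom_seqs)


def _tx_to_genomic(
    gene: _Gene, t0: int, t1: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic intervals."""
    exon_iter = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
    out = []
    offset = 0
    for start, end in exon_iter:
        length = end - start
        lo, hi = max(t0, offset), min(t1, offset + length)
        if lo < hi:
            if gene.strand == "+":
                out.append((start + lo - offset, start + hi - offset))
            else:
                out.append((end - (hi - offset), end - (lo - offset)))
        offset += length
    return sorted(out)


def make_toy_genome(spec: FixtureSpec) -> tuple[str, str]:
    """Render the toy genome as (FASTA text, GTF text)."""
    layout = build_layout(spec)
    fasta_lines = []
    for chrom in sorted(layout.chrom_seqs):
        fasta_lines.append(f">{chrom}")
        seq = layout.chrom_seqs[chrom]
        fasta_lines.extend(seq[i: i + 60] for i in range(0, len(seq), 60))
    gtf_lines = []
    coding_len = spec.exons_per_gene * spec.exon_length - 3  # excl. stop
    for gene_id in sorted(layout.genes):
        gene = layout.genes[gene_id]
        tx_id = f"{gene_id}.t1"
        attrs = (
            f'gene_id "{gene_id}"; gene_name "{gene_id}"; '
            f'transcript_id "{tx_id}";'
        )
        gene_attrs = f'gene_id "{gene_id}"; gene_name "{gene_id}";'

        def row(kind: str, start: int, end: int, attributes: str) -> str:
            return "\t".join(
                [
                    gene.chromosome, "fusionsieve", kind,
                    str(start + 1), str(end), ".", gene.strand, ".",
                    attributes,
                ]
            )

        gtf_lines.append(row("gene", gene.start, gene.end, gene_attrs))
        gtf_lines.append(row("transcript", gene.start, gene.end, attrs))
        for start, end in gene.exons:
            gtf_lines.append(row("exon", start, end, attrs))
        for start, end in _tx_to_genomic(gene, 0, coding_len):
            gtf_lines.append(row("CDS", start, end, attrs))
    return "\n".join(fasta_lines) + "\n", "\n".join(gtf_lines) + "\n"


# ---------------------------------------------------------------------------
# breakpoint geometry of planted events


def fusion_breakpoints(
    spec: FixtureSpec, layout: _Layout, fusion: PlantedFusion
) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
    """(chrom, 0-based position, direction) of both planted breakpoints.

    The 5' gene retains its transcription start: the break sits at the
    transcript-end boundary of exon ``exon5`` (an internal donor).  The
    3' gene retains its transcription end: the break sits at the
    transcript-start boundary of exon ``exon3`` (an internal acceptor).
    Non-splice-site fusions shift the positions into the exon bodies.
    """
    g5, g3 = layout.genes[fusion.gene5], layout.genes[fusion.gene3]
    n = spec.exons_per_gene
    if g5.strand == "+":
        pos5, dir5 = g5.exons[fusion.exon5][1] - 1, "right"
        if not fusion.at_splice_sites:
            pos5 -= fusion.offset5
    else:
        pos5, dir5 = g5.exons[n - 1 - fusion.exon5][0], "left"
        if not fusion.at_splice_sites:
            pos5 += fusion.offset5
    if g3.strand == "+":
        pos3, dir3 = g3.exons[fusion.exon3][0], "left"
        if not fusion.at_splice_sites:
            pos3 += fusion.offset3
    else:
        pos3, dir3 = g3.exons[n - 1 - fusion.exon3][1] - 1, "right"
        if not fusion.at_splice_sites:
            pos3 -= fusion.offset3
    return (g5.chromosome, pos5, dir5), (g3.chromosome, pos3, dir3)


def _context(layout: _Layout, chrom: str, pos: int, direction: str,
             length: int, side: str) -> str:
    """Reference sequence entering the junction, fusion-oriented."""
    seq = layout.chrom_seqs[chrom]
    if side == "5":
        if direction == "right":
            return seq[pos + 1 - length: pos + 1]
        return revcomp(seq[pos: pos + length])
    if direction == "left":
        return seq[pos: pos + length]
    return revcomp(seq[pos + 1 - length: pos + 1])


def _sam_flag(paired=False, proper=False, reverse=False, mate_reverse=False,
              first=False, second=False, supplementary=False, dup=False) -> int:
    return (
        (0x1 if paired else 0)
        | (0x2 if proper else 0)
        | (0x10 if reverse else 0)
        | (0x20 if mate_reverse else 0)
        | (0x40 if first else 0)
        | (0x80 if second else 0)
        | (0x400 if dup else 0)
        | (0x800 if supplementary else 0)
    )


def _sam_line(qname, flag, chrom, pos0, cigar, seq, nm=0,
              rnext="*", pnext0=-1, tlen=0) -> str:
    return "\t".join(
        [
            qname, str(flag), chrom, str(pos0 + 1), "60", cigar,
            rnext, str(pnext0 + 1) if pnext0 >= 0 else "0", str(tlen),
            seq, "*", f"NM:i:{nm}",
        ]
    )


def _mutate(rng: np.random.Generator, read: str, lo: int, hi: int, n: int) -> str:
    """Introduce ``n`` mismatches at distinct positions in [lo, hi)."""
    if n <= 0 or hi - lo <= 0:
        return read
    out = list(read)
    positions = rng.choice(np.arange(lo, hi), size=min(n, hi - lo), replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def split_read_records(
    layout: _Layout,
    bp5: tuple[str, int, str],
    bp3: tuple[str, int, str],
    anchor: int,
    read_id: str,
    rng: np.random.Generator | None = None,
    nm5: int = 0,
    nm3: int = 0,
    duplicate: bool = False,
) -> list[str]:
    """Two SAM records (primary + supplementary) for one split read."""
    spec = layout.spec
    length = spec.read_length
    chrom5, pos5, dir5 = bp5
    chrom3, pos3, dir3 = bp3
    read = (
        _context(layout, chrom5, pos5, dir5, length, "5")[-anchor:]
        + _context(layout, chrom3, pos3, dir3, length, "3")[: length - anchor]
    )
    if rng is not None:
        read = _mutate(rng, read, 0, anchor, nm5)
        read = _mutate(rng, read, anchor, length, nm3)
    tail = length - anchor
    lines = []
    if dir5 == "right":
        lines.append(_sam_line(
            read_id, _sam_flag(dup=duplicate), chrom5, pos5 - anchor + 1,
            f"{anchor}M{tail}S", read, nm5,
        ))
    else:
        lines.append(_sam_line(
            read_id, _sam_flag(reverse=True, dup=duplicate), chrom5, pos5,
            f"{tail}S{anchor}M", revcomp(read), nm5,
        ))
    if dir3 == "left":
        lines.append(_sam_line(
            read_id, _sam_flag(supplementary=True, dup=duplicate), chrom3, pos3,
            f"{anchor}S{tail}M", read, nm3,
        ))
    else:
        lines.append(_sam_line(
            read_id,
            _sam_flag(reverse=True, supplementary=True, dup=duplicate),
            chrom3, pos3 - tail + 1, f"{tail}M{anchor}S", revcomp(read), nm3,
        ))
    return lines


def discordant_pair_records(
    layout: _Layout,
    bp5: tuple[str, int, str],
    bp3: tuple[str, int, str],
    gap5: int,
    gap3: int,
    read_id: str,
) -> list[str]:
    """Two SAM records for a discordant mate pair flanking a junction."""
    spec = layout.spec
    length = spec.read_length
    chrom5, pos5, dir5 = bp5
    chrom3, pos3, dir3 = bp3
    seqs = layout.chrom_seqs
    if dir5 == "right":
        start5 = pos5 - gap5 - length + 1
        rev5 = False
    else:
        start5 = pos5 + gap5
        rev5 = True
    if dir3 == "left":
        start3 = pos3 + gap3
        rev3 = True
    else:
        start3 = pos3 - gap3 - length + 1
        rev3 = False
    seq5 = seqs[chrom5][start5: start5 + length]
    seq3 = seqs[chrom3][start3: start3 + length]
    rnext5 = "=" if chrom3 == chrom5 else chrom3
    rnext3 = "=" if chrom3 == chrom5 else chrom5
    return [
        _sam_line(
            read_id,
            _sam_flag(paired=True, first=True, reverse=rev5, mate_reverse=rev3),
            chrom5, start5, f"{length}M",
            revcomp(seq5) if rev5 else seq5, 0, rnext5, start3,
        ),
        _sam_line(
            read_id,
            _sam_flag(paired=True, second=True, reverse=rev3, mate_reverse=rev5),
            chrom3, start3, f"{length}M",
            revcomp(seq3) if rev3 else seq3, 0, rnext3, start5,
        ),
    ]


def gapped_read_records(
    layout: _Layout,
    bp5: tuple[str, int, str],
    bp3: tuple[str, int, str],
    anchor: int,
    read_id: str,
) -> list[str]:
    """One gapped (intron-like) SAM record spanning a focal deletion."""
    chrom5, pos5, dir5 = bp5
    chrom3, pos3, dir3 = bp3
    if chrom5 != chrom3 or dir5 != "right" or dir3 != "left" or pos3 <= pos5:
        raise ValueError("gapped encoding requires a same-chromosome deletion")
    length = layout.spec.read_length
    read = (
        _context(layout, chrom5, pos5, dir5, length, "5")[-anchor:]
        + _context(layout, chrom3, pos3, dir3, length, "3")[: length - anchor]
    )
    gap = pos3 - pos5 - 1
    return [
        _sam_line(
            read_id, 0, chrom5, pos5 - anchor + 1,
            f"{anchor}M{gap}N{length - anchor}M", read,
        )
    ]


def _sam_header(layout: _Layout) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(layout.chrom_seqs):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(layout.chrom_seqs[chrom])}")
    return lines


def plant_fusion_reads(
    spec: FixtureSpec, layout: _Layout | None = None
) -> tuple[str, list[dict]]:
    """Chimeric SAM text plus a truth table for every planted fusion.

    Gapped-encoding fusions appear in the truth table but their reads
    belong in the main alignment stream (see :func:`generate_bundle`).
    """
    layout = layout or build_layout(spec)
    lines = _sam_header(layout)
    truth: list[dict] = []
    for index, fusion in enumerate(spec.fusions):
        name = fusion.name or f"fusion{index + 1}"
        bp5, bp3 = fusion_breakpoints(spec, layout, fusion)
        if fusion.encoding == "chimeric":
            for i in range(fusion.split_reads):
                anchor = 30 + (i * 13) % 41
                lines.extend(
                    split_read_records(
                        layout, bp5, bp3, anchor, f"{name}_sr{i + 1}"
                    )
                )
            for i in range(fusion.discordant_pairs):
                gap = 120 + 60 * (i % 5)
                lines.extend(
                    discordant_pair_records(
                        layout, bp5, bp3, gap, gap + 30, f"{name}_dp{i + 1}"
                    )
                )
        truth.append(
            {
                "name": name,
                "gene5": fusion.gene5,
                "gene3": fusion.gene3,
                "chrom5": bp5[0], "pos5": bp5[1] + 1, "direction5": bp5[2],
                "chrom3": bp3[0], "pos3": bp3[1] + 1, "direction3": bp3[2],
                "split_reads": fusion.split_reads,
                "discordant_mates": fusion.discordant_pairs,
                "at_splice_sites": fusion.at_splice_sites,
                "encoding": fusion.encoding,
                "with_sv": fusion.with_sv,
            }
        )
    return "\n".join(lines) + "\n", truth


def _splice_edges(spec: FixtureSpec, gene: _Gene) -> list[tuple[int, str]]:
    edges = []
    for start, end in gene.exons[1:]:
        edges.append((start, "left"))
    for start, end in gene.exons[:-1]:
        edges.append((end - 1, "right"))
    return sorted(edges)


def _noise_breakpoint(
    rng: np.random.Generator, spec: FixtureSpec, gene: _Gene,
    site_mix: tuple[float, float, float],
) -> tuple[str, int, str, str]:
    """Random (chrom, pos, direction, site_class) inside a gene."""
    site = ["intron", "exon", "splice"][
        rng.choice(3, p=np.asarray(site_mix) / sum(site_mix))
    ]
    if site == "splice":
        pos, direction = _splice_edges(spec, gene)[
            rng.integers(0, 2 * (spec.exons_per_gene - 1))
        ]
    elif site == "exon":
        start, end = gene.exons[rng.integers(0, spec.exons_per_gene)]
        pos = int(rng.integers(start + 2, end - 2))
        direction = "right" if rng.integers(0, 2) else "left"
    else:
        k = rng.integers(0, spec.exons_per_gene - 1)
        pos = int(rng.integers(gene.exons[k][1] + 1, gene.exons[k + 1][0] - 1))
        direction = "right" if rng.integers(0, 2) else "left"
    return gene.chromosome, pos, direction, site


def plant_noise(
    spec: FixtureSpec, layout: _Layout | None = None
) -> tuple[str, list[dict]]:
    """Background-noise split reads plus their truth table.

    Per-gene candidate counts follow a Poisson law with the configured
    rate (or an exact total), support the configured geometric
    distribution, and breakpoint positions the configured site mixture.
    Noise junctions are kept disjoint from planted-fusion breakpoints.
    """
    layout = layout or build_layout(spec)
    rng = np.random.default_rng([spec.seed, 2])
    cfg = spec.noise
    gene_ids = sorted(layout.genes)
    planted = set()
    for fusion in spec.fusions:
        bp5, bp3 = fusion_breakpoints(spec, layout, fusion)
        planted.add((bp5[0], bp5[1]))
        planted.add((bp3[0], bp3[1]))

    counts: list[tuple[str, int]] = []
    if cfg.total is not None:
        for j in range(cfg.total):
            counts.append((gene_ids[rng.integers(0, len(gene_ids))], 1))
        counts = [(g, 1) for g, _ in counts]
    else:
        for gene_id in gene_ids:
            n = int(rng.poisson(cfg.rate_per_gene))
            counts.extend((gene_id, 1) for _ in range(n))

    lines = _sam_header(layout)
    truth: list[dict] = []
    used: set[tuple] = set()
    p_geom = min(1.0, 1.0 / cfg.support_mean)
    mism = np.asarray(cfg.mismatch_probs) / sum(cfg.mismatch_probs)
    for j, (gene_id, _) in enumerate(counts):
        gene_a = layout.genes[gene_id]
        other_ids = [g for g in gene_ids if g != gene_id]
        gene_b = layout.genes[other_ids[rng.integers(0, len(other_ids))]]
        for _attempt in range(100):
            bp_a = _noise_breakpoint(rng, spec, gene_a, cfg.site_mix)
            bp_b = _noise_breakpoint(rng, spec, gene_b, cfg.site_mix)
            key = (bp_a[:3], bp_b[:3])
            if (
                key not in used
                and (bp_a[0], bp_a[1]) not in planted
                and (bp_b[0], bp_b[1]) not in planted
            ):
                used.add(key)
                break
        support = int(rng.geometric(p_geom))
        if cfg.support_cap is not None:
            support = min(support, cfg.support_cap)
        for k in range(support):
            anchor = int(rng.integers(15, 86))
            nm5, nm3 = rng.choice(3, size=2, p=mism)
            lines.extend(
                split_read_records(
                    layout, bp_a[:3], bp_b[:3], anchor,
                    f"noise{j + 1}_r{k + 1}", rng, int(nm5), int(nm3),
                )
            )
        truth.append(
            {
                "name": f"noise{j + 1}",
                "gene_a": gene_a.gene_id, "gene_b": gene_b.gene_id,
                "chrom_a": bp_a[0], "pos_a": bp_a[1] + 1,
                "direction_a": bp_a[2], "site_a": bp_a[3],
                "chrom_b": bp_b[0], "pos_b": bp_b[1] + 1,
                "direction_b": bp_b[2], "site_b": bp_b[3],
                "support": support,
            }
        )
    return "\n".join(lines) + "\n", truth


def background_pair_records(layout: _Layout) -> list[str]:
    """Concordant read pairs inside single exons (non-chimeric filler)."""
    spec = layout.spec
    length = spec.read_length
    lines = []
    for gene_id in sorted(layout.genes):
        gene = layout.genes[gene_id]
        start0, end0 = gene.exons[0]
        for i in range(spec.background_pairs_per_gene):
            s1 = start0 + (i * 7) % max(1, end0 - start0 - length - 160)
            s2 = s1 + 150
            seq1 = layout.chrom_seqs[gene.chromosome][s1: s1 + length]
            seq2 = layout.chrom_seqs[gene.chromosome][s2: s2 + length]
            qname = f"{gene_id}_bg{i + 1}"
            lines.append(_sam_line(
                qname,
                _sam_flag(paired=True, proper=True, first=True, mate_reverse=True),
                gene.chromosome, s1, f"{length}M", seq1, 0, "=", s2,
                s2 + length - s1,
            ))
            lines.append(_sam_line(
                qname,
                _sam_flag(paired=True, proper=True, second=True, reverse=True),
                gene.chromosome, s2, f"{length}M", revcomp(seq2), 0, "=", s1,
                -(s2 + length - s1),
            ))
    return lines


def structural_variant_rows(
    spec: FixtureSpec, layout: _Layout | None = None
) -> list[str]:
    """BEDPE rows corroborating the planted fusions flagged ``with_sv``."""
    layout = layout or build_layout(spec)
    rows = []
    for index, fusion in enumerate(spec.fusions):
        if not fusion.with_sv:
            continue
        bp5, bp3 = fusion_breakpoints(spec, layout, fusion)
        ends = []
        for chrom, pos, direction in (bp5, bp3):
            # the genomic break lies beyond the transcriptomic one on
            # the retained side
            sv_pos = pos - fusion.sv_offset if direction == "right" else (
                pos + fusion.sv_offset
            )
            ends.append((chrom, max(0, sv_pos), direction))
        rows.append(
            "\t".join(
                [
                    ends[0][0], str(ends[0][1]), str(ends[0][1] + 1),
                    ends[1][0], str(ends[1][1]), str(ends[1][1] + 1),
                    fusion.name or f"sv{index + 1}", ".",
                    "+" if ends[0][2] == "right" else "-",
                    "+" if ends[1][2] == "right" else "-",
                ]
            )
        )
    return rows


def generate_bundle(spec: FixtureSpec, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the full fixture bundle and return the file paths.

    ``chimeric.sam`` holds only chimeric records (split reads,
    discordant mates, noise); ``main.sam`` holds everything a full
    alignment stream would: concordant background pairs, the chimeric
    records, and gapped alignments for gapped-encoding fusions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = build_layout(spec)
    fasta, gtf = make_toy_genome(spec)
    chimeric_sam, fusion_truth = plant_fusion_reads(spec, layout)
    noise_sam, noise_truth = plant_noise(spec, layout)

    chimeric_lines = chimeric_sam.rstrip("\n").split("\n")
    noise_body = [
        line for line in noise_sam.rstrip("\n").split("\n")
        if not line.startswith("@")
    ]
    chimeric_all = chimeric_lines + noise_body

    gapped_lines: list[str] = []
    for index, fusion in enumerate(spec.fusions):
        if fusion.encoding != "gapped":
            continue
        name = fusion.name or f"fusion{index + 1}"
        bp5, bp3 = fusion_breakpoints(spec, layout, fusion)
        for i in range(fusion.split_reads):
            anchor = 30 + (i * 13) % 41
            gapped_lines.extend(
                gapped_read_records(layout, bp5, bp3, anchor, f"{name}_g{i + 1}")
            )

    main_lines = (
        _sam_header(layout)
        + background_pair_records(layout)
        + [line for line in chimeric_all if not line.startswith("@")]
        + gapped_lines
    )

    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.gtf",
        "chimeric_sam": out / "chimeric.sam",
        "main_sam": out / "main.sam",
        "sv_bedpe": out / "sv.bedpe",
        "fusion_truth": out / "truth_fusions.tsv",
        "noise_truth": out / "truth_noise.tsv",
    }
    paths["genome"].write_text(fasta)
    paths["annotation"].write_text(gtf)
    paths["chimeric_sam"].write_text("\n".join(chimeric_all) + "\n")
    paths["main_sam"].write_text("\n".join(main_lines) + "\n")
    sv_rows = structural_variant_rows(spec, layout)
    paths["sv_bedpe"].write_text("\n".join(sv_rows) + ("\n" if sv_rows else ""))
    paths["fusion_truth"].write_text(_truth_tsv(fusion_truth))
    paths["noise_truth"].write_text(_truth_tsv(noise_truth))
    return paths


def _truth_tsv(rows: list[dict]) -> str:
    if not rows:
        return ""
    header = list(rows[0])
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(row[k]) for k in header))
    return "\n".join(lines) + "\n"


def default_benchmark_spec(seed: int = 0) -> FixtureSpec:
    """Study-condition fixture: five genuine fusions with ample spliced
    support over two hundred low-support background candidates.

    Noise support is geometric with mean 1.3 capped at two reads and
    the site mixture avoids splice sites, emulating the dominant
    artifact population of one-to-two-read non-spliced candidates.
    No structural variants are planted: on toy chromosomes far shorter
    than the 100 kb corroboration window an SV would blanket-match
    every candidate, so the SV distance/orientation rules are exercised
    on explicitly constructed variants instead.
    """
    fusions = tuple(
        PlantedFusion(
            gene5=f"GENE{2 * i + 1:03d}",
            gene3=f"GENE{2 * i + 12:03d}",
            split_reads=4 + i,
            discordant_pairs=2,
            at_splice_sites=True,
            name=f"fusion{i + 1}",
        )
        for i in range(5)
    )
    return replace(
        FixtureSpec(
            n_genes=20,
            fusions=fusions,
            noise=NoiseConfig(
                total=200,
                support_mean=1.3,
                support_cap=2,
                site_mix=(0.5, 0.5, 0.0),
            ),
        ),
        seed=seed,
    )
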
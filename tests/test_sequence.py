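"""Fused transcript assembly and peptide/frame prediction."""

import io

from Bio.Seq import Seq

from fusionsieve.annotation import read_gene_annotation
from fusionsieve.candidates import Breakpoint, FusionCandidate
from fusionsieve.fixtures import (
    FixtureSpec,
    PlantedFusion,
    build_layout,
    fusion_breakpoints,
    make_toy_genome,
    revcomp,
)
from fusionsieve.sequence import junction_flanking_sequence, predict_peptide

from conftest import gtf_text


def _candidate(bp5, bp3):
    cand = FusionCandidate(breakpoint5=bp5, breakpoint3=bp3)
    cand.split_reads5 = 4
    return cand


def test_spliced_flank_crosses_exons_plus_strand(toy_annotation, toy_genome):
    """Manual assembly oracle on GENEA (3 exons of 200 bp): a 250 bp
    flank at the second exon's donor splices 50 bp of exon 1 onto all
    of exon 2 and ends exactly at the exon's last base."""
    bp5 = Breakpoint("chr1", 1699, "right", "GENEA", "splice_site")
    bp3 = Breakpoint("chr1", 5500, "left", "GENEB", "splice_site")
    out = junction_flanking_sequence(
        _candidate(bp5, bp3), toy_genome, toy_annotation, flank=250
    )
    chr1 = toy_genome["chr1"]
    assert out.sequence5 == chr1[1150:1200] + chr1[1500:1700]
    # GENEB has no further exon: the walk stops at the transcript end
    assert out.sequence3 == chr1[5500:5700]
    assert out.marked == out.sequence5 + "|" + out.sequence3


def test_intronic_breakpoint_uses_genomic_flank(toy_annotation, toy_genome):
    bp5 = Breakpoint("chr1", 1300, "right", "GENEA", "intronic")
    bp3 = Breakpoint("chr1", 5500, "left", "GENEB", "splice_site")
    out = junction_flanking_sequence(
        _candidate(bp5, bp3), toy_genome, toy_annotation, flank=200
    )
    assert out.sequence5 == toy_genome["chr1"][1101:1301]


def test_minus_strand_five_prime_gene(toy_annotation, toy_genome):
    """GENEC (minus strand) donating its 5' part: the transcript-
    oriented flank is the reverse complement of the genomic walk."""
    bp5 = Breakpoint("chr2", 1500, "left", "GENEC", "splice_site")
    bp3 = Breakpoint("chr2", 5100, "left", "GENED", "exonic")
    out = junction_flanking_sequence(
        _candidate(bp5, bp3), toy_genome, toy_annotation, flank=250
    )
    chr2 = toy_genome["chr2"]
    assert out.sequence5 == revcomp(chr2[1500:1700] + chr2[2000:2050])
    # exonic (non-splice) breakpoint: plain genomic flank
    assert out.sequence3 == chr2[5100:5350]


def test_strand_mirrored_fixture_gives_identical_sequence(toy_genome):
    """Mirroring the chromosome (reverse complement) and flipping the
    gene strand and breakpoint direction leaves the fused transcript
    sequence unchanged."""
    length = len(toy_genome["chr2"])
    mirrored_genome = {
        "chr2": revcomp(toy_genome["chr2"]),
        "chr1": toy_genome["chr1"],
    }
    # GENEC exons mirrored: [s,e) -> [L-e, L-s), minus -> plus
    rows = []
    for start, end in [(1000, 1200), (1500, 1700), (2000, 2200)]:
        rows.append((length - end, length - start))
    rows.sort()
    gtf_rows = [("chr2", "gene", rows[0][0] + 1, rows[-1][1], "+", "GENEM",
                 "GENEM.t1", None),
                ("chr2", "transcript", rows[0][0] + 1, rows[-1][1], "+",
                 "GENEM", "GENEM.t1", None)]
    gtf_rows += [("chr2", "exon", s + 1, e, "+", "GENEM", "GENEM.t1", None)
                 for s, e in rows]
    mirrored = read_gene_annotation(io.StringIO(gtf_text(gtf_rows)))
    bp5 = Breakpoint("chr2", length - 1501, "right", "GENEM", "splice_site")
    bp3 = Breakpoint("chr1", 5500, "left", None, "intergenic")
    out = junction_flanking_sequence(
        _candidate(bp5, bp3), mirrored_genome, mirrored, flank=250
    )
    assert out.sequence5 == revcomp(
        toy_genome["chr2"][1500:1700] + toy_genome["chr2"][2000:2050]
    )


def _fixture_setup(at_splice=True, offset5=36, offset3=23, strip_cds=False):
    spec = FixtureSpec(n_genes=4, seed=11)
    layout = build_layout(spec)
    fasta, gtf = make_toy_genome(spec)
    if strip_cds:
        gtf = "\n".join(
            line for line in gtf.splitlines() if "\tCDS\t" not in line
        ) + "\n"
    annotation = read_gene_annotation(io.StringIO(gtf))
    genome = {}
    for block in fasta.split(">")[1:]:
        name, _, body = block.partition("\n")
        genome[name.strip()] = body.replace("\n", "")
    fusion = PlantedFusion(
        gene5="GENE001", gene3="GENE003", at_splice_sites=at_splice,
        offset5=offset5, offset3=offset3,
    )
    bp5t, bp3t = fusion_breakpoints(spec, layout, fusion)
    site = "splice_site" if at_splice else "exonic"
    bp5 = Breakpoint(bp5t[0], bp5t[1], bp5t[2], "GENE001", site)
    bp3 = Breakpoint(bp3t[0], bp3t[1], bp3t[2], "GENE003", site)
    return layout, annotation, genome, _candidate(bp5, bp3)


def _transcript_seq(layout, gene_id):
    gene = layout.genes[gene_id]
    chunks = [layout.chrom_seqs[gene.chromosome][s:e] for s, e in gene.exons]
    seq = "".join(chunks)
    return seq if gene.strand == "+" else revcomp(seq)


def test_in_frame_fusion_reproduces_partner_peptides():
    """A splice-site fusion joining codon-aligned exons is in-frame and
    its peptide equals the 5' partner's peptide prefix followed by the
    3' partner's peptide suffix (independently derived from the toy
    transcript sequences)."""
    layout, annotation, genome, cand = _fixture_setup()
    pred = predict_peptide(cand, genome, annotation)
    assert pred.frame_status == "in-frame"
    tx5 = _transcript_seq(layout, "GENE001")
    tx3 = _transcript_seq(layout, "GENE003")
    # break after exon 2 of GENE001 (600 coding bases) onto exon 2 of
    # GENE003 (300 bases into its CDS); stop codon ends the 3' gene
    prefix = str(Seq(tx5[:600]).translate())
    suffix = str(Seq(tx3[300:]).translate())
    assert suffix.endswith("*")
    assert pred.peptide == prefix + suffix[:-1]
    assert pred.stop_relative_to_junction == len(suffix) - 1


def test_one_base_shift_breaks_the_frame():
    layout, annotation, genome, cand = _fixture_setup(
        at_splice=False, offset5=36, offset3=23
    )
    pred = predict_peptide(cand, genome, annotation)
    assert pred.frame_status == "out-of-frame"
    aligned = _fixture_setup(at_splice=False, offset5=36, offset3=24)[3]
    assert predict_peptide(
        aligned, genome, annotation
    ).frame_status == "in-frame"


def test_noncoding_five_prime_partner_is_unknown():
    _, annotation, genome, cand = _fixture_setup(strip_cds=True)
    pred = predict_peptide(cand, genome, annotation)
    assert pred.frame_status == "unknown"
    assert pred.peptide == ""
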
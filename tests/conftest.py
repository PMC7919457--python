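import io

import numpy as np
import pytest

from fusionsieve.annotation import read_gene_annotation

# A small hand-written two-chromosome annotation used across tests.
# GENEA (+, 3 exons) and GENEB (+, 2 exons) on chr1; GENEC (-, 3 exons)
# and GENED (+, single exon) on chr2.  Coordinates 1-based inclusive as
# in any GTF.
TOY_GTF_ROWS = [
    ("chr1", "gene", 1001, 2200, "+", "GENEA", "GENEA.t1", None),
    ("chr1", "transcript", 1001, 2200, "+", "GENEA", "GENEA.t1", None),
    ("chr1", "exon", 1001, 1200, "+", "GENEA", "GENEA.t1", None),
    ("chr1", "exon", 1501, 1700, "+", "GENEA", "GENEA.t1", None),
    ("chr1", "exon", 2001, 2200, "+", "GENEA", "GENEA.t1", None),
    ("chr1", "gene", 5001, 5700, "+", "GENEB", "GENEB.t1", None),
    ("chr1", "transcript", 5001, 5700, "+", "GENEB", "GENEB.t1", None),
    ("chr1", "exon", 5001, 5200, "+", "GENEB", "GENEB.t1", None),
    ("chr1", "exon", 5501, 5700, "+", "GENEB", "GENEB.t1", None),
    ("chr2", "gene", 1001, 2200, "-", "GENEC", "GENEC.t1", None),
    ("chr2", "transcript", 1001, 2200, "-", "GENEC", "GENEC.t1", None),
    ("chr2", "exon", 1001, 1200, "-", "GENEC", "GENEC.t1", None),
    ("chr2", "exon", 1501, 1700, "-", "GENEC", "GENEC.t1", None),
    ("chr2", "exon", 2001, 2200, "-", "GENEC", "GENEC.t1", None),
    ("chr2", "gene", 5001, 5300, "+", "GENED", "GENED.t1", None),
    ("chr2", "transcript", 5001, 5300, "+", "GENED", "GENED.t1", None),
    ("chr2", "exon", 5001, 5300, "+", "GENED", "GENED.t1", None),
]


def gtf_text(rows=TOY_GTF_ROWS) -> str:
    lines = []
    for chrom, kind, start, end, strand, gene, tx, _ in rows:
        attrs = f'gene_id "{gene}"; gene_name "{gene}";'
        if kind != "gene":
            attrs += f' transcript_id "{tx}";'
        lines.append(
            "\t".join(
                [chrom, "test", kind, str(start), str(end), ".", strand, ".", attrs]
            )
        )
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_annotation():
    return read_gene_annotation(io.StringIO(gtf_text()))


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(20240917)
    bases = np.array(list("ACGT"))
    return {
        "chr1": "".join(bases[rng.integers(0, 4, size=8000)]),
        "chr2": "".join(bases[rng.integers(0, 4, size=8000)]),
    }


def sam_text(records, lengths={"chr1": 8000, "chr2": 8000}) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    lines.extend(records)
    return "\n".join(lines) + "\n"


def sam_record(
    qname, flag, chrom, pos1, cigar, seq="*", nm=0, rnext="*", pnext1=0, tlen=0,
    mapq=60,
) -> str:
    return "\t".join(
        [
            qname, str(flag), chrom, str(pos1), str(mapq), cigar,
            rnext, str(pnext1), str(tlen), seq, "*", f"NM:i:{nm}",
        ]
    )
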
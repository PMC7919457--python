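"""Filter cascade: negative filters, rescues, confidence, conservation."""

import random

import pytest
from scipy.stats import binom

from fusionsieve.alignments import AlignmentSegment, ChimericAlignment
from fusionsieve.candidates import Breakpoint, FilterDecision, FusionCandidate
from fusionsieve.constants import FilterThresholds
from fusionsieve.filters import (
    assign_confidence,
    filter_blacklist,
    filter_homologous_genes,
    filter_read_artifacts,
    filter_short_anchor,
    filter_support_vs_noise,
    has_sv_support,
    rescue_multi_transcript,
    rescue_splice_sites,
    rescue_structural_variant,
    rescue_whitelist,
)
from fusionsieve.io import BlacklistEntry, StructuralVariant

THRESHOLDS = FilterThresholds()


def _split_with_sequence(seq5, seq3, read_id="r", nm5=0, nm3=0,
                         anchor5=50, anchor3=50):
    """Split read whose junction-proximal windows are the tails of the
    given aligned sequences (5' side ends at the junction)."""
    full = seq5 + seq3
    seg5 = AlignmentSegment(
        read_id=read_id, chromosome="chr1", start=1000, end=1000 + len(seq5),
        strand="+", aligned_length=len(seq5), left_clip=0,
        right_clip=len(seq3), mismatches=nm5, sequence=full,
    )
    seg3 = AlignmentSegment(
        read_id=read_id, chromosome="chr2", start=5000, end=5000 + len(seq3),
        strand="+", aligned_length=len(seq3), left_clip=len(seq5),
        right_clip=0, mismatches=nm3, sequence=full,
    )
    return ChimericAlignment(
        kind="split_read", segment5=seg5, segment3=seg3,
        junction5=999 + len(seq5), junction3=5000,
        direction5="right", direction3="left",
        anchor5=anchor5, anchor3=anchor3,
    )


def _candidate(reads=None, site5="splice_site", site3="splice_site",
               pos5=1199, pos3=5000, chrom3="chr2", gene5="GENEA",
               gene3="GENEB", evalue=0.0, support=None):
    bp5 = Breakpoint("chr1", pos5, "right", gene5, site5)
    bp3 = Breakpoint(chrom3, pos3, "left", gene3, site3)
    cand = FusionCandidate(breakpoint5=bp5, breakpoint3=bp3)
    cand.event_type = "translocation" if chrom3 != "chr1" else "deletion"
    cand.evalue = evalue
    if reads is not None:
        cand.reads = reads
        cand.split_reads5 = len(reads)
    if support is not None:
        cand.split_reads5 = support
    return cand


CLEAN = "ACGTTGCAGATCCGATACGGTTAGCACTGATGCCGTAAGCTTACGGATCA"


def test_support_vs_noise_thresholds():
    assert filter_support_vs_noise(_candidate(support=10, evalue=2.5)).action == "pass"
    # two reads are at/below the detection limit regardless of e-value
    assert filter_support_vs_noise(_candidate(support=2, evalue=0.1)).action == "discard"
    # strict inequality against the e-value
    assert filter_support_vs_noise(_candidate(support=5, evalue=5.0)).action == "discard"
    with pytest.raises(RuntimeError):
        filter_support_vs_noise(_candidate(support=5, evalue=None))


def test_read_artifacts_homopolymer_and_repeats():
    poly = [_split_with_sequence(CLEAN[:42] + "A" * 8, CLEAN, f"r{i}")
            for i in range(3)]
    assert filter_read_artifacts(_candidate(poly)).action == "discard"
    # one clean read among artifactual ones saves the candidate
    mixed = poly[:2] + [_split_with_sequence(CLEAN, CLEAN, "c")]
    assert filter_read_artifacts(_candidate(mixed)).action == "pass"
    # dinucleotide tandem repeat covering >= 12 bases near the junction
    rep = [_split_with_sequence(CLEAN[:36] + "TG" * 7, CLEAN, f"t{i}")
           for i in range(2)]
    assert filter_read_artifacts(_candidate(rep)).action == "discard"
    clean = [_split_with_sequence(CLEAN, CLEAN, f"k{i}") for i in range(2)]
    assert filter_read_artifacts(_candidate(clean)).action == "pass"


def test_read_artifacts_mismatch_excess_binomial():
    """10% mismatches at an assumed 1% error rate fails the exact
    binomial test; the decision matches a direct scipy computation."""
    noisy = [_split_with_sequence(CLEAN, CLEAN, f"n{i}", nm5=5, nm3=5)
             for i in range(2)]
    cand = _candidate(noisy)
    n = sum(s.aligned_length for a in noisy for s in (a.segment5, a.segment3))
    k = sum(s.mismatches for a in noisy for s in (a.segment5, a.segment3))
    assert binom.sf(k - 1, n, 0.01) < 0.01  # oracle agrees it is extreme
    assert filter_read_artifacts(cand).action == "discard"
    ok = [_split_with_sequence(CLEAN, CLEAN, f"o{i}", nm5=1) for i in range(2)]
    assert filter_read_artifacts(_candidate(ok)).action == "pass"


def test_short_anchor_boundary():
    assert filter_short_anchor(
        _candidate([_split_with_sequence(CLEAN, CLEAN)])
    ).action == "pass"
    short = _split_with_sequence(CLEAN, CLEAN, anchor5=10, anchor3=60)
    assert filter_short_anchor(_candidate([short])).action == "discard"
    exact = _split_with_sequence(CLEAN, CLEAN, anchor5=23, anchor3=23)
    assert filter_short_anchor(_candidate([exact])).action == "pass"
    # mate-only candidates pass
    assert filter_short_anchor(_candidate([])).action == "pass"


def test_homologous_genes(toy_annotation, toy_genome):
    # fuse GENEA to a copy of itself on chr2 by aliasing the sequence
    genome = dict(toy_genome)
    genome["chr2"] = genome["chr1"]
    clone = _candidate(gene5="GENEA", gene3="GENEC")
    # GENEC's exons coincide with GENEA's coordinates; with chr2 == chr1
    # the exon sequences are identical -> identity 1.0
    assert filter_homologous_genes(
        clone, toy_annotation, genome
    ).action == "discard"
    random_pair = _candidate(gene5="GENEA", gene3="GENEC")
    assert filter_homologous_genes(
        random_pair, toy_annotation, toy_genome
    ).action == "pass"
    # threshold is strict: identity exactly at the limit passes
    lax = FilterThresholds(max_identity=1.0)
    assert filter_homologous_genes(
        clone, toy_annotation, genome, lax
    ).action == "pass"
    assert filter_homologous_genes(
        clone, toy_annotation, None
    ).detail == "not_evaluable"


def test_blacklist_matching(toy_annotation):
    cand = _candidate()
    assert filter_blacklist(cand, []).action == "pass"
    exact = BlacklistEntry(kind="position_pair", chrom1="chr1", pos1=1199,
                           chrom2="chr2", pos2=5000, tolerance=0)
    assert filter_blacklist(cand, [exact]).action == "discard"
    # inclusive tolerance boundary, order-insensitive
    edge = BlacklistEntry(kind="position_pair", chrom1="chr2", pos1=5010,
                          chrom2="chr1", pos2=1189, tolerance=10)
    assert filter_blacklist(cand, [edge]).action == "discard"
    miss = BlacklistEntry(kind="position_pair", chrom1="chr2", pos1=5011,
                          chrom2="chr1", pos2=1188, tolerance=10)
    assert filter_blacklist(cand, [miss]).action == "pass"
    genes = BlacklistEntry(kind="gene_pair", gene1="GENEB", gene2="GENEA")
    assert filter_blacklist(cand, [genes], toy_annotation).action == "discard"
    region = BlacklistEntry(kind="region", chrom1="chr1",
                            region_start=1000, region_end=1300)
    assert filter_blacklist(cand, [region]).action == "discard"


def _low_support(cand):
    cand.filter_history.append(
        FilterDecision("support_vs_noise", "discard", "low_support:reads=2")
    )
    return cand


def _artifact_discard(cand):
    cand.filter_history.append(
        FilterDecision("read_artifacts", "discard", "low_complexity_junction")
    )
    return cand


def test_splice_site_rescue_rules():
    both = _low_support(_candidate(support=2))
    assert rescue_splice_sites(both).filter_name == "spliced"
    one_intronic = _low_support(_candidate(support=2, site3="intronic"))
    assert rescue_splice_sites(one_intronic) is None
    single_read = _low_support(_candidate(support=1))
    assert rescue_splice_sites(single_read) is None
    # only low-support discards are rescuable
    artifact = _artifact_discard(_candidate(support=2))
    assert rescue_splice_sites(artifact) is None


def test_whitelist_rescue_symmetric():
    whitelist = {frozenset(("GENEB", "GENEA"))}
    listed = _low_support(_candidate(support=1))
    assert rescue_whitelist(listed, whitelist).filter_name == "whitelist"
    unlisted = _low_support(_candidate(support=1, gene3="GENEC"))
    assert rescue_whitelist(unlisted, whitelist) is None
    artifact = _artifact_discard(_candidate(support=1))
    assert rescue_whitelist(artifact, whitelist) is None


def test_structural_variant_rescue_window_and_orientation():
    # breakpoints far from the chromosome starts so SV ends can sit on
    # either side at controlled distances
    def cand():
        return _low_support(_candidate(support=1, pos5=400_000, pos3=800_000))

    def sv(offset5, offset3, o1="right", o2="left"):
        return StructuralVariant(
            chrom1="chr1", pos1=400_001 + offset5, orientation1=o1,
            chrom2="chr2", pos2=800_001 + offset3, orientation2=o2,
        )

    assert rescue_structural_variant(cand(), [sv(-50_000, 50_000)]) is not None
    # exactly at the window boundary: inclusive
    assert rescue_structural_variant(cand(), [sv(100_000, -100_000)]) is not None
    assert rescue_structural_variant(cand(), [sv(150_000, 0)]) is None
    assert rescue_structural_variant(cand(), [sv(0, 0, o1="left")]) is None
    # end order does not matter
    swapped = StructuralVariant(
        chrom1="chr2", pos1=800_001, orientation1="left",
        chrom2="chr1", pos2=400_001, orientation2="right",
    )
    assert has_sv_support(
        _candidate(support=1, pos5=400_000, pos3=800_000), [swapped]
    )


def test_multi_transcript_rescue_needs_four_distinct_spliced():
    def group(positions, shared_gene="GENEA"):
        out = []
        for pos in positions:
            cand = _candidate(pos5=pos, support=1)
            out.append(_low_support(cand))
        return out

    rescued = rescue_multi_transcript(group([1199, 1699, 2199, 2599]))
    assert all(d is not None and d.filter_name == "many_spliced" for d in rescued)
    too_few = rescue_multi_transcript(group([1199, 1699, 2199]))
    assert all(d is None for d in too_few)
    not_distinct = rescue_multi_transcript(group([1199, 1199, 1199, 1199]))
    assert all(d is None for d in not_distinct)


def test_confidence_rules():
    high = _candidate(support=10)
    high.filter_history = [FilterDecision("support_vs_noise", "pass")]
    assert assign_confidence(high) == "high"
    spliced_rescue = _low_support(_candidate(support=2))
    spliced_rescue.filter_history.append(FilterDecision("spliced", "rescue"))
    assert assign_confidence(spliced_rescue) == "low"
    intronic_sv = _candidate(support=5, site3="intronic")
    assert assign_confidence(intronic_sv, sv_supported=True) == "medium"
    sv_rescue = _low_support(_candidate(support=1))
    sv_rescue.filter_history.append(FilterDecision("sv_support", "rescue"))
    assert assign_confidence(sv_rescue) == "medium"
    sparse = _candidate(support=2, site5="exonic", site3="intronic")
    assert assign_confidence(sparse) == "low"
    with pytest.raises(RuntimeError):
        assign_confidence(_artifact_discard(_candidate(support=9)))


def test_run_filters_conservation_and_determinism(toy_annotation):
    from fusionsieve.filters import FilterResources, run_filters

    def build():
        cands = []
        for i in range(30):
            rng = random.Random(i)
            support = rng.randint(1, 6)
            cand = _candidate(
                support=support,
                pos5=1199 if i % 2 else 1100,
                site5="splice_site" if i % 2 else "exonic",
                evalue=0.01 * i,
            )
            cand.breakpoint5.position += i  # distinct candidates
            cand.reads = [
                _split_with_sequence(CLEAN, CLEAN, f"c{i}_{j}")
                for j in range(support)
            ]
            cands.append(cand)
        return cands

    resources = FilterResources(annotation=toy_annotation)
    kept1, discarded1 = run_filters(build(), resources)
    assert len(kept1) + len(discarded1) == 30
    histories1 = [
        [(d.filter_name, d.action) for d in c.filter_history]
        for c in kept1 + discarded1
    ]
    kept2, discarded2 = run_filters(build(), resources)
    histories2 = [
        [(d.filter_name, d.action) for d in c.filter_history]
        for c in kept2 + discarded2
    ]
    assert histories1 == histories2
    assert [c.confidence for c in kept1] == [c.confidence for c in kept2]
    # rescue soundness: a rescue directly follows the (single) discard
    for cand in kept1 + discarded1:
        actions = [d.action for d in cand.filter_history]
        assert actions.count("discard") <= 1
        if "rescue" in actions:
            assert actions.index("rescue") == actions.index("discard") + 1


def test_added_support_never_discards_a_kept_candidate(toy_annotation):
    from fusionsieve.filters import FilterResources, run_filters

    def run_one(support):
        cand = _candidate(support=support, evalue=0.5)
        cand.reads = [
            _split_with_sequence(CLEAN, CLEAN, f"r{j}") for j in range(support)
        ]
        kept, _ = run_filters([cand], FilterResources(annotation=toy_annotation))
        return bool(kept)

    outcomes = [run_one(s) for s in range(1, 12)]
    # once kept, more support never flips the outcome back to discarded
    first_kept = outcomes.index(True)
    assert all(outcomes[first_kept:])
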
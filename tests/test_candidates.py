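"""Candidate assembly: event typing, grouping, orientation, tallies."""

import random

import pytest

from fusionsieve.alignments import (
    AlignmentSegment,
    ChimericAlignment,
    read_chimeric_alignments,
)
from fusionsieve.annotation import read_gene_annotation
from fusionsieve.candidates import (
    Breakpoint,
    assemble_candidates,
    classify_event_type,
    orient_breakpoints,
    tally_gene_stats,
)
from fusionsieve.fixtures import (
    FixtureSpec,
    NoiseConfig,
    PlantedFusion,
    generate_bundle,
)


def _bp(chrom, pos, direction):
    return Breakpoint(chromosome=chrom, position=pos, direction=direction)


# Geometric definitions, enumerated: a left-directed breakpoint retains
# sequence to its right, a right-directed one to its left.  Opposite
# directions with the left-directed break at the higher coordinate lose
# the intervening segment (deletion); at the lower coordinate the
# segment is traversed twice (duplication); equal directions join one
# partner in reversed orientation (inversion).
EVENT_CASES = [
    (("chr1", 1000, "right"), ("chr2", 5000, "left"), "translocation"),
    (("chr1", 1000, "right"), ("chr1", 9000, "left"), "deletion"),
    (("chr1", 9000, "left"), ("chr1", 1000, "right"), "deletion"),
    (("chr1", 9000, "right"), ("chr1", 1000, "left"), "duplication"),
    (("chr1", 1000, "left"), ("chr1", 9000, "right"), "duplication"),
    (("chr1", 1000, "right"), ("chr1", 9000, "right"), "inversion"),
    (("chr1", 1000, "left"), ("chr1", 9000, "left"), "inversion"),
    (("chr1", 9000, "left"), ("chr1", 1000, "left"), "inversion"),
]


@pytest.mark.parametrize("a,b,expected", EVENT_CASES)
def test_event_type_enumeration(a, b, expected):
    assert classify_event_type(_bp(*a), _bp(*b)) == expected


def test_orientation_follows_gene_strand(toy_annotation):
    """GENEC is on the minus strand: a left-directed break there retains
    the gene's 5' region, so GENEC becomes the 5' partner even though
    it sorts after the other breakpoint."""
    bp_c = _bp("chr2", 1500, "left")
    bp_c.gene_id = "GENEC"
    bp_d = _bp("chr2", 5100, "left")
    bp_d.gene_id = "GENED"  # plus strand, direction left: 3'-compatible
    bp5, bp3 = orient_breakpoints(bp_d, bp_c, toy_annotation)
    assert bp5.gene_id == "GENEC"
    # both intergenic: coordinate order decides
    i1, i2 = _bp("chr1", 9000, "left"), _bp("chr1", 3000, "left")
    bp5, bp3 = orient_breakpoints(i1, i2, toy_annotation)
    assert bp5.position == 3000


def _split(chrom5, j5, d5, chrom3, j3, d3, read_id, anchor5=50, anchor3=50):
    def seg(chrom, junction, direction, anchor):
        if direction == "right":
            start, end = junction - anchor + 1, junction + 1
        else:
            start, end = junction, junction + anchor
        return AlignmentSegment(
            read_id=read_id, chromosome=chrom, start=start, end=end,
            strand="+", aligned_length=anchor, left_clip=0, right_clip=0,
            mismatches=0, sequence="",
        )

    return ChimericAlignment(
        kind="split_read",
        segment5=seg(chrom5, j5, d5, anchor5),
        segment3=seg(chrom3, j3, d3, anchor3),
        junction5=j5, junction3=j3, direction5=d5, direction3=d3,
        anchor5=anchor5, anchor3=anchor3,
    )


def test_identical_junction_split_reads_merge(toy_annotation):
    alignments = [
        _split("chr1", 1199, "right", "chr1", 5500, "left", f"r{i}")
        for i in range(3)
    ]
    candidates, stats = assemble_candidates(alignments, toy_annotation)
    assert len(candidates) == 1
    assert candidates[0].supporting_reads == 3
    assert candidates[0].event_type == "deletion"
    assert stats.total_candidates == 1
    assert stats.total_candidates_of_gene["GENEA"] == 1
    assert stats.total_candidates_of_gene["GENEB"] == 1


def test_split_read_partition_by_longer_segment(toy_annotation):
    alignments = [
        _split("chr1", 1199, "right", "chr1", 5500, "left", "a", 70, 30),
        _split("chr1", 1199, "right", "chr1", 5500, "left", "b", 30, 70),
    ]
    (cand,), _ = assemble_candidates(alignments, toy_annotation)
    assert (cand.split_reads5, cand.split_reads3) == (1, 1)


def test_duplicates_excluded_from_support(toy_annotation):
    keep = _split("chr1", 1199, "right", "chr1", 5500, "left", "a")
    dup = _split("chr1", 1199, "right", "chr1", 5500, "left", "b")
    dup.duplicate_flag = True
    candidates, _ = assemble_candidates([keep, dup], toy_annotation)
    assert candidates[0].supporting_reads == 1


def _bundle(tmp_path, seed, fusions, noise, n_genes=6):
    spec = FixtureSpec(
        n_genes=n_genes,
        exons_per_gene=3,
        exon_length=150,
        intron_length=80,
        intergenic_gap=400,
        background_pairs_per_gene=0,
        fusions=fusions,
        noise=noise,
        seed=seed,
    )
    paths = generate_bundle(spec, tmp_path / f"bundle{seed}")
    annotation = read_gene_annotation(str(paths["annotation"]))
    return spec, paths, annotation


def random_fixture_spec(seed: int):
    rng = random.Random(seed)
    genes = [f"GENE{i + 1:03d}" for i in range(6)]
    fusions = []
    for k in range(rng.randint(1, 2)):
        g5, g3 = rng.sample(genes, 2)
        fusions.append(
            PlantedFusion(
                gene5=g5, gene3=g3,
                split_reads=rng.randint(2, 5),
                discordant_pairs=rng.randint(0, 2),
                at_splice_sites=rng.random() < 0.6,
                name=f"f{k + 1}",
            )
        )
    return tuple(fusions), NoiseConfig(rate_per_gene=1.0)


def brute_force_groups(alignments, window=500):
    """O(n^2) all-pairs grouping oracle over unordered junction keys.

    Split reads group by exact junction equality; each discordant pair
    is assigned to a split group when both of its breakpoints match one
    group's junctions in chromosome and direction within the window,
    otherwise discordant pairs group among themselves by chromosome
    pair and directions.
    """
    def jkey(aln):
        return tuple(sorted([
            (aln.segment5.chromosome, aln.junction5, aln.direction5),
            (aln.segment3.chromosome, aln.junction3, aln.direction3),
        ]))

    splits = {}
    mates = []
    for aln in alignments:
        if aln.duplicate_flag:
            continue
        if aln.kind == "split_read":
            splits.setdefault(jkey(aln), []).append(aln)
        else:
            mates.append(aln)

    attached = {key: 0 for key in splits}
    loose = {}
    for aln in mates:
        ends = [
            (aln.segment5.chromosome, aln.junction5, aln.direction5),
            (aln.segment3.chromosome, aln.junction3, aln.direction3),
        ]
        hits = []
        for key in splits:
            for pairing in (list(key), list(key)[::-1]):
                if all(
                    e[0] == k[0] and e[2] == k[2] and abs(e[1] - k[1]) <= window
                    for e, k in zip(ends, pairing)
                ):
                    gap = sum(abs(e[1] - k[1]) for e, k in zip(ends, pairing))
                    hits.append((gap, key))
        if hits:
            # nearest candidate wins; ties go to the smallest junction key
            attached[min(hits)[1]] += 1
        else:
            lkey = tuple(sorted((e[0], e[2]) for e in ends))
            loose[lkey] = loose.get(lkey, 0) + 1
    return splits, attached, loose


@pytest.mark.parametrize("seed", range(8))
def test_assembly_matches_brute_force_oracle(tmp_path, seed):
    fusions, noise = random_fixture_spec(seed)
    spec, paths, annotation = _bundle(tmp_path, seed, fusions, noise)
    alignments = list(
        read_chimeric_alignments(paths["chimeric_sam"], "separate_file")
    )
    candidates, stats = assemble_candidates(alignments, annotation)

    splits, attached, loose = brute_force_groups(alignments)
    got_split = {
        tuple(sorted([c.breakpoint5.key, c.breakpoint3.key])): c
        for c in candidates
        if c.split_reads5 + c.split_reads3 > 0
    }
    assert set(got_split) == set(splits)
    for key, group in splits.items():
        cand = got_split[key]
        assert cand.split_reads5 + cand.split_reads3 == len(group)
        assert cand.discordant_mates == attached[key]
    got_loose = sum(
        c.discordant_mates for c in candidates
        if c.split_reads5 + c.split_reads3 == 0
    )
    assert got_loose == sum(loose.values())
    # conservation: every non-duplicate alignment in exactly one candidate
    assert sum(c.supporting_reads for c in candidates) == len(
        [a for a in alignments if not a.duplicate_flag]
    )


@pytest.mark.parametrize("seed", [3, 11])
def test_assembly_is_order_independent(tmp_path, seed):
    fusions, noise = random_fixture_spec(seed)
    spec, paths, annotation = _bundle(tmp_path, seed, fusions, noise)
    alignments = list(
        read_chimeric_alignments(paths["chimeric_sam"], "separate_file")
    )
    baseline, base_stats = assemble_candidates(alignments, annotation)
    shuffled = alignments[:]
    random.Random(99).shuffle(shuffled)
    permuted, perm_stats = assemble_candidates(shuffled, annotation)
    assert [c.key for c in baseline] == [c.key for c in permuted]
    assert [
        (c.split_reads5, c.split_reads3, c.discordant_mates) for c in baseline
    ] == [(c.split_reads5, c.split_reads3, c.discordant_mates) for c in permuted]
    assert base_stats == perm_stats


def test_tally_matches_brute_force_recount(tmp_path):
    fusions, noise = random_fixture_spec(5)
    spec, paths, annotation = _bundle(tmp_path, 5, fusions, noise)
    alignments = read_chimeric_alignments(paths["chimeric_sam"], "separate_file")
    candidates, stats = assemble_candidates(alignments, annotation, mapped_reads=123)

    total = len(candidates)
    inversions = sum(c.event_type == "inversion" for c in candidates)
    duplications = sum(c.event_type == "duplication" for c in candidates)
    sites = {"intronic": 0, "exonic": 0, "splice_site": 0}
    per_gene = {}
    for cand in candidates:
        for bp in (cand.breakpoint5, cand.breakpoint3):
            if bp.gene_id is None:
                continue
            per_gene[bp.gene_id] = per_gene.get(bp.gene_id, 0) + 1
            sites[bp.site] += 1
    assert stats.total_candidates == total
    assert stats.total_inversions == inversions
    assert stats.total_duplications == duplications
    assert stats.total_intronic_candidates == sites["intronic"]
    assert stats.total_exonic_candidates == sites["exonic"]
    assert stats.total_spliced_candidates == sites["splice_site"]
    assert dict(stats.total_candidates_of_gene) == per_gene
    assert stats.mapped_reads == 123
    # conservation across genic breakpoints
    genic = sum(len(c.gene_ids()) for c in candidates)
    assert sum(per_gene.values()) == genic
    assert stats.total_inversions + stats.total_duplications <= total


def test_gapped_encoding_equivalent_to_chimeric(tmp_path):
    """A focal deletion planted as gapped alignments yields the same
    candidate (breakpoints and split support) as the same event planted
    as true chimeric records."""
    from fusionsieve.alignments import detect_boundary_spanning

    results = {}
    for encoding in ("chimeric", "gapped"):
        fusion = PlantedFusion(
            gene5="GENE001", gene3="GENE003", split_reads=4,
            discordant_pairs=0, encoding=encoding, name="del1",
        )
        spec, paths, annotation = _bundle(
            tmp_path / encoding, 7, (fusion,), NoiseConfig()
        )
        if encoding == "chimeric":
            alignments = list(
                read_chimeric_alignments(paths["chimeric_sam"], "separate_file")
            )
        else:
            alignments = detect_boundary_spanning(paths["main_sam"], annotation)
        candidates, _ = assemble_candidates(alignments, annotation)
        assert len(candidates) == 1
        cand = candidates[0]
        results[encoding] = (
            cand.breakpoint5.key,
            cand.breakpoint3.key,
            cand.split_reads5 + cand.split_reads3,
            cand.event_type,
        )
    assert results["chimeric"] == results["gapped"]
    assert results["chimeric"][3] == "deletion"
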
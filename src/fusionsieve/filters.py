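"""Negative filters, positive rescues, and confidence classing.

Negatively selecting filters discard likely artifacts: blacklisted
positions/genes, homologous fusion partners, reads with junction-
proximal homopolymers/tandem repeats or excess mismatches, short
anchors, and — last — candidates with no more supporting reads than
the modelled background noise.  Positively selecting filters rescue
candidates discarded *only* for low support, when independent evidence
argues they are genuine: a whitelist entry, a corroborating structural
variant, both breakpoints on splice sites, or at least four distinct
spliced breakpoints linking the same gene pair.  Artifact discards are
final; the rescues address sensitivity, not specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy.stats import binom

from .annotation import SITE_SPLICE, AnnotationIndex
from .alignments import KIND_SPLIT
from .candidates import FilterDecision, FusionCandidate
from .constants import FilterThresholds
from .io import BlacklistEntry, StructuralVariant

CONFIDENCE_HIGH = "high"
CONFIDENCE_MEDIUM = "medium"
CONFIDENCE_LOW = "low"

LOW_SUPPORT = "low_support"
RESCUABLE = {LOW_SUPPORT}

logger = logging.getLogger("fusionsieve.filters")


def _log_decision(cand: FusionCandidate, decision: FilterDecision) -> None:
    if decision.action == "pass":
        return
    bp5, bp3 = cand.breakpoint5, cand.breakpoint3
    logger.debug(
        "%s %s %s:%d--%s:%d %s",
        decision.action, decision.filter_name,
        bp5.chromosome, bp5.position + 1,
        bp3.chromosome, bp3.position + 1,
        decision.detail,
    )


@dataclass
class FilterResources:
    """Everything the filter cascade consumes besides the candidates."""

    annotation: AnnotationIndex
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    blacklist: list[BlacklistEntry] = field(default_factory=list)
    whitelist: set[frozenset] = field(default_factory=set)
    structural_variants: list[StructuralVariant] = field(default_factory=list)
    #: chromosome-name -> sequence mapping (e.g. a pyfaidx Fasta)
    genome: Mapping | None = None


# ---------------------------------------------------------------------------
# negatively selecting filters


def filter_support_vs_noise(
    candidate: FusionCandidate, thresholds: FilterThresholds = FilterThresholds()
) -> FilterDecision:
    """Keep only candidates with more supporting reads than the
    estimated background noise, and at least ``min_support`` reads
    (two or fewer reads is at/below the detection limit)."""
    if candidate.evalue is None:
        raise RuntimeError("e-value must be computed before the noise filter")
    reads = candidate.supporting_reads
    if reads > candidate.evalue and reads >= thresholds.min_support:
        return FilterDecision("support_vs_noise", "pass")
    return FilterDecision(
        "support_vs_noise",
        "discard",
        f"{LOW_SUPPORT}:reads={reads},evalue={candidate.evalue:.3g}",
    )


def _has_homopolymer(seq: str, min_len: int) -> bool:
    run = 0
    prev = ""
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        if run >= min_len:
            return True
    return False


def _has_tandem_repeat(seq: str, unit_max: int, min_span: int) -> bool:
    n = len(seq)
    for unit in range(1, unit_max + 1):
        run = unit  # a periodic stretch includes its first unit
        for i in range(unit, n):
            if seq[i] == seq[i - unit]:
                run += 1
                if run >= min_span:
                    return True
            else:
                run = unit
    return False


def _junction_windows(aln, window: int) -> list[str]:
    """Aligned subsequence adjacent to the junction on each segment.

    Low-complexity detection is orientation-insensitive, so the SAM
    orientation of the stored sequence is scanned directly.
    """
    out = []
    for seg, direction in (
        (aln.segment5, aln.direction5),
        (aln.segment3, aln.direction3),
    ):
        if not seg.sequence:
            continue
        aligned = seg.sequence[
            seg.left_clip: len(seg.sequence) - seg.right_clip or None
        ]
        if not aligned:
            continue
        # the junction sits at the reference end matching the direction
        if direction == "right":
            out.append(aligned[-window:] if seg.strand == "+" else aligned[:window])
        else:
            out.append(aligned[:window] if seg.strand == "+" else aligned[-window:])
    return out


def filter_read_artifacts(
    candidate: FusionCandidate,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterDecision:
    """Discard candidates whose support looks like a sequence artifact.

    Two tests: (a) every supporting split read carries a homopolymer or
    short-unit tandem repeat in the junction-proximal window — genuine
    fusions are not systematically anchored in low-complexity sequence;
    (b) the pooled mismatch rate across supporting segments exceeds the
    upper binomial quantile expected from the per-base error rate.
    """
    name = "read_artifacts"
    splits = [r for r in candidate.reads if r.kind == KIND_SPLIT]
    window_sets = [
        _junction_windows(aln, thresholds.artifact_window) for aln in splits
    ]
    window_sets = [ws for ws in window_sets if ws]
    if splits and not window_sets:
        return FilterDecision(name, "pass", "not_evaluable")
    if window_sets and all(
        any(
            _has_homopolymer(w, thresholds.homopolymer_len)
            or _has_tandem_repeat(
                w, thresholds.repeat_unit_max, thresholds.repeat_min_span
            )
            for w in ws
        )
        for ws in window_sets
    ):
        return FilterDecision(name, "discard", "low_complexity_junction")

    aligned_bases = 0
    mismatches = 0
    for aln in candidate.reads:
        for seg in (aln.segment5, aln.segment3):
            aligned_bases += seg.aligned_length
        mismatches += aln.segment5.mismatches + aln.segment3.mismatches
    if aligned_bases > 0 and mismatches / aligned_bases > thresholds.mismatch_rate:
        # one-sided exact binomial test for mismatch excess
        p_tail = binom.sf(mismatches - 1, aligned_bases, thresholds.mismatch_rate)
        if p_tail < thresholds.mismatch_alpha:
            return FilterDecision(
                name,
                "discard",
                f"mismatch_excess:{mismatches}/{aligned_bases}",
            )
    return FilterDecision(name, "pass")


def filter_short_anchor(
    candidate: FusionCandidate,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterDecision:
    """Require at least one split read anchored with >= ``min_anchor``
    aligned bases on both sides of the junction.  Mate-only candidates
    pass (their anchors are entire mate alignments)."""
    splits = [r for r in candidate.reads if r.kind == KIND_SPLIT]
    if not splits:
        return FilterDecision("short_anchor", "pass", "mate_only")
    best = max(min(r.anchor5, r.anchor3) for r in splits)
    if best >= thresholds.min_anchor:
        return FilterDecision("short_anchor", "pass")
    return FilterDecision(
        "short_anchor", "discard", f"best_min_anchor={best}"
    )


def _gene_sequence(gene, genome: Mapping) -> str:
    chrom = str(genome[gene.chromosome])
    return "".join(chrom[s:e] for s, e in gene.exons).upper()


_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i: i + k]
        out.add(min(kmer, kmer.translate(_REVCOMP)[::-1]))
    return out


def filter_homologous_genes(
    candidate: FusionCandidate,
    annotation: AnnotationIndex,
    genome: Mapping | None,
    thresholds: FilterThresholds = FilterThresholds(),
    _cache: dict | None = None,
) -> FilterDecision:
    """Discard fusions between homologous genes.

    Chimeric alignments between paralogs are usually mapping artifacts.
    Homology is measured as the fraction of shared (strand-canonical)
    k-mers between the two genes' exon-union sequences, normalized by
    the smaller gene's k-mer count; the candidate is discarded when the
    fraction strictly exceeds ``max_identity``.
    """
    name = "homologs"
    bp5, bp3 = candidate.breakpoint5, candidate.breakpoint3
    if bp5.gene_id is None or bp3.gene_id is None or bp5.gene_id == bp3.gene_id:
        return FilterDecision(name, "pass")
    if genome is None:
        return FilterDecision(name, "pass", "not_evaluable")
    cache = _cache if _cache is not None else {}

    def kmers(gene_id: str) -> set[str]:
        if gene_id not in cache:
            cache[gene_id] = _canonical_kmers(
                _gene_sequence(annotation.genes[gene_id], genome),
                thresholds.homology_k,
            )
        return cache[gene_id]

    k5, k3 = kmers(bp5.gene_id), kmers(bp3.gene_id)
    smaller = min(len(k5), len(k3))
    if smaller == 0:
        return FilterDecision(name, "pass", "not_evaluable")
    identity = len(k5 & k3) / smaller
    if identity > thresholds.max_identity:
        return FilterDecision(name, "discard", f"identity={identity:.2f}")
    return FilterDecision(name, "pass")


def filter_blacklist(
    candidate: FusionCandidate,
    blacklist: list[BlacklistEntry],
    annotation: AnnotationIndex | None = None,
) -> FilterDecision:
    """Discard candidates matching a recurrent-artifact blacklist."""
    names: set[str] = set()
    if annotation is not None:
        for gid in candidate.gene_ids():
            names.add(gid)
            names.add(annotation.genes[gid].gene_name)
    for entry in blacklist:
        if entry.matches(candidate, names):
            return FilterDecision("blacklist", "discard", entry.kind)
    return FilterDecision("blacklist", "pass")


# ---------------------------------------------------------------------------
# positively selecting filters (rescues)


def _discard_reason(candidate: FusionCandidate) -> str | None:
    for decision in candidate.filter_history:
        if decision.action == "discard":
            return decision.detail.split(":", 1)[0]
    return None


def _rescuable(candidate: FusionCandidate) -> bool:
    return _discard_reason(candidate) in RESCUABLE


def rescue_splice_sites(
    candidate: FusionCandidate,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterDecision | None:
    """Rescue low-support candidates with both breakpoints on splice
    sites (strong evidence of a genuine spliced fusion transcript)."""
    if not _rescuable(candidate):
        return None
    if (
        candidate.breakpoint5.site == SITE_SPLICE
        and candidate.breakpoint3.site == SITE_SPLICE
        and candidate.supporting_reads >= thresholds.rescue_min
    ):
        return FilterDecision("spliced", "rescue")
    return None


def rescue_whitelist(
    candidate: FusionCandidate,
    whitelist: set[frozenset],
    annotation: AnnotationIndex | None = None,
) -> FilterDecision | None:
    """Rescue low-support candidates between whitelisted gene pairs
    (known/highly recurrent fusions warrant sensitive parameters)."""
    if not _rescuable(candidate) or not whitelist:
        return None
    if candidate.supporting_reads < 1:
        return None
    ids5 = _name_set(candidate.breakpoint5, annotation)
    ids3 = _name_set(candidate.breakpoint3, annotation)
    for name5 in ids5:
        for name3 in ids3:
            if frozenset((name5, name3)) in whitelist:
                return FilterDecision("whitelist", "rescue", f"{name5}--{name3}")
    return None


def _name_set(bp, annotation: AnnotationIndex | None) -> set[str]:
    if bp.gene_id is None:
        return set()
    names = {bp.gene_id}
    if annotation is not None:
        names.add(annotation.genes[bp.gene_id].gene_name)
    return names


def has_sv_support(
    candidate: FusionCandidate,
    svs: list[StructuralVariant],
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """Whether a structural variant corroborates the candidate: both SV
    ends within ``sv_window`` bp of the respective breakpoints with
    matching orientations (in either end order)."""
    bp5, bp3 = candidate.breakpoint5, candidate.breakpoint3
    for sv in svs:
        ends = (
            (sv.chrom1, sv.pos1 - 1, sv.orientation1),
            (sv.chrom2, sv.pos2 - 1, sv.orientation2),
        )
        for (c1, p1, o1), (c2, p2, o2) in (ends, ends[::-1]):
            if (
                c1 == bp5.chromosome
                and o1 == bp5.direction
                and abs(p1 - bp5.position) <= thresholds.sv_window
                and c2 == bp3.chromosome
                and o2 == bp3.direction
                and abs(p2 - bp3.position) <= thresholds.sv_window
            ):
                return True
    return False


def rescue_structural_variant(
    candidate: FusionCandidate,
    svs: list[StructuralVariant],
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterDecision | None:
    """Rescue low-support candidates corroborated by a structural
    variant from whole-genome sequencing."""
    if not _rescuable(candidate) or not svs:
        return None
    if has_sv_support(candidate, svs, thresholds):
        return FilterDecision("sv_support", "rescue")
    return None


def rescue_multi_transcript(
    group: list[FusionCandidate],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[FilterDecision | None]:
    """Rescue every low-support member of a gene-pair group linked by
    at least four distinct fusion transcripts, as evidenced by four or
    more distinct breakpoints coinciding with a splice site in one of
    the genes (not necessarily in both)."""
    distinct: dict[str, set[int]] = {}
    for cand in group:
        for bp in (cand.breakpoint5, cand.breakpoint3):
            if bp.gene_id is not None and bp.site == SITE_SPLICE:
                distinct.setdefault(bp.gene_id, set()).add(bp.position)
    qualified = any(
        len(positions) >= thresholds.multi_transcript_min
        for positions in distinct.values()
    )
    out: list[FilterDecision | None] = []
    for cand in group:
        if qualified and _rescuable(cand):
            out.append(FilterDecision("many_spliced", "rescue"))
        else:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# confidence and orchestration


def assign_confidence(
    candidate: FusionCandidate,
    sv_supported: bool = False,
    thresholds: FilterThresholds = FilterThresholds(),
) -> str:
    """Three-level confidence for a kept candidate.

    High: never discarded, ample support and both breakpoints at splice
    sites.  Medium: never discarded but missing one of those criteria,
    or rescued on group-level/genomic evidence (multi-transcript, SV).
    Low: rescued on single-candidate evidence (spliced pair,
    whitelist), or sparse support with non-spliced breakpoints.
    """
    if candidate.discarded:
        raise RuntimeError("confidence is assigned to kept candidates only")
    rescues = [d.filter_name for d in candidate.filter_history if d.action == "rescue"]
    if rescues:
        if rescues[0] in ("many_spliced", "sv_support"):
            return CONFIDENCE_MEDIUM
        return CONFIDENCE_LOW
    both_spliced = (
        candidate.breakpoint5.site == SITE_SPLICE
        and candidate.breakpoint3.site == SITE_SPLICE
    )
    ample = candidate.supporting_reads >= thresholds.high_confidence_support
    if ample and both_spliced:
        return CONFIDENCE_HIGH
    if ample or both_spliced or sv_supported:
        return CONFIDENCE_MEDIUM
    return CONFIDENCE_LOW


def run_filters(
    candidates: Iterable[FusionCandidate], resources: FilterResources
) -> tuple[list[FusionCandidate], list[FusionCandidate]]:
    """Apply the full cascade and return (kept, discarded).

    Order: blacklist, homologs, read artifacts, short anchors, then the
    support-vs-noise model; rescues (whitelist, structural variant,
    spliced breakpoints, multi-transcript) apply only to candidates
    discarded by the noise filter, so that every rescue has a single
    discard source.  Every input candidate ends up in exactly one of
    the two output lists.
    """
    if resources.annotation is None:
        raise RuntimeError("filter cascade requires a gene annotation")
    thresholds = resources.thresholds
    candidates = list(candidates)
    homology_cache: dict = {}
    for cand in candidates:
        stages = [
            filter_blacklist(cand, resources.blacklist, resources.annotation),
            filter_homologous_genes(
                cand, resources.annotation, resources.genome, thresholds,
                homology_cache,
            ),
            filter_read_artifacts(cand, thresholds),
            filter_short_anchor(cand, thresholds),
            filter_support_vs_noise(cand, thresholds),
        ]
        for decision in stages:
            cand.filter_history.append(decision)
            _log_decision(cand, decision)
            if decision.action == "discard":
                break
        if not cand.discarded:
            continue
        for rescue in (
            rescue_whitelist(cand, resources.whitelist, resources.annotation),
            rescue_structural_variant(
                cand, resources.structural_variants, thresholds
            ),
            rescue_splice_sites(cand, thresholds),
        ):
            if rescue is not None:
                cand.filter_history.append(rescue)
                _log_decision(cand, rescue)
                break

    # group-level rescue across each gene pair
    groups: dict[frozenset, list[FusionCandidate]] = {}
    for cand in candidates:
        ids = cand.gene_ids()
        if len(ids) == 2:
            groups.setdefault(frozenset(ids), []).append(cand)
    for key in sorted(groups, key=sorted):
        group = groups[key]
        for cand, rescue in zip(group, rescue_multi_transcript(group, thresholds)):
            if rescue is not None and not any(
                d.action == "rescue" for d in cand.filter_history
            ):
                cand.filter_history.append(rescue)
                _log_decision(cand, rescue)

    kept, discarded = [], []
    for cand in candidates:
        if cand.discarded:
            discarded.append(cand)
        else:
            sv_ok = bool(resources.structural_variants) and has_sv_support(
                cand, resources.structural_variants, thresholds
            )
            cand.confidence = assign_confidence(cand, sv_ok, thresholds)
            kept.append(cand)
    return kept, discarded
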
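# Methods

## Evidence extraction

Fusion evidence is read from SAM streams in the conventions of spliced
aligners: a split read is a primary record plus a supplementary record
with complementary clipping; a discordant mate pair is an improperly
paired read pair.  Two input modes exist — a dedicated chimeric file
(every record belongs to a chimeric read) and a full alignment stream,
where chimeric reads are recognized by supplementary flags and, for
pairs, by improper-pair geometry (different chromosomes, same-strand
mates, or an inner distance above 2 kb; the last bound is a
compromise — smaller values would misclassify long-insert concordant
pairs, larger ones would miss short-range rearrangements backed only
by mates).

Junction coordinates follow from segment geometry.  Internally all
coordinates are 0-based half-open; every printed position is 1-based.
A breakpoint's *direction* names the side on which the fused partner
attaches: the read continues past the right end of a plus-strand 5'
segment (direction `right`), past the left end of a minus-strand one
(direction `left`), and mirrored for the 3' segment.  A discordant
mate points at the junction with its 3' end.

Gapped alignments whose intron-like gap joins two different annotated
genes are converted into synthetic split reads with junctions at the
gap edges.  This recovers fusions caused by focal deletions, which
aligners encode as splicing because the intron/chimera decision is
made on gap size alone; gaps within one gene are normal splicing and
are ignored.

Duplicates are removed from support and from mapped-read totals: the
SAM duplicate flag is honored, and unflagged alignments with identical
coordinates, strands and clipping are treated as copies of one
fragment.  PCR duplication would otherwise inflate read support.

## Candidate assembly

Split reads merge only on exact junction equality (split junctions are
base-precise).  Discordant pairs attach to a split-read candidate when
chromosomes and directions match and both mates end within the
insert-size window (default 500 bp) of the respective junctions; with
equal directions (inversions) both end pairings are tried.  When
several candidates qualify, the smallest total breakpoint distance
wins, with ties resolved by junction key — this makes assembly a pure
function of the input set, independent of record order.  Pairs
matching no split candidate merge into mate-only candidates keyed by
gene pair and directions; their breakpoint estimate is the innermost
mate end on each side.

The 5'/3' order of a candidate's breakpoints follows transcription:
the partner whose retained side contains its transcription start is
the 5' gene; if gene strands leave this unresolved (or both sides are
intergenic), coordinate order decides.  Event types are geometric:
different chromosomes → translocation; equal directions → inversion;
otherwise deletion when the left-directed breakpoint has the higher
coordinate, else duplication.

When a breakpoint overlaps several genes, the gene whose exon contains
it wins over span-only overlap, then the longer exon union, then the
smaller identifier.  Site classes use internal exon edges only: a
transcript's outermost ends are not donor/acceptor sites.

## Noise model

The e-value model and its constants are described in the README.  The
constants are shipped as fixed defaults (they were calibrated on a
large clinical RNA-seq cohort and are stable across data sets) and can
be overridden via the config file; no refitting is implemented.
Numerical notes:

- All factors are computed in double precision; the only clamp is the
  printed one (no distance penalty at >= 400 kb or across
  chromosomes).  The two distance regimes do not meet continuously at
  400 bp; the model is applied exactly as calibrated.
- The per-gene base level of a two-gene candidate is the maximum of
  the two genes' levels (the conservative choice; the combination rule
  is otherwise unconstrained).
- Intron/exon/splice tallies are counted per breakpoint, because a
  candidate's two breakpoints can differ in class; the ratio factor of
  a candidate is the product over its classified breakpoints, and the
  denominator is the grand classified-breakpoint count.  Intergenic
  breakpoints contribute factor 1 and are excluded from per-gene
  tallies.
- Intergenic breakpoints have no exon length to normalize by; they
  borrow a 10 kb pseudo-gene window centered on the breakpoint, with
  the number of intergenic candidate breakpoints inside the window as
  the candidate count.  10 kb is of the order of a typical gene
  footprint; the choice only affects candidates outside any
  annotation.

## Filter cascade

Order: blacklist → homologous genes → read artifacts → short anchors →
support vs noise; rescues apply only to candidates discarded by the
noise filter, so every rescue has a single discard source, and
artifact discards are final (rescuing a sequence artifact would defeat
the artifact filters).  Thresholds, all config-exposed:

| parameter | default | meaning |
|---|---|---|
| `min_support` | 3 reads | absolute detection limit (<= 2 reads is at/below it) |
| `rescue_min` | 2 reads | minimum support for the splice-site rescue |
| `homopolymer_len` | 6 bp | run length flagged near the junction |
| `repeat_unit_max` / `repeat_min_span` | 4 / 12 bp | tandem-repeat motif flagged near the junction |
| `artifact_window` | 30 bp | junction-proximal window scanned per segment |
| `mismatch_rate` / `mismatch_alpha` | 0.01 / 0.01 | per-base error rate and level of the one-sided exact binomial excess test |
| `min_anchor` | 23 bp | at least one split read must reach this on both sides |
| `homology_k` / `max_identity` | 16 / 0.30 | shared canonical k-mer fraction (normalized by the smaller gene) above which partners count as homologs |
| `sv_window` | 100 kb | breakpoint-to-SV corroboration distance, orientations must match |
| `mate_window` | 500 bp | discordant-mate attachment window |
| `multi_transcript_min` | 4 | distinct spliced breakpoints in one gene required for the group rescue |
| `blacklist_tolerance` | 100 bp | default tolerance of position-pair blacklist entries |

The low-complexity test discards only when *every* supporting split
read carries a flagged motif in its junction window; a single clean
read keeps the candidate alive.  The mismatch test pools NM counts
over all supporting segments and discards when the observed count is
in the upper `mismatch_alpha` tail of a binomial with the assumed
per-base error rate.  Only the 100 kb structural-variant window and
the four-distinct-spliced-breakpoints rule are fixed by the method
description; the remaining thresholds are package defaults.

Confidence classes (config-exposed policy, not a calibrated
probability): `high` = never discarded, >= 4 supporting reads and both
breakpoints at splice sites; `medium` = never discarded but missing
one of those criteria (structural-variant corroboration also lifts a
sparse candidate to medium), or rescued on group/genomic evidence
(multi-transcript, SV); `low` = rescued on single-candidate evidence
(spliced pair, whitelist) or sparse non-spliced support.

## Sequence and peptide annotation

The junction-flanking sequence (default 200 bp per side) is spliced
across the retained exons of the highest-priority transcript when the
breakpoint is at a splice site — crossing as many exons as the flank
needs — and is plain genomic sequence otherwise; both halves are
oriented so the output reads 5'→3' across the junction (marked `|`).
Transcript priority: longest coding sequence, then longest transcript,
then smallest identifier.  The peptide is translated from the 5'
partner's annotated start codon through the junction into the retained
3' exon sequence, stopping at the first stop codon.  The frame is
`in-frame` when the 5'-side coding length modulo 3 equals the 3'
partner's annotated codon phase at the junction, `out-of-frame` when
it does not, and `unknown` when either partner lacks a usable
annotated CDS at its breakpoint.  No realignment of junction-proximal
unmapped bases is attempted; frame assessment is purely
annotation-based.

## Cohort statistic

`fisher_exact_2x2` implements the two-sided Fisher's exact test with
the probability-mass convention: the p-value sums the hypergeometric
probabilities, over all tables with the observed margins, that do not
exceed the observed table's probability (relative tie slack 1e-7).
The enumeration is evaluated in log space over the full support, which
keeps it exact and fast for any table size; tests cross-check it
against scipy's independent implementation and an explicit
enumeration.  The odds ratio is the sample odds ratio `(a·d)/(b·c)`.

## Synthetic fixtures

The generator emulates the aligner conventions above as a pure
function of a spec and a seed: non-overlapping genes on alternating
strands (default 20 genes, three 300 bp exons, 200 bp introns, 1 kb
intergenic gaps over two chromosomes; coding along every exon with a
start codon, no internal stops, and a terminal stop), split reads as
primary/supplementary record pairs with complementary soft clips and
anchors between 30 and 70 bp, discordant pairs facing the junction
within the insert window, optional gapped-alignment encoding of focal
deletions, and background noise with configurable per-gene candidate
rates, a geometric support distribution (default mean 1.3, matching
the steeply decaying low-support artifact population of real data) and
an intron/exon/splice-site breakpoint mixture (default
0.45/0.45/0.10).

The benchmark fixture used by the acceptance script plants five
fusions with 4–8 spliced supporting reads each over 200 noise
candidates with one or two reads at non-spliced positions.  Toy
genomes are generated free of homopolymer runs and short tandem
repeats so that the artifact filter responds to what a fixture plants
rather than to chance genome content, and no structural variants are
planted there because toy chromosomes (~25 kb) are far smaller than
the 100 kb corroboration window — an SV would blanket-match every
candidate; the SV distance and orientation rules are exercised on
explicitly constructed variants at realistic coordinates instead.

What the fixtures do *not* emulate: sequencing-error and coverage
models (reads are reference copies with controlled mismatch counts),
multimapping chimeric alignments, alternative isoforms (one transcript
per gene), and genome-scale repeat structure.  Passing tests therefore
demonstrate the correctness of extraction, assembly, scoring,
filtering and annotation logic under controlled conditions — not
calling accuracy on real libraries.

## Problem sizes and limitations

Tests run on sub-megabase toy genomes (tens of genes) so that
brute-force oracles — all-pairs grouping, linear-scan interval
lookups, tally recounts, exhaustive hypergeometric enumeration up to
grand total 60 — stay feasible; the assembly oracle sweep uses 100
seeded fixtures.  Known limitations: multimapping chimeric reads are
out of scope (the upstream aligner does not report them); the
blacklist is applied, never trained; breakpoints are taken from the
alignments as-is (no assembly-based refinement); and the e-value is
used only as a reporting threshold, not as a calibrated expected
count.
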
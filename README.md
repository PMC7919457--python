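# fusionsieve

Detection of gene fusions from RNA-seq alignments, for researchers and
clinical bioinformaticians who already run a spliced aligner (e.g.
STAR) and want fusion calls from the chimeric alignments it produces —
without a second alignment pass.

Fused transcripts leave two kinds of evidence in an alignment stream:
**split reads**, whose two segments map to noncontiguous loci and pin
the junction to the base, and **discordant mates**, read pairs whose
mates flank a junction in a nonlinear configuration.  A third, easily
missed class arises from **focal deletions**: because aligners decide
between "intron" and "chimera" purely on gap size, a small deletion
fusing two neighboring genes is written as an intron-like gapped
alignment.  `fusionsieve` collects all three, assembles them into
breakpoint-pair candidates, and filters them.

## The background-noise model

The central statistic is an expected level of background noise per
candidate (its *e-value*): a candidate is reported only if it has more
supporting reads than this expectation.  The e-value is a product of
five factors,

```
e_value = base_level_bg_noise * depth_penalty * distance_penalty
          * inv_to_dup_ratio * intron_to_exon_ratio
```

with

```
base_level_bg_noise = total_candidates_of_gene / sum_of_exon_lengths_of_gene
                      * (supporting_reads - SHIFT_noise)^SLOPE_noise * INTERCEPT_noise
                      SHIFT_noise = -0.73, SLOPE_noise = -2.28, INTERCEPT_noise = 10^-1.75

depth_penalty       = SLOPE_depth * SLOPE_MODIFIER^supporting_reads * mapped_reads
                      SLOPE_depth = 2e-11, SLOPE_MODIFIER = 0.02

distance_penalty    = distance^SLOPE_distance * INTERCEPT_distance
                      (-4.58, 8.27e10) below 400 bp; (-1.53, 3.73e8) from 400 bp;
                      no penalty at >= 400 kb or across chromosomes
```

plus two frequency ratios penalizing inversion/duplication event types
and intron/exon/splice-site breakpoint locations in proportion to how
common they are among all candidates.  Around this model sits a filter
cascade: negatively selecting filters remove blacklisted loci,
homologous gene pairs, low-complexity or mismatch-heavy read support,
and short anchors; positively selecting rescues recover low-support
candidates backed by strong independent evidence (both breakpoints at
annotated splice sites, a whitelisted gene pair, a corroborating
structural variant within 100 kb with matching orientation, or at
least four distinct spliced breakpoints linking one gene pair).  Kept
calls get a confidence class, the junction-flanking transcript
sequence (for primer design) and the predicted fusion peptide with
reading-frame status (a basis for neoepitope prediction).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Generate a self-contained synthetic bundle (toy genome + annotation +
chimeric SAM with five planted fusions over 200 background-noise
candidates) and run the detector on it:

```sh
fusionsieve fixture --out-dir demo --seed 1
fusionsieve detect \
    --gtf demo/annotation.gtf \
    --chimeric-sam demo/chimeric.sam \
    --main-sam demo/main.sam \
    --genome demo/genome.fa \
    --output demo/calls.tsv
```

The log reports each stage:

```
INFO fusionsieve: annotation: 20 genes
INFO fusionsieve: chimeric alignments: 291
INFO fusionsieve: mapped reads: 501
INFO fusionsieve: candidates assembled: 205
INFO fusionsieve: discarded: 200
INFO fusionsieve: discarded_read_artifacts: 1
INFO fusionsieve: discarded_short_anchor: 35
INFO fusionsieve: discarded_support_vs_noise: 164
INFO fusionsieve: kept: 5
INFO fusionsieve: kept_high: 5
```

205 candidates were assembled; the 200 planted noise candidates (one
to two supporting reads each) fall at or below the detection limit or
fail an artifact filter, and exactly the five planted fusions survive,
all with high confidence.  The first output line (18 tab-separated
columns; breakpoints printed 1-based, the junction marked with `|`):

```
gene5   gene3   breakpoint5 breakpoint3 ... split_reads5 split_reads3 discordant_mates evalue  confidence ... reading_frame
GENE009 GENE020 chr1:11000  chr2:22500  ... 4            4            2                1.1e-34 high       ... in-frame
```

meaning: a translocation-type fusion joining the donor site at
chr1:11000 (GENE009) to the acceptor at chr2:22500 (GENE020), with
eight split reads and two discordant pairs against an expected noise
level of ~1e-34, preserving the downstream reading frame.

A small cohort utility is included for enrichment questions such as
"are fusions concentrated in KRAS wild-type tumors?":

```sh
fusionsieve enrich --input samples.tsv --output report.tsv
```

with `samples.tsv` rows of `sample_id  kras_status  fusion_status`;
the report contains the 2x2 table and a two-sided Fisher's exact test.

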
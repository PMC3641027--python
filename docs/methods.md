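# Methods

This note documents the models and procedures implemented in `lepitran`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the published
analysis protocol left the design open.

## Read quality control

Raw Illumina reads carry per-base Phred scores encoded at ASCII offset 33
or 64; the offset is an explicit argument and is never auto-detected, so a
mis-declared file fails loudly (any character below the declared offset
raises a malformed-FASTQ error naming the read) rather than silently
shifting every score by 31.

The chain is: decode → purge artifact reads → clip terminal low-quality
spans → length filter → quality-fraction filter → mask.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `clip_qmax` | 20 | terminal bases with Q ≤ 20 (error ≥ 1%) are clipped |
| `min_len` | 36 nt | reads shorter than this after clipping are discarded |
| `frac_qmin` / `min_fraction` | 21 / 0.90 | ≥ 90% of remaining bases must be Q ≥ 21 |
| `mask_qmax` | 20 | surviving bases with Q ≤ 20 become `N` (scores kept) |

Both thresholds are boundary-inclusive on the side their definitions
state: Q20 is clipped/masked, Q21 counts as good, a read with exactly 90%
good bases passes, a 36-base core is retained.  Clipping removes the
*maximal* low-quality run at each end, so after clipping the first and
last base are above Q20 — which is what makes the whole chain idempotent
(verified by a property test).  "Artifact" reads are defined here as reads
whose base composition is a single nucleotide ignoring `N`; the historical
FASTX artifact rule is not published precisely, so this stand-in rule is
an approximation chosen to capture the dominant artifact class
(monopolymer reads) while remaining exactly testable.

Filter order is clip → length → fraction → mask: masking last matches the
phrasing that masking applies to "remaining" reads, and computing the
fraction before masking means the fraction filter sees true qualities.

## rRNA depletion

Reads are partitioned on pre-computed PSL alignments against an rRNA
reference locus: any alignment with ≥ `min_matches` matched bases
(default 30) discards the read.  The aligner itself is out of scope; the
threshold is exposed because the original protocol ran the aligner with
default parameters and did not state an acceptance cutoff — 30 mirrors the
referenced aligner's default minimum score.  Raising `min_matches` can
only grow the retained set (tested as a monotonicity property).

## Homology tiers

Tier assignment consumes the top-scoring BLASTX hit per PUT (bitscore,
ties by E-value, then subject id for determinism).  The gold criteria are
conjunctive: one HSP, PUT ≥ 300 nt, subject ≥ 100 aa, positives fraction
≥ 0.75, and hit span ≥ 90% of the subject.  "Hit length" is measured in
subject (amino-acid) coordinates, since it is compared against the subject
protein's length.  Silver and bronze require only PUT ≥ 100 nt and merged
subject coverage ≥ 0.75 / ≥ 0.30 respectively; merging unions HSP subject
intervals, ignoring frame, and counts overlapping residues once.  The
cascade is evaluated gold → silver → bronze → none, so a PUT failing gold
(e.g. by HSP count) can still be silver — this makes the tiers disjoint
and exhaustive by construction.

Gold PUTs are trimmed to the HSP's query span (reverse-complemented first
when the hit is on the minus strand, i.e. q_start > q_end in the tabular
report) and translated with the standard genetic code; trailing partial
codons are dropped, internal stops render as `*`, and codons containing
`N` — masked bases propagated from QC — render as `X`.  The 14-column
tabular dialect carries no frame column; the frame is derived from the
HSP orientation and the query length taken from the PUT FASTA.

The classifier is validated two ways: against an independently written
direct-inequality checker (which merges coverage via position sets rather
than interval arithmetic) on 10,000 randomized hit geometries with the
299/300 nt, 0.899/0.900 coverage and 0.749/0.750 positives boundaries
forced to occur, and end-to-end on a 200-transcript synthetic world where
the tier confusion matrix must be exactly diagonal.

## Annotation rollups

The longest ORF is the maximal stop-free peptide stretch over all six
frames, with no start-codon requirement; ties resolve by frame order
(+1, +2, +3, −1, −2, −3) then leftmost position, replacing an "arbitrary"
selection with a deterministic one.  hmmscan domain tables are reduced to
one family per query by full-sequence E-value (≤ 1e-2 by default, matching
hmmscan's default ranking), ties by bitscore then accession.

GO-Slim terms are defined structurally as *penultimate ancestors*: the set
of direct `is_a` children of an ontology root that lie on some `is_a` path
from the term to that root.  Roots map to the empty set (they carry no
information), a root's direct child maps to itself, and a term with
multiple paths contributes all its penultimate ancestors.  Whether a
multi-path term should count once per slim term or once per annotation is
genuinely ambiguous, so the tally offers both `set` and `multiset` modes
(default `set`).  Only `is_a` edges are traversed; `part_of` and other
relations are ignored by design.  Pfam accessions are version-stripped
before `pfam2go` lookup so `PF00400.25` matches `PF00400`.

## Digital gene expression

"At least 95% of the read aligned with perfect identity" is implemented
as: zero mismatches within aligned blocks AND matched bases ≥
`ceil(0.95 × read_len)`.  Each read counts toward at most one PUT — most
matched bases wins, ties to the lexicographically smallest PUT id.
Counts accumulate to the PUT's reference protein and are normalized by
the condition's total read count (not the assigned count), so normalized
values are comparable across conditions with different assignment rates.
Fold change is max/min of the two normalized values with an up/down
direction relative to infection; genes detected in only one condition get
no finite fold (no pseudocount) and are listed separately as "exclusive".
Swapping condition labels flips every direction and preserves every fold
(tested).  No significance testing is performed: with one library per
condition there is no replication to estimate dispersion from, so the
output is a descriptive ranking.

## qPCR relative expression

ΔCt = mean(technical Cts of the gene) − mean(technical Cts pooled across
the endogenous controls), per biological replicate; relative expression is
2^-ΔCt, summarized per condition by the mean with SEM = sd/√n (sd with
n−1 degrees of freedom; a single replicate reports SEM 0).  Two controls
are combined by pooling their technical Cts into one arithmetic reference
mean on the Ct scale (default); the alternative `geometric` mode averages
per-control ΔCts, equivalent to a geometric mean of per-control relative
quantities.  Fold changes are signed ratios of condition means — +r for
r ≥ 1, else −1/r — not ΔΔCt, because the quantity being compared is the
per-sample 2^-ΔCt itself.  No technical-replicate outlier rule is applied.

## The synthetic-data generator

`make_world` builds proteins (random sequences of 110–260 aa) and
transcripts back-translated from them with one fixed codon per amino
acid, so the planted hit geometry is exact without running an aligner:

- **gold** destinies: one contiguous back-translated region covering
  92–100% of its protein plus short random UTR flanks (PUT ≥ 300 nt
  follows from the covered length); ~30% are reverse-complemented to
  exercise minus-frame trimming;
- **silver**: either a single HSP covering 76–88% (fails the 90% span),
  or two HSPs separated by a spacer jointly covering ≥ 91% (fails the
  single-HSP rule) — the "gold-disqualified by HSP count" case;
- **bronze**: a single HSP covering 32–68%;
- **none**: random sequence with no emitted hit.

Proteins are assigned round-robin, so with at least as many proteins as
homologous transcripts the PUT→protein map is injective and protein-level
folds equal transcript-level planted folds.  Planted expression ratios
are exact by construction: differential transcripts get a fixed control
fraction (default 0.002, large enough that a 100k-read experiment counts
them with ~7% multinomial error) and `fraction × fold` in the infected
condition; only non-differential transcripts are renormalized.

`simulate_reads` draws reads multinomially from the abundance fractions,
uniformly positioned within each transcript, with a stated fraction drawn
from the rRNA reference (binomially).  Reads are exact substrings — the
generator models base-call *confidence* through the two-state quality
model (body ≈ Q38 ± 2; optional terminal spans ≈ Q15 with geometric
lengths, mean 4), not miscalls.  Consequences to keep in mind when
interpreting green tests: no sequencing errors, no indels, no paired ends,
no isoforms, no realistic position-dependent error profile, and
single-library conditions (overdispersion beyond multinomial noise is not
asserted because the emulated study design had one library per condition).
Recovery results on this generator demonstrate the correctness of the
counting and ranking machinery, not robustness to real Illumina noise.

`align_exact` is a fixture aligner: a k-mer-anchored (k = 20) exact
full-length substring matcher over both strands, emitting gapless PSL
records.  Reads straddling a trimmed CDS boundary therefore get no
alignment; this per-transcript thinning is identical in both conditions
and cancels exactly in the fold ratio, since normalization uses total
(not assigned) reads.

The toy ontology has the three GO domain roots, `branching` direct
children per root (the slim vocabulary) and two further levels by
default; about a third of deeper terms get a second parent to exercise
multi-path rollups.  It is written and re-read as OBO 1.2.

`make_ct_table` plants folds on the Ct scale: control-condition ΔCt
centered at 0, infected shifted by −log2(fold), Gaussian noise of
`noise_sd` cycles (default 0.2) on every individual technical measurement.

## Problem sizes and tolerances

The validation suite uses 10,000 randomized tier geometries, 1,000
QC-boundary reads, 1,000 random ORF sequences, a 200-transcript
end-to-end world, 100,000 reads per condition × 10 seeds for expression
recovery (planted folds 2/5/10/100; mean estimate within ±20%, direction
exact per seed — the expected error of the seed-averaged estimate is ~2%,
so the bound is loose by design, not tuned), and 20 seeds × folds
{0.1, 1, 10, 427} for qPCR recovery (|log2 error| < 0.5; expected ~0.1).
These sizes keep the whole suite under a minute per stage while leaving
order-of-magnitude headroom between expected and tolerated error.

## Known limitations

- Assembly, repeat masking and the external aligners/scanners are out of
  scope; the package consumes their report formats.
- The artifact-read rule and the rRNA acceptance threshold are documented
  stand-ins for under-specified steps of the original protocol, exposed
  as parameters.
- Absolute published counts (tier sizes, N50, family tables) depend on
  ~94M real reads and 2011-era databases and are not reproduction targets;
  the package reproduces the *procedures* and validates them on planted
  truth.
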
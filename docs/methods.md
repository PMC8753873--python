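# Methods

## Scope

`cernet` implements the desk half of a ceRNA discovery study: it starts
from a differential-expression table (log₂FC and p per transcript, as a
sequencing vendor would deliver), predicts miRNA target sites on
transcript sequences, tests lncRNA–mRNA pairs for shared-miRNA
enrichment, intersects the resulting partner set with a differential
mRNA profile, and provides the statistics used to analyse the wet-lab
follow-up (qPCR relative expression, Oil-red-O OD readings).  Read
alignment, expression quantification and DE calling from raw reads are
out of scope — the pipeline begins at the log₂FC/p table.

Because studies of this kind rarely deposit raw data, the package ships
a first-class synthetic-data module whose generators produce every input
the pipeline consumes together with machine-readable ground truth.  All
recovery claims in the test suite are claims about those synthetic
conditions; see "What the simulations do and do not show" below.

## Differential screening

A row is retained when |log₂FC| ≥ `min_abs_log2fc` (default 1, i.e. at
least a twofold linear change) **and** p < `max_p` (default 0.05).  The
effect cutoff is non-strict and the p cutoff strict, matching the usual
"fold change at least twofold, P less than 0.05" reporting convention.
Top-N lists per direction sort by log₂FC with ties broken by ascending
p and then lexicographic id, so output is reproducible.  The
`fold_change` column is redundant with log₂FC; on load it is recomputed
when absent and verified when present (default relative tolerance 1e-3;
the bundled 40-row worked-example table, transcribed from a printed
4-decimal source, is loaded at 5e-3).  Chromosome tallies classify
log₂FC ≥ 0 as "up" so that per-chromosome counts always conserve the
row total; exact zeros are measure-zero in real data.

## Target-site prediction

Site classes follow the TargetScan canonical convention (8mer, 7mer-m8,
7mer-A1, 6mer; the transcript A1 is required as a literal A regardless
of miRNA position 1).  Seed matching is Watson–Crick only; wobble
pairing is recognised only by the duplex score.  Coordinates are
0-based half-open on the transcript plus strand.  Each 6mer-core locus
yields exactly one site, labelled with the most specific class that
applies there.

The duplex score is a deliberately simple additive alignment, not a
thermodynamic ΔG: Watson–Crick +5, G:U +1, mismatch −3, affine gaps −9
to open and −4 to extend, with substitution scores at miRNA seed
positions 2–8 doubled (gap costs are not doubled).  The alignment is
local but anchored at the 3′ end of the site window: the window may
extend 15 nt upstream of the site (default `flank`) so the miRNA 3′
region can pair, any window prefix and any miRNA overhang are free, and
the duplex must reach the window's last nucleotide.  Under these
weights a perfect gapless seed duplex scores 60 (6mer), 70 (7mer-m8) or
75 (8mer, when miRNA position 1 is U).  The default retention
thresholds — site class ≥ 7mer-m8, duplex score ≥ 50 — therefore admit
every canonical 7mer/8mer site while discarding heavily degraded
duplexes.  These defaults are declared choices of this package;
published pipelines in this family do not state theirs.  All weights
are a `ScoringWeights` parameter and CLI-exposed.

Input sequences are normalised to the RNA alphabet (T→U, uppercase);
IUPAC ambiguity codes are a hard error rather than a silent wildcard.

## The shared-miRNA ceRNA test

For anchor lncRNA with target-miRNA set of size K, candidate mRNA with
set of size n, overlap k, and universe N, the per-pair statistic is the
upper tail P(X ≥ k) of Hypergeometric(N, K, n).  It is computed by
log-space summation of log-gamma pmf terms (`logsumexp`), so
enrichment p-values of order 1e-300 are representable; the test suite
verifies exact agreement (1e-12) with exhaustive subset enumeration
over the complete N ≤ 12 grid and with an independent library tail
function at larger sizes.

Choices made where the recipe is conventionally under-specified:

- **Universe N** defaults to the full miRNA set supplied to the
  prediction run, i.e. the sampling frame from which target sets are
  drawn — not the union of observed targeting miRNAs.  It is overridable.
- **Tested family**: only candidates with k ≥ `min_shared` (default 3)
  are tested, and Benjamini–Hochberg runs across exactly that family.
- **Retention**: q < `max_q` (default 0.05).
- Edges are ordered by (q ascending, k descending, mrna_id) for
  deterministic output.  Violated hypergeometric bounds raise; nothing
  is clipped silently.

The retained network is tripartite: anchor → each shared miRNA → each
mRNA sharing it, exported as GraphML and a flat edge list.

## Profile intersection

Venn-style intersection is plain string comparison after trimming and
uppercasing — the same semantics as pasting id lists into a web Venn
tool.  Mixing transcript ids with gene symbols is the caller's
responsibility (a documented footgun, deliberately not "fixed" by id
mapping).  The candidate report joins each intersected mRNA's DE
statistics (log₂FC, p, direction) with its ceRNA statistics (k, q); ids
missing from either source are reported as discrepancies, never dropped.

## Quantification statistics

**2^−ΔΔCt.**  Per sample, ΔCt = Ct(target) − Ct(reference);
ΔΔCt subtracts the *mean* control-group ΔCt (replicate-based centering
rather than a single calibrator well), so the control group's geometric
mean fold is 1 by construction.  Samples without exactly one well per
gene are excluded and reported.  No amplification-efficiency correction
is applied.

**Group comparisons.**  Two groups: Student's pooled-variance t-test
(pooled rather than Welch, as the classical "Student's t-test" names);
zero pooled variance returns p = 1 flagged as degenerate when means are
equal and raises otherwise.  Three or more groups: one-way
fixed-effects ANOVA followed by the Student–Newman–Keuls stepwise
studentized-range procedure — the classical post-ANOVA "q test" — at
α = 0.05, with the Tukey–Kramer standard error √(MSW/2·(1/nᵢ+1/nⱼ)) for
unequal group sizes.  SNK tests ranges widest-first; a non-significant
stretch freezes every pair inside it (those pairs carry p = None).
Tukey HSD is available as an alternative post-hoc.  Summaries are
mean ± SD with the n−1 denominator.

## The synthetic-data generators

Each generator takes one integer seed; per-stream sub-seeds are derived
deterministically (`numpy` `SeedSequence` spawning), and identical seeds
give byte-identical FASTA/TSV output.  Sequences are emitted in the RNA
alphabet; readers normalise T↔U.

- **miRNAs**: i.i.d. sequences, lengths uniform in [21, 23] by default,
  with unique ids *and unique seed7 regions* — the latter so a site
  implanted for one miRNA can never be an exact canonical site of
  another, keeping implant ground truth unambiguous.
- **Transcripts**: i.i.d. background at a chosen GC fraction (default
  0.5) with the exact canonical site string (including the
  transcript-side A of 8mer/7mer-A1 sites) written at each planned
  offset, so substring read-back recovers every implant verbatim and
  perfect recall is a meaningful test.
- **DE tables**: true rows get |log₂FC| = threshold + Exponential(0.7)
  and p log-uniform in (1e-6, p_sig); null rows get
  log₂FC ~ Normal(0, 0.5) and p uniform in (0.05, 1), failing the
  default screen through the p cutoff regardless of effect.  The
  default profile is 351 up / 297 down / 1000 null — the null count is
  a free parameter, since screens of this kind report only the
  significant count.  `fold_change` is exactly 2^log₂FC.
- **qPCR plates**: Ct = per-gene baseline − log₂(true fold) +
  Normal(0, σ); the reference gene's baseline does not depend on group.
  The default simulated anchor effect is a 0.35-fold knockdown with
  σ = 0.2 cycles and 4 replicates, reproducing a ±0.07-scale spread in
  recovered folds.
- **OD readings**: Normal(mean, sd) per treatment group, truncated at
  zero; defaults 0.22 ± 0.028 (control), 0.51 ± 0.02 (oleic acid),
  0.48 ± 0.013 (OA + empty vector), 0.42 ± 0.01 (OA + anchor
  overexpression), 3 replicates.

**The ceRNA fixture.**  The composite fixture plants an anchor lncRNA
with one 8mer site per anchor-targeting miRNA (119 of a 300-miRNA
universe; K must be strictly below N for the hypergeometric test to
discriminate), partner mRNAs sharing planted subsets of the anchor's
miRNAs, and decoys carrying sites only for non-anchor miRNAs plus at
most one anchor miRNA.  Two shapes are used: 5 strong partners
(partitioning all 119 anchor miRNAs) among 236 decoys, and 241 partners
of 5 shared miRNAs each whose union covers the anchor set.  Fixture
backgrounds are additionally *masked*: stray 6mer seed cores outside
implant windows are mutated away, as are unplanned full 8mer site
strings straddling window boundaries (possible because a different
miRNA's site can reuse a protected core with its m8 or A1 position in
free background; unplanned 8mers wholly inside an 8-nt window are
impossible given unique seed7 regions).  With masking, 8mer-level
prediction recovers the implant plan *exactly*, which is what makes
"retains exactly the planted partners, counts exactly 119 shared
miRNAs" a sharp test rather than a statistical one.  The plain
transcript generator leaves chance sites in place so that background
match rates remain testable (a 6mer core occurs at the uniform-model
rate (L−5)/4⁶ per transcript).

**What the simulations do and do not show.**  Backgrounds are i.i.d.
nucleotides: no repeats, no composition bias, no secondary structure,
no homology between transcripts.  Effects are drawn from simple
parametric spreads, not from read-count models; there is no
normalisation error, batch structure or annotation ambiguity.  Passing
recovery tests therefore demonstrates that the *computational chain* is
correct and self-consistent — filters filter, the test ranks true
sharing above chance, arithmetic inverts the generative model — not
that the thresholds would achieve any particular sensitivity or FDR on
real transcriptomes.

## Problem sizes and runtime

The default end-to-end run uses a 1648-row lncRNA table, a 300-miRNA
universe, 242 transcripts (anchor ~2.4 kb, candidates 800 nt), a
600-row mRNA table, 4 qPCR replicates and 3 OD replicates per group —
sizes chosen to mirror the emulated study's reported counts while
keeping a full run in a few seconds on one CPU.  The exhaustive
hypergeometric oracle in the tests enumerates every subset for all
N ≤ 12.

## Known limitations

- The duplex score is ordinal, not thermodynamic; it should not be
  compared across weight settings or interpreted as binding energy.
- Conservation, context features and 3′-supplementary site taxonomy are
  not modelled.
- The ceRNA test conditions only on target-set overlap; expression
  correlation, miRNA abundance and binding-site occupancy are not used.
- The SNK "q test" is implemented by its classical stepwise definition;
  its familywise error control is known to be approximate, which is one
  reason Tukey HSD is offered alongside.
- GroundTruth serialisation is a simple sectioned text format intended
  for fixtures and audits, not a general interchange format.
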
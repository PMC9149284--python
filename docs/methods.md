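# Methods

This note documents the statistical model behind `lmrnet`, the numerical
conventions of each pipeline stage, the design of the synthetic-data
generator, and the limits of what the synthetic results demonstrate.

## The analysis

The pipeline consumes a feature × sample count table (mRNA + TF + lncRNA),
a separate small-RNA count table, a GFF3 annotation, a genome, transcript
and miRNA sequences, and a TF → binding-element table. Nine samples in a
3-condition × 3-replicate design are the reference layout (three nitrate
regimes, N0/N6/N18), but any ≥ 2 × 2 design works.

**Normalization.** mRNA and lncRNA abundances are FPKM
(count · 10⁹ / (spliced length · library size)); small-RNA abundances are
TPM (count · 10⁶ / library size) without length normalization, because for
a mature miRNA the read *is* the molecule. TPM columns sum to 10⁶ by
construction.

**Differential expression.** For every pairwise contrast of conditions,
log2 fold change is computed from group means of normalized abundance with
a pseudocount of 1.0 (the estimator is configurable; means-of-normalized
with a pseudocount is the assumption-lightest choice when the upstream
count model is unknown). Significance comes from a Welch unequal-variance
t-test on log2(normalized + 1), BH-adjusted per contrast. A feature is
called up/down when |FC| ≥ 2 (inclusive) **and** FDR < 0.05 (strict); the
boundary semantics follow the printed forms of the thresholds. A
negative-binomial GLM with dispersion shrinkage would be more powerful at
n = 3, but it is deliberately out of scope: the calling *thresholds* are
the method's contract, and the Welch test keeps the pipeline free of a
second inference framework. Features constant in both groups get p = 1.

**lncRNA stage.** Candidates (features labeled `lncRNA`) are retained when
≥ 200 nt with a longest forward-frame ORF (ATG → stop, stop not counted,
open 3′ ends counted) under 100 codons — a transparent stand-in for
coding-potential classifiers. Each retained locus gets exactly one
positional class by precedence: same-strand exonic overlap → *sense*; any
opposite-strand overlap → *antisense*; fully inside a same-strand intron →
*intronic*; otherwise *lincRNA*. The precedence is this package's own
choice (the class names are standard, their overlap priority is not);
same-strand exonic overlap is the strongest evidence against an
independent locus, so it wins.

*cis* targets are genes whose span lies within 10 kb of the lncRNA span
(gap between half-open intervals; overlap = 0; 10 000 bp inclusive),
strand-agnostic, filtered to differentially expressed genes. The lncRNA's
own differential status is deliberately not required for cis pairs: cis
evidence is positional, and requiring co-response would silently merge it
with the trans criterion (see the generator section for the second reason).

*trans* targets are DE lncRNA × DE gene pairs with Pearson r ≤ −0.9 across
samples and opposite differential calls in at least one shared contrast.
"Opposite expression with correlation ≥ 0.9" is operationalized as signed
anticorrelation by default; `trans_correlation_mode="absolute"` accepts
|r| ≥ 0.9 for users who read the magnitude only. Correlations here and in
the TF stage are computed on log2(normalized + 1): expression changes are
multiplicative, and the log scale keeps a single strong condition from
dominating the estimate.

**miRNA stage.** Small RNAs outside 18–30 nt (inclusive) are dropped
(18–32 is available by configuration; the two bounds circulate in the
field and the package does not adjudicate). Target sites are scored by
antiparallel alignment of the miRNA against every transcript window:
Watson–Crick pair 0, G:U wobble 0.5, mismatch 1.0, each inserted/deleted
base 2.0, all penalties doubled at miRNA positions 2–13 (1-based from the
5′ end); the site score is the minimum over alignments with at most one
contiguous bulge (length ≤ 1 by default), and sites with penalty ≤ 4.0 are
reported, best site per pair, ties to the leftmost. Bulge bookkeeping: a
bulged miRNA base is penalized at its own position's weight; a bulged
target base takes the weight of the miRNA position immediately 3′ of the
insertion point (clamped to the last position). This penalty family is the
classic plant target rule; every weight and the cutoff are configuration
keys. Pairs in which both the miRNA and its target are DE in a contrast
are *coherent* when their calls point in opposite directions (consistent
with cleavage) and *noncoherent* otherwise.

**TF stage.** Promoters are the 2 kb immediately upstream of the TSS,
strand-aware and reverse-complemented for minus-strand genes, truncated at
chromosome ends with a warning. Binding elements are IUPAC consensus
strings (or position weight matrices with a fractional score threshold)
scanned on both strands. Every DE TF × DE gene combination is evaluated
and recorded; a pair is accepted iff |PCC| > 0.8 (strict), p < 0.05
(strict, two-sided from t = r√(n−2)/√(1−r²)), and — unless motif gating is
disabled — the TF's element hits the gene's promoter at least once. The
sign of the correlation is not restricted, so repressive TFs remain
representable; the sign travels with the edge evidence.

**Network.** Accepted pairs become typed directed edges; duplicates
collapse to the record with the strongest evidence (lowest p or penalty).
TF targets may themselves be sources, so lncRNA → TF → gene chains are
representable. Exports: edge TSV (round-trips exactly), SIF, GraphML.
Recovery against a known edge set uses edge identity
(source, target, mechanism), precision = TP/(TP+FP) with 0 for no
predictions, recall = TP/(TP+FN), F1 their harmonic mean.

## The synthetic-data generator

The generator's job is to produce data in which the pipeline's rules have
a known right answer.

**Layout.** One chromosome. Protein-coding genes are three-exon models on
a 20-kb pitch, so a cis-planted lncRNA placed 2.1–6 kb from its target is
within 10 kb of *only* that gene. lncRNA loci realize all four positional
classes whenever ≥ 4 are requested (intronic/antisense/sense exemplars
overlap designated decoy host genes); remote lincRNAs sit on a 21-kb pitch
past the gene block, beyond every cis window.

**Sequences.** Each planted TF receives its own concrete binding element,
instantiated from the degenerate IUPAC consensus (default `TGACGTNNNN`);
its target promoters carry one exact instance at a random offset and
strand, and *every other promoter is rejection-sampled against all
instantiated elements*, so motif presence is equivalent to planted
regulation. miRNA target transcripts embed a perfect complementary site;
lncRNA sequences are rejection-sampled to pass the ORF filter. All
sequences are re-derived from the final genome, so FASTA, GFF3 and genome
are mutually consistent by construction.

**Counts.** Every feature has a baseline log2 abundance and a latent
*condition trajectory*; counts are negative binomial around
2^(baseline + trajectory) with one shared dispersion (default 0.05), the
standard single-knob RNA-seq noise model. Regulators carry the intrinsic
response; each target inherits its regulator's trajectory scaled by
`target_correlation` (sign-flipped for miRNA and trans-lncRNA mechanisms).
`target_correlation` is therefore the planted effect size: at 1.0 targets
move in lockstep, at 0 regulation has no expression consequence and
targets stay flat — which is exactly what the null-control contract needs
(no DE targets ⇒ no accepted TF or trans pairs). An additive-jitter
parameterization was rejected: with three conditions the centered
trajectories live on a circle, and acos(0.95) ≈ 18° of direction rotation
would break the separation geometry described next.

**Trajectory geometry.** Whether an *unplanted* pair can cross the trans
threshold |r| = 0.9 depends on the angle between the two trajectory
directions and on how far the realized (noisy) directions wobble around
the designed ones — roughly noise_sd/(√replicates · amplitude) radians.
The direction budget on the 3-condition circle is tight, and the design
spends it deliberately:

* the ten trans axes take 32° steps over a 288° arc (adjacent cross-pairs
  then sit near cos 32° ≈ 0.85, below threshold);
* TF pairs, miRNA targets and cis target genes all share the one direction
  at 324°, a 36° clearance from the nearest trans axis;
* amplitudes are large (log2 amplitudes 3–5, i.e. strong 10–70-fold
  responders, as nutrient transporters show), so realized directions
  wobble by only a few degrees. Monte-Carlo of the NB model puts every
  unplanted channel's crossing probability below ~1%.

Two consequences of this geometry are worth stating plainly. First, TF
pairs cannot be separated by correlation alone — dozens of pairs share a
handful of distinguishable expression shapes — which is precisely why the
per-TF binding element exists: motif gating, not the PCC threshold, is
what drives TF precision to 1.0. Second, cis lncRNAs carry **no**
expression trajectory: any DE lncRNA direction has its antipode within
~16° of a trans axis, so a co-expressed cis lncRNA would systematically
create spurious trans pairs. Since cis targeting is positional, the
generator plants the cis signal in the coordinates and the target gene's
response, and the pipeline's cis rule correspondingly keys on the DE
target, not on the lncRNA's own differential status.

**Library composition.** FPKM/TPM are relative abundances: if the
responsive minority shifted total library mass by condition, every feature
would inherit a spurious common-mode trajectory. The generator therefore
draws the flat decoy bulk at a higher baseline (the stable housekeeping
transcriptome that dominates real libraries) and rescales it
proportionally so the expected per-condition mass is constant; the induced
per-feature swing (< 0.3 log2) stays far below the differential-call
thresholds.

**Determinism.** All randomness flows from numpy Generators seeded from
(seed, phase); identical config + seed reproduces the fixture bundle and
every pipeline output byte for byte.

## Problem sizes and defaults

The default design is 130 mRNA genes, 30 TFs, 40 lncRNAs and 40 miRNAs
(3.8 Mb genome), with 30/20/10/10 planted TF/miRNA/cis/trans edges and 100
flat decoys across roles — large enough that every rule's precision is
exercised against a substantial background, small enough that a full
simulate-to-network run takes seconds on one core. Two decoy miRNAs are
emitted at 17 and 31 nt to exercise the length filter.

## What passing does and does not show

On this fixture the pipeline recovers the planted program exactly
(precision = recall = 1.0 per mechanism at the documented seed; across
seeds, occasional single trans false positives at r ≈ −0.90 to −0.93
appear when a realized direction wobbles into an adjacent axis — the
honest residual of a 2-D trajectory space). That validates the *rules*:
thresholds, boundary semantics, scoring arithmetic, gating logic and
plumbing. It does not validate the method's power on real data, where
dispersion varies per gene, coexpression structure is not low-rank,
binding elements are shared across TF families (so motif gating cannot
reach precision 1.0), miRNA sites are imperfect, and coding-potential
calling needs more than an ORF rule. The generator also does not simulate
reads, sequencing error, isoforms, or miRNA hairpin structure; known-vs-
novel miRNA discovery is replaced by a curated miRNA FASTA input.

## Numerical conventions

* Coordinates: 0-based half-open internally; GFF3's 1-based inclusive only
  at the file boundary; converting back is the identity.
* Zero-variance features are skipped with a warning in correlation stages,
  never emitted as NaN.
* p-values outside [0,1], negative counts, duplicate ids, unknown roles,
  samples without conditions, malformed GFF3 lines (with line number) are
  all hard errors — readers reject rather than coerce.
* Ties in miRNA site selection: lowest penalty, then leftmost transcript
  start, then shortest window.
* The qPCR helper computes 2^−ΔΔCt from four finite Ct values; enrichment
  is a one-sided hypergeometric upper tail (k = 0 ⇒ p = 1) with BH across
  terms.
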
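# Methods

This note documents the models, estimators and numerical choices behind
`verncre`, and what the synthetic experiment does and does not show
about real data.

## The synthetic hexaploid experiment

The simulator builds a miniature allohexaploid genome: one chromosome
per sub-genome (chr1A/chr1B/chr1D, 2 Mb each by default), 300 gene
triads placed at syntenic slots (one gene per sub-genome at the same
relative position) plus 60 singleton genes. Homoeologous gene copies
derive from one ancestral sequence with 4% per-copy substitution, so
within-triad identity is ~92–96% (the construction guarantees >= 85%).

**Regulatory elements.** Every gene gets a 400 bp promoter ACR 200–600 bp
upstream of its TSS. Each triad gets one 400 bp distal ACR per gene slot,
placed in the intergenic window with > 2.2 kb clearance to the flanking
gene bodies; the ~200 bp safety margin beyond the 2 kb promoter rule
exists so that called element boundaries (which can extend ~1 bin past
the planted edge) cannot flip the promoter/distal classification. A
configurable fraction of distal elements (60%) is planted at syntenic
positions in all three sub-genomes from one ancestral element sequence
(3% divergence); the rest exist in a single sub-genome ("specific").
40% of distal elements receive a flanking H3K4me3 domain (K4-dACRs).
Element sequences are drawn at GC 0.55 against a 0.45 background.

**Conditions and responsiveness.** Two conditions ("before"/"after"
vernalization), one tissue per run, two replicates per condition. A
fraction (default 0.3) of gene units respond; responders are assigned
induced/repressed in strict alternation so the two directions are
exactly balanced. A responsive element's TIS rate is multiplied by
2^(±log2FC/2) in the two conditions — the symmetric split keeps the
generative ratio exactly 2^log2FC while leaving the expected library
mass equal across conditions, so each track's expected total equals the
configured library size (2 × 10⁶) and realized totals land within a few
percent. Genes whose planted mean is below the expression gate cannot
respond and are never marked responsive.

**Noise model.** TIS counts are gamma-Poisson: per-base Poisson
background plus one independent gamma multiplier (shape 1/dispersion,
default dispersion 0.1) per 200 bp segment of each planted ACR per
sample. The 200 bp granularity matches the unit at which the
differential engine tests, so bin-level counts are exactly negative
binomial at the configured dispersion. RNA counts are NB per gene per
sample with the same dispersion. Histone-mark coverage is Poisson
(background 0.02/bp, domain 0.6/bp); mark peak sets are the true
domains. Mark domains follow gene chromatin states (activated genes:
H3K4me3 at the TSS, H3K27ac and H3K36me3 over the body; repressed
genes: an H3K27me3 domain; mixed: both; responsive genes swap state
between conditions) and the planted A/R/M/U labels of distal elements
(static across conditions so classification is well defined).

**Auxiliary features.** SNPs are a per-base Bernoulli process (rate
0.004/bp) thinned 3× inside elements; half of 200 GWAS signals fall
within 1 kb of a responsive element, the rest are uniform; TEs carry
superfamily codes {DTT, DTX, RLG, RLC, RIX, other} with retrotransposon
codes preferentially overlapping sub-genome-specific elements; an
SPL-like PWM with a GTAC core (consensus TCGTACGA) is planted in 80% of
responsive distal elements vs 5% of others, alongside MYB/WRKY/Dof-like
decoy PWMs.

All randomness flows from one root seed through named substreams (keyed
by a stable byte hash, so runs are byte-identical across processes and
platforms).

**What the simulation does not emulate:** mappability and GC bias,
fragment-length structure, replicate-specific batch effects,
copy-number and repeat-driven multi-mapping artifacts, distance decay of
enhancer–promoter assignment, and realistic wheat gene density (real
intergenic distances are far larger). Passing tests therefore
demonstrate correctness and calibration of the algorithms under the
stated generative model, not performance on real wheat libraries.

## ACR calling

Candidate regions come from a sliding Poisson window scan: 150 bp
windows at 50 bp step scored by the upper-tail probability of the
window sum under the genome-wide rate, BH-corrected; significant
windows are unioned. This emulates a centered-pileup peak caller run
with a fixed 150 bp extension and no local background. Refinement
follows the published geometry exactly: 150 bp bins at 50 bp overlap,
bins kept iff normalized density >= 2× the genome-wide mean (the source
procedure states a density filter without a threshold; 2× is the
package default and configurable), survivors merged with a 200 bp gap,
clipped to chromosome bounds, then blacklist-overlapping regions
dropped (>= 1 bp). Density is TIS·bp⁻¹ per million library TIS.

## The NB differential engine

Size factors are DESeq2's median-of-ratios over features positive in
all samples (library-size fallback otherwise), normalized to geometric
mean 1. Dispersions are method-of-moments per feature
(α̂ = (pooled within-condition variance − μ)/μ²), floored at 10⁻⁸,
shrunk 50% toward a mean–dispersion trend a/μ + b fitted by least
squares, **with the trend as a lower bound**: at the small replicate
numbers this pipeline targets (2–3 per condition) a raw estimate below
the trend is dominated by sampling noise, and letting it pull the SE
down inflates the Wald statistic; bounding below by the trend restores
calibration (measured type-I fraction at p<0.05 is ~0.04 under the
reference null) at no measurable cost in power. The Wald statistic is
log2FC/SE with log2FC from normalized group means (+0.5 pseudo-count)
and SE from the delta method on the NB variance (μ + αμ²)/n per group;
two-sided normal p-values, BH across features.

DEGs use the raw p < 0.01 and fold-change > 2 rule (not FDR — the rule
is stated on raw p). Histone-modification-change genes use the same
engine on strand-oriented [TSS, TSS+500) windows for H3K27ac, H3K36me3
and H3K4me3 and the gene body for H3K27me3.

**Differential ACRs.** The ACR union is tiled into 200 bp bins;
per-bin TIS counts are Wald-tested with size factors estimated from the
full bin matrix (estimating them from significant intervals only would
bias median-of-ratios, since that subset is mostly differential).
Adjacent significant bins (bin-level BH < 0.05) of the same direction
merge across gaps <= 200 bp; merged intervals are re-tested on their
summed counts. Because the candidates were screened out of the same
data, the re-test's BH runs at the screened family size (the p-vector
is padded to the total bin count); without that correction the realized
false-discovery proportion of the final table is roughly double the
nominal level. Kept intervals need re-test FDR < 0.05, |log2FC| >= 1
and direction agreement with their bins. Merging never crosses the ACR
union footprint, and induced/repressed runs never merge with each other.

## Chromatin-state HMM

Tracks are binarized on a 200 bp grid: peak mode sets a bin to 1 iff it
overlaps a peak by >= 1 bp (the default, matching peak-set inputs);
coverage mode uses a Poisson upper tail against the genome-wide mean
per-bin rate at p < 10⁻⁴. The model is a K-state HMM (default K = 9)
whose state k emits each track m independently as Bernoulli(p[k,m]).
Training is Baum-Welch with scaled forward–backward, chromosomes as
independent sequences (no transitions across boundaries; the initial
distribution is re-estimated from chromosome starts), emissions clipped
to [10⁻⁴, 1−10⁻⁴], convergence at relative log-likelihood change
< 10⁻⁴ or 200 iterations, best of 3 seeded restarts, and states
re-ordered by descending total emission so serialized models are
byte-stable. K = 1 is a closed form (emissions = marginal
frequencies). The inner recursions are numba-compiled; Viterbi is
provided for exact-path checks and posterior argmax for decoding.

Labels are a pure function of emissions: a state is *active* if any of
ATAC/H3K4me3/H3K36me3/H3K27ac emits above 0.5 and *repressive* if
H3K27me3 does; mixed if both, activated/repressed if exactly one,
unmodified otherwise (threshold configurable). Per-gene labels take the
bp-majority over gene body plus 2 kb upstream with ties broken by
mixed > activated > repressed > unmodified; the transition matrix
counts (before, after) pairs and the maintained fraction is its
normalized trace.

## CRE classification

Promoter vs distal is the gap from the ACR to the nearest gene *body*
(<= 2 kb ⇒ promoter; overlap counts as 0), while target assignment is
nearest *TSS* with the distance signed negative upstream and ties
broken lexicographically — the promoter rule is phrased against genes,
accessibility windows anchor on the TSS. "Surrounded by"/"next to" a
mark means the element extended by a 500 bp flank overlaps the mark's
domain (flank configurable). An element near H3K4me3 but neither K27
mark has not "lacked the four modifications" and is reported A rather
than U by default (`k4_counts_as_active=False` restores the strict K27
reading). Homoeologous distal elements must both target homoeologs of
one triad and align locally (Smith–Waterman via Bio.Align in local
mode) at >= 70% identity over >= 50 columns; elements homologous in no
sub-genome pair are "specific".

## Triad balance

Quantifications (v_A, v_B, v_D) are normalized to proportions and
assigned to the nearest Euclidean centroid among Ba = (⅓,⅓,⅓), the
dominant vertices A/B/D and the suppressed mid-edges a/b/d; exact ties
resolve to Ba. Triads with max TPM < 1 are Un. Response balance uses
the same geometry on |log2((after+1)/(before+1))| magnitudes with a
2-fold gate below which a triad is non-responsive ("NR"); the metric
and pseudo-count are package choices (signed-difference alternatives
are plausible) and are exposed as parameters. Cross-layer association
reports, per epigenomic layer, the unbalanced-given-unbalanced
fractions and a two-sided Fisher exact test on the 2×2
balanced/unbalanced table.

## Characterization and network

GC content is (G+C)/(A+C+G+T) with ambiguous bases excluded; group
comparisons use Mann–Whitney U against length-matched random intervals
on the same chromosome (optionally excluding genic space). The SNP
meta-profile rescales element bodies onto 10 bins between fixed-width
2 kb flanks. Shuffle-null overlap enrichment places length-matched
elements uniformly on the source chromosome per shuffle (default 1000)
and reports the empirical p (1+#{null >= obs})/(n+1), never zero.
Motif scanning is a log-odds scan of both strands; the hit threshold
for a target p-value comes from the exact background score
distribution — expanded in full for motifs <= 10 bp, and by a
conservative ceiling-lattice dynamic program for longer ones (the
lattice tail dominates the true tail, so the threshold errs
conservative by at most one lattice step per position). Motif
enrichment compares >= 1-hit element fractions (targets vs background)
with a two-sided hypergeometric p and BH across motifs; depletion is
reported when fold < 1. The network adds an edge TF → gene for every
hit of a responsive TF's motif in a promoter or distal element assigned
to a responsive gene, collapsing duplicate (tf, target, element, motif)
tuples with the maximum score; both raw and collapsed counts are
reported since interaction counts depend on that granularity.

## Problem sizes and runtime

The default experiment (3 × 2 Mb, 960 genes, ~1,600 planted elements,
4 TIS tracks, 8 mark track/peak sets, 4 RNA samples) runs the full
pipeline in ~10–15 s on one CPU. Calibration simulations use 2,000
features at n = 3 vs 3 for the NB engine and 100,000 bins for HMM
parameter recovery; interval and alignment oracles run on instances of
up to 1,000 intervals and a few hundred base pairs, where brute-force
references are exact.

## Known limitations

- The candidate caller uses a single global background rate; on real
  data with fluctuating coverage a local lambda would be needed.
- Exact parity with DESeq2/ChromHMM is out of scope by design; the
  estimators are calibrated by simulation instead.
- Gene models carry no exon structure, so the genomic-feature
  classifier treats gene bodies as exonic unless exon intervals are
  supplied.
- Multi-factor designs, shrunken LFCs, IDR replicate merging, and
  Hi-C-based target assignment are not implemented.
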
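# Methods

## Study design being modeled

The pipeline targets diel (light/dark-entrained) bulk RNA-seq time
courses of the kind used to dissect underwater CAM in quillworts:
samples every 3 h over a 27-h span (ZT 1, 4, …, 28; ZT0 = lights-on
under 12 h light / 12 h dark at constant temperature), three replicates
per timepoint, alongside the genome, its annotation, a plastid variant
table, and paralog codon alignments. All times are Zeitgeber hours; a
"phase" is always the ZT hour of peak expression, mod 24.

## Expression preprocessing

**TPM.** TPM_gs = 10⁶ · (count/length) / Σ(count/length), with length
the spliced CDS length. Genes with mean TPM across all samples below 1
are treated as not expressed; a gene at exactly 1.0 is kept.

**Median-of-ratios.** Size factors are the median, over genes with
nonzero counts in every sample, of count / per-gene geometric mean.
Factors are then scaled to geometric mean 1 — only their ratios matter
downstream, and the scaling makes re-estimation on normalized counts
return exactly 1 (a convenient fixed point the tests exercise). There
is no pseudo-reference fallback: if no gene is nonzero everywhere, the
call fails loudly.

**TMM / log2-CPM.** edgeR-style trimmed mean of M-values: reference =
sample whose 75th count-fraction percentile is closest to the mean; M
trimmed at 30%, A at 5%; delta-method precision weights; factors
normalized to geometric mean 1; output log2(CPM + 0.5) with the offset
configurable.

**MDS outlier screen.** Classical (Torgerson) scaling of Euclidean
distances on log2(x+1). A sample is flagged when its distance to its
timepoint's mean centroid exceeds `flag_multiplier` (default 3) × the
median of all centroid distances. The threshold is a documented,
automated stand-in for by-eye outlier removal; note that a single
*extreme* outlier also drags its replicate mates' mean centroid, so
mates of a wrecked sample can be co-flagged — inspect the report before
dropping. An epsilon guard keeps byte-identical replicates from being
flagged by floating-point noise.

**Regression screen.** Per gene, OLS of expression on a polynomial of
ZT hour (degree 2 by default, the maSigPro convention), F-tested
against the intercept-only model. Significance is on the raw p-value
(default α = 0.001), deliberately uncorrected. Constant genes get
F = 0, p = 1. On 10,000 simulated flat negative-binomial genes the
realized type-I rate is within 3 binomial standard errors of α (the
acceptance script recomputes this).

## Cycling detection

The model library holds, for each family, one trace sampled at the
observed timepoints: sinusoid cos(2π(t−phase)/period) and a triangle
wave with the same extrema (the "rough linear interpolation" of a
sinusoid), on periods 20–28 h × phases 0–23 h in 1-h steps, plus one
spike model per timepoint (1 there, 0 elsewhere). Zero-variance traces
are dropped.

Each gene is Pearson-correlated against every model. By default the
model trace is expanded to one value per *sample* (replicates share
their timepoint's model value) rather than correlating
replicate-collapsed means: with only 10 collapsed points, the maximum
over ~440 correlated models of the null R exceeds 0.8 for ≈11% of flat
genes no matter how small the noise is (Pearson R is scale-free), which
would make the R > 0.8 call threshold meaningless; per-sample
correlation keeps the null's 99th percentile near 0.6 while attenuating
true-cycler R only mildly. `collapse=True` restores the collapsed-mean
behavior for comparison.

Best model = first argmax of R in a fixed tie-break order (smaller
period, then smaller phase, then sinusoid < triangle < spike); ties are
resolved within 1e-12 because coarse sampling aliases some grid models
(e.g. period 21 sampled every 3 h makes phases 0 and 21 identical up to
rounding). A gene is a cycler when best R > 0.8 (R unsquared); constant
genes get R = 0. Raising the threshold can only shrink the cycler set,
and affine transforms of a trace change nothing — both are property-
tested, and the whole classifier is checked exactly against a naive
per-gene/per-model scan.

CAM gene sets carry a fixed label vocabulary (β-CA, plant- and
bacterial-type PEPC, PPCK, MDH, NADP-ME, PEPCK, PPDK); curated ids
missing from the calls are reported on a warnings channel, never
silently dropped.

## Promoter cis-regulatory elements

Promoters are the 500 bp upstream of the annotated gene start (not the
translation start), strand-corrected, clipped at contig edges with a
truncated flag, and never masked for neighboring genes. Enrichment is
promoter *presence* (a k-mer counts once per promoter; k-mers
containing N are skipped) to avoid length bias: per (k-mer, phase bin),
a one-tailed hypergeometric test of cycler promoters in that bin
against all promoters genome-wide. BH correction runs jointly across
all k-mer × bin tests (the conservative reading; per-bin correction is
available by flag). A k-mer is cycling-associated when q < 0.05 in at
least one bin.

Significant k-mers are single-linkage clustered: two k-mers join when
one contains the other or their best ungapped overlap (≥ 4 bp) has
identity ≥ 0.85 — thresholds chosen here, since "sequence similarity"
alone underdetermines them. The consensus is a per-column majority over
the offset-stacked members with ties emitted as IUPAC codes; the phase
profile is the mean ± SD of −log10(q) per bin over members. A cluster
matches a known CRE (ME CCACAC, EE AAATATCT, CBS AAAAATCT, G-box
CACGTG, TCP15 NGGNCCCAC, TBX AAACCCT) when some ungapped alignment has
≤ 1 mismatch over ≥ 5 *informative* positions — positions where neither
letter is N — so a low-complexity consensus cannot match through
wildcards alone. The morning element AGAATAAG is catalog-loadable but
carries no identity claim. Targeted enrichment of catalog motifs in CAM
promoters uses promoter-level IUPAC presence (given strand only by
default) and one-sided Fisher tests, BH-corrected across motifs. Both
exact tests are verified against brute-force tail enumeration.

## Plastid RNA editing

Sites (biallelic SNVs with depth, QUAL, a bcftools-style
mapping-quality-bias p-value, and an alt read count) pass when
depth ≥ 20 AND QUAL ≥ 20 AND bias p ≥ 0.05 — "bias < 0.05" is read as
*removing* sites whose bias-test p falls below 0.05 — then require
alt/depth ≥ 0.10 (boundary inclusive). Classification is on the
transcript strand of each overlapping gene: genomic C>T on + or G>A on
− is C-to-U; T>C on + or A>G on − is U-to-C; anything else "other".
Intergenic sites are kept with a flag and classified on the + strand.
CDS sites get codon number (⌈offset/3⌉), codon position, ref/alt codon
and amino acids under the standard nuclear code (plastid code nuances
are out of scope at this resolution), with a trailing partial codon
skipped under a warning. Classification is invariant to
reverse-complementing the genome and flipping all coordinates/strands,
and on noise-free synthetic tables precision = recall = 1.

## Ks, 4dtv and the WGD signal

Ks/Ka use Nei–Gojobori (1986) counting: per-codon synonymous site
fractions (changes to stops not counted synonymous) averaged over both
sequences; differences averaged with equal weight over all orderings of
the single-base steps for multi-hit codons (steps through stops count
nonsynonymous); Jukes–Cantor correction d = −¾·ln(1 − 4p/3), flagged
undefined at p ≥ ¾. Codons containing an alignment gap are excluded
from all counts. NG86 was chosen over codon-model maximum likelihood as
a transparent, dependency-free estimator that is fully checkable
against a pathway-enumeration oracle; its known cost is an upward drift
at high divergence (below).

4dtv: a third position qualifies when both codons share a four-fold
degenerate first-two-base prefix; raw 4dtv = transversions among
qualifying positions / qualifying count; corrected =
−½·ln(1 − 2·raw) — the two-state transversion-distance correction
(K80 with the transition term at zero) used by the standard 4dtv
scripts — undefined at raw ≥ 0.5. Worked 10-codon examples
(Ks ≈ 0.1073, corrected 4dtv ≈ 0.1116) are frozen in the tests.

The paranome Ks distribution clips values to [0.05, 5] (discarding
allelic/very recent duplicates and saturated pairs), fits a Gaussian
KDE (Silverman bandwidth) and reports density maxima with prominence
≥ 5% of the peak density, sorted by prominence. Pairwise Ks over a
paranome overweights large gene families relative to per-duplication-
node deduplication; peak *positions* are robust to this but peak
heights are not — interpret heights qualitatively.

**Accuracy envelope.** On simulated pairs (events uniform over
synonymous single-nucleotide changes, transition:transversion weight
κ = 2), median Ks recovery error pooled over divergence levels up to
true Ks = 1.0 is ≈ +8%. The bias is systematic and grows with
divergence (≈ +12–15% at true Ks 0.8–1.0): at two-fold degenerate
sites the substitution process is a two-state flip whose multiple-hit
behavior the four-state Jukes–Cantor correction overcompensates.
Treat NG86 Ks peaks above ~1 as upper-biased; 4dtv is the
saturation-resistant cross-check for exactly this regime.

## Synthetic data: what it does and does not emulate

The generator writes genomes with strand-mixed, non-overlapping,
single-CDS genes (ATG + sense codons + stop), ≥ 500 bp upstream flanks
except for a configurable edge-truncated fraction placed on short
contigs to exercise promoter clipping; diel counts as negative-binomial
draws (default dispersion 0.05) around baseline × (1 + amplitude ×
waveform) means, scaled by CDS length and a per-sample library size so
TPM is nontrivial; cyclers default to period 24 h (entrained), integer
phases, amplitudes 0.6–1.0, and are planted among expressed genes; 20%
of genes sit below 1 TPM to exercise the filter. Editing sites pass
every threshold (true) or are constructed to fail at least one (noise).
Codon pairs accumulate a fixed number of synonymous events, uniform
over available synonymous changes with κ = 2, so a four-fold site draws
3× the rate of a two-fold site — the same weighting NG86's site
counting assumes.

The NB replicate-noise model is a surrogate chosen for realism, not an
inference from any particular dataset. The generator has no isoforms,
no mappability or GC artifacts, no batch structure, and plants motifs
by overwriting rather than insertion; passing tests therefore
demonstrate correctness of the statistics and plumbing under a
controlled noise model, not robustness to every artifact of real
libraries. Every generator is deterministic per seed, byte for byte.

## Orchestration

`quillcycle run --config run.toml` executes
simulate → normalize → screen → cycling → cre → editing → molevo as
toggled, validating the TOML against a closed key schema before any
stage runs, and writes a manifest (package version, resolved config,
per-stage outputs with SHA-256 checksums). One global seed fans out to
per-stage seeds by fixed offsets so stages can be re-run in isolation;
identical config and inputs give byte-identical outputs.

## Problem sizes

Defaults used by the test suite and the acceptance script: 1,000 genes
for cycling recovery and the oracle scan, 10,000 genes for the
regression null, ~2,000 promoters for the exhaustive 3–7-mer scan,
60-gene genomes with 40 planted edits for the editing checks, and
60 pairs × 200 codons per divergence level for Ks recovery. These sizes
give stable Monte-Carlo estimates while keeping a full run under a
minute on one CPU.
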
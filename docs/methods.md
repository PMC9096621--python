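# Methods

This note documents the models, parameter choices and numerical decisions
behind photoepi, and what the synthetic-data validation does and does not
demonstrate about real data.

## Study design assumptions

The package targets a two-condition design: one *pooled* bisulfite library
per condition (no replicate variance on the methylation side), replicated
count libraries (default 3 vs 3) for RNA-seq and sRNA-seq, and a shared
gene/TE annotation. All internal coordinates are 0-based half-open; the
format readers are the only code performing ±1 arithmetic (GFF3 and
cytosine reports are 1-based on disk, BED is not).

## Differential methylation

*Context assignment.* A cytosine's context is read 5'→3' on its own
strand: CG if the next base is G, CHG if the base after next is G, CHH
otherwise (H = A, C, T). Cytosines within 2 bp of a chromosome end that
cannot complete the trinucleotide default to CHH. The rule is verified
against exhaustive enumeration of all trinucleotides on both strands.

*Per-cytosine test.* Two-sided Fisher's exact test on the 2×2
methylated/unmethylated table, vectorized over sites (the hypergeometric
support is iterated; probabilities come from scipy). Only cytosines with
coverage ≥ `min_coverage` (default 10) in **both** samples are tested.
P-values are BH-adjusted across all tested cytosines of the region set; a
DMC requires q < `c_fdr` (0.05) and |level difference| ≥ `min_diff_c`
(default 0; set ~0.25 to mimic common methylKit practice).

*Region call.* Because a pooled design gives the region-level test no
replicate variance, the caller is deliberately conservative: a region is
non-ns only if (a) a Fisher test on counts pooled over its cytosines
passes BH FDR < `region_fdr` across regions **and** (b) the region holds
≥ `min_dmc` (10) DMCs in the tested context. Both thresholds are
configurable. Regions may overlap (adjacent 2-kb promoters often do); a
shared cytosine contributes to each covering region but is only tested
once. Regions with zero covered cytosines are reported ns with
`n_covered_c = 0` rather than dropped silently.

*Binned profiles.* 1-Mb bins tiling each chromosome (last bin short); the
bin level is Σmeth/Σtotal over cytosines covered ≥ 10× in *all* samples,
so all samples are compared on the same site set. Differences vs the
reference sample are classified hypo-/hypermethylated beyond ∓5
percentage points. Empty bins carry NaN, never 0. Gene/TE density is
feature nucleotides per million bases of bin.

## Differential counts

Counts are modelled per feature as NB with mean proportional to total
library size (log offsets) and a fixed dispersion; the test is the LRT of
equal rates between groups against a χ²₁ reference.

*Dispersion.* With two or three replicates per group, per-feature moment
estimates of φ are noisy enough to destroy type-I calibration when plugged
into an LRT (measured null p < 0.05 fractions near 0.07–0.09 in
simulation). The default is therefore a single common dispersion estimated
by maximizing the Cox–Reid adjusted profile likelihood over all features
(golden-section search on log φ); a `shrink < 1` option blends per-feature
Pearson-moment estimates (n/(n−p) dof correction, clipped at 0) toward the
common value for larger designs. With the default, the measured null
fraction is ≈ 0.051 (range 0.044–0.058 over ten simulation seeds at
n = 3 + 3, φ = 0.05). The cost of the common-dispersion default is
insensitivity to feature-specific dispersion (e.g. highly variable genes
appear slightly anticonservative on real data); that is the main caveat
when moving beyond the synthetic conditions.

*Fold changes* are group-B-over-A ratios of fitted per-million rates,
stabilized with a 0.5-read prior at the average depth. The reference group
defaults to the first label seen and can be forced (`reference=`), which
exactly negates every log₂FC. Normalization uses total library size only
(the study's stated normalization); TMM-style composition correction is
out of scope. Scaling all library sizes by a constant (changing depth
units) leaves results exactly unchanged; scaling one library's counts and
size jointly is *not* an exact invariance of a count-scale model — the
scaled library genuinely carries more counts — but calls are stable
(≤ 1 % boundary flips at 2× scaling in the test suite).

*Filtering.* Features need ≥ 2 CPM in at least `min_samples` samples
(default: the smallest group size — the number of samples that could
plausibly all express the feature).

## sRNA clusters

Cluster calling is intentionally a simplification of aligner-integrated
tools such as ShortStack: no multimapper placement model, no phasing. Size-
selected reads (18–24 nt) from all samples are pooled, sorted, and merged
into islands joined across gaps ≤ 75 bp; islands with < 3 supporting reads
are dropped. Calling on the union of samples guarantees every sample a
count for every cluster, which the NB test requires. Categorization uses
≥ 1 bp overlap with precedence gene body > promoter > TE > intergenic and
largest-overlap tie-breaks, so the four categories partition the set; the
overlap rule and pad are configurable.

## Positional motif enrichment

PFM → PWM: column probabilities (count + 0.25)/(colsum + 1) against a
uniform 0.25 background (configurable), log₂ odds. Scores are discretized
to 10⁻³ bits; the exact null score distribution is the DP convolution of
per-column distributions, verified against exhaustive 4^L enumeration for
L ≤ 8. The hit threshold is the smallest score with null tail < 10⁻⁵ —
note an 8-column motif cannot reach 10⁻⁵ under a uniform background
(0.25⁸ ≈ 1.5×10⁻⁵), so informative motifs of length ≥ 9 are required at
the default threshold.

Scanning covers both strands of the ≤ 20-kb upstream window (clipped at
chromosome edges); a hit's distance is the gap between its TSS-proximal
end and the TSS. Curves are per-gene indicators (multiple hits per gene
count once), evaluated on a 0–20,000 bp grid with 100-bp steps. The scalar
summary of ES(x) is its maximum over x — the standard conservative scan
reduction; mean-ES is selectable. The permutation null draws same-size
gene subsets without replacement from all genes with an annotated TSS;
p = (1 + #{null ≥ obs})/(n_perm + 1), z from the null mean and SD (z is
NaN when the null SD is 0, p remains valid). Per-gene minimum distances
are precomputed once, so 1,000 permutations take well under a second.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study's data: genome
composition (GC 0.36), spatial organisation (genes on chromosome arms,
TEs pericentromeric), context methylation means (CG 0.80 / CHG 0.67 /
CHH 0.23), beta-binomial overdispersion (ρ = 0.05) at Poisson(20)
coverage, NB counts (φ = 0.05) with log-normal library sizes (σ = 0.15
around 2×10⁶), discrete sRNA loci with a 21/24-nt-biased length mix, and
uniform-background motif landscapes with TSS-proximal planted occurrences
(probability 0.6 within 1 kb). Planted effect sizes default to the
recovery conditions exercised in validation: |Δ methylation| = 0.3,
|log₂FC| = 2.

Deliberate simplifications: no sequence-composition realism for TEs, no
read-level errors or mapping bias, no methylation–expression mechanism
(cross-layer coupling exists only as explicit hooks — DMRs placeable on
chosen promoters, differential sRNA loci placeable inside chosen regions,
count changes plantable per feature), independent cytosines (no local
autocorrelation), and dispersion constant across features. Passing
recovery and calibration on these data therefore demonstrates the
*statistics* are implemented correctly and calibrated under their own
assumptions — not that the assumptions hold for any particular real
dataset.

Chromosome count/length (2 × 500 kb), gene/TE numbers (200/80) and the
problem sizes used by the validation battery (2,000-feature matrices, 10
calibration seeds, 200 permutation-null repetitions, 20 power seeds) were
chosen so the complete battery runs in well under a minute while keeping
Monte-Carlo error small relative to the acceptance margins.

## Determinism

Every generator seeds `numpy.random.default_rng([seed, stage_salt])`, so
outputs are byte-identical across runs and independent of call order; the
pipeline writes SHA-256 checksums of every stage output into its manifest,
and the bundled demo configuration reproduces checked-in checksums
exactly. The permutation test requires an explicit seed.

## Known limitations

* The pooled WGBS design means region-level significance reflects
  sequencing depth, not biological replication; treat "hyper/hypo" calls
  as descriptive at fixed FDR, as in the underlying study design.
* The common-dispersion NB test trades per-feature adaptivity for
  small-sample calibration (see above).
* Cluster calling ignores strandedness and multimapping; clusters are
  purely positional.
* The enrichment null permutes gene identity, not genomic position, so it
  conditions on the observed per-gene hit landscape.
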
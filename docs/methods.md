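# Methods

`sweepscan` detects recent selective sweeps in a focal population by
comparing haplotype homozygosity decay between populations (XP-EHH), and
surrounds that scan with the standard descriptive stages of a resequencing
study: windowed nucleotide diversity, identity-by-state distances with a
neighbor-joining tree, GRM-based PCA, and term enrichment of candidate
genes. Everything runs from phased biallelic genotypes; a deterministic
synthetic-data generator provides a complete study when no real data are
available.

## Haplotype statistics

**EHH.** For a core SNP and a flanking SNP at signed distance *d*, the
extended haplotype homozygosity is the probability that two haplotypes drawn
at random without replacement from the sample are identical at every SNP in
the closed interval between core and flank:

    EHH = Σ_h C(c_h, 2) / C(n, 2)

where the `c_h` are the multiplicities of the distinct haplotypes over the
interval and `n` the number of haplotypes. The interval includes the core
site; the curve is anchored at (0, 1) by convention and is non-increasing in
|d| because extending the interval can only split haplotype classes.

**Truncation.** The curve is extended SNP by SNP on each side until the EHH
of the *pooled* two-population sample falls below a threshold (default
0.05), the extension exceeds `max_extension` (default 1 Mb), or the
chromosome ends. The first sub-threshold SNP is retained as the terminal
point of the last trapezoid; dropping it would systematically underestimate
iHH and make the truncation rule untestable. Using the pooled sample to set
the boundary means both populations are integrated over the *same* physical
interval, so the ratio below compares like with like.

**iHH and XP-EHH.** iHH is the trapezoidal integral of EHH over physical
distance in bp, summed over the two flanks. At each eligible core,

    XP-EHH_raw = ln iHH_A − ln iHH_B

(computed as a difference of logarithms so that swapping the populations
negates every score bit-exactly). Positive values mean longer haplotype
homozygosity — a candidate sweep — in population A. Cores monomorphic in
the pooled pair are skipped; cores with no flanking point before truncation
on both sides, or a zero iHH in either population, are excluded and counted.
Distances are physical bp throughout (no genetic map is assumed); any
constant per-bp scaling cancels in the ratio, which is tested as an
invariance. Raw scores are standardized to mean 0, sd 1 (n−1 denominator)
across all chromosomes of a comparison; both raw and standardized scores are
emitted.

## Window scan and empirical outliers

The genome is tiled with non-overlapping 50-kb windows (0-based half-open;
a core at position p belongs to the window starting at `p // 50000 * 50000`).
Each window's summary statistic is the **maximum** standardized XP-EHH among
its scored cores — the statistic is directional and the scan asks for
selection in the focal population. Windows with no scored core are dropped.

To avoid biasing outlier calls toward SNP-dense windows, windows are
stratified by scored-SNP count into four clusters in increments of 350:
1–349, 350–699, 700–1049, ≥1050. (The printed cluster bounds in the source
description overlap at 349/350; the contiguous reading consistent with
"increments of 350" is used, and the boundary cases 349→1, 350→2, 1049→3,
1050→4 are pinned by tests.) `n_snps` counts scored cores — cores with a
defined XP-EHH — not raw VCF records, since that is the quantity whose
density the stratification is meant to control; this is documented as a
possible divergence from counting all variant records.

Within each cluster of size N, the empirical p-value of window *i* is the
fraction of windows in the cluster whose summary strictly exceeds it,
`p_i = |{j : s_j > s_i}| / N`; the cluster maximum gets exactly 0 and ties
share values. A conservative (k+1)/(N+1) variant exists behind a flag but is
off by default. Outliers are windows with `p < 0.01` (strict) and positive
summary. Genes overlap-associate with an outlier window when their half-open
intervals share at least 1 bp. Adjacent outlier windows are reported
separately, never merged. Regions called in every comparison form the
intersection table (one row per (chromosome, start), carrying each
comparison's summary and p side by side, with the scored-SNP count taken
from the first comparison — counts can differ slightly between comparisons
because core eligibility depends on the population pair); per-comparison and
pairwise counts are emitted for a Venn summary.

No model-based or FDR-corrected p-values are computed: with demographic
parameters unknown, the empirical rank within a SNP-count stratum is the
defensible quantity.

## Nucleotide diversity

Per window of length L and population of n haplotypes,

    π = (1/L) Σ_sites (n/(n−1)) · 2 p̂ (1 − p̂)

which equals the mean pairwise per-site Hamming distance between the
population's haplotypes — an algebraic identity the tests verify directly.
The denominator is the full window span including invariant sites (the
input is assumed to carry all segregating sites of the region); monomorphic
windows are reported as 0, and a shorter terminal window is normalized by
its actual span. The cumulative average is the running mean of π over
windows in genome order. Between-population π uses the mean per-site
difference of haplotypes drawn one from each population,
`p̂_A(1−p̂_B) + p̂_B(1−p̂_A)`. Reporting default is 10-Mb windows;
analyses at desk scale use 0.1–1-Mb windows.

## Population structure

Haplotype pairs are collapsed to per-sample dosages in {0,1,2}. Two samples
share 2 − |d_i − d_j| alleles at a locus; IBS similarity is the mean of
(shared alleles)/2 over loci (identical individuals score 1) and the
distance matrix is 1 − IBS. The neighbor-joining tree is built with
scikit-bio's Saitou–Nei implementation, which is exact on additive matrices
(tested against path-length oracles on random additive trees) and clamps
the rare negative branch length to zero. The GRM is the allele-frequency
standardized genotype covariance

    G_ij = (1/m) Σ_l (x_il − 2p_l)(x_jl − 2p_l) / (2 p_l (1 − p_l))

over the m polymorphic loci (monomorphic loci dropped); PCA is its
eigendecomposition, with per-component variance fractions reported as
eigenvalue over eigenvalue sum.

## Enrichment

EASE is the one-sided Fisher exact (hypergeometric upper-tail) test with
one gene removed from the list/term overlap before computing the tail:
`ease_p = P(X ≥ k−1)`, and 1 when k ≤ 1. It is conservative:
`ease_p ≥ fisher_p` whenever the term is hit. The background is the whole
annotation table. Terms with EASE < 0.05 are flagged; a Benjamini–Hochberg
column is emitted for information only and plays no role in selection.
Instead of automated term clustering, pairwise shared-gene Jaccard distances
between flagged terms are reported.

## Synthetic data

The generator favors determinism and desk-scale speed over demographic
realism; every stage draws from one seeded NumPy generator per call and
identical seeds give bit-identical output.

* **Neutral panel.** The number of segregating sites is Binomial(L,
  density); positions are uniform without replacement; at each site the
  pooled derived-allele count k ∈ {1, …, n−1} is drawn with probability
  ∝ 1/k (the neutral frequency spectrum) and assigned to exactly k
  chromosomes chosen uniformly, so every site segregates and chromosomes are
  exchangeable. Sites are independent — there is no background linkage
  disequilibrium.
* **Hard sweep.** One donor haplotype is chosen in the target population;
  each of the population's chromosomes becomes a carrier with probability
  `frequency`; a carrier copies the donor's alleles from the sweep position
  outward to per-side breakpoints drawn as `scale` × unit-exponential
  (infinite scale copies the whole chromosome). Because the unit draws are
  made before scaling, a larger scale copies a superset of sites for a fixed
  seed, making homozygosity monotone in scale — a tested coupling property.
* **Founder bottleneck.** A population's haplotypes are rebuilt as mosaics
  of F of its own rows with exponential segment lengths. This reduces π by
  roughly a factor 1 − 1/F, and — because each population resamples its own
  founders — differentiates populations enough for NJ monophyly and PCA
  separation. It is the generator's stand-in for breed formation.
* **Annotations.** Non-overlapping gene intervals with stable identifiers;
  a term table with one implanted enriched term (the genes within ±100 kb of
  each sweep — a swept locus spans several genes) plus random background
  terms.

**The default five-breed study** is one 75-Mb chromosome at SNP density
10⁻³ with 24 haplotypes (12 diploids) per breed: a focal minipig-like breed
(founder bottleneck F=8) carrying two hard sweeps (frequency 0.9, scale
200 kb) at mid-window positions, three commercial-like comparison breeds
(F=12) and a wild outgroup (F=16), all with 100-kb founder blocks. The
genome extent is sized to the rank-based outlier budget: each sweep's
footprint spans ~6 windows, so the within-cluster p < 0.01 cut must admit
comfortably more windows than the two footprints combined (~15 of 1500
here, as in a genome-wide scan) or one sweep can crowd the other out of the
outlier set entirely. Founder blocks are kept shorter than the sweep scale
so that background homozygosity tracts do not mimic sweeps.
With these choices the study simultaneously exhibits the qualitative
targets: lowest π in the focal breed and highest in the wild outgroup,
breed-monophyletic NJ tree, PCA separation, and recovery of both implanted
sweeps by all three comparisons.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: background LD and genealogical correlation between
sites (each site is independent given the founder mosaics), recombination
rate variation, genotyping and phasing error, allele-frequency
differentiation from long-term drift or admixture, and realistic gene
density. In particular, with independent background sites the per-core
iHH of the reference population is noisier along the chromosome than it
would be with coalescent LD, which blurs exactly which window inside a swept
region carries the maximum score.

## Numerical and procedural choices

* Positions are 1-based bp; BED and window coordinates 0-based half-open.
* Missing or unphased genotypes are hard errors — phasing and imputation
  happen upstream, and silently imputing here would corrupt EHH.
* Haplotype class tracking during curve extension uses incremental
  relabelling (`id*2 + allele`, recompacted each step), exact and O(n) per
  SNP.
* Degenerate inputs: standardization refuses fewer than two scores or an
  all-equal score set; EHH needs ≥ 2 haplotypes; NJ needs ≥ 3 taxa; empty
  gene lists and empty comparison maps are domain errors.
* One run seed fans out to per-stage child seeds through `SeedSequence`, so
  stages are individually reproducible and mutually independent.
* Problem sizes: unit and property tests run on panels of ≤ 20 haplotypes
  and ≤ 1-Mb chromosomes; end-to-end checks use two populations × 40
  haplotypes on a 10-Mb chromosome, and the full study one 30-Mb chromosome
  — sizes chosen so the whole suite and the acceptance script each finish in
  minutes on one core.

## Known limitations

* XP-EHH localizes a sweep to a *region* of a few windows, not to a single
  50-kb window: carriers share the donor haplotype from the sweep site
  outward, so windows within ±scale of the sweep have statistically
  comparable maxima. Region-level recovery (an outlier within one window of
  the sweep) is correspondingly stronger than single-window recovery; the
  acceptance script reports both rates.
* The empirical-p procedure is rank-based: it always calls ~1% of windows
  per cluster, sweep or no sweep. Interpretation rests on the outlier logic,
  not on a null model.
* The copy-model sweep has no partial/soft-sweep diversity of origins, and
  the founder-bottleneck differentiation has no explicit divergence-time
  interpretation.
* NJ negative-branch handling follows scikit-bio (clamp to zero) rather
  than redistributing the deficit to the sibling branch; on the
  near-additive IBS matrices produced here the difference is negligible.
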
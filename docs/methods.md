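# Methods

`slafkit` characterizes diploid germplasm panels from biallelic SNP data of
the kind produced by reduced-representation (SLAF/ddRAD-style) sequencing.
This note documents the statistical models, estimator choices, numerical
conventions and known limitations.

## Genotype model and filtering

Genotypes are diploid allele-index pairs; a call with any missing allele
(including half-missing `./1` VCF calls) is treated as entirely missing.
The *dosage* view counts non-reference alleles per call (0/1/2, −1 for
missing) and is the substrate of distances, PCA and kinship.

Locus integrity (INT) is the fraction of samples with a non-missing call;
minor allele frequency (MAF) is the frequency of the second-most-frequent
allele over observed gene copies. The quality filter retains sites with
MAF ≥ 0.05 **and** INT ≥ 0.3, both inclusive, matching the conventional
thresholds for SLAF SNP panels. The filter is idempotent and preserves
sample set and site order; all-missing sites are dropped because their MAF
is undefined.

## Diversity indices

For allele frequencies *p₁ … p_k* at a locus and *n* diploid individuals
actually genotyped there:

| index | estimator | bounds (biallelic) |
|---|---|---|
| He | 1 − Σpᵢ² | [0, 0.5] |
| H (Nei) | (2n/(2n−1)) · (1 − Σpᵢ²) | ≥ He; → He as n → ∞ |
| Ne | 1 / Σpᵢ² | [1, 2] |
| I (Shannon–Wiener) | −Σ pᵢ ln pᵢ | [0, ln 2 ≈ 0.693] |
| PIC (Botstein) | 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ² | [0, 0.375] |
| Ho | heterozygous / non-missing calls | [0, 1] |

Three choices here are worth flagging because diversity software varies:

* **H carries the small-sample correction 2n/(2n−1)** while He does not.
  At p = q = 0.5 this yields H = 0.667 with two typed individuals and
  0.556 with five, against He = 0.500 — exactly the pattern of per-
  population range maxima printed in published germplasm tables, which is
  what pins the estimator pair down.
* **n is the per-locus, per-population count of genotyped individuals**,
  not the population size: only then do per-locus H maxima differ between
  populations with different missingness.
* **PIC is the Botstein 1980 estimator**, the standard in the marker-
  informativeness literature; its biallelic maximum 0.375 at p = q = 0.5
  distinguishes it from He-like surrogates.

Per-population summaries compute each index per locus over population
members only (loci untyped within the population are skipped), report
(min, max, mean) rendered as `min–max(mean)` to three decimals, and count
A = loci with ≥ 2 observed alleles in the population. The table's Mean row
is the **unweighted** arithmetic mean of per-population means (and of A):
population-level summaries in this literature average across populations,
not samples.

## Hardy–Weinberg exact test

The fingerprint panel requires HWE consistency. The test is the exact
conditional test: given the observed allele counts, every heterozygote
count of the same parity is enumerated with weight
w(h) = C(n, h) · C(n−h, (rare−h)/2) · 2ʰ (the multinomial count of
genotype configurations), and the p-value is the total probability of
configurations with weight ≤ the observed one. Weights are exact integers,
so probability ties (frequent in small symmetric tables) are resolved
without floating-point ambiguity; the p-value is returned as an exact
rational converted to float. A 1-df chi-square variant is available behind
a flag for users who want the asymptotic test; the exact test is the
default since panel candidates can have unbalanced genotype classes.

## Distances, trees, bootstrap

The p-distance between two unphased diploid samples is the mean over loci
typed in both of (allele mismatches)/2, i.e. |dosage difference|/2 for
biallelic loci: 0/0 vs 1/1 → 1.0, 0/0 vs 0/1 → 0.5. Pairs sharing no typed
locus are an error, not a guess. Trees are classical Saitou–Nei
neighbor-joining (scikit-bio backend) with negative intermediate branch
lengths clamped to zero; on additive matrices the tree reproduces the
input distances exactly (tested against a path-length oracle).

Bootstrap resamples loci with replacement, rebuilds the tree, and scores
each internal edge by the fraction of replicates containing the same leaf
bipartition. Supports are fractions in [0, 1] stored as internal node
labels in Newick output; runs are deterministic under a seed.

## PCA, kinship, grouping

PCA standardizes dosages EIGENSOFT-style: missing values mean-imputed,
columns centered by 2p̂ and scaled by √(2p̂(1−p̂)), monomorphic columns
dropped; the samples-by-samples covariance X Xᵀ/m is eigendecomposed and a
component's variance fraction is its eigenvalue over the trace. The
genomic-relationship matrix (VanRaden type) is the same X Xᵀ/m; under
Hardy–Weinberg proportions its diagonal averages ≈ 1 and unrelated pairs
≈ 0.

`cut_tree(tree, k)` partitions leaves by removing the k−1 longest internal
edges (terminal edges are considered only when internal edges are
exhausted, so k = leaf count yields singletons); an edge is cut only when
it actually separates leaf groups. On clean, well-separated clades this
recovers the clades exactly.

Cutting a taxon-level NJ tree of real-scale noisy genotype data is,
however, outlier-sensitive: strongly admixed individuals form long pendant
cherries whose stem edges out-rank the cluster-separating edges. The
package's grouping route (`genetic_groups`) therefore cuts a **Ward
dendrogram built over the leading principal components** (default: two
components for a three-group analysis — the top K−1 axes carry the
structure while per-locus noise averages out, and Ward's size-weighted
merge cost keeps isolated samples from dominating the top of the tree).
The dendrogram is an ordinary tree object, so the same `cut_tree`
operation applies. On simulated three-pool panels at FST 0.1 this recovers
dominant-ancestry labels at ≥ 95% concordance.

Concordance between two partitions is the fraction of samples agreeing
under the best one-to-one matching of cluster labels (Hungarian assignment
on the contingency table); it is invariant under relabeling. Published
concordance figures rarely state their matching rule, so this definition
is documented rather than claimed to reproduce any particular printed
percentage. Cluster-by-origin tables carry row totals, column totals and
row percentages of the panel.

## Core markers and fingerprints

The fingerprint panel filter chain runs in a fixed order — biallelic →
complete data (INT = 1.0) → MAF ≥ 0.20 → PIC ≥ 0.35 → HWE exact p > 0.01 →
adjacency exclusion → per-window thinning — and the audit trail records
the first failing stage per rejected site. Two interpretation choices:

* **Adjacency is checked against the unfiltered variant set**: a nearby
  variant disqualifies a candidate even if that variant itself failed
  earlier stages (distance ≤ 100 bp on the same chromosome). This is the
  conservative reading for assay robustness.
* **"Uniform genomic distribution" is operationalized as per-window
  thinning**: within each window (default 1 Mb) the highest-PIC markers
  are kept up to a quota (default 1), ties broken by position. Window and
  quota are configuration knobs since no standard procedure exists.
* HWE is computed over the full panel jointly, not per population, since
  the fingerprint panel serves the whole collection.

Fingerprint encoding maps each core-marker genotype to one state character:
homozygous calls to their base letter (colors: yellow C/C, green A/A, blue
T/T, purple G/G), heterozygous to `H` (white), missing to `N` (gray). The
payload string is `sample_id|states`. Decoding restores homozygous,
heterozygous and missing states exactly; heterozygous base identities are
not recoverable — the white state of the color scheme is inherently lossy,
by design of that scheme. Rasterizing payloads into 2-D barcodes is
presentation-layer work left outside the library.

## In silico double digest

Recognition sites are IUPAC patterns matched case-insensitively with
overlaps allowed; a cut coordinate is match start + the enzyme's offset
(HaeIII GG^CC offset 2, Hpy166II GTN^NAC offset 3, both blunt, per REBASE
convention). Digestion takes the union of cut positions over enzymes;
fragments tile the sequence exactly (conservation is asserted in tests)
and record the enzyme producing each flank. Tags are fragments with both
flanks enzymatic and length inside the selection window (default
364–394 bp, the insert range of a typical SLAF library); single-flank
dialects are available via a flag. Scheme scoring reports tag yield,
duplication rate (tags with soft-masked fraction > 0.5 — a repeat proxy —
or non-unique uppercase sequence) and genomic uniformity as the
coefficient of variation of tag counts over fixed bins (default 1 Mb).
Coordinates are 0-based half-open internally; only VCF output is 1-based.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
any particular demographic history:

* **Ancestral pools**: K pools (default 3) diverge from a common ancestor
  under the Balding–Nichols model — pool frequency ~
  Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p drawn uniformly in
  [maf_floor, 1−maf_floor] (default floor 0.05), with per-pool FST F
  (default 0.1, a typical crop-germplasm divergence).
* **Collection populations**: default eight labeled populations of sizes
  29, 29, 10, 9, 11, 29, 61, 35 (codes B, E, ES, ED, EY, G, Q, X; 213
  samples), each with a base ancestry vector putting weight 0.8 on its
  primary pool (round-robin assignment).
* **Admixture**: each sample draws its ancestry from
  Dirichlet(α · base) with α = 10, yielding roughly 60% near-pure and 40%
  visibly admixed accessions — the mixture regime germplasm collections
  report. The truth object exposes per-sample ancestry and the
  dominant-pool assignment used as ground-truth labels.
* **Genotypes**: Binomial(2, q·p_locus) per sample and locus, i.e.
  Hardy–Weinberg proportions at each sample's mixed frequency.
* **Missingness**: independent Bernoulli per call, default rate 0.02.
  This default keeps the complete-data (INT = 1.0) fingerprint criterion a
  live filter at n = 213 (≈ 1% of loci complete); under an independent-
  missingness model a rate of 0.1 would leave no complete locus at all.
  The Bernoulli model deliberately does not reproduce the heavy-tailed
  integrity spectrum of real reduced-representation data, where whole tags
  drop out in subsets of samples — so passing tests say nothing about
  performance under structured missingness.
* **Coordinates**: 5,000 loci by default, spread in contiguous blocks over
  12 chromosomes (`Chr01`…`Chr12`), positions random, sorted, unique, ~1
  SNP per kb. Monomorphic loci are retained so the MAF filter has work to
  do. Identical configuration + seed gives byte-identical output files.

Toy genomes for digestion are i.i.d. nucleotide sequences (default GC
0.40) with contiguous soft-masked blocks (geometric lengths, mean 200 bp)
placed until exactly the requested masked fraction is reached. They have
no repeat families or compositional heterogeneity, so duplication-rate
estimates on them are optimistic relative to real plant genomes.

## Problem sizes and numerical notes

The test suite and examples run the study-scale configuration
(213 × 5,000) for simulation, filtering, diversity, PCA/GRM and grouping;
bootstrap trees are exercised at 10–12 taxa × 60–100 columns × ≤ 100
replicates, and oracle equivalences at n ≤ 50 (HWE), 4–8 taxa (NJ) and
10 kb (cut sites) — sizes at which the independent oracles are exact and
fast. Frequency vectors must sum to 1 within 1e−9; NJ Q-matrix ties break
to the lowest index pair; Shannon's index clamps the −0.0 float artifact;
bootstrap and simulation randomness comes from seeded NumPy generators
only.

## Known limitations

* Admixture-model inference itself (the Q-matrix estimation) is out of
  scope; any externally produced partition can be supplied for concordance
  analysis.
* Multiallelic sites are retained through I/O and filtering (MAF = second-
  most-frequent allele) but are excluded from fingerprint candidacy, and
  their p-distance contribution collapses alleles to a non-reference
  dosage.
* The concordance statistic depends on the label-matching rule; figures
  computed with other rules (e.g. fixed label orderings) are not
  comparable.
* Genotyping error, allele dropout and depth-dependent missingness are not
  modeled.
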
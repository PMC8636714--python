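# Methods

This note documents the models and procedures `gourdcore` implements, the
parameter defaults and why they were chosen, the numerical conventions,
and the limits of what the synthetic panels can establish.

## Data model

The substrate everywhere is a matrix of codominant biallelic calls —
reference homozygote, heterozygote, alternate homozygote, or no-call — as
a KASP fluorescence assay or a GT-only VCF produces. Calls are unphased
(AB ≡ BA) and a missing call never contributes alleles to any statistic.
Coordinates are 1-based throughout, matching VCF and assay-table
conventions; no 0-based interval type exists in the package. In text
tables, `NA`, `-` and the empty cell are accepted as no-call on input and
`NA` is emitted on output; any other token is a parse error rather than a
silent missing value, because fingerprinting and authentication must not
manufacture or hide genotype differences.

## Synthetic panels

No real germplasm genotypes ship with the package; two generators create
panels with the statistical structure the analyses assume.

**Structured inbred collection.** Per marker, an ancestral reference
frequency p₀ ~ U(maf_floor, 1 − maf_floor); subpopulation frequencies
follow the Balding–Nichols compound, Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), with
differentiation parameter F (= fst). Accessions are fully inbred — a
homozygote drawn from their subpopulation's frequency — then each call is
flipped to heterozygous with probability `het_rate` and masked missing
with probability `missing_rate`. Defaults are the study conditions the
package targets: 206 accessions, 93 markers over 11 chromosomes, two
subpopulations, fst 0.1, maf_floor 0.05, het_rate 0.02, missing_rate
0.03. The noise rates sit at the level real inbred-collection KASP panels
show (per-locus observed heterozygosity < 0.10 with a mean of a few
percent; missing-call rates a few percent). Balding–Nichols is the
minimal standard model that yields a two-sub-gene-pool structure; it makes
no claim to model any crop's actual history.

**MAGIC-like RIL panel.** Eight fully homozygous founders with per-marker
allele indicators drawn at Bernoulli(p₀), p₀ ~ U(0.1, 0.9); each line is,
per chromosome, a run-length mosaic of founder haplotypes with geometric
block lengths (mean `block_len_markers`, default 3 markers), fully
inbred, then the same het/missing noise (defaults 0.04 and 0.02, matching
the published per-marker summaries for such a population: mean observed
heterozygosity ≈ 0.04, missing ≤ 0.06). Blocks are indexed in markers,
not centimorgans, because no genetic map is assumed; the mosaic
reproduces the only properties used downstream (high homozygosity, an
intermediate MAF spectrum, within-chromosome correlation).

All randomness flows from one explicit `seed` through a single
`numpy` generator per call; the same config always returns the identical
matrix. Subpopulation / line truth is encoded in accession ids so tests
can recover it without side channels.

What the generators do **not** emulate: linkage disequilibrium calibrated
to any real map, selection, genotyping batch effects, or locus-specific
error rates. Tests passing on these panels therefore establish the
*algorithms* behave as specified under realistic summary statistics, not
that any real collection would yield the same panel or core.

## Diversity statistics

Per locus, over called samples only: p = (2n_AA + n_AB)/(2n_called);
MAF = min(p, q); Ho = n_AB/n_called; gene diversity He = 2pq; Botstein
PIC = 1 − (p² + q²) − 2p²q²; effective alleles Ne = 1/(p² + q²). He and
PIC are always reported side by side: Botstein's PIC is capped at 0.375
for a biallelic locus, while widely used software and published marker
tables often print 2pq under the name "PIC" (values up to 0.5). Wherever
published tables are reproduced, He is the comparable quantity; the
package never silently redefines either statistic.

The panel-level Shannon index pools alleles across loci: each locus
contributes its two allele frequencies with weight 1/L, giving
SH = −Σ (p/L)·ln(p/L) over up to 2L pooled alleles, bounded by ln(2L).
The pooled form is used because per-locus biallelic entropy is bounded by
ln 2 ≈ 0.693, while reported panel-level Shannon values for ~22-locus
panels are near 3 — only attainable under pooling.

A note on Ne: published core-collection tables sometimes print Ne = 1
for clearly polymorphic panels, which the standard per-locus 1/Σp²
(averaged over loci) cannot produce. The package computes the standard
quantity and leaves the discrepancy documented rather than chased.

## Genetic distances

Individuals are per-locus allele-frequency vectors ((1,0), (½,½), (0,1)).
Loci missing in either member of a pair are deleted pairwise — no
imputation — and L′ shared called loci normalize the sums. Modified
Rogers and the Cavalli-Sforza–Edwards chord are bounded by 1 and MR is
Euclidean (triangle inequality holds on complete data); Nei's standard
distance is −ln of the normalized gene identity and is unbounded. A pair
with no shared called locus, or zero Nei identity, is an error naming the
pair, not a silent NaN.

## Core marker panel selection

Candidates are first filtered by the printed retention rule — MAF
strictly above 0.05 and missing rate strictly below 0.05 (boundary values
rejected; an epsilon of 1e-9 absorbs float representation at the
boundary) — and can be thinned to k per chromosome by nearest-marker
assignment to k evenly spaced anchor positions (ties: higher gene
diversity, then lower position).

Selection is greedy set cover over accession pairs with a per-chromosome
quota. A marker resolves a pair only when both calls are present and
differ: a missing call must never fake a difference, which is the
authentication-safe convention. Ties on gain break by higher He, then by
the chromosome with fewest selected markers, then by marker id — the
balanced-informative reading of "minimum markers, maximum diversity". In
minimal-panel mode a reverse-delete pass then removes any selected marker
whose pairs the rest of the panel still resolves; brute-force comparison
on small instances (10 accessions × 12 markers from the package's own
generator, 30 fixed seeds) shows the pruned greedy matching the
exhaustive optimum in 25/26 resolvable instances, and it can never
undercut it. With `target_size` set, selection continues by the same rule
to a fixed balanced size (e.g. 22 = 2 × 11 chromosomes) even after full
resolution.

The saturation curve counts distinct multilocus classes per panel prefix
with missing as its own symbol; pairs distinct *only* through missingness
are flagged separately (`missingness_only_pairs`) rather than silently
counted as discriminated. Theoretical capacity is 3ⁿ exact integer
arithmetic.

## Fingerprinting and authentication

Fingerprints are code strings over {A, H, B, N} in panel order, doubling
as Code128-compatible barcode payloads (image rendering is out of scope).
Duplicate detection groups codes differing at ≤ `max_mismatch` compared
positions (N skipped by default) by single linkage. Authentication
compares loci called in both sample and reference; the verdict is
`match` only with zero mismatches and at least ⌊0.8 × panel size⌋
comparable loci, `inconclusive` below that floor. The 0.8 completeness
floor and the purity rule's heterozygosity fraction (default 1.0: a true
F1 must be heterozygous at every called parent-diagnostic locus) are
explicit, configurable stand-ins — no published numeric acceptance rule
exists for these assays. Seed-lot purity is the fraction of evaluable
seeds (≥ 1 called diagnostic locus) that pass the F1 rule; seeds matching
one parent's homozygote across their called diagnostic loci are classed
as selfed toward that parent.

## Core collection selection

The core is a subset of accessions under a hard constraint — 100% of the
(locus, allele) pairs observed in the whole collection must be carried in
the core (heterozygotes carry both alleles) — with the average
entry-to-nearest-entry distance as the objective, a standard measure for
pushing core entries apart. A single-objective design with coverage as a
constraint was chosen over a weighted multi-objective blend for
testability. Optimization: forced inclusions, then greedy coverage
completion (most uncovered alleles first; ties toward larger mean
distance to the current core), then farthest-point completion to the
target size, then a seeded randomized improving-swap search (each
iteration scores the full in/out neighborhood incrementally and accepts
one improving swap at random; swaps breaking coverage or evicting forced
ids are excluded; capped by `max_swap_iters`, default 200). The objective
is monotone across accepted swaps, and the returned core's coverage is
re-verified independently of the optimizer. Infeasible coverage at the
requested size is an error reporting the greedy minimum feasible size.
Forced inclusions model manual augmentation of an algorithmic core
(e.g. breeder-chosen additions) without pretending that step is
optimized.

Evaluation reports mean pairwise MR and CE within the core, pooled
Shannon, mean He, mean Ne, mean Botstein PIC, and coverage, in that
table order.

## Ordination, trees, grouping

PCA runs on mean-centered alt-allele dosage (0/1/2); missing dosages are
imputed with the per-marker mean *in the PCA only*, keeping the
decomposition dense and deterministic, and component signs are fixed by
making each component's largest-magnitude loading positive. Neighbor
joining is delegated to scikit-bio's canonical implementation behind the
package's distance types; negative branch lengths are clamped to zero
with the adjustment recorded. Group assignment is k-means on the leading
components — a deliberately lightweight stand-in for model-based
admixture inference, returning hard labels, never ancestry fractions.

Under the default study conditions (fst 0.1), k-means-on-PCs labels agree
with the simulated truth for roughly 94–98% of accessions on the full
93-marker panel and 85–94% on the 22-marker panel, so panel-vs-panel
grouping agreement lands around 86–94% per replicate; the tests assert
agreement well above chance per replicate (≥ 80%) and ≥ 85% on average,
which is what this stand-in can support at these conditions.

## Problem sizes and determinism

Study-scale analyses run at 206 accessions × 93 markers with five
replicate seeds; parameter-recovery checks use 2,000 accessions at ~30–40
markers; brute-force oracles (exhaustive set cover, per-pair distance
loops) run at ≤ 12 markers and ≤ 10 accessions, sizes where enumeration
is exact and fast. Every stochastic component — simulation, swap search,
k-means — takes an explicit integer seed, and all results in the README
and the acceptance script are reproducible from those seeds alone.

## Known limitations

- Distances assume biallelic loci; no multiallelic generalization.
- No AMOVA/F-statistics estimators; no tree bootstrapping; no admixture
  proportions; no ΔK-style model selection.
- The purity and authentication thresholds are conventions, not
  validated assay standards.
- Synthetic panels carry no calibrated linkage disequilibrium, so
  map-aware thinning beyond even physical spacing is untested against
  realistic LD structure.
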
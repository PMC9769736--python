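# Methods

This note documents the models and procedures magcat implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Bin quality control

The quality score is `S = completeness − 5 × contamination`, both on the
0–100 percent scale; S may be negative. The retention rule is the
conjunction completeness ≥ 70, contamination < 5 (strict) and S > 55
(strict): a bin landing exactly on S = 55 — e.g. 70 % complete, 3 %
contaminated — is rejected. Where wordings of the contamination bound
differ (`<` vs `≤`), the strict form is adopted and configurable
(`RunConfig.contamination_max`). The score is always recomputed from
completeness and contamination, never trusted from an input column.

Rejection reports carry the *first* failed criterion in the fixed order
completeness → contamination → quality score, so reports are deterministic.

**Merging.** Within one sample, bins with identical species assignment,
depths within ±10 % and G+C within ±0.02 are merged. Because the source
rule is silent on seeding and transitivity, merging is made deterministic
and drift-free: bins are sorted by descending quality score; the best
unmerged bin seeds a group; every candidate is compared against the *seed's*
depth and G+C (never chained through earlier members). Depth tolerance is
relative: `|d − d_seed| / d_seed ≤ 0.10`. A merged bin's depth is the
length-weighted member mean; its G+C is recomputed from the concatenated
sequence; completeness and contamination are inherited from the seed and the
row is flagged `merged` — re-estimating them would require marker-gene
analysis, which is out of scope, and the flag keeps that honest. Merging
runs before filtering, following the narrative order of the original
workflow; the alternative order is not emulated.

## ANI estimation and dereplication

ANI is estimated from canonical k-mer sets (k = 16, the largest k whose
2-bit packing fits 32 bits; configurable). With containment
`c = |A∩B| / min(|A|,|B|)` — robust to unequal genome completeness — the
Jaccard equivalent for equal-content genomes is `J = c/(2−c)`, and the
Mash-style transform `ANI = 100·(1 + (1/k)·ln(2J/(1+J)))` simplifies to
`ANI = 100·(1 + ln(c)/k)`, floored at 0 when no k-mer is shared. Plugging
raw containment directly into the Jaccard transform would overestimate ANI
by >1 point at 3 % divergence; the containment→Jaccard conversion restores
the expected `ANI ≈ 100(1 + ln((1−p)^k)/k) = 100(1−p)` behaviour, verified
in tests against construction truth (±1 point at 97 % identity on 20 kb
sequences). `aligned_fraction` reports c and acts as a secondary gate
(default ≥ 0.3 at both clustering levels; the original workflow states this
only for the 99 % step, so the 95 % default is an explicit assumption,
configurable via `min_aligned_fraction`).

Clustering is greedy centroid clustering: genomes sorted by quality score
(ties: longer genome, then lexicographically smaller id — a total order, so
results are deterministic); the best unassigned genome becomes a
representative; unassigned genomes with ANI *strictly above* the threshold
join. At 99 % this yields dereplication collections whose best-scoring
member is retained as the MAG; at 95 % it yields SGBs. Tests verify the
greedy result equals the unique minimum-cardinality valid clustering on
threshold-forced instances of ≤ 8 genomes, and that planted species
partitions (1 % within, 10 % between divergence) are recovered exactly.

## Prevalence and core sets

Presence is defined on genome *coverage* percent (the natural reading of a
per-sample coverage table; a depth-derived reading would change little but
is not assumed), with boundary `coverage ≥ cutoff` (default 1 %). Coverage
and relative abundance are carried as distinct matrix kinds and cannot be
interchanged silently. Core = present in ≥ 90 % of samples (exact fractional
comparison, not a rounded count, so 27/30 qualifies); universal = present in
all; unique = present in exactly one. Region universality: relative
abundance ≥ 0.01 % in ≥ 50 % of a region's samples; `shared` is the
intersection over regions and `endemic(r)` the set universal in r only.

## Module integrity and functional profiles

A genome's integrity code for a module is determined solely by how many of
the module's KOs it lacks: 0 → 2 (complete), 1 → 1 (partial), ≥ 2 → 0
(absent). Module definitions arrive as a flat module→KO table; Boolean
AND/OR structure in KEGG definitions is flattened to the KO union. This is
an approximation of KEGG's stepwise logic, adopted because the missing-KO
count is defined on a flat set; it makes integrity monotone under KO
addition, which tests exploit. Gene counts per category count each label
once per gene (a gene may carry both a KO and a CAZy family) and are
additive over genome groups.

## Enrichment (reporter scores)

For a two-group contrast on a samples × KO relative-abundance matrix:

1. KOs nonzero in strictly more than `min_samples` (default 3) samples are
   tested with a one-tailed Wilcoxon rank-sum test in each direction.
   scipy's implementation is used: exact for small tie-free samples,
   midrank normal approximation with continuity correction otherwise; a
   fully degenerate KO (all values identical) is assigned p = 0.5.
2. Benjamini–Hochberg adjustment is applied within each direction. Whether
   the original analysis pooled directions is unknowable from its
   description; per-direction adjustment is the symmetric choice and is
   documented here.
3. `z = Φ⁻¹(1−q)` with q clamped to `[1e−15, 1−1e−15]`, keeping z finite
   (±7.94 at the clamp) without materially altering any realistic q.
4. `Z_module = Σz/√k` over the module's k *tested* KOs. The printed formula
   in the source literature is typographically ambiguous between 1/k and
   1/√k; the cited reporter-feature method uses 1/√k, so `sqrt_k` is the
   default and `k` is selectable. Modules with no tested KO are reported
   untested rather than scored. Significance: `Z_module ≥ 1.6`.

**Calibration.** Under a global null with *unadjusted* q = p, each KO's z is
standard normal and `Z_module` is too, so the flag rate matches
P(Z ≥ 1.6) ≈ 0.055 — the acceptance suite verifies this within Monte-Carlo
tolerance (±0.03 over 2,400 module-direction draws). With BH adjustment the
null q-values concentrate near 1, z becomes strongly negative, and the
pipeline is *conservative* (flag rate ≈ 0); the suite asserts that bound
separately. Power is demonstrated at a strong planted effect (log-fold 4 on
the KOs of 5 of 20 modules, 15 vs 15 samples): ≥ 90 % of planted modules are
flagged in the planted direction over 50 replicates.

## Ecology

Shannon `H = −Σ p ln p` (natural log) and Simpson `1 − Σ p²` on per-sample
proportions; all-zero samples are an error. Bray–Curtis
`d = Σ|x−y|/Σ(x+y)` via scipy. PCoA applies Gower double-centering and a
symmetric eigendecomposition; coordinates are `eigenvector·√eigenvalue` for
positive eigenvalues; negative eigenvalues are reported unchanged (no
Lingoes/Cailliez correction) and explained-variance fractions are over the
positive-eigenvalue sum. PERMANOVA is single-factor (marginal per metadata
factor — region, host species, sex, altitude class — with no sequential
model, the order-invariant reading), uses Anderson's pseudo-F from squared
distances, R² = SS_between/SS_total, a seeded permutation stream and the
add-one p estimator `p = (1+hits)/(1+n_perm)` (resolution 1/(n_perm+1),
never 0; default 1,000 permutations). Continuous altitude is binned at
2,500 m into lowland/highland for the factor test — a stand-in, not a
reproduction of any particular encoding. Rarefaction averages the
cumulative union-species count over seeded random sample orderings.
The implementation is cross-checked in tests against scikit-bio's PCoA and
PERMANOVA on identical inputs.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
raw reads (no FASTQ, assembly graphs, or within-bin strain mixtures):

- **Genomes.** Substitution-only mutation keeps true ANI analytically
  `≈ 100(1−rate)`. Species ancestors derive from one root with per-branch
  rate `r = (3/4)(1−√(1−4d/3))` so expected pairwise ancestor divergence
  equals the between-species rate d exactly (back-mutation corrected). The
  first copy of a species is the unmutated ancestor; further copies mutate
  at the within-species rate. Defaults (1 % within, 10 % between, 100 kb,
  20 species × 3 copies) straddle the 95 % species boundary with wide
  margins: ancestor–copy ANI ≈ 99, copy–copy ≈ 98, between-species ≈ 89.5.
- **Bins.** Completeness/contamination uniform over configured ranges
  (defaults 55–100 % and 0–8 %, deliberately spanning the retention
  thresholds, truth-flagged); per-bin depth log-normal; G+C computed from
  sequence; planted mergeable pairs (same sample, same species, depths 5 %
  apart) truth-flagged.
- **Community.** 30 samples in 6 regions (region 1 is the high-altitude
  group). Log-normal abundances (σ = 1); per-species prevalence uniform on
  [0.3, 1] with the first 30 % of species fully prevalent (planted core) and
  the last species planted in exactly one sample; a planted compositional
  shift `exp(group_effect)` on the first fifth of species in region 1; rows
  normalised to 100. Coverage is a saturating transform `100(1−e^{−mass})`
  of abundance mass, bounded in [0, 100].
- **Functions.** Disjoint 5-KO modules; per genome-and-module integrity
  states drawn 2/1/0 with probabilities 0.5/0.25/0.25 and the KO set built
  to realise them; unannotated filler genes give a ~60 % annotation
  fraction; a planted log-fold `differential_effect` on the KOs of the first
  `n_differential_modules` modules in region-1 samples of the KO matrix.

Each stage draws from an independent substream fanned out from the single
global seed, so outputs are byte-identical under a fixed seed and stages are
regenerable in isolation. Because mutation is substitution-only and modules
are disjoint, passing tests demonstrate correctness of the *rules* under
clean planted signals — they do not demonstrate robustness to indels,
chimeric bins, overlapping module definitions, or compositional artefacts
beyond the renormalisation the generator itself induces (note that a strong
planted shift on some KOs necessarily depresses the relative abundance of
all others in that group; the enrichment tests account for this by checking
the planted direction explicitly).

## Problem sizes

The default end-to-end run (60 genomes of 100 kb, 30 samples, 150 KOs)
completes in well under a minute on one CPU; simulation-based test
campaigns use 40–200 replicates at these scales, chosen to keep Monte-Carlo
standard errors several times smaller than the asserted tolerances.

## Known limitations

- ANI is k-mer containment-based; it is validated against construction
  truth, not against alignment-based tools, and degrades for divergences
  beyond ~20 % where shared 16-mers vanish.
- Merged bins inherit seed completeness/contamination (no re-estimation).
- KEGG Boolean module logic is flattened; integrity codes for modules with
  alternative paths can differ from a stepwise evaluation.
- PERMANOVA is marginal single-factor; confounded factors are not
  partialled out.
- The KO abundance entering enrichment is relative abundance by contract;
  count- or coverage-weighted variants are not implemented.
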
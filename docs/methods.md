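# Methods

## Problem setting

Supragingival dental plaque is a dense, phylogenetically diverse biofilm.
Its metatranscriptome — RNA-Seq reads mapped to oral reference genomes
and counted per transcript — summarizes which community members are
metabolically active and what they are doing. A twin cohort (pairs of
monozygotic and dizygotic children, concordant or discordant for dental
caries) makes it possible to ask how much of the community's expression
profile is shared within families versus driven by caries status, while a
signed co-abundance analysis asks which taxa form coordinated or
antagonistic groups. This package implements that analysis as a reusable,
tested pipeline operating on a transcript × subject count matrix; it does
not perform read QC, rRNA filtering, alignment, or annotation — those
belong to upstream tools whose output is this pipeline's input.

## Normalization

Sequencing depth and library composition differ across subjects, so raw
counts are scaled by **median-of-ratios size factors**, implemented
directly from the definition: the reference pseudo-sample is the
per-transcript geometric mean across subjects; the factor for subject *j*
is the median over transcripts of `k_ij / geomean_i`. Transcripts with a
zero count in any subject are excluded from factor estimation (their log
geometric mean is undefined) but are still scaled. The even-length median
is the mean of the two central ratios. Factors are computed on
transcript-level counts, before taxon aggregation, mirroring the order
counts → scaling → analysis; both transcript- and taxon-level inputs are
accepted by the downstream stages for users who prefer the other order.
The variance-compressing transform is `log2(k/s + 1)`, which maps zeros
to zero and makes the ~6-decade abundance range comparable across taxa.
If no transcript is positive in every subject the estimator raises rather
than guessing.

## Taxon profiles and the core microbiota

Transcript counts are summed within species or genus (annotations are
required at the requested level; totals per subject are conserved
exactly). Relative abundances divide by per-subject totals. The
**functional core microbiota** is the set of taxa with at least
`min_count` raw counts in *every* subject; the default threshold is 10
counts, a conservative "reliably detected" presence level exposed as a
flag, since any fixed threshold on count data is somewhat arbitrary.
Cross-subject variability of scaled-log2 abundances is summarized per
taxon with quartiles (linear interpolation of the empirical CDF, numpy's
default, fixed for reproducibility), Tukey-fence outliers (beyond
1.5 × IQR outside the quartiles), and an extreme-variation flag (any
value beyond mean ± 2 SD, SD with the n − 1 denominator, computed on the
log2 scale).

## Twin-pair dendrogram linkage

Subjects are compared by 1 − Spearman ρ between their scaled-log2
species profiles (rank-based, hence robust to the heavy-tailed abundance
distribution; Euclidean distance is available) and clustered
agglomeratively with average linkage (UPGMA) via
`scipy.cluster.hierarchy`; complete and single linkage are options. Trees
are deterministic for a given input; merge ties, which have probability
zero on continuous profiles, resolve by scipy's internal order. The tree
is exported as Newick with merge-height differences as branch lengths.

A twin pair is **linked** when its two subjects are *sister leaves* (a
cherry): the strictest reading of "most similar to each other". A looser
mutual-nearest-neighbor definition is available behind
`linked_def="nearest"`. Linked counts and fractions are reported overall,
by zygosity, by concordance, and for the four zygosity × concordance
cells; a pair is concordant when both twins are caries-free or both
caries-experienced (active or inactive).

Significance is assessed by a **permutation null**: the dendrogram is
fixed (it does not depend on pair labels) and subjects are re-partitioned
into random pairs; the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` is used. For two pairs the
null linked fraction is exactly 1/3 (a balanced 4-leaf tree has two
cherries and the 6 pair slots across the 3 possible pairings hit them
twice), which the test suite verifies by enumeration.

## Signed co-abundance networks

Spearman ρ between taxa across subjects is computed as average ranks
followed by Pearson correlation of the rank vectors; constant taxa have
undefined correlation, are marked NaN, and can never form edges. An edge
is retained when |ρ| ≥ 0.5 and its two-sided p-value (t approximation for
the rank correlation) passes Benjamini–Hochberg FDR at q = 0.05; both
knobs are exposed, and FDR control can be disabled. The retained graph is
signed (sign ρ) and weighted (|ρ|). **Complexes** are its connected
components through edges of either sign — mixed-sign complexes are
biologically expected (a member can be anti-correlated with the rest) —
reported with positive/negative edge counts. The per-node sign profile
flags taxa whose retained edges are ≥ 80% negative as predominantly
anti-correlated, the signature of an antagonist whose activity runs
against its neighbors. Correlations are computed on scaled-log2
abundances; ranks make the scaling largely immaterial except at zeros,
where the +1 offset stabilizes ties. Genus level is the default for
network output, species level for linkage; both are supported everywhere.

Compositional effects are a known caveat: relative abundances must sum to
one, so a strongly fluctuating group induces weak opposite-signed
correlations in bystander taxa. The default threshold plus FDR filter
suppresses most of these, but no SparCC-style compositional correction is
applied.

## Functional role categories

Each transcript carries a function label mapped through a three-level
hierarchy (function → subsystem → category), supplied as a three-column
TSV. A default hierarchy ships with the package covering the dominant
plaque-biofilm functions: protein translation, RNA metabolism,
carbohydrate utilization (glycolysis, mono- and disaccharide
utilization), stress response with an oxidative-stress subsystem,
resistance to antibiotics and toxic compounds, membrane transport, and an
uncharacterized bucket. Functions absent from the hierarchy fall into an
explicit `unassigned` bucket so proportions sum to one at every level; a
flag switches the denominator to assigned counts only. A function listed
under several subsystems keeps its first listing (logged), which keeps
the level-consistency law exact: category counts equal the sum of their
subsystems' counts, which equal the sum of their functions'. Nested
shares (subgroup/group and subgroup/total) and per-category
across-subject min/max/range/CV are provided; the CV summary is what
shows functional composition to be more conserved across subjects than
taxonomic composition.

## Synthetic twin cohorts

The generator emulates the statistical structure the analysis assumes,
with exact ground truth returned alongside the counts. Per species *s*
and subject *j* in pair *p*, in natural-log space:

```
eta[s,j] = ln(10)·b[s] + u[p,s] + v[p,s]·1[MZ] + Σ_c L[c,s]·f[c,j] + e[s,j]
```

- `b[s] ~ U(0, 6)` — baseline log10 abundance, spanning six decades;
- `u[p,s] ~ N(0, pair_effect_sd)` — shared within a twin pair
  (environment and/or vertical inheritance), default SD 1.0;
- `v[p,s] ~ N(0, mz_extra_effect_sd)` — additional monozygotic-shared
  component (genetic), default SD 0.5;
- `f[c,j] ~ N(0, factor_sd)` — latent factor of planted complex *c* with
  signed loadings `L`; the expected correlation sign between two members
  is the sign of the product of their loadings;
- `e[s,j] ~ N(0, subject_noise_sd)` — individual noise, default SD 0.5.

Expected relative abundance is the per-subject softmax of `eta`. Subject
depth is lognormal around `depth_mean` (default 2 × 10⁶ mapped reads,
log-SD 0.4, matching the rough spread of per-subject mapped read counts
in cohorts of this kind). Within a species, transcripts receive fixed
lognormal weights, and observed counts are negative binomial around
depth × abundance × weight with dispersion `depth_dispersion`
(default 0.05; Poisson is the dispersion → 0 limit). One root seed is
split into independent substreams per stage (cohort, baselines, pair
effects, factors, noise, depth, observation, roles), so identical
configurations reproduce byte-identical outputs.

The default cohort is 19 pairs (6 MZ / 13 DZ) with a 4/6/9 split of
concordant caries-free / concordant caries-experienced / discordant
pairs; the discordant quota is split across zygosities proportionally
(3 MZ / 6 DZ). The relative magnitudes of the pair, MZ and noise scales
are free parameters — the relative weight of genetics versus environment
is exactly what such a cohort is too small to pin down — and the defaults
were chosen once to give a realistic but not degenerate linkage signal.
Species ids carry one of 27 oral genus names as a prefix, so genus
aggregation needs no taxonomy file. Default planted complexes reproduce
the qualitative motifs seen in plaque co-abundance analysis: an
all-positive group, a mixed-sign group, an anti-correlated pair, and a
group with a single all-negative antagonist.

What the generator does **not** emulate: caries-associated differential
expression (statuses are labels only), strain-level structure, rRNA
carry-over, mapping artifacts, or compositional zero-inflation beyond
what the NB layer produces. Passing recovery tests therefore shows the
pipeline recovers planted twin and network structure under the assumed
model, not that real plaque data satisfies that model.

## Numerical choices and degenerate inputs

- Even-length medians: mean of the two central values.
- Quartiles: linear interpolation (numpy default), fixed and documented.
- Distances are symmetrized exactly ((D + Dᵀ)/2) and clipped at 0 before
  clustering; correlation distances live in [0, 2].
- Constant profiles: a constant *subject* profile is an error for the
  correlation metric (ρ undefined); a constant *taxon* gets NaN
  correlations and no edges.
- All-zero subject columns are an error for relative abundance; missing
  taxon annotations are an error listing the offending transcripts;
  twin pairs without exactly two members are a metadata error.
- The permutation p-value uses the add-one estimator and is therefore
  never exactly zero.

## Bundled cohort table

A 38-subject sequencing summary (caries status, decayed/filled surfaces,
zygosity, filtered and mapped read counts, printed mapping percentage)
ships as a TSV resource for the bookkeeping utilities: recomputing
mapping rates from the raw read counts and stratifying reported per-pair
linkage flags. One row's printed percentage (subject 2011, 45.00) is
internally inconsistent with its own read counts (45.08); the pipeline
reports the recomputed value. The per-pair linked flags for the
concordant strata are not individually identified in the source summary;
`study_linkage_flags` reconstructs a deterministic assignment consistent
with all stratum totals, to which the stratified fractions are invariant.

## Problem sizes used in tests

The test suite and acceptance script run on reduced-load cohorts (full
19-pair structure, 30–60 species, 3–5 transcripts per species) chosen so
recovery statistics are stable across seeds: 50 replicates for
twin-effect recovery and null calibration, 20 for complex recovery
(factor SD 2.5, the "strong loading" condition), 200 random matrices for
the normalization oracle. The full default cohort (60 species × 20
transcripts) is used for the pipeline and worked examples.

## Known limitations

- Cherry-based linkage is conservative: a pair separated by one rogue
  merge counts as unlinked even if the twins are each other's nearest
  neighbors (the `nearest` definition relaxes this).
- No compositional correction in the network stage (see above).
- The permutation null re-pairs subjects uniformly, which assumes
  exchangeability of subjects under the null — appropriate for testing
  "no family structure at all", not for partial nulls.
- Heritability (ACE) decomposition is out of scope; the MZ/DZ contrast
  is descriptive.
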
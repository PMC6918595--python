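# Methods

## Quantitation model

Isobaric labeling reads the relative abundance of multiplexed samples from
reporter-ion intensities released within a single MS/MS spectrum.  Because
all channels of one spectrum share the same peptide, the same ionization
efficiency and the same injection, the within-spectrum channel ratio cancels
peptide- and run-level nuisance factors; all inference in this package is
therefore built on within-spectrum ratios, never on raw intensities.

For a contrast (case group vs control group) with one channel per group per
pool:

* peptide ratio: `r = I_case / I_control`, computed only for *unique*
  peptides (sequence maps to exactly one accession across the whole
  experiment, all pools jointly) with both channels present and positive;
* pool-level protein fold change: median of the protein's unique-peptide
  ratios in that pool (midpoint interpolation for even counts);
* combined fold change: geometric mean `(∏_r FC_r)^(1/R)` over the R pools,
  defined only for proteins quantified in every pool — mirroring the
  restriction of the comparison to the commonly quantified protein set;
* significance: two-tailed one-sample t-test of the protein's log2 ratios,
  pooled across pools, against 0.

The t-test unit is the main interpretive choice.  With a single channel per
group per pool, a two-sample test "between groups" on raw intensities has no
operable replicate structure; the within-spectrum log-ratio, in contrast, is
a paired measurement with the protein's peptides as replicates.  We test the
mean log2 ratio against 0.  Degenerate rules: fewer than 2 measurements →
p undefined (protein ineligible for DEP calling, reported separately, never
dropped); zero sample variance with zero mean → p = 1; zero variance with
non-zero mean → p = 0 (logged).  No multiple-testing correction is applied to
protein p-values; the DEP thresholds operate on raw p.

Medians make the rollup robust to a single aberrant peptide; the geometric
mean is the natural average of ratios (symmetric in log space, so a 2.0 and a
0.5 replicate average to 1.0 exactly).  The product-form implementation
`(∏ FC_r)^(1/R)` keeps simple rational cases exact in floating point.

## DEP calling

Increased: FC ≥ 1.3 and p < 0.05.  Decreased: FC ≤ 0.70 and p < 0.05.
Fold-change boundaries are inclusive (thresholds read as attainable cutoffs),
the p boundary strict.  The thresholds are deliberately asymmetric —
0.70 < 1/1.3 ≈ 0.769 — so the down-call is stricter than the reciprocal of
the up-call, and the caller must not symmetrize; this is asserted by test.
Identification filters are strict in the other direction: ion score > 20,
q-value < 0.01.

## Enrichment

Each contrast's DEP set is tested per term against the background of proteins
quantified in all pools (not the full search database).  The 2×2 table fixes
all margins; the two-tailed p uses the probability-mass rule — the sum of
hypergeometric probabilities of all tables no more probable than the observed
one.  This is the dominant convention for the two-tailed Fisher exact test
but not the only one (doubling the one-tailed p differs), so it is stated
explicitly.  The implementation compares integer binomial-coefficient
weights, so tie decisions (which tables count as "equally probable") are
exact rather than subject to floating-point rounding; the final p is a
rational number converted to float.  Proteins missing from the annotation map
count in the without-term cells, preserving the margins.  Benjamini–Hochberg
adjusted p-values are reported for transparency, but top-k selection (15 for
biological process, 5 for pathways) uses raw p < 0.05 with odds ratio > 1,
sorted by p, then by descending overlap count, then term id — a deterministic
total order.  Annotations are used as given; no propagation up the GO graph
is performed, which is the main comparability caveat against GO-aware tools.

## Overlap analysis

Venn regions over 2–4 named DEP sets are exclusive intersections keyed by
sorted name tuples (deterministic output).  DEPs shared between two contrasts
are labeled `both_increased`, `both_decreased`, or `reverse`; the three
labels partition the shared set, and the labeling is symmetric in argument
order.

## Orthogonal validation

* **Densitometry**: per lane, band / actin (same lane) removes loading
  differences; all values for a protein are then divided by the mean of the
  reference group (first group in table order; recorded in the output), so
  the reference mean is exactly 1.  One-way ANOVA across groups per protein;
  stars `*` p < 0.05, `**` p < 0.01.  If every group has zero within-group
  variance the F statistic is undefined: we report p = 0 when the group
  means differ (perfect separation) and p = 1 when all values are identical.
* **WB vs reporter-ion correlation**: Pearson correlation on raw fold
  changes over matched (protein, contrast) pairs, missing pairs dropped,
  n ≥ 3 required; a log2 option exists for sensitivity analysis.
* **Fetal loss**: `100 · (mean_early − mean_late) / mean_early` on per-sow
  viable-fetus counts, with group means and population SDs (divisor n, the
  convention that reproduces summary values like 0.47 for counts {16,16,17}).
  The bundled fixture realizes the recorded group summaries as integer
  counts: MSD49 {16,16,17}, MSD72 {14,14,15}, DUD49 {10,11,12}, DUD72
  {8,9,9}; it yields a 21.2% Duroc loss (DUD49→DUD72) and a 12.2% Meishan
  loss (MSD49→MSD72).

## Synthetic data generator

The generator emulates what the downstream analysis assumes about a
two-pool, four-group reporter-ion experiment:

* protein baselines: log-normal (natural-log mean 13.8 ≈ 10^6 median
  intensity, sd 1.0 — typical Orbitrap reporter scales);
* per-protein group multipliers: 1.0 everywhere except spiked proteins,
  which get one fold change in one randomly chosen group.  Default spike
  fold changes are the discrete set {0.5, 0.67, 1.5, 2.0} (two comfortably
  callable effects and two sitting near the 0.70/1.3 boundaries); a
  continuous-range mode (up ≥ 1.5–2.0, down 0.5–0.70) is available;
* peptides: 3–6 unique peptides per protein plus shared sequences (10% of
  all sequences by default) carried by two parents, whose intensity is the
  *sum* of the parents' contributions;
* per-peptide ionization factors: log-normal (sd 0.5 in log space),
  constant across channels and pools so ratios cancel them;
* reporter noise: multiplicative log-normal per peptide × pool × channel
  with `sigma = sqrt(ln(1 + cv²))`; at cv = 0 the noise factor is omitted,
  so fold changes propagate exactly and noise-free tests can assert
  equality;
* annotations: 30 terms, 20% planted.  Each planted term targets one
  channel group and draws ~80% of its 8–13 members from the proteins spiked
  in that group; planting per group (rather than across all spiked proteins)
  is what makes a planted term's members co-occur in one contrast's DEP set,
  the structure a per-contrast enrichment test can detect.  Background terms
  annotate random proteins across all four namespaces, and every protein
  carries at least one term;
* densitometry: three lanes per group; band and actin share a per-lane
  loading factor (cancelling under normalization); noise-free mode is exact;
* fetal counts: the fixed integer fixture above (the study records only
  group summaries; the integers reproduce them).

What the generator does *not* model: isotope-impurity cross-talk between
reporter channels, missed cleavages and modification variants, missing
reporter values, batch effects between pools, and compositional/ratio
compression effects from co-isolated precursors.  Passing recovery tests
therefore demonstrates correctness of the statistical pipeline under its own
assumptions, not robustness to those instrument-level artifacts.

## Benchmark conditions and what the tests show

The recovery benchmark uses 200 proteins, 20% spiked, cv 0.05, two pools,
and 20 consecutive seeds (≈1600 spiked protein-contrast pairs and ≈14,000
null pairs) — sizes chosen so that the full benchmark completes in well under
a minute per stage on one core while keeping Monte-Carlo error on a 0.95
power bound below a percentage point.  Under these conditions:

* power ≥ 0.95 on spiked pairs (observed ≈ 0.98; the misses are almost all
  true fold changes of 0.67, whose estimate must land below the 0.70 cutoff
  only 4.3% away — an inherent boundary effect, not an estimator defect);
* false-positive rate ≤ 0.05 on null pairs (observed ≈ 0 — a null must
  *jointly* clear the fold-change and p thresholds);
* fold-change accuracy is asserted as ≥ 95% of spiked estimates within
  ±10% of truth.  A strict "all estimates within 10%" cannot hold at these
  conditions: a 3-peptide protein's combined FC has ≈3–4% log-sd, so over
  1600 draws a handful of >10% excursions is expected; the 95% fraction is
  the coherent aggregate statement at the same confidence level as the
  power bound (observed ≈ 1.0).

Numerical conventions collected in one place: even-count medians use
midpoint interpolation; geometric means use the product-root form; Fisher
p-values are exact rationals; all output TSVs use `%.6g` floats, tab
separators and '.' decimals; manifests contain no timestamps and only input
*basenames*, so identical inputs in different directories reproduce result
bundles byte for byte.

## Known limitations

* Protein accessions are taken verbatim; no protein-group inference or
  isoform collapsing.
* Uniqueness is sequence-level; modified forms of a sequence are not
  distinguished.
* One channel per group per pool means biological replication enters only
  through the pooled samples; the t-test's replicates are peptides, so its
  p-values describe measurement consistency, not population-level biological
  variance.
* Enrichment treats annotations as flat labels (no ontology structure).
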
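# Methods

This note documents the models and procedures implemented in `cortaxis`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Pseudobulk aggregation and filtering

Within one cell subclass, counts are summed over cells per
(region, donor) pair; each donor is treated as a biological replicate of
its region. Pairs with zero cells produce no column (they are absent,
not zero), so downstream sample counts reflect the actual design.

Lowly expressed features are removed with a CPM rule: a feature is kept
iff its CPM exceeds `min_count / median(library sizes) × 10⁶` in at
least *n_min* samples, where *n_min* is the size of the smallest region
group, **and** its total count is ≥ `min_total_count`. Defaults are
10/15 for genes and 5/15 for peaks (peaks get the laxer cutoff because
accessibility matrices are sparser). This re-implements the documented
behavior of the standard `filterByExpr`-style filter rather than binding
to an external implementation, so the semantics are fixed and testable;
the filter is provably monotone in `min_total_count`.

Down-sampling for cross-subclass comparability keeps at most
*n* (default 1,000) cells per region, uniformly without replacement and
deterministically per seed; when fewer are available all cells are kept
and the shortfall is reported rather than failing.

Abundance for all correlation screens is log2(CPM + 1) on pseudobulk
samples, stamped into every results file. No TMM or size-factor scaling
is applied: CPM already removes library-size differences, which is also
why the simulator's shared per-donor offsets cancel (see below).

## Axis-correlation screen

Features are correlated against the integer order indices of their
samples' regions along a configured axis. Conventions:

- **Coefficient.** Pearson on log2 CPM is the default; Spearman (ranks,
  then the same machinery) is available. Both carry two-sided p-values
  from the t distribution with n−2 df. The method used is stamped into
  every output row.
- **Sample mode.** `per_sample` (default): every (region, donor) sample
  is one observation, so n = regions × donors. `region_mean`: values are
  first averaged within region (n = number of regions). Per-sample is
  the default because with nine regions alone the BH-adjusted p < 0.01
  bar is rarely attainable.
- **FDR scope.** BH adjustment runs within one
  (subclass, axis, modality) screen over the post-filtering background —
  the filtered feature set is the denominator of the multiple-testing
  correction, not the pre-filter universe.
- **Thresholds.** Genes: |r| > 0.7 and q < 0.01. Peaks: |r| > 0.5 and
  q < 0.05. Both are parameters, not constants.
- **Degenerate inputs.** Zero-variance features have undefined
  correlation; they are excluded and counted, never assigned r = 0.
- **Axis orderings.** The R-C and T-S region orders ship as editable
  configuration (`examples/config.yaml`); nothing downstream hard-codes
  a biological ordering.

`adjust_bh` implements the step-up definition directly
(q₍ᵢ₎ = min over j ≥ i of m·p₍ⱼ₎/j, clipped at 1) and is tested against
an independent literal implementation and statsmodels on random vectors.

## Spatial laminar and neighborhood analysis

- **Depth.** For each cell, depth = d_p / (d_p + d_w), the Euclidean
  distances to the nearest points of the pial and white-matter landmark
  polylines (proper point-to-segment distance, not nearest vertex),
  clipped to [0, 1]. Coincident boundaries are a validation error.
- **Density.** Gaussian KDE (Scott's rule by default, overridable)
  evaluated at 1,000 equally spaced depth units, then renormalized so
  the profile integrates to 1 on the bounded grid. Renormalization was
  chosen over boundary reflection as the simplest defensible treatment
  of the [0, 1] truncation; profiles from < 2 distinct depths are
  flagged undefined and excluded from correlations.
- **Neighborhoods.** Up to 100 query cells per subclass and region
  (all of them when fewer exist), sampled without replacement by seed.
  Neighbors are all other cells within a **closed** 200-µm ball — the
  boundary cell counts — and the query cell is excluded from its own
  neighborhood, since self-inclusion would bias every profile toward
  the query subclass. Queries with zero neighbors are dropped from the
  average. No edge correction is applied near tissue borders; profiles
  record the query count so sparse regions can be filtered downstream.
- **Composition normalization.** Raw neighbor proportions divided by the
  region's overall subclass fractions give enrichment ratios (1 = the
  neighborhood matches the regional mix).
- **Cross-region comparison.** The per-region feature vector for density
  is the concatenated 1,000-unit KDE profiles of its subclasses; for
  neighborhoods, the normalized composition vector. Region × region
  Pearson matrices from the four modalities (density, neighborhood,
  expression, accessibility) are compared through the Pearson
  correlation of their upper triangles — a scalar "modality agreement
  index" defined by this package as a quantification of how similar two
  modalities' regional similarity structures are. It is symmetric and
  reported for all six modality pairs.

## eRegulon concordance

Enhancer peaks from TF → enhancer → target-gene tables are classified
positive/negative/null with the peak screen thresholds (the only peak
criteria defined anywhere in the workflow). Target-gene correlation
distributions are **per enhancer–gene link**: a gene targeted by two
same-class enhancers contributes twice, since the question is whether
enhancers of a class predict their targets' trends. Per-TF summaries use
**distinct** peaks (activity) and **distinct** genes (target
expression) — a peak listed under two target genes counts once.

The positive- vs negative-class comparison uses a two-sided
Mann-Whitney U test with the direction reported separately. The U
distribution is computed exactly by the classic counting recursion when
n₁ + n₂ ≤ 12 and there are no ties (verified against full enumeration of
all rank assignments); larger or tied samples use the normal
approximation with tie and continuity corrections (verified against
scipy's asymptotic implementation, which serves as an independent
cross-check, not the implementation).

## Regional signatures

Z-scores standardize each feature's donor-averaged regional abundance
across regions using the **sample** SD (n−1); the convention is recorded
in output metadata. Exactly constant rows (detected by exact range, so
floating-point rounding of the mean cannot leak huge z-scores) become
zeros and are flagged. Donor-averaged region means were chosen over
per-sample values so the z-profile reflects regional identity rather
than replicate noise.

Receptor-family membership ships as an editable mapping (YAML/config);
a family "switches" when it has both a positive- and a negative-class
subunit on the screened axis. The detector is monotone: adding subunits
never un-switches a family.

## Synthetic-data generator

Counts: per cell, feature *g* in a (subclass, region o, donor d) group is

    NB(mean = L · 2^(b_g + s_g·β·(o − ō) + u_d),  variance = µ + φµ²)

with baseline b_g ~ Normal(−1, 1) on log2 (median ≈ 0.5 counts/cell, a
typical snRNA-seq depth at ~2,000 genes; peaks reuse the machinery with
L scaled 5× down to mimic sparser accessibility), trend sign
s_g ∈ {+1, −1, 0} for a configured fraction of features (split evenly,
ties to +), slope β = 0.3 log2 per region step by default, trends
centered on the axis midpoint so a trending gene's average abundance
matches its baseline, dispersion φ = 0.1, and donor offsets
u_d ~ Normal(0, 0.2) shared across features within a donor. The shared
donor offset scales the whole library, so CPM normalization removes it —
replicate structure without feature-specific confounding. Defaults
emulate the nine-region, six-donor survey design.

Spatial maps place Poisson numbers of cells per (subclass, region) with
uniform x and truncated-normal depth (per-subclass mean/SD, default SD
0.06 ≈ one cortical layer) between flat pial and white-matter landmark
polylines 2,000 µm apart. eRegulon simulations assign half the TFs +
activity and half −, propagating the sign to enhancer accessibility and
target-gene expression so concordance holds by construction, with
untrended background features added so FDR adjustment runs over a
realistic background.

What the generator does **not** emulate: doublets, ambient RNA,
batch/chemistry effects, feature–feature correlation beyond the shared
donor offset, subclass-specific library sizes, curved laminar geometry,
cell-size exclusion effects in point patterns, or peak–gene physical
linkage. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated generative model, not
robustness to every artifact of real tissue data.

## Verification experiments and problem sizes

The recovery benchmarks (`cortaxis.recovery`, re-run by
`scripts/acceptance.py` and the end-to-end tests) use:

- Axis screen: 9 regions × 5 donors, 2,000 genes with 100 trending at
  |β| = 0.3, φ = 0.1, 300 cells per group; sensitivity and null
  false-positive rate averaged over 5 seeds.
- Null FDR: β = 0, 1,000 genes, 9 regions × 4 donors × 100 cells per
  group, 20 seeds — a size chosen to make 20 replicates a desk-scale
  computation while keeping 36 pseudobulk samples.
- Spatial: three subclasses at depth means 0.2/0.5/0.8 (SD 0.05), ~600
  cells each; one region pair with identical and one with disjoint
  laminar assignments.
- GRN: 2+2 TFs × 3 enhancers × 2 genes, β = 0.3, 5 donors, 200
  background features, 20 seeds.
- Determinism: the full pipeline run twice at one seed; byte-identical
  outputs are required, which constrains every writer to sorted keys and
  fixed float formatting (17 significant digits, round-trip parsing).

## Known limitations

- The screen assumes a *linear-in-order-index* association on the log2
  scale; non-monotone regional patterns (e.g. a single enriched region)
  are the province of one-vs-rest differential testing, which this
  package deliberately consumes rather than fits.
- Per-sample mode treats donors as exchangeable replicates; donor
  pseudo-replication inflates n relative to a mixed model. The
  region-mean mode is the conservative alternative.
- KDE argmax is a coarse laminar summary; bimodal subclasses are better
  read from the full profile.
- Exact MWU enumeration is limited to small tie-free samples; with the
  heavily tied correlations of large screens the asymptotic path is
  effectively always taken.
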
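# Methods

## Experimental design assumed

The pipeline models a SILAC ChEP time course of mitotic entry: heavy-labeled
cells sampled at a G2 arrest point and at 0, 5, 10, 15, 20 and 25 min after
release, each mixed with a common light-labeled G2/M reference, in two
biological replicates (14 samples). Ratios are stored time-point over
reference, so depletion from chromatin is negative in log2. Internally the
G2 arrest sample is placed at t = −15 min — release kinetics put the arrest
point roughly that far before the t = 0 sample — but only the ordering of
time points matters anywhere downstream.

## Normalization

Log2 ratios are anchored per sample on the flagged core histones: the mean
of the non-missing histone log2 ratios is subtracted from every protein in
that sample. This removes sample-to-sample differences in heavy/light
mixing and chromatin yield, under the assumption that core histones are
quantitatively retained on chromatin throughout mitotic entry. When some
histone cells are missing, the anchor is the mean over the observed
histones (the minimal-assumption choice); a sample with no quantified
histone is an error, not a silent fallback. The transform is idempotent:
already-log2 input is only re-anchored.

## Detection filter

A protein is discarded iff it is detected in `floor(f · n_samples)` or
fewer samples, with f = 0.5 by default — so on 14 samples, 7-of-14 is
discarded and 8-of-14 retained (the inclusive "half or less" boundary).
The complete-case subset (no missing values at all) is the input to PCA,
t-SNE and clustering. Missing values are never imputed: missingness in
this kind of data is intensity-dependent, and imputation would fabricate
kinetics for low-abundance proteins.

Note the parameter's direction: raising `max_missing_fraction` raises the
discard cutoff and therefore shrinks the retained set; monotonicity is
tested in that direction.

## k-means

`kmeans_profiles` implements the Hartigan–Wong transfer algorithm: after a
random-rows initialization and nearest-center assignment, single points are
moved to the cluster minimizing the exact size-corrected cost change
(n/(n+1)·d² to join vs n/(n−1)·d² to leave), with incremental centroid
updates, until a full pass makes no move. The best of `n_restarts` runs by
within-cluster SS is kept. No installed library provides Hartigan–Wong, so
it is implemented here; scikit-learn's Lloyd k-means with many restarts
serves as an independent oracle in the tests. Cluster numbers are assigned
by first appearance in input order. An empty cluster during initialization
is repaired by donating a random point; degenerate all-identical input with
k ≥ 2 is an error.

`variance_explained_curve` evaluates between-SS/total-SS over a k range.
Each k gets the random restarts plus one warm start built from the k−1
solution by splitting off the worst-fitting point, which guarantees the
curve is non-decreasing in k (a pure restart scheme can violate this by
chance).

Profiles are clustered on the full 14-dimensional concatenated replicate
vectors without z-scoring: after histone anchoring all samples share a
scale, and standardizing would inflate the invariant core's noise.

## Hierarchical clustering and tree cuts

UPGMA (unweighted average linkage) over pairwise Euclidean distances, via
`scipy.cluster.hierarchy.linkage(method="average")`; a brute-force O(n³)
re-averaging agglomerator is kept in the test suite as the oracle. A cut at
height h joins exactly the merges with height ≤ h (inclusive boundary,
covered by a test). Cuts are nested and cluster counts are non-increasing
in h. Clusters are named `X_/N` — cluster X from the cut yielding N
clusters — so identities at different granularities stay distinguishable.
Default cut heights are 1.7 / 1.0 / 0.6 (coarse / medium / fine). The tree
is exported as Newick with branch lengths for external inspection.

## Trend classification

A cluster's trend is decided by its end-course level: the mean of its
median log2 ratios over the 15–25 min samples, where the time course has
plateaued. Defaults of ±0.58 log2 (1.5-fold) separate depleted /
accumulated / minor-change; the thresholds are configuration, since trend
classes are descriptive rather than inferential. Using the plateau rather
than the full course makes the call robust to transient excursions.

## Embedding

Exact t-SNE (no Barnes–Hut approximation) at perplexity 50, computed with
scikit-learn's `method="exact"`; feasibility requires n ≥ 3·perplexity + 1.
Initialization is deterministic PCA and the random seed is a required,
logged parameter: the map is reproducible in structure given a seed, but —
as with any t-SNE — not in orientation across seeds. Iteration count
defaults to 1000 and is configurable.

## GO enrichment

The universe is restricted to proteins that entered the cluster analysis
*and* carry GO annotations; annotations are closed under the true-path
rule (is_a and part_of) before testing. Each term with at least
`min_term_size` (default 5, the topGO nodeSize convention) annotated
universe proteins is tested with a one-sided Fisher's exact test
(hypergeometric upper tail). Two modes are first-class:

* `classic` (default): every term tested independently;
* `elim`: terms processed leaf-upward; once a term is significant at
  `elim_alpha`, its proteins are discounted from all ancestors' gene sets,
  so general terms are not called purely on the strength of a specific
  child. With `elim_alpha = 0` the mode reduces exactly to classic.

Benjamini–Hochberg q-values are attached per cluster × namespace family.
The multiple-testing correction and the choice between classic and elim
are configuration, never silently chosen.

GAF files are read with a small csv-based reader rather than Biopython's
GAF iterator because the loader must count and skip malformed lines and
exclude NOT-qualified rows explicitly; OBO files are read with obonet.

## iBAQ composition

Tryptic digestion follows the Keil rule (cleave after K/R, suppressed
before P; the proline rule is toggleable since in-silico digesters differ).
Observable peptides are those of 6–30 residues with 0 missed cleavages —
the original iBAQ convention; both bounds and the missed-cleavage count are
configurable. iBAQ = intensity / #observable peptides is proportional to
molar amount; per sample, normalized iBAQ gives copy-number fractions and
MW-weighted iBAQ gives mass fractions, each summing to 100%. Molecular
weight uses average (not monoisotopic) residue masses plus one water,
appropriate for bulk mass budgeting. Output is relative fractions rather
than absolute copies per cell: absolute scaling requires an external ruler
that is deliberately out of scope. Proteins with no observable peptide are
excluded from the fractions and reported.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* **Kinetic archetypes.** Six logistic-transition programs — immediate
  (onset 0 min), mid-prophase (~5 min) and post-NEBD (~10 min) depletion,
  an invariant core, early and late accumulation. Each curve is exactly 0
  at the G2 reference point, monotone after onset, and plateaus by 15–25
  min. Amplitudes (−2.5 to +1.5 log2) match the magnitude of chromatin
  exodus/accrual the design targets; logistic transitions reproduce
  plateau behavior without asserting a mechanism.
* **Noise.** Independent Normal(0, noise_sd) per cell; the default
  noise_sd = 0.2 log2 is a configurable, realistic replicate-noise guess
  (the underlying studies do not quantify it).
* **Abundance and dropout.** Latent per-protein intensity is log-normal
  (log10 mean 7.0, sd 0.75 — about three orders of magnitude). A cell is
  missing with probability logistic((midpoint − log10 intensity) ×
  steepness); defaults (5.6, 3.0) concentrate missingness in low-abundance
  proteins and put the complete-case share of retained proteins near 0.7,
  the regime a 14-sample ChEP experiment shows. This is
  missing-not-at-random by construction, which is why downstream stages
  refuse to impute.
* **Histones.** Exactly four flagged histone proteins drawn from the
  invariant archetype at 100× median abundance, so the anchor is always
  quantified.
* **GO fixture.** A root plus n random-parent terms (acyclic by
  construction); one planted term annotates one archetype's proteins at
  `enrichment_factor` × the background rate. Every protein is annotated to
  the root so universe restriction is well-defined.
* **Sequences.** Random 20-letter sequences with controlled combined K/R
  frequency (default 0.1), which sets the expected tryptic peptide count.

What the generator does **not** emulate: peptide-level evidence, ratio
compression, shared/razor peptides, correlated replicate error, batch
structure, or real GO DAG shape. Passing tests therefore demonstrate the
correctness and calibration of the analysis logic under the assumed
generative model, not performance on any real dataset.

## Problem sizes and numerical choices

Default simulated runs use 100 proteins per archetype (604 with histones);
tests and the worked example use 25–100 per archetype. The acceptance
script runs the full pipeline at the 604-protein default with 20 k-means
restarts, a k = 1…8 variance curve, and 20 planted-GO replicates. Histone
anchoring is asserted to 1e-9; UPGMA oracle agreement to 1e-9; Fisher
p-values to 1e-10 against exact integer tail sums; composition sums to
1e-6. Hartigan–Wong transfers use a 1e-12 improvement margin to avoid
oscillating on ties, and cluster renumbering is deterministic (first
appearance in input order), making whole runs byte-reproducible from one
integer seed expanded into per-stage seeds via `numpy.random.SeedSequence`.

## Known limitations

* Headline numbers of any specific real dataset (protein counts, cluster
  counts at a given h, composition percentages) depend on that dataset and
  its search pipeline; the package reproduces the *procedure* and verifies
  it on planted truth.
* The elim implementation discounts child proteins from ancestors only
  (the topGO "elim" idea); the "weight01" hybrid is out of scope.
* t-SNE layouts are seed-reproducible but not orientation-stable across
  seeds; cluster overlays, not coordinates, are the interpretable output.
* The k-means empty-cluster repair (donating a random point at
  initialization) is one of several defensible conventions; results at the
  study's scale are insensitive to it because restarts dominate.
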
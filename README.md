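# chepflow

Analysis pipeline for **time-resolved chromatin proteomics** of mitotic
entry, built around ChEP (chromatin enrichment for proteomics) with SILAC
quantification. Cells released from a G2 arrest are sampled at 0, 5, 10,
15, 20 and 25 min, each mixed with a common light-labeled G2/M reference,
in two replicates — 14 samples of heavy/light ratios per protein. The
package turns such protein-group tables into kinetic-behavior maps: which
proteins leave chromatin in which wave, which accumulate, and how the
absolute composition of chromatin changes as the nucleus disassembles.

It is written for proteomics/cell-biology groups running synchronized
time-course ChEP (or similar chromatin-fractionation) experiments, and
ships a synthetic-data generator with planted ground truth so every stage
is testable end to end without raw mass-spectrometry data.

## Method

For protein *i* in sample *s* with heavy/light ratio *r<sub>is</sub>*:

1. **Histone-anchored normalization.** Values are log2-transformed and,
   per sample, shifted so the mean log2 ratio of the four core histones is
   exactly 0: *x<sub>is</sub>* = log2 *r<sub>is</sub>* − mean<sub>h∈H</sub>
   log2 *r<sub>hs</sub>*. Histones are retained quantitatively on chromatin,
   so they serve as an internal standard for chromatin yield.
2. **Detection filtering.** Proteins detected in half or less of the 14
   samples are discarded; the complete-case subset (no missing values)
   feeds PCA, t-SNE and clustering. Missing values are never imputed.
3. **Kinetic clustering.** k-means (Hartigan–Wong, best of *n* restarts)
   summarized by variance explained = SS<sub>between</sub>/SS<sub>total</sub>;
   and UPGMA (average linkage, Euclidean distance) with the tree cut at
   heights h = 1.7 / 1.0 / 0.6 for coarse → fine granularities. Cluster
   X of a cut yielding N clusters is named `X_/N`.
4. **Trend calls.** Each cluster's median profile is classified as
   depleted / accumulated / minor-change by its end-course (15–25 min)
   level against ±0.58 log2 (1.5-fold) thresholds.
5. **Embedding.** Exact t-SNE (theta = 0, perplexity 50, PCA init).
6. **GO enrichment.** One-sided Fisher's exact test per term over a
   *restricted universe* — only clustered, GO-annotated proteins — after
   true-path propagation; optional topGO-style `elim` that discounts the
   proteins of significant child terms from their ancestors; BH q-values.
7. **Composition.** iBAQ = intensity / #observable tryptic peptides
   (Keil rule, 6–30 aa); normalizing iBAQ per sample gives copy-number
   fractions, weighting by average molecular mass gives mass fractions;
   sums over clusters give the chromatin mass budget per time point.

## Worked example

```python
import chepflow as cf

config = cf.PipelineConfig(
    outdir="demo_run", seed=7,
    simulation=cf.SimulationConfig(n_proteins_per_archetype=60, seed=11),
)
manifest = cf.run(config)
print(open("demo_run/summary.txt").read())
```

```
chepflow run summary
====================

proteins: 364 input, 350 retained, 255 complete cases
cut_h0.6: 229 clusters (204 singletons)
cut_h1.0: 60 clusters (29 singletons)
cut_h1.7: 6 clusters (0 singletons)
kmeans_k6: variance explained 0.976
```

364 simulated proteins (6 kinetic archetypes × 60, plus 4 core histones)
pass through the filter leaving 255 complete cases; the coarse cut
(h = 1.7) recovers exactly the 6 planted archetypes, and k = 6 k-means
explains 97.6% of the profile variance. `demo_run/` also contains the
per-protein cluster assignments at every granularity, cluster median
profiles and trend calls (e.g. cluster `1_/6`, end-course −2.5 log2 →
*depleted*), the t-SNE map, GO enrichment table and iBAQ composition,
plus a `manifest.json` with every parameter and derived seed.

The same pipeline runs from the shell:

```bash
chepflow simulate --outdir sim --seed 2        # write a synthetic dataset
chepflow run --config pipeline.yaml            # full analysis from YAML
```

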
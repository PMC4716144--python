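# keystonekit

Tools for discovering **keystone (hub) genes** — transcripts whose products
coordinate an unusually large number of otherwise-separate signaling
pathways — from bulk transcriptomic data, gene–literature association, and
pancreatic-islet histology. The package is aimed at researchers analysing
small-*n* expression studies (e.g. knockout-vs-wild-type bead arrays at
n = 3 per group) who want the full chain from differential calls to
cross-pathway hub selection, plus the supporting text-mining and islet
morphometry, as reusable, tested code.

## The pipeline

1. **Differential expression (z-ratio).** Per-array log₁₀ intensities are
   z-scored across genes; for a contrast (a, b) each gene gets

   z-ratio_g = ( z̄_g,a − z̄_g,b ) / SD_genes( z̄·,a − z̄·,b ),

   the between-group difference standardised by the dispersion of those
   differences over all genes. Genes pass with |z-ratio| ≥ 1.50
   (inclusive), are refined by Benjamini–Hochberg FDR q < 0.05 over the
   filtered candidates, and gated by one-way ANOVA p < 0.05 across all
   condition groups.
2. **Polarity-aware Venn partitioning.** Signed per-condition gene lists
   are decomposed into exact Venn sectors; a gene present in ≥2 lists with
   opposite regulation signs is *contra-regulated*. Per-list uniqueness
   percentages and "common to at least k" cores are reported.
3. **Over-representation with hybrid scores.** A pathway with overlap k,
   size K, query size n and universe N gets the exact hypergeometric tail
   p = P(X ≥ k), the enrichment ratio R = k/(nK/N), and the single index
   **hybrid = (−log₁₀ p) · R**; pathways are admitted only with k ≥ 2 and
   p ≤ 0.05.
4. **Latent semantic indexing (LSI).** One document per gene (token
   multiset); log-entropy weighting; truncated SVD; gene↔term cosine
   similarity clamped to [0, 1], with **≥ 0.1 marking an implicit
   association**.
5. **Keystone selection.** Each enriched pathway becomes an LSI query; the
   genes × pathways cosine matrix is filtered to genes associated with ≥2
   pathways; per-gene *conservation* = number of associated pathways; the
   **99% class percentile** (the whole tied top class) is the keystone set.
6. **Term trajectories, phrase mining.** Interrogation terms are ranked
   per timepoint by the mean cosine of their implicitly associated
   transcripts (reciprocal-rank transform for plotting); noun-phrase lists
   are mined for overlapping n-gram frequencies (n = 2…7) and word-cloud
   weights.
7. **Islet morphometry.** Inside a hand-drawn ROI, after background
   subtraction (mean outside the ROI), pixels strictly above intensity 8
   form the islet mask; the mask's second central moments give an
   equivalent ellipse with full axes 4√λ; insulin/glucagon channel areas
   give beta/alpha-cell percentages, and diameters feed a size histogram.

A synthetic-data module generates every input with planted ground truth
(fold-changes, gene–theme seeds, pleiotropic genes, islet geometry, list
overlaps), so each stage is testable end-to-end without any downloads.

## Worked example

```python
from keystonekit import diffexpr, synthetic_data

matrix, truth = synthetic_data.gen_expression(
    n_genes=22000, n_de=200, lfc_min=1.0, lfc_sd=0.0, seed=1)
records = diffexpr.differential_expression(matrix, "KO", "WT")
called = {r.gene_id for r in records if r.significant}
planted = set(truth.planted_de_genes)
print(f"sensitivity {100 * len(called & planted) / len(planted):.1f}%")
print(f"false calls {100 * len(called - planted) / 21800:.3f}%")
```

prints

```
sensitivity 93.0%
false calls 0.142%
```

— of 200 genes planted with a 10-fold (1.0 log₁₀-unit) change at n = 3
per group, 93% survive all three gates, while 0.14% of the 21,800 null
genes are falsely called. The same kind of planted-truth readout exists
for every stage: e.g. the keystone chain on a corpus with 10 planted
pleiotropic genes among 1,600 returns exactly those 10 (Jaccard 1.0), and
planted islet ellipse axes are recovered within 1%.

A command-line surface mirrors the library
(`keystonekit de|venn|enrich|lsi|keystone|rank-terms|phrases|islet|simulate`);
see `keystonekit --help`.

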
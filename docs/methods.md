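# Methods

This note documents the statistical conventions keystonekit implements,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical edge-case rules. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Differential expression (`diffexpr`)

**Model.** Raw bead-array intensities are assumed log-normal. Intensities
are log-transformed (base 10 by default; the base is configurable and only
rescales the z-scores' input, not the z-scores themselves) after
floor-clipping non-positive cells to the smallest positive value in the
matrix (the clipped count is logged). Each array (sample) is standardised
across genes with the population (n) standard deviation, so every column
has mean exactly 0 and sd exactly 1.

**z-ratio.** For contrast (a, b), d_g = mean z-score in a − mean z-score
in b, and z-ratio_g = d_g / SD(d) where SD uses the sample (n−1) estimator
over genes. The sign is positive when the gene is higher in group a. The
statistic is antisymmetric under swapping the groups.

**Gates and their order.** The calling chain is sequential, mirroring the
spreadsheet-era microarray workflow it reimplements:

1. |z-ratio| ≥ 1.50 — *inclusive* threshold;
2. BH FDR q < 0.05 — *strict*, computed over the candidates that passed
   the z filter, from two-sided normal-tail p-values of the z-ratios
   (under the null the z-ratio is approximately standard normal); genes
   outside the filter carry q = 1;
3. one-way fixed-effects ANOVA p < 0.05 — *strict*, across **all**
   condition groups, equal-variance (no Welch correction).

The asymmetry (inclusive z, strict q and p) follows the conventions
"≥ ±1.50" versus "< 0.05" of the workflow's thresholds. ANOVA edge cases:
a gene with zero within-group variance in every group gets p = 0 if the
group means differ (infinite F) and p = 1 if they are all equal; both are
counted in the log as degenerate.

**What sensitivity is attainable at n = 3.** The ANOVA gate alone caps
sensitivity at two-sample t power: at a standardised effect d = 3
(log-fold-change of 3 residual sds) the power at n = 3/group is 0.78, and
it passes 0.8 only near d ≈ 3.2 (noncentral-t, df = 4). Planted-recovery
fixtures therefore use d = 4 effects (a 10-fold change at the default
noise sd of 0.25) — the scale of strongly regulated, Western-validated
transcripts — at which the full chain recovers >90% of planted genes with
a false-call rate of ~0.1%. These figures are fixture expectations for
those conditions, not universal truths.

## Venn partitioning (`vennplex`)

Exact set algebra over 2–6 signed lists (up to 63 sectors). Gene
identifiers are matched case-insensitively across lists; spellings that
collide after case-folding are recorded on the partition (`collisions`)
rather than silently merged. *Contra-regulation* is defined purely by
polarity: a gene in ≥2 lists where any pair of containing lists disagrees
in sign; magnitudes are ignored. Because the original tool's figures are
ambiguous about whether contra-regulated genes are counted inside their
sector, `sector_counts(separate_contra=True)` reports both tallies.
Uniqueness is 100·|singleton sector|/|list|, reported to 2 decimals.

## Over-representation (`enrichment`)

The enrichment probability is the exact one-sided hypergeometric upper
tail P(X ≥ k) (the default convention of the web over-representation
tools the workflow used); the enrichment ratio is R = k/(nK/N), observed
over expected overlap. Admission requires k ≥ 2 and raw p ≤ 0.05 — no
multiple-testing correction is applied to the filter because the source
workflow filtered on the raw enrichment value; a BH column is emitted for
transparency. Before the hybrid score (−log₁₀ p)·R, p is floored at
1e-300 (configurable, logged) to avoid infinities. Identifier matching is
case-insensitive; query genes outside the universe are dropped with a
logged count, and each set is intersected with the universe before K is
taken.

## Latent semantic indexing (`lsi_engine`)

**Weighting** is classic log-entropy: cell(t, d) = log₂(1 + tf) · g_t
with g_t = 1 + Σ_d p log₂ p / log₂ D, p = tf/gf. A term confined to one
document has g = 1; a term spread uniformly over all documents has g = 0.
The corpus tool this emulates never disclosed its weighting; log-entropy
is the scheme classically associated with that tool's lineage, and the
choice is surfaced as configuration (`weighting` is recorded in the model
manifest). A corpus needs ≥ 2 documents (log₂ D = 0 otherwise).

**Decomposition.** Truncated SVD with default rank
min(100, min(dims) − 1). Sign ambiguity is fixed deterministically: the
largest-|loading| term coefficient of each dimension is made positive.
Both terms (U·S) and documents (V·S) live in the singular-value-scaled
space, and similarity is the cosine there. Negative cosines are clamped
to 0 because the association score is declared to span [0, 1]; clamping
and the 0.1 threshold coincide for positive scores, so the threshold is
applied inclusively (≥ 0.1) to the clamped value. Out-of-vocabulary terms
or unknown genes soft-fail to score 0 with a warning.

**Tokenisation** (shared with phrase mining): lowercase, split on
non-alphanumeric boundaries, internal hyphens preserved
("insulin-responsive" is one token); no stemming, no stop-word removal.

## Keystone selection (`keystone`)

A pathway's name becomes an LSI query by tokenising it and removing
generic pathway vocabulary ("of", "and", "pathway", "signaling",
"disease", …); a gene's score against the pathway is the mean cosine over
the query's in-vocabulary tokens. This construction — how a named pathway
becomes a literature query — is the module's central documented
interpretation; pathways whose query is fully out-of-vocabulary are
dropped with a warning, never zero-filled.

Genes associated (score ≥ 0.1) with fewer than 2 pathways are removed.
*Conservation* is the **count** of associated pathways (a cosine-sum
variant is available via `percentile_class(..., cosine_sums=...)` for
sensitivity analysis). Selection is class-based: cut_value is the
smallest count whose below-fraction reaches percentile/100, and the whole
tied class at the cut is admitted — never split. If the top class itself
exceeds (100 − percentile)% of retained genes, the top class alone is
admitted; this keeps selection monotone in the percentile (raising it
never adds members). Note the arithmetic consequence: a 99% class can
only isolate a small planted group if the retained population is ≥ ~100×
larger than that group.

## Term trajectories (`term_ranking`)

Per timepoint model and term: associated transcripts are those with
cosine ≥ 0.1; the term's score is the arithmetic mean over that
associated set only (not all transcripts), 0 with a `no_hits` flag when
empty. Terms are ranked 1..T within each timepoint by descending mean,
ties broken lexicographically; zero-hit terms necessarily trail because
associated scores are bounded below by the threshold. The reciprocal
transform 1/rank is order-preserving by construction.

## Phrase mining (`phrase_mining`)

Overlapping sliding-window n-grams (n = 2–7) within each input phrase;
n-grams never span phrase boundaries, so Σ counts = Σ max(0, len − n + 1).
Word-cloud weights are raw frequencies (proportionality constant 1);
rendering is left to consumers. No stemming or stop-word removal — the
cloud outputs retain common words deliberately.

## Islet morphometry (`islet_morphometry`)

Background is the mean intensity outside the ROI (an explicit background
region can be supplied by passing a different ROI to
`background_subtract`); subtraction rounds half-up and clips at 0. The
islet mask is pixels inside the ROI **strictly above** the threshold
(default 8), reading "above the set threshold of eight" literally — a
pixel at exactly 8 is background. "Normalized variance" is interpreted as
the covariance matrix of the segmented pixel coordinates (second central
moments, population-normalised, unweighted by intensity); the equivalent-
moment ellipse has full axes 4√λ, the same convention as regionprops'
axis lengths, under which a filled ellipse with semi-axes (a, b) recovers
(2a, 2b). The alternative 2√λ scaling and intensity-weighted moments were
considered and rejected as defaults: 4√λ is the moment-matching constant
for a filled region, and the binary-mask convention matches thresholded
segmentation.

The overall islet area for percentages is the **union** of the two
channel masks; double-positive pixels count in both channels (their
fraction is logged), so beta% + alpha% can mildly exceed 100. The single
binning diameter is the mean of major and minor axes (min/max are also
available through the axes themselves); size bins are half-open [lo, hi).

One deliberate note on bit depth: 8-bit intensities span 0–255. A
"0 to 256" range sometimes quoted for 8-bit imagery is not realizable;
the package validates against 2^depth − 1.

## Synthetic data (`synthetic_data`)

Every generator is a pure function of its parameters and an explicit
seed (no global random state) and emits a `SyntheticTruth` JSON-serialisable
record that fully reconstructs what was planted.

- **Expression**: ~22,000 probes, n = 3 per group, log₁₀-normal baselines
  (mean 2.5, sd 0.6), residual noise sd 0.25. Planted genes get signed
  shifts of magnitude lfc_min + |N(0, lfc_sd)| with lfc_min defaulting to
  2 residual sds; recovery fixtures use the d = 4 condition above. Not
  emulated: bead-level noise physics, probe cross-hybridisation, intensity-
  dependent variance — so passing tests show the chain's statistical
  behaviour, not robustness to array artefacts.
- **Corpus**: Zipf-distributed background vocabulary (exponent 1.05),
  Poisson(80) document lengths, theme marker terms planted at a
  configurable rate. The pleiotropic variant gives each theme a 40-word
  sub-vocabulary (pathway literatures have vocabularies, not single
  markers), seeds 1,200 background genes with exactly two themes each and
  10 hub genes with all five at full budget (a hub's literature is richer,
  not thinner per topic), and records the decomposition rank (400) at
  which the planted themes stay separable at the 0.1 threshold — at low
  rank, transitive co-occurrence through shared documents merges themes,
  which is a real property of LSI, not an artefact. Not emulated: real
  biomedical word statistics, synonymy, polysemy.
- **Islets**: rotated filled ellipses, interior partitioned along the
  major axis at the planted beta fraction, uniform background offset
  (default 10), Gaussian pixel noise (sd 2), clipped to bit depth; one
  elliptical ROI per islet (planted shape dilated 1.4×). Not emulated:
  staining gradients, islet shape irregularity, touching islets,
  autofluorescence.
- **Protein lists**: two identifier lists (defaults 170 and 153, the
  scale of a two-condition co-immunoprecipitation comparison) with an
  exact planted overlap; the conserved fraction is defined as
  |A∩B|/|A∪B| and the overlap count is solved from it.

## Problem sizes

The default test and acceptance runs use: the full 22,000-probe matrix
for differential expression (the vectorised chain runs in well under a
second), a 1,000-probe null matrix for calibration, 200-gene/500-term
corpora for association recovery, the 1,600-gene pleiotropic corpus for
keystone recovery, and 40 random islet geometries at 192×192 px. These
sizes were chosen so each fixture exercises the regime its statistics
need (e.g. the ≥100:1 retained-to-keystone ratio required by a 99% class
percentile) while the whole suite stays interactive.

## Known limitations

- The FDR is Benjamini–Hochberg; the original workflow's internal FDR
  may have been a permutation variant, which is not reimplemented.
- The LSI weighting, rank, and score normalisation of the proprietary
  tools being emulated are undisclosed; all are configuration here, and
  absolute cosine values should not be compared across tools.
- Probe-to-gene collapsing is first-occurrence-wins; no background
  correction or quantile normalisation is provided.
- ROIs are inputs: there is no automatic islet detection, and no stain
  deconvolution for brightfield imagery.
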
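# Methods

`volatilink` implements a paired analysis of two untargeted GC-MS compound
tables measured on the same experimental units — headspace volatiles (BVOCs)
and tissue metabolites from coral fragments under a transient high-light
treatment — and the statistics used to integrate them: differential
abundance, distance-based multivariate testing, a rank-correlation screen of
the combined matrix, and correlation-based attribution of unannotated
volatiles to metabolic pathways. This note records the models, the defaults
and the reasoning behind the genuinely open design choices.

## Preprocessing chain

Raw peak areas pass through a fixed stage order per dataset:

1. **Internal-standard normalisation.** Each sample row is divided by its
   spiked internal-standard signal (chlorobenzene-D5 peak area for volatile
   runs; 13C6-sorbitol relative abundance for metabolite runs). Corrects
   per-run instrument response.
2. **Blank subtraction** (volatiles only in the default pipeline — seawater
   blanks are a headspace construct). For each compound the mean across that
   treatment's blanks is subtracted from that treatment's coral samples;
   negative results floor to 0, because a sample detecting less than the
   seawater background carries no evidence of coral emission. Blanks are
   per-treatment by default (each treatment's blanks were run under its own
   light); a pooled-blank mode exists. Negatives are floored immediately at
   this stage, before surface-area scaling — the order is not observable
   downstream because scaling is positive and multiplicative.
3. **Scale normalisation.** Division by coral surface area (cm², volatiles)
   or tissue protein content (metabolites). The two datasets end up in
   different units; no cross-dataset abundance comparison is ever made —
   downstream integration is rank-based, which is invariant to per-compound
   monotone scale changes.
4. **Prevalence filter** (volatiles): a compound is dropped when detected
   (value > 0) in three or fewer replicates of *every* treatment group
   (default `min_detected_replicates = 4` of n = 6). The "at least one group"
   reading is deliberate: a compound robustly present under only one
   condition is biologically informative, and group-specific compound counts
   are part of the result surface. A stricter all-groups mode is available.
5. **RSD filter** (metabolites): a compound is dropped when its within-group
   relative standard deviation (sample sd / mean) exceeds 50% in *either*
   treatment group — noise in one group can mask broader trends. A
   both-groups mode is available. Groups of fewer than two replicates are an
   error (RSD undefined); a group mean of zero counts as failing.
6. **log10 + mean-centring.** Zeros are replaced by half the smallest
   positive value of that compound across samples (the standard half-minimum
   imputation for log transforms of peak areas), then log10, then per-compound
   mean subtraction. A compound with no positive value at this stage is an
   error — the prevalence filter should have removed it.

Filters only drop columns; retained values are never altered, and every
removal is logged as (compound, reason, statistic, threshold).

## Differential abundance

Per compound, a two-sample t-test on the log-centred values compares
high-light to control. Welch's unequal-variance form is the default — peak
areas routinely violate variance homogeneity — with the pooled form
available. Raw p-values are adjusted per dataset (volatiles and metabolites
separately) with Benjamini–Hochberg by default; Holm and no adjustment are
selectable. Fold changes are computed on the pre-log normalised table as
(high-light mean)/(control mean); 0/0 reports NaN (undefined) and x/0
reports +inf, both preserved in the output rather than silently clamped.

## PCA

Principal components come from the SVD of the already mean-centred matrix.
Variance-explained proportions sum to one over all components. Loadings are
unit-norm right singular vectors — the dimensionless convention under which
the |loading| > 0.2 "driver" threshold on PC1/PC2 is comparable across
datasets — with each component's sign fixed so its largest-magnitude loading
is positive, making results deterministic.

## PERMANOVA

One-factor permutational multivariate ANOVA on Euclidean distances of the
log-centred rows (Anderson's formulation):

    SS_total  = (1/N) Σ_{i<j} d_ij²
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d_ij²
    pseudo-F  = (SS_between/(a−1)) / (SS_within/(N−a)),  SS_between = SS_total − SS_within

Significance comes from permuting group labels over samples. When the number
of distinct label assignments is at most 10,000 the full distribution is
enumerated — p = #(F_perm ≥ F_obs)/#assignments, identity included, exact and
seed-independent (at the study size, C(12,6) = 924, this is always the
path). Otherwise 999 random permutations are drawn and p = (count+1)/(n+1),
which cannot report zero. Ties at F_obs count as "as extreme"; this is the
statistically valid convention (without it, data with internally identical
groups would get anti-conservative p-values). A group of size one is an
error; fully identical samples yield an undefined (NaN) statistic flag.

## Correlation screen and network

Spearman rho for every unordered compound pair of the combined
volatile + metabolite matrix (samples shared by both datasets), computed as
the Pearson correlation of average ranks; p from the t approximation
t = rho·√((n−2)/(1−rho²)) with n−2 df, matching common analysis-platform
behaviour (an exact permutation p is available for single pairs at n ≤ 10).
Compounds constant across samples have undefined rho; their pairs are
reported missing and excluded from the adjustment family. Holm's step-down
adjustment runs over the whole family of defined pairs — within- and
cross-dataset alike, since the screen is defined on the combined matrix.
An edge requires |rho| > 0.7 **and** adjusted p < 0.05; its sign is the sign
of rho.

The cluster rule "every compound correlates with at least k = 5 others in
the cluster" is exactly the defining property of the graph k-core, so
clusters are the connected components of the k-core of the positive-edge
graph (negative edges are kept in the edge set for reporting but do not
enter clustering). The k-core is removal-order independent, which makes the
formalisation deterministic where a hand-curated network layout would not
be. Hubs are ranked by total degree in the full positive network.

## Pathway statistics

Two computations connect edges to a user-supplied compound → pathway map
(KEGG-style identifiers; no live retrieval):

* **Co-pathway fraction** — among significant metabolite–metabolite pairs
  with both endpoints annotated, the proportion sharing at least one
  pathway. Unannotated endpoints are excluded from the denominator by
  default: missing annotation is missing data, not evidence of different
  pathways (an inclusive mode counts such pairs as non-shared). Zero
  qualifying pairs yields an undefined fraction, not 0. "Same pathway" means
  a non-empty intersection of pathway sets, since compounds can be
  multi-pathway.
* **Volatile → pathway assignment** — each volatile with at least one
  positive significant edge to an annotated metabolite inherits the union of
  those metabolites' pathways, with per-pathway support counts (number of
  distinct correlated metabolites carrying the pathway). Positive edges only
  by default, matching the sign structure a shared biosynthetic origin
  predicts; a both-signs mode exists. Ties in top support break
  lexicographically.

A permutation utility reassigns annotation sets among annotated compounds,
giving the null distribution of the co-pathway fraction; its expectation is
the analytic probability that two random annotated compounds share a
pathway, which the test suite verifies.

## Photophysiology

Replicate-level PSII photochemical-efficiency values (dimensionless, in
[0, 1]) with two crossed factors — treatment (control/high light) and
timepoint (before / end of light / recovery) — are analysed with a two-way
ANOVA with interaction using sequential (type-I) sums of squares; the
designs targeted are balanced, where the decomposition orders coincide.
Tukey HSD compares all treatment × timepoint cells via the studentized range
with the pooled within-cell variance. `mean_ratio` reports a group-mean
ratio and its nearest-integer rounding. Because replicate-level source data
for the emulated study exist only as printed means ± SEM (n = 3), this
module's reproduction surface is the mean-ratio arithmetic plus
property-based checks on synthetic replicates; no attempt is made to
regenerate a specific F statistic from rounded summaries. Timepoint is
treated as a crossed fixed factor, not repeated-measures.

## Synthetic studies

The generator produces the full study design: 6 replicates and 3 per-treatment
seawater blanks, 113 volatiles and 121 metabolites (table sizes keep the
multiple-testing burden realistic). On the log10 scale,

    s_ij = baseline_j + effect_j·[high light] + σ_f·f_{block(j),i} + σ·ε_ij

with per-pathway latent factors `f` shared across both datasets by the
compounds of a block. σ_f is parameterised so `block_loading` *is* the
induced log-scale correlation between same-block compounds
(σ_f = σ·√(r/(1−r))). Zero inflation is left-truncation at a detection
limit — instrument limit-of-detection semantics that keep ground truth
recoverable — applied to volatiles (log10 limit 4.6 against a baseline of
5.0 ± 0.7, giving roughly a third of volatile cells as non-detections) and
effectively not to metabolites, exercising the prevalence/RSD filter
asymmetry. Raw peak areas additionally fold in surface area (25 ± 2 cm²),
protein content (2 ± 0.2 mass units), internal-standard signal (3% CV) and,
for a 15% subset of volatiles, an additive seawater background shared with
the blanks, so the preprocessing chain has real work to undo.

Defaults chosen once as the study conditions: planted log2 effects on ~16
volatiles (10 decreases at −3, 6 increases at +3.5) and ~31 metabolites (17
at +2.5, 14 at −2.5), mirroring the reported counts and magnitudes of
differential compounds; `block_loading = 0.97` and independent noise
σ = 0.025, splitting replicate variation so that within-group RSDs land
around 30–40% (most metabolites pass the 50% filter, as in the emulated
study) while same-block correlations reach the near-perfect values at which
edges survive a Holm family of ~20,000 pairs at n = 12 — the regime the
published correlation heatmaps show; 8 pathway blocks covering 60% of
metabolites and 40% of volatiles, the rest unstructured, with a 30% chance
of an off-block metabolite carrying a random annotation and a 5% chance of a
second pathway per block metabolite. Everything is deterministic given the
seed, and a `StudyTruth` object records planted effects, block memberships
and each volatile's generating pathway.

What the generator does **not** emulate: retention-time drift, peak-shape
artefacts, correlated non-detections, heavy-tailed or compound-specific
noise, annotation errors, and any real biochemistry — passing tests show the
statistical chain is correct and well-calibrated under the stated model, not
that the biological conclusions of any particular study are right.

## Numerical choices and problem sizes

* Permutation p-values never report 0 (exact: identity counts; sampled:
  (count+1)/(n+1)); F comparisons use a 1e-12 absolute tie tolerance.
* Holm/BH run through `statsmodels.stats.multitest`; PERMANOVA, the
  correlation screen, the pathway statistics and the generator are
  implemented here (scikit-bio's PERMANOVA and `scipy.stats.spearmanr` serve
  as independent cross-checks in the tests).
* Monte-Carlo test sizes are chosen to terminate in minutes on one CPU:
  500 simulations for the PERMANOVA type-I check (n = 6+6, 20 compounds,
  exhaustive enumeration per run), 200 paired studies for differential
  recovery/FDR, 200 annotation shuffles and 200 small studies for the
  pathway statistics. These sizes give Monte-Carlo standard errors well
  inside the asserted tolerances.
* Statistical tolerance bands follow binomial/Monte-Carlo error (2–4
  standard errors) rather than fixed fudge factors; algebraic identities are
  asserted at 1e-10 to 1e-12.

## Known limitations

* PERMANOVA is one-factor only; no multi-factor designs, no dispersion
  homogeneity test (PERMDISP), so a significant result can reflect location
  or spread differences.
* The correlation screen's t-approximation p is approximate at n = 12,
  especially with many ties; the exact option covers single pairs only.
* The prevalence/RSD rule variants ("any group" vs "all groups", "either" vs
  "both") are both implemented because published descriptions of such
  filters are routinely ambiguous; results can differ materially between
  readings, which is why the choice is logged in the filter log.
* The co-pathway fraction depends strongly on annotation coverage and the
  pathway granularity of the supplied map; it is a validation heuristic, not
  an enrichment test with a calibrated null.
* Pathway assignment is correlational: a high-support assignment is a
  hypothesis for isotope-tracing or biochemical validation, not an identity.
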
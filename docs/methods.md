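# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Study design assumed

A gene × sample matrix of normalized log2 intensities covering several
drugs (default six, two flagged as opioids), time points 0/1/2/4/8 h after
a single exposure, and ≥ 2 (default 3) biological replicates per (drug,
time). The time-0 control is a naive/saline group shared across drugs: the
same control columns are duplicated into every drug's series. No
array-level preprocessing (probe summarization, normalization, batch
correction) is performed or modelled; the matrix is taken as already
normalized.

## Time-course differential expression

**Smoother.** For each gene and drug, the replicate-level series
(y_i, t_i), i = 1..n (n = 15 by default) is fitted by local polynomial
regression of degree 2 with tricube weights w_i = (1 − (|t_i − t0|/h)³)³.
The fit at t0 is linear in y: f̂(t0) = l(t0)ᵀy. Evaluation happens on a
grid of 33 equally spaced points over the design span plus the observed
times.

**Bandwidth.** Candidates are {0.4, 0.55, 0.7, 0.85, 1.0} × the design
span (3.2–8 h on the default grid). Per gene, leave-one-out CV selects the
candidate minimizing the LOO prediction error, computed with the exact
leverage shortcut (y_i − f̂_i)/(1 − h_ii); ties go to the smallest
candidate. Where a candidate's local design is singular at an evaluation
point (fewer than three distinct design times with positive weight, which
happens for small bandwidths between 4 and 8 h), that point alone falls
back to the next larger candidate, with 2 × span as a last resort. The
smoother matrices depend only on the design times, so thousands of genes
are fitted with a handful of matrix products.

**Variance.** σ̂² is pooled per gene across all of that gene's series:
σ̂² = Σ_d RSS_d / Σ_d (n_d − tr H_d), where d runs over drugs and H_d is
the smoother at the observed times. With six drugs this gives ν ≈ 70
residual df instead of ≈ 11 from a single 5-time-point series — the
difference between a workable detection threshold and a t-tail so heavy
that moderate fold changes are undetectable. This is still a *within-gene*
estimate; no information is shared across genes (no empirical-Bayes
moderation), so per-gene heteroscedasticity in real data is respected. The
duplicated control columns make the pooled series slightly dependent; the
measured null family-wise error rate (≈ 0.02 at the nominal 0.05, see
`scripts/acceptance.py`) shows the effect is absorbed by the construction's
overall conservatism.

**Band-exclusion p-value.** The null hypothesis per gene is "flat relative
to the control level". The difference curve D(t) = f̂(t) − f̂(0) has
standard error σ̂‖l(t) − l(0)‖; the test statistic is
c* = max_t |D(t)|/se(t) over the evaluation grid. Its tail is approximated
by the volume-of-tube formula for the maximum of a studentized process,

    P(sup_t |T(t)| > c) ≈ (κ₀/π)(1 + c²/ν)^(−ν/2) + 2 P(t_ν > c),

with κ₀ the spherical path length of the unit vectors
(l(t) − l(0))/‖l(t) − l(0)‖ along the grid. Two deliberate choices here:

* *The reference's uncertainty enters the statistic.* Treating f̂(0) as a
  fixed constant (studentizing by σ̂‖l(t)‖ only) inflates the null
  family-wise error rate to ≈ 0.7 in simulation, because ‖l(0)‖ is
  comparable to ‖l(t)‖ — the control estimate is as noisy as any other
  point of the curve.
* *The p-value is a scan over the candidate bandwidths*, not conditioned on
  the LOO-CV-selected one: band_p = n_cand × min over candidates of the
  tube tail. Conditioning on the selected bandwidth is anti-conservative
  (LOO-CV picks small bandwidths precisely when the noise looks wiggly;
  measured ≈ 6× inflation of small-bandwidth tails), while the union bound
  over the five candidate processes is valid regardless of selection and
  *gains* power, since a real response is strongest at its best-matched
  bandwidth.

The fitted curve, fold change and peak time are taken from the LOO-CV
bandwidth. Degenerate cases: zero residual variance with a moving curve
gives band_p = 0; a perfectly flat constant series gives band_p = 1.

**DE rule.** adj_p = min(1, band_p × n analyzed genes) (Bonferroni);
a gene is DE iff adj_p < α (default 0.05) and |signed FC| ≥ 1.2, where
signed FC = ±2^max_t|D(t)| with the sign of the maximizing deviation
(negative = down). The FC is computed from the smoothed curve, not from
raw replicate means. t_max is the grid argmax of |D|; phases are
IE = (0, 2], M = (2, 4], L = (4, 8] h (boundaries belong to the earlier
phase).

**Simultaneous bands.** `simultaneous_band` returns c(α)·se_fitted with
c(α) from the same tube formula using the fitted-curve process (κ₀ from
l(t)/‖l(t)‖), floored at the pointwise t quantile so the simultaneous band
always contains the pointwise band. Empirical coverage of a flat true
curve at nominal 95% is ≈ 94% over 1000 null series.

## Temporal patterns

Profiles are fitted log2 ratios at the observed post-exposure times
(1/2/4/8 h), unstandardized — magnitude is what separates up from down
patterns. K-means uses the Hartigan–Wong transfer criterion (move a point
when n_b/(n_b+1)·d² to the receiving centroid is less than
n_a/(n_a−1)·d² to its own), best of `n_restarts` (default 1000) random
initializations by within-cluster SS, each capped at 100 sweeps; the inner
loop is numba-compiled. K (default range 2–10) maximizes the average
silhouette width; ties go to the smaller K. Cluster labels are the modal
(direction, phase) of members, ties resolved to the earlier phase, then
"up".

## Enrichment

`hypergeom_upper_tail(k, K, n, N)` is the exact upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n). Functional mode: universe = all
genes on the analyzed matrix, significance at nominal p < 0.05. Regulator
mode: universe = all annotated genes, Benjamini–Hochberg FDR < 0.05.
Multiple probes per symbol collapse to one symbol before counting; query
genes outside the universe are dropped with a logged count.

Target windows: a gene is a target of a regulator iff any of its peaks
overlaps the gene body extended by `window_bp` (default 1000) on both
flanks. Because the two flanks get the same extension, the strand-oriented
rule ("upstream of TSS and downstream of TTS") reduces to a symmetric
genomic interval [start − w, end + w); gene-body overlaps count. Windows
clip at coordinate 0; peaks on unknown chromosomes are skipped with a log
message. All coordinates are 0-based half-open (GFF3 converted at parse
time).

## Harm association

S_i is the i-th effect's score vector over the drugs in the harm table's
column order; G_j is the gene's fitted log2 ratio per drug at time j. Each
opioid DEG is tested at its own t_max (the `all_timepoints` flag tests
every observed post-exposure time instead). Two tests per (gene, effect)
pair: Pearson r with the exact two-sided t transform on n − 2 df, and the
F-test of y = b0 + b1·x + b2·x² against intercept-only on (2, n − 3) df,
with expression as the response and score as the regressor (the F-test is
not symmetric in its arguments; regressing the noisier quantity on the
cleaner expert scores is the natural direction). Significance is
min(p_pearson, p_quad) < 0.05 with no multiplicity correction — the
either-test compound null rate is by construction above 0.05 (≈ 8–10%
measured), which mirrors the nominal-significance screening design.
Degenerate inputs (zero variance, ≤ 2 distinct scores) are flagged and
never significant.

## Regulator scoring

FCᵢ = 2^max|log2 ratio| over the dense-grid points inside the phase
window. The dependence score of regulator R in phase P is Σ FCᵢ over the
dependence-associated DEGs (effects: dependence, physical and
psychological dependence) among R's targets with phase P; association
scores repeat the sum per effect over the genes significant for that
effect. Scores are stored as magnitudes with a separate majority
`direction`; the signed presentation (negative for down-regulating gene
sets) is derived, keeping the invariants score ≥ 0, score = 0 ⟺ N = 0,
and monotone growth under target-set growth testable.

## Compound reversal

Compound signatures are filtered at load time to p < 0.05 and |FC| > 1.2.
For a query signature (gene → signed weight), the compound's genes are
ranked by signed FC (descending, ties by symbol); weighted KS running sums
give ES_up for the query's up-set (hit mass weighted by the compound's
|FC|) and ES_down for the down-set; the raw score is (ES_up − ES_down)/2.
The reported score is antisymmetrized by construction —
(raw(order) − raw(reversed order))/2, clipped to [−1, 1] — because
negating a compound exactly reverses its ranking, this makes
score(q, negate(c)) = −score(q, c) hold to the last bit while changing the
value only at rounding level. When the extreme positive and negative
running-sum deviations tie in magnitude the ES is 0.

The permutation null shuffles the compound's gene labels (equivalently,
permutes the membership pattern along the fixed ranking);
p = (1 + #{null ≤ observed})/(n_perm + 1), one-sided for reversal, with an
exhaustive enumeration mode for tiny signatures. Ranking is by score
(strongest reversal first), ties by perm_p then compound id; compounds
sharing no genes with the query are excluded and logged.

A known limitation, visible in the synthetic studies: a decoy sharing only
2–3 genes with the query can reach an extreme negative score by chance
(the running-sum statistic is unstable at tiny overlaps) and occasionally
outrank a genuine full-signature reverser. The per-compound `n_shared`
column and the permutation p — which is far less extreme for such decoys —
are the intended guards; downstream users should read the ranking jointly
with both.

## Synthetic-data generator

The generator's defaults are the study conditions: 1000 genes, six drugs
(morphine and heroin flagged opioid), times 0/1/2/4/8 h, 3 replicates,
noise sd 0.2 log2 units, DE fraction 0.1, planted linear fold change 2.0,
baselines N(7, 1), twelve harm effects on a 0–3 score scale, 20 regulators,
200 compounds. The planted layout (which gene indices are DE, their
patterns, regulator target maps, which compound is the reverser) is a
deterministic function of the configuration; the seed moves only noise and
nuisance values, so structural ground truth is seed-invariant.

Templates are piecewise-cubic smoothstep shapes with unit peak: IE rises
within the first hour, holds briefly, returns most of the way to baseline;
M rises after 1 h to a plateau around 3 h; L rises after 3 h and holds
through 8 h. Peaks sit on plateaus in well-estimated interior regions of
the design rather than at single points, which is both biologically
sensible (transcriptional episodes persist for hours) and what makes the
planted fold change recoverable by a local fit from five design times.
Because the templates are not polynomials, the refitted peak is attenuated
by smoothing bias at the few-percent level; recovery tests therefore use a
10% tolerance at zero noise rather than machine precision.

Harm-associated genes: per planted effect, a latent score vector s is
drawn (uniform 0–3 per drug); each associated gene's per-drug amplitude is
an exact affine image a0 + b·s with the opioid minimum pinned at
log2(fc_planted), so the gene is DE in both opioids and its cross-drug
response correlates perfectly with the latent scores. The written harm
table is s plus N(0, 0.05) jitter; unplanted effects get scores
independent of the expression data. Near-miss genes (fold change 1.1,
below the 1.2 threshold) are planted as designed negatives.

The toy genome puts one 2-kb transcript per gene every 10 kb on one
chromosome, alternating strands; each regulator target gets one 200-bp
peak 150–800 bp upstream of its strand-oriented TSS, plus desert decoy
peaks; non-targets have no peak within any window. The compound library
contains one exact negation of the planted dependence signature among
random decoys that share a few signature genes (so every compound is
comparable) and carry entries the load-time DEG filter must drop.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: probe-level artifacts and normalization,
within-gene temporal autocorrelation of replicates (noise is independent
per observation), gene–gene correlation, heteroscedasticity across genes,
mouse→human orthology beyond symbol uppercasing, and realistic compound
signature structure (decoys are random, not drawn from perturbation
atlases).

## Problem sizes and numerical conventions

The calibration studies run at the sizes reported by
`scripts/acceptance.py`: 200 all-null datasets of 200 genes for the
family-wise error rate, 25 × 1000-gene datasets for sensitivity, 1000 null
series for band coverage, 100-seed Monte-Carlo for association recall and
reversal ranking, 10 000 draws for the F-test null — sizes at which the
binomial error of each rate is small against the margins the test suite
asserts.
Ties: bandwidth ties to the smaller candidate, K ties to the smaller K,
cluster-label ties to the earlier phase then "up", compound-rank ties to
smaller permutation p then id. p-values are floored at the smallest
positive double rather than reported as 0. All seeds are explicit
arguments; every stage output records the configuration hash and seed in
its header, and identical configurations reproduce byte-identical outputs.
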
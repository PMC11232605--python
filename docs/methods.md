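# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `sepsaki`, and what the synthetic studies
do and do not demonstrate.

## AKI staging rules

The staging engine grades timestamped serum-creatinine (SCr, μmol/L)
series and urine-output epochs (ml/kg/h) into stages 0–3.

**Baseline.**  The historical baseline SCr is used when known;
otherwise the first measurement collected on admission.  All ratio
criteria are relative to this baseline; all ratio checks are restricted
to measurements within one week (168 h) of the first draw.

**Creatinine rules.**  Stage 1: ratio ≥ 1.6, or a 48-h rise ≥ 27.1
μmol/L (the rise at measurement j is v_j minus the running minimum over
measurements within the preceding 48 h — a dip-then-rebound therefore
counts).  Stage 2: ratio ≥ 2.3.  Stage 3: ratio strictly above 2.3, or
absolute SCr ≥ 427.1 μmol/L.  The *comprehensive* (any-AKI) criterion
combines a 48-h rise > 27.5 μmol/L with a weekly ratio ≥ 1.8; the two
parts are combined with a configurable conjunction, default **or** —
the standard clinical reading — because the published table prints the
conjunction ambiguously.  The defaults deliberately reproduce the
published cut-offs verbatim, including their internal tension (27.5 vs
27.1 μmol/L, 1.8× vs 1.6×, and a stage-2 creatinine band that collapses
to exactly 2.3×); every constant is a field of `StagingThresholds`, so
a user who prefers reconciled values can supply them.

**Urine rules.**  Rates are piecewise-constant over half-open epochs
[start, end); a gap between epochs breaks contiguity.  Stage 1: rate
< 0.46 for 5–10 h; stage 2: > 10 h; stage 3: rate < 0.26 for > 24 h or
anuria (rate exactly 0) for > 12 h.  The comprehensive urine criterion
is < 0.46 sustained ≥ 5 h.

**Overrides.**  RRT, or age < 18 with GFR < 31 ml/min/m², force stage 3
regardless of the laboratory picture.  The final stage is the maximum
of the creatinine stage, the urine stage and the overrides.

**Tie-breaking.**  "Reaches 2.3×" must be decidable at exactly 2.3, so
threshold comparisons use a relative tolerance of 1e-9: `ge` accepts
values within 1e-9 below the cut-off, `gt` requires exceeding it by
more than 1e-9.  Stage 1's "increased to 27.1 μmol/L" is read as a 48-h
rise (mirroring the comprehensive criterion's window), since no other
window is stated.

## Knowledge-graph embedding

The graph g = (ε, R) is stored as a triple set; neighbourhoods N_i^r
are **undirected** (j neighbours i under r if either orientation is a
triple), so the convolution propagates information regardless of edge
direction, while scoring keeps the (head, relation, tail) orientation.
Two graph-convolution layers are the default — the update is applied
twice in sequence — and the count is configurable.

The normalisation constant is 1/|N_i^r| exactly; entities with an empty
neighbourhood under r simply contribute no term for that relation.
R_r is constrained diagonal (standard DistMult), which makes scores
symmetric in head/tail and keeps the relation parameters identifiable
at this scale.  Initialisation is zero-mean normal with scale 1/√d_e
for every array.

Training is full-batch SGD on the cross-entropy triple loss with its
1/(2|Γ|) normalisation; each epoch re-draws 2 uniform head-or-tail
corruptions per true triple (corruptions that are themselves true
triples are rejected and redrawn).  Scores are clipped to
[1e-12, 1 − 1e-12] inside logarithms.  Defaults: d_e = 16, 200 epochs,
learning rate 2.0 — the rate is large because the 1/(2|Γ|) factor
scales gradients down by the batch size; with it, the loss falls from
log(2)/2 ≈ 0.347 to ≈ 0.17 on the default synthetic graph.  A 10%
triple holdout (with matched corruptions) is scored after training to
report held-out triple-classification AUC.

A patient's knowledge feature x^k is the arithmetic mean of the
final-layer embeddings of the patient's linked concepts; patients with
no links get the zero vector and a warning.

## Risk network

Encoders and the decoder are **linear** (affine) maps — no activation —
so the autoencoder half is essentially a learned linear projection with
reconstruction pressure; the nonlinearity of the model lives in the
co-attention gates and the heads.  The reconstruction loss is the
ordinary non-negative mean squared error (a sign slip in some
presentations would make it unbounded below; minimising the standard
form is the only coherent reading).

Co-attention: the per-sample correlation matrix is the outer product
M = z^p (z^k)^T, the only shape-consistent reading of a cross-view
"correlation" whose (i, j) entry relates element i of z^p to element j
of z^k.  α^p is the softmax of M's row-means and α^k of its
column-means (the two printed formulas being otherwise identical, the
row/column assignment is fixed here once).  For an outer product these
reduce to z^p·mean(z^k) and z^k·mean(z^p); the batch path uses this
identity and is tested against the explicit outer-product route.  The
gating operator ⊙ is elementwise multiplication — the only conformable
reading — and π(x) = [B^P ⊙ z^p ; B^K ⊙ z^k] has length 2 d_z.

Both heads are one-hidden-layer (tanh) networks: the classifier ends in
a K-way softmax, the discriminator in a sigmoid.  Adversarial training
uses a gradient-reversal layer by default: the discriminator minimises
L_adv at full strength while the representation receives the −λ1-scaled
gradient.  An alternating min–max scheme (discriminator step on frozen
representations, then a representation+classifier step against the
frozen discriminator) is available by configuration; with λ1 = 0 both
schemes reduce to plain supervised training with identical classifier
traces, which is tested.

Defaults: d_z = 16, hidden width 16, K = 2, λ1 = λ2 = 0.1, 300 epochs
of full-batch SGD at learning rate 0.2, probabilities clipped at 1e-12
inside logs.  Full-batch optimisation makes runs deterministic given
the seed (randomness enters only through initialisation) and keeps the
λ1 = 0 reduction exact.

Gradients for both models come from a small reverse-mode tape
(`sepsaki._autodiff`) written for exactly the operations these networks
use; every loss gradient is checked against central finite differences
(relative tolerance 1e-5) in the test suite, and every forward
operation against a loop-based re-implementation at 1e-10.

## Synthetic study design

The generator defines the default study conditions; everything below
was fixed by design, before measurement, and is not tuned per run.

**Knowledge graph.**  40 entities in 2 equal communities, 3 relations;
each ordered pair carries a triple independently with probability 0.9
within a community and 0.01 between.  The community densities were
chosen by an explicit Bayes argument: with uniform corruption, a
held-out true triple can only be recognised through structure shared
with the training graph, and negatives that fall on within-community
non-edges are indistinguishable from held-out positives.  The
community-only optimum is ≈ 0.74 at (0.25, 0.02) — too weak a planted
signal to certify learning — and ≈ 0.95 at (0.9, 0.01).  The defaults
therefore use the denser planting, so a correct learner should reach
held-out triple AUC well above 0.9 and a broken one will not.

**Cohorts.**  n = 500 per center, p = 10 standardised Gaussian
features.  The outcome follows one shared logistic model
P(y=1|x) = σ(βᵀx − 0.5) with β = (+0.8, −0.8, ..., ±0.8, 0, 0, 0, 0)
on the first six features, plus 5% label noise — moderate, realistic
effect sizes giving ≈ 40% prevalence.  The center shift is δ = 2 SD on
the four features **outside** β's support.  Placing δ off-support is
deliberate: it is the clean covariate-shift regime — P(y|x) shared and
prevalence equal across centers — in which the center signal is
entirely outcome-irrelevant and an adversarial aligner can remove it
completely without destroying label information.  If δ overlapped β,
the centers would differ in outcome prevalence, the label-informative
knowledge features would become irreducibly center-informative, and no
aligner could (or should) drive the discriminator to chance.

**Concept links.**  Each patient receives Poisson(3) ∨ 1 concept links,
each landing in the community indexed by the patient's outcome with
probability 0.8 (else uniform).  Knowledge features therefore carry
outcome signal that the raw features alone lack — the co-attention path
has something real to fuse — and, because links depend on the final
(noisy) label, a model using them can exceed the feature-only Bayes
AUC recorded in the manifest.

**Timelines.**  For the staging pipeline, AKI-labelled patients ramp
creatinine to a uniform 1.7–2.6× baseline over four days (half also
get an oliguric window); non-AKI patients fluctuate within ±15%.  These
timelines exercise the rules engine end to end; they are not a model of
real creatinine kinetics.

**What passing shows — and does not.**  The simulation demonstrates
that the estimator recovers planted structure under its own generating
assumptions: Gaussian features, identity covariance, mean-shift-only
domain difference, a logistic outcome, and label-correlated concept
links.  Real multicenter EHR data violate most of these (mixed-type
and missing features, covariance and concept drift, label-definition
differences between hospitals), so green tests certify correctness of
the machinery, not clinical performance.  Published headline metrics
from private hospital cohorts cannot be recomputed here and are not
asserted anywhere.

**Problem sizes.**  The bundled studies use 40-entity graphs and
500+500-patient cohorts with 200–300 training epochs; these sizes were
chosen so a full replicate sweep (10 paired seeds) completes in about a
minute on one CPU while leaving wide margins on every property being
checked.

## Evaluation

AUC is the rank-based (Mann–Whitney) statistic with ties counted one
half, computed via scikit-learn and cross-checked in the tests against
exhaustive pair counting.  Sensitivity is undefined without positives
(an explicit error, never a silent 0).  Net benefit follows the
standard Vickers–Elkin definition NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)
over a default grid 0.01–0.99 (step 0.01, the value 1 excluded because
the weight p_t/(1−p_t) diverges); treat-all is π − (1−π)·p_t/(1−p_t)
and treat-none is identically zero.  `benefit_range` reports the
longest contiguous grid interval on which the model strictly beats both
references — an empty result is a valid outcome, not an error.  The
default classification cutoff is 0.5.

## Reproducibility conventions

A single master seed fans out to named SHA-256-derived child seeds
(one per module, epoch, split, ...), so every stage is independently
reproducible and reruns of the CLI pipeline are byte-identical.  All
artifacts are plain text (CSV/TSV/JSON) written atomically via
temp-file-and-rename.  Configuration files are flat YAML; unknown keys
are hard errors.

## Known limitations

* The mapping from ultrasound imaging findings to knowledge-graph
  triples is outside scope: the package ingests triples as data and the
  synthetic generator stands in for them.
* The embedding trainer materialises dense per-relation adjacency
  matrices — fine for hundreds of entities, wrong tool for large
  ontologies.
* No probability calibration beyond the raw softmax outputs, and no
  handling of missing clinical features; inputs are assumed complete
  and standardised.
* Stage-2's creatinine band is reachable only at exactly 2.3× baseline
  (as published); users wanting a conventional band should override
  `StagingThresholds`.
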
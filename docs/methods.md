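# Methods

`steptriage` implements a machine-learning triage funnel for single-concentration
high-throughput screening (HTS) data with extreme class imbalance, of the kind
produced by a fluorescence phosphatase-inhibition screen: a few hundred actives
among several hundred thousand inactives. The funnel is: activity labeling →
2D descriptors → redundancy removal → correlation-based feature selection →
cost-sensitive classification tuned to a false-positive ceiling → consensus →
structural-alert and drug-likeness filtering → substructure-fragment enrichment.
This note records the models, the defaults and why, and what the synthetic data
does and does not establish.

## Activity model

The assay readout is % inhibition at 20 µM. A compound is *active* iff its
readout is ≥ 40% (inclusive), receiving the conventional bioassay activity
score of 20; everything else is inactive with score 0. Labeling is total on
finite readouts (negative inhibition is a valid inactive) and idempotent; a
missing or non-numeric readout is a record-level error naming the compound.

## Synthetic libraries

Real screening decks cannot be redistributed, so the generator builds
chemically valid libraries from a bundled grammar: 20 drug-like scaffolds and
32 substituents, combined by attaching 1–3 substituents to H-bearing ring
atoms and sanitizing the result. Known fragment content is the point of the
grammar — several substituents deliberately carry dictionary fragments
(carboxylic acid, nitrate ester, Michael acceptor, alkene…).

Activity is generated through a latent propensity on the logit scale:

    z_i = ε_i + Σ_f log(m_f) · [compound i contains fragment f]
    inhibition_i = 100 · sigmoid(b0 + z_i) + η_i,  clipped to [−20, 120]

with ε_i ~ N(0, latent_sd²) (default 2.0 logits), readout noise
η_i ~ N(0, noise_sd²) (default 5 percentage points), and m_f the enrichment
odds multiplier for each planted fragment. The baseline b0 is calibrated by
order statistics of the per-compound critical baselines so the 40% rule yields
exactly `round(active_fraction · n)` actives; `base_logit` overrides the
calibration (e.g. −∞ forces an all-inactive deck for degenerate-case tests).
The default `active_fraction` is 0.0025, the prevalence of the emulated
screen (887/359,231); desk-scale runs and the test suite use 2000 compounds at
5% so that stratified folds and fragment tables stay populated, with the
planted carboxylic-acid fragment at an odds multiplier of 8.

What the generator does *not* emulate: the chemical space of a real vendor
deck (scaffold diversity is bounded by the grammar), assay artifacts
(autofluorescence, aggregation), plate/batch structure, or any true
structure–activity relationship. Passing tests therefore demonstrate that the
pipeline machinery recovers planted signal under its stated model, not that
the models would reach any particular performance on a real screen.

## Descriptors (147 + 24 + 8)

* **Pharmacophore-pair fingerprint (147 binary bits, schema version 1).** Six
  features (H-bond donor, acceptor, aromatic atom, hydrophobic atom, positive
  centre, negative centre) assigned by bundled SMARTS; 21 unordered feature
  pairs × 4 topological-distance bins (bond counts 1–2 / 3–4 / 5–6 / 7+, with
  inter-fragment pairs in the 7+ bin) plus 60 per-feature count-threshold bits
  (count ≥ 1…10) and 3 ring-count bits. The bit order is fixed by the bundled
  feature file and documented in `descriptors.py`; changing it is a schema
  version bump.
* **Burden (BCUT-style) eigenvalues (24 continuous).** Burden matrix with the
  atomic property on the diagonal, 0.1 × bond order on bonded pairs and 0.001
  on non-bonded pairs of the same connected component (so disconnected salts
  are block-diagonal and their spectra are unions of the fragment spectra).
  Three weightings — atomic mass, Gasteiger partial charge (heavy atom plus
  its hydrogens), and tabulated atomic polarizability (10⁻²⁴ cm³; elements not
  in the table fall back to the carbon value with a warning) — each
  contributing the 4 largest and 4 smallest eigenvalues. Molecules with fewer
  than four heavy atoms replicate their extreme eigenvalues into the unused
  slots; the single-atom case warns.
* **Property descriptors (8 continuous).** Molecular weight (g/mol),
  Wildman–Crippen logP, donor and acceptor counts by the same bundled SMARTS
  as the fingerprint features, rotatable bonds (strict definition: terminal
  single bonds excluded), topological polar surface area (Å²), heavy-atom
  count, net formal charge.

These definitions are open re-specifications of the three classical HTS
descriptor families; bit-for-bit compatibility with any proprietary tool is a
non-goal, and downstream stages depend only on the (binary, continuous)
column schema.

**Redundancy removal** drops every column whose most common value covers more
than `max_identical_fraction` (default 0.99) of the rows; constant columns are
the fraction-1.0 special case. The operation is idempotent and preserves row
and column order.

## Feature selection

CFS merit over symmetric uncertainty:

    merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff),   SU(x,y) = 2·I(x;y)/(H(x)+H(y))

with continuous descriptors pre-binned by equal frequency into ≤ 10 bins
(simple and deterministic; MDL binning is out of scope). SU is 0 by convention
when either marginal entropy is 0. The search is best-first with backtracking:
a merit-keyed priority queue of subsets, expanded by single additions
(forward), deletions (backward) or both; a popped subset that does not improve
the global best increments a staleness counter and the search stops once it
exceeds `stale_limit` (default 5, matching common toolkit practice). Ties are
broken lexicographically on sorted column-name tuples, which makes the search
fully deterministic. At desk scale the search is verified against exhaustive
enumeration of all subsets on ≤ 12-feature tables.

## Cost-sensitive classification

Three families: a native naive Bayes (weighted class priors; Bernoulli
likelihoods with Laplace α = 1 for binary columns, Gaussian likelihoods with
weighted mean/variance (ddof 0, variance floor 1e−9) for continuous columns),
a 100-tree random forest, and a linear SVM of the sequential-minimal-
optimisation family with a logistic model fitted on its decision values for
calibrated scores. Cost sensitivity is instance reweighting — active rows get
weight `c_fn`, inactive rows weight 1 — applied identically to all families;
for the native naive Bayes an integer weight is exactly equivalent to row
replication, which the tests check. Minimum-expected-cost prediction would be
an alternative realization; reweighting was chosen because it applies
uniformly to all three families.

**FN-cost tuning.** The imbalance policy caps the cross-validated
false-positive rate FP/(FP+TN) at `fp_ceiling` (default 20%). The cost is
escalated by geometric doubling from 1 until the pooled-CV FP rate crosses the
ceiling, then bisected to a resolution of one cost unit; the result is the
largest integer cost whose FP rate stays at or below the ceiling. Tuning uses
pooled CV (per-fold tuning is a documented alternative; pooled is what is
implemented). Two edge cases: if the ceiling is exceeded already at cost 1 the
model is returned flagged (ceiling unreachable from below); if the ceiling is
never crossed up to 2²⁰ (e.g. separable data) escalation buys nothing, so the
smallest tested cost whose CV confusion matrix equals the plateau is returned
— separable data yields cost 1.

Cross-validation is stratified (mandatory at sub-percent prevalence so every
fold holds actives), shuffled, and seeded; the pooled confusion matrix is the
element-wise sum over folds and conserves the dataset size. Reports carry
sensitivity, specificity, accuracy, G-mean and AUC. G-mean is
sqrt(sensitivity × specificity) — the geometric mean, which is what published
G-mean values in this literature actually are even when the formula is printed
as a bare product. Undefined ratios (an empty class margin) are reported as
undefined, never as 0. Percentages are rounded to one decimal with
round-half-even. AUC is the trapezoidal ROC area, identical to Mann–Whitney
concordance with ties counted ½. Consensus across models is plain set
intersection of per-model active sets.

## Structural filtering and enrichment

Five alert families ship as small representative demonstration subsets written
for this package (PAINS-, Glaxo-, Oprea-, Pfizer LINT- and ALARM NMR-style);
complete curated lists load from `name<TAB>SMARTS` files. A compound fails a
set iff any pattern matches; it passes overall iff it matches nothing in any
set. Per-set fail percentages are computed over all parseable input compounds
(not over failures), so they can sum past 100%; unparseable structures are
excluded from percentages and listed separately. The Lipinski check uses the
canonical rule-of-five limits (MW ≤ 500, HBD ≤ 5, HBA ≤ 10, logP ≤ 5) with
strict inequalities for violations; fractional acceptor counts are accepted.

Fragment enrichment uses a bundled 44-entry substructure dictionary (a subset
of the classical 307-pattern substructure-fingerprint scheme, covering every
fragment family the pipeline plants or reports). For each fragment and class,

    frequency = (N_fragment_class · N_total) / (N_fragment_total · N_class)

equals 1 under uniform distribution, and the class-size-weighted frequencies
sum to 1 identically — a useful internal consistency check. Significance is a
two-sided Fisher exact test on the 2×2 presence-by-class table (standard for
sparse fragment counts); the default filter is plain p < 0.01 with no
multiple-testing correction, and a Benjamini–Hochberg option is available as a
flag. Fragments absent from the data are reported as absent, not as zero.

## Pipeline

`run_pipeline` executes the stages in the order above from a JSON config with
a mandatory seed, writing every artifact plus a manifest (config echo, input
hashes, per-stage counts). The structural-alert stage can run after consensus
(default) or per-model before consensus via `smarts_stage` — both orders occur
in practice. Identical configs reproduce identical outputs modulo the manifest
timestamp. The final SMARTS- and Lipinski-passing candidates are exported as
SMILES and SDF for downstream tools (docking and dynamics are out of scope).

## Numerical and scale choices

Default desk-scale problem sizes — 2000 compounds, 5% prevalence, 5 folds,
multiplier-8 planting — were chosen once as the smallest sizes at which every
stage is statistically exercised (≥ 20 actives per fold, Fisher tests with
power at p < 0.01); the acceptance script and test suite use them throughout.
Merit comparisons use an absolute 1e−12 tolerance; SU is clipped to [0, 1]
against floating-point drift. Seeds thread from a single integer through the
generator, fold shuffling, and the stochastic learners.

## Known limitations

* Descriptor schemas are family-faithful, not name-faithful, to the historical
  tools; absolute metric values on real decks are not transferable.
* The bundled alert sets are demonstration subsets; production screening
  should load complete curated lists.
* FP-rate monotonicity in the FN cost is an empirical regularity, not a
  guarantee; the doubling/bisection search assumes it within the bracket.
* Naive Bayes treats descriptors as conditionally independent; correlated
  fingerprint bits violate this, which is the usual trade-off of the family.
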
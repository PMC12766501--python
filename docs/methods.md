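# Methods

## Problem and model

The package clusters critically ill patients by the joint dynamics of six
organ systems over the first 48 h after diagnosis. Each patient is a
sequence of T = 12 attributed graphs with a fixed star-of-stars topology:
a patient node (age, gender, weight) connected to six organ-system nodes
(binary diagnosis vectors), each connected to one clinical-feature node
carrying that system's binned measurements. Attributes are zero-padded to
a common width and a 13-way node-identity one-hot is appended; distinct
identities (rather than a shared role code) prevent unrelated nodes from
sharing a large constant attribute component that would otherwise dominate
cosine-based coupling analyses.

Per step, an LSTM emits a death probability ŷ_t that conditions a
graph unit: a conditional VAE encodes node attributes (semantic pathway),
a two-head graph attention layer with additive LeakyReLU scoring
propagates information over the graph (structural pathway), an adaptive
attention unit takes the convex combination of the two, and a second
attention layer (linear output) refines the fused embeddings. The refined
mean-pooled embedding feeds the LSTM at the next step. The patient
representation z_i for clustering is the **sum-pooled graph readout of the
fused node embeddings at the final step**. Two properties force this
choice: the fused layer is the deepest representation anchored by a
reconstruction loss (so it is informative before centroid initialisation,
which K-Means requires), and sum pooling keeps between-patient distances
on the unit scale of the Student's-t kernel — mean pooling shrinks
distances to ~0.1, the soft assignments go near-uniform, and the
self-training collapses to one cluster.

## Losses and training

The composite objective is L = L_G + α·L_C + β·L_AR + γ·L_CVAE + σ·L_S
with L_C = KL(P‖Q) (Student's-t soft assignment Q against the sharpened
self-training target P), L_G = KL(P‖Q_G) where Q_G soft-assigns the pure
structural-pathway readout against the same centroids (aligning both
pathways with one target), L_AR the mean binary cross-entropy of the
inner-product adjacency decoder over node pairs, L_CVAE the ELBO
(reconstruction MSE plus prior KL), and L_S the mean outcome
cross-entropy over all (patient, time) predictions.

Defaults: α = 1, σ = 1, γ = 1, **β = 0.1**, and the prior-KL inside
L_CVAE is weighted 0.05 (β-VAE style). The two down-weightings are
load-bearing and were set by measuring cluster recoverability during
development: the graph topology is identical for every patient, so a
strong adjacency term actively removes between-patient variation from the
embeddings (pretraining init-ARI falls from ~0.98 to ~0.62 at β = 1), and
an unweighted pull toward the standard-normal prior washes out cluster
separation the same way. All weights are exposed in `ModelConfig`.

Training is three-phase: (1) pretraining on reconstruction and outcome
terms only (8 epochs default); (2) centroid initialisation by K-Means
(10 restarts, seeded) on the current embeddings; (3) joint optimisation of
the full objective (30 epochs default), with P refreshed from the
full-cohort Q once per epoch — per-minibatch refreshes destabilise the
self-training target. Optimiser: Adam (lr 1e-3), global-norm gradient
clipping at 5.0, minibatch 128, variational sampling noise drawn from the
run's seeded generator; a fixed seed reproduces training bit-exactly.
KL logs are clamped at 1e-7; argmax ties break to the lowest cluster
index. The network runs on a compact reverse-mode autodiff core written
on NumPy (`odtgc.autodiff`); every layer's gradients are checked against
central finite differences in the test suite.

Risk trajectories re-assign the per-step readout against the centroids and
map the winning cluster through the mortality-sorted cluster order
(0 = lowest training-split mortality), giving a length-12 ordinal risk
sequence per patient.

## Model selection and clustering quality

The number of clusters is chosen by the elbow rule on the within-cluster
SSE over a k grid (default 2..8, seeded K-Means with 10 restarts): the
selected k maximises the discrete second difference of the curve, which is
defined on the grid's interior points; ties break to the smallest k and a
flat curve returns the smallest k with a warning. Silhouette and
Davies-Bouldin delegate to scikit-learn and are verified against naive
pairwise-distance oracles to 1e-9.

## Synthetic cohort generator

The generator emulates the statistical structure the model assumes, not
any real database. Three archetypes are planted on a per-system latent
level (z-scale): **A** — all six systems share one latent factor plus a
monotone improving trend (+1.5 → +3.0 over the window); **B** — each
system follows an independent latent factor around baseline; **C** —
independent factors over bins 1–6, then all systems collapse onto one
shared deteriorating factor (0 → −3 over bins 7–12). Latent factors are
stationary AR(1) processes (ρ = 0.9 per bin); shared factors have
amplitude 0.3 and independent (decoupled) factors amplitude 0.8 —
dysregulated systems fluctuate more. Observed features are
latent × loading (loadings U(0.5, 1.5), drawn once per feature) plus
N(0, 0.4) noise, with one measurement per feature per 4-h bin and 10%
MCAR missingness. The archetype geometry was calibrated while building
the generator so that its own contract holds: K-Means on flattened
noise-free trajectories recovers the labels exactly, default-noise
recovery reaches ARI ≥ 0.8, and the SSE elbow selects k = 3; A's trend is
monotone on one side of baseline because a sign-crossing ramp flips the
embedding direction mid-window (breaking the cross-time coupling
signature) while a recovery-to-zero ramp empties A's final-bin signal
(breaking the final-bin coupling ordering).

Mortality is Bernoulli per phenotype (5.68% / 14.38% / 38.27%), phenotype
proportions 1127:751:554, both following the development-cohort
composition; deaths occur uniformly over (0, 28] days and survivors are
censored at 28 days. Demographics (age, weight, sex), a SOFA-like
severity score and one diagnosis code per system (prevalence 0.15 / 0.30
/ 0.50 for A/B/C) follow the same phenotype gradients. Fluid volumes are
log-normal in mL/kg (median 35, σ_log 0.5) scaled by weight, so all three
strategy bands (<30, 30–50, >50 mL/kg) are populated in both the 0–12 h
and 12–24 h windows. The default cohort is 600 patients, seed 7.

What the generator does **not** emulate: informative (non-MCAR)
missingness, measurement-unit heterogeneity, treatment feedback on
trajectories, inter-current interventions, or correlated comorbidity
structure. Passing tests therefore demonstrate that the implementation
recovers structure it is designed to represent, not that it would recover
phenotypes in registry data.

## Coupling analytics

An organ system's state at bin t is its fused node embedding g′. Coupling
strength between two systems is the cosine similarity of their state
vectors; phenotype-level matrices average per-patient cosines (preserving
per-patient geometry) and hour marks map to 1-based bins (4 h → bin 1,
48 h → bin 12). Three views are provided: synchronous 6×6 matrices at
chosen hours, temporal profiles of a target system against the other
five, and asynchronous coupling of the target's 48-h state against
earlier states. Known limitation: system-node embeddings retain a static
attribute component, so cross-time cosines have a floor for near-baseline
states; the synchronizing archetype's cross-time coupling therefore rises
toward its 48-h reference and exceeds the decoupled archetype's flat
profile from mid-window onward rather than at the earliest bins.

## Preprocessing

Fixed order: bin (half-open 4-h intervals, final bin closed at 48 h,
within-bin averaging) → feature filter (cohort missing rate > 40%) →
patient filter (> 40% missing over remaining features) → essential
monitoring filter (no observation of an essential feature within 24 h) →
Tukey-fence censoring (k = 1.5, closed fences, train-split quartiles,
zero-IQR features skipped) → forward/backward fill (all-missing series
take the train cohort mean) → per-feature z-scoring with train statistics
(zero-variance features map to 0). The 6:2:2 split is seed-deterministic
and all statistics come from the training split only — perturbing
test-split values provably leaves every transform unchanged.

## Downstream analyses

Fluid strategies band weight-indexed dose with a closed middle band
(30 and 50 mL/kg both fall in strategy 1). The propensity model is an
(essentially unregularized) multinomial logistic regression on
standardized baseline covariates; stabilized weights are marginal
frequency over fitted propensity, truncated at the 99th percentile when
near-separation produces extreme weights. The outcome model is a weighted
binomial GLM (frequency weights, HC1 robust covariance for Wald 95% CIs)
with strategy, phenotype and their interaction, strategy 0 as reference;
the likelihood-ratio test compares against the additive reduced model
(df = number of interaction columns). A binary-outcome logistic model is
used rather than a multinomial outcome model: mortality is binary, and
the multinomial family belongs to the 3-level propensity model. Patients
surviving less than 24 h are excluded from fluid analyses. Survival uses
the Kaplan-Meier product-limit estimator (lifelines) over 28 days. The
early classifier is XGBoost (depth 4, 200 rounds, learning rate 0.1,
exposed as arguments) on 0–4 h features with stratified 5-fold
cross-validation, pooled out-of-fold one-vs-rest macro AUROC/AUPRC and
bootstrap CIs. Prognostic comparison fits one lightly regularized
logistic model per predictor (categorical predictors one-hot encoded) and
reports AUROC plus threshold metrics at 0.5.

## Problem sizes

Defaults are desk-scale by design: 600-patient cohorts for
generator-level checks and the full model fit (~1 min on one CPU),
240-patient cohorts with reduced epochs for model-dependent analytics
tests, 2000-sample replicates for the weighting/LRT calibration suite.
All sizes are configuration parameters.
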
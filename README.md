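# odtgc — outcome-guided deep temporal graph clustering

`odtgc` identifies **subphenotypes of critically ill (sepsis-like) patients
from the trajectories of their organ-system interactions**. Instead of
clustering each vital sign or severity score as an independent time series,
it represents every patient as a sequence of attributed graphs over the
first 48 h after diagnosis — one patient node, six organ-system nodes
(circulatory, urinary, hematologic, hepatic, respiratory, nervous) and six
clinical-feature nodes — and clusters patients by how those organ states
co-evolve. It is aimed at computational clinical researchers studying
heterogeneity of multi-organ dysfunction and treatment response.

## The model

At each 4-h step *t* the network processes the attributed graph
G(V, E, X_t):

* an **LSTM** tracks temporal context and emits an outcome (death)
  probability ŷ_t, which conditions the representation at the next step;
* a **conditional variational autoencoder** models the latent distribution
  of node attributes (semantic pathway *h*), a **graph attention layer**
  propagates information over the organ graph (structural pathway *g*),
  and an adaptive attention unit fuses them into joint embeddings
  *g′ = a_h·h + a_g·g*, refined by a second attention layer.

The sum-pooled fused embedding at 48 h is the patient representation
*z_i*. Clustering is self-supervised in the deep-embedded-clustering
style: the Student's-t soft assignment

&nbsp;&nbsp;&nbsp;&nbsp;q_ij = (1 + ‖z_i − μ_j‖²)⁻¹ / Σ_j′ (1 + ‖z_i − μ_j′‖²)⁻¹

is sharpened into the auxiliary target p_ij = (q_ij²/f_j)/Σ_j′(q_ij′²/f_j′)
with f_j = Σ_i q_ij, and the composite objective

&nbsp;&nbsp;&nbsp;&nbsp;L = L_G + α·L_C + β·L_AR + γ·L_CVAE + σ·L_S

combines the two clustering KL terms L_C = KL(P‖Q) and L_G (structural
pathway), the inner-product adjacency reconstruction
L_AR (Â_ij = sigmoid(z_i·z_j)), the variational ELBO L_CVAE, and the
outcome cross-entropy L_S that makes the clusters prognosis-aware.
Centroids are initialised by seeded K-Means; hard phenotypes are
C = argmax_j q_ij; per-step risk levels (0–2 for K = 3) re-assign each
4-h embedding and order clusters by training mortality. The network runs
on a small reverse-mode autodiff core (`odtgc.autodiff`) written on NumPy.

Around the model the package provides: a synthetic cohort generator with
three planted trajectory archetypes (synchronous improvement / persistent
decoupling / early asynchrony then synchronized deterioration), the full
preprocessing pipeline (4-h binning, 40% missingness filters, Tukey-fence
outlier censoring, forward/backward fill, train-split z-scoring, 6:2:2
split), elbow-based model selection with silhouette and Davies-Bouldin
quality metrics, organ-coupling analytics (cosine similarity between organ
state embeddings), a 4-h XGBoost phenotype classifier, Kaplan-Meier
survival stratification, and fluid-strategy heterogeneous-treatment-effect
analysis with stabilized inverse-probability weighting and a
likelihood-ratio interaction test.

## Worked example

`examples/03_fit_and_cluster.py` trains on a reduced synthetic cohort
(240 patients, ~30 s on one CPU) and prints:

```
elbow-selected k: 3  (planted: 3 archetypes)
ARI vs planted phenotypes: 0.991  (1.0 = perfect recovery)
silhouette: 0.639 (higher better), Davies-Bouldin: 0.488 (lower better)
mortality by final risk level: {0: 0.05, 1: 0.183, 2: 0.38}
  (levels are clusters ordered by training mortality: 0 < 1 < 2)
mean risk level per 4-h step: [0.78, 0.73, 0.7, 0.65, 0.62, 0.58, 0.55, 0.52, 0.6, 0.7, 0.7, 0.71]
```

The elbow on the within-cluster SSE curve recovers the three planted
archetypes; the adjusted Rand index of 0.991 means the learned phenotypes
almost exactly match the planted labels; in-hospital mortality rises
monotonically across the risk levels (5% → 18% → 38%), so the time-resolved
risk output tracks true prognosis. The other example scripts cover cohort
simulation, preprocessing/graph construction, coupling heatmaps and the
downstream clinical analyses; each prints its numbers with a line on what
they mean. A thin `odtgc` command-line interface
(`simulate`, `preprocess`, `build-graphs`, `train`, `cluster`, `select-k`,
`couple`, `survival`, `fluids`, `classify`) wraps the same library calls
for shell use.

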
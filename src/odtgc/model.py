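"""Outcome-guided deep temporal graph clustering network.

The network consumes a per-patient sequence of attributed organ-interaction
graphs {G_1..G_T}.  At each step an LSTM emits an outcome (death)
probability ŷ_t, which conditions an attention-fused graph unit: a
conditional variational autoencoder models the latent distribution of node
attributes (semantic pathway h), a graph attention layer propagates
information over the organ graph (structural pathway g), an adaptive
attention unit fuses them into joint node embeddings g', and a second
graph attention layer refines g' into the step's node embeddings.  The
mean-pooled refined embedding feeds the LSTM at the next step; the
sum-pooled graph readout of the fused joint embeddings at the final step
is the patient's clustering representation z_i (sum pooling keeps
between-patient distances on the unit scale the Student's-t kernel
expects).

Training couples representation learning with deep embedded clustering:
soft assignments Q use a Student's-t kernel around centroids μ (initialised
by K-Means), the sharpened auxiliary target P self-supervises via
KL(P‖Q), a parallel KL(P‖Q_G) aligns the structural pathway, an
inner-product decoder reconstructs the adjacency (cross-entropy L_AR), the
variational unit contributes its ELBO (L_CVAE), and the outcome head is
supervised with cross-entropy (L_S).  The composite objective is

    L = L_G + α·L_C + β·L_AR + γ·L_CVAE + σ·L_S.

Hard phenotypes are argmax_j q_ij at the final step; time-resolved risk
levels re-assign the per-step patient embedding against μ and map the
winning cluster through the mortality-sorted cluster order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from odtgc import nn
from odtgc.autodiff import Tensor, concat, no_grad
from odtgc.graphs import GraphDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "EmbeddingSet",
    "CentroidSet",
    "SoftAssignment",
    "OutcomePrediction",
    "FittedModel",
    "soft_assign",
    "target_distribution",
    "kl_divergence",
    "decode_adjacency",
    "adjacency_loss",
    "outcome_loss",
    "cvae_kl",
    "total_loss",
    "TemporalGraphClusterNet",
    "fit",
    "assign",
    "risk_trajectory",
]

EPS = 1e-7  # log/probability clamp used throughout


# --------------------------------------------------------------------------
# configuration and result containers
# --------------------------------------------------------------------------
@dataclass
class ModelConfig:
    """Hyperparameters of the clustering network.

    ``loss_weights`` is (α, β, γ, σ); the L_G weight is fixed at 1.  The
    ablation flags zero individual loss components without changing the
    architecture.
    """

    K: int = 3
    d_latent: int = 24
    gat_heads: int = 2
    gat_layers: int = 2
    lstm_hidden: int = 16
    cvae_hidden: int = 32
    loss_weights: tuple[float, float, float, float] = (1.0, 0.1, 1.0, 1.0)
    cvae_prior_weight: float = 0.05
    lr: float = 1e-3
    epochs: int = 30
    pretrain_epochs: int = 10
    batch_size: int = 128
    seed: int = 0
    use_LC: bool = True
    use_LAR: bool = True
    use_LS: bool = True
    use_CVAE: bool = True
    grad_clip: float = 5.0
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")
        if self.epochs < 1 or self.pretrain_epochs < 0:
            raise ValueError("epochs must be >= 1 and pretrain_epochs >= 0")


@dataclass
class EmbeddingSet:
    """Patient embeddings and the per-time per-node pathway embeddings."""

    Z: np.ndarray            # (N, d) final patient embeddings z_i
    Z_structural: np.ndarray  # (N, d) pure GAT-pathway patient embeddings
    H: np.ndarray            # (N, T, 13, d) refined node embeddings per step
    H_fused: np.ndarray      # (N, T, 13, d) fused g' node embeddings per step
    patient_ids: list[str]


@dataclass
class CentroidSet:
    """Cluster centroids plus the mortality-sorted cluster ordering.

    ``risk_order[j]`` is the risk level (0 = lowest training mortality) of
    cluster j.
    """

    mu: np.ndarray
    risk_order: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.risk_order = np.asarray(self.risk_order, dtype=int)
        if sorted(self.risk_order.tolist()) != list(range(self.mu.shape[0])):
            raise ValueError("risk_order must be a permutation of 0..K-1")


@dataclass
class SoftAssignment:
    Q: np.ndarray
    P: np.ndarray
    Q_G: np.ndarray


@dataclass
class OutcomePrediction:
    y: np.ndarray       # (N,)
    y_hat: np.ndarray   # (N, T)

    @property
    def M(self) -> int:
        return int(self.y_hat.size)


# --------------------------------------------------------------------------
# parameter-free clustering math (deterministic, exactly reproducible)
# --------------------------------------------------------------------------
def soft_assign(Z: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Student's-t soft assignment q_ij of embeddings to centroids.

    q_ij ∝ (1 + ‖z_i − μ_j‖²)⁻¹, normalised over clusters.
    """
    Z = np.asarray(Z, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if mu.ndim != 2 or mu.shape[0] == 0:
        raise ValueError("centroids must be a non-empty K x d matrix")
    if Z.shape[-1] != mu.shape[-1]:
        raise ValueError("embedding and centroid widths differ")
    d2 = ((Z[:, None, :] - mu[None, :, :]) ** 2).sum(axis=-1)
    s = 1.0 / (1.0 + d2)
    return s / s.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened auxiliary target p_ij = (q²/f_j) / Σ_j'(q²/f_j'), f_j = Σ_i q_ij."""
    Q = np.asarray(Q, dtype=float)
    f = Q.sum(axis=0)
    if np.any(f <= 0):
        raise ValueError("degenerate cluster: a column of Q sums to zero")
    w = Q**2 / f
    return w / w.sum(axis=1, keepdims=True)


def kl_divergence(P: np.ndarray, R: np.ndarray, eps: float = EPS) -> float:
    """Σ_i Σ_u p_iu log(p_iu / r_iu); zeros in R are clamped at ``eps``."""
    P = np.asarray(P, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any((R < eps) & (P > 0)):
        logger.warning("kl_divergence: clamping target entries below %g", eps)
    R = np.clip(R, eps, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P / R), 0.0)
    return float(terms.sum())


def decode_adjacency(node_embeddings: np.ndarray) -> np.ndarray:
    """Inner-product decoder Â_ij = sigmoid(z_i · z_j) over one graph's nodes."""
    Z = np.asarray(node_embeddings, dtype=float)
    logits = Z @ Z.T
    return 1.0 / (1.0 + np.exp(-logits))


def adjacency_loss(A: np.ndarray, A_hat: np.ndarray, eps: float = EPS) -> float:
    """Binary cross-entropy between the true and decoded adjacency, over node pairs."""
    A = np.asarray(A, dtype=float)
    Ah = np.clip(np.asarray(A_hat, dtype=float), eps, 1.0 - eps)
    bce = -(A * np.log(Ah) + (1.0 - A) * np.log(1.0 - Ah))
    return float(bce.mean())


def outcome_loss(y: np.ndarray, y_hat: np.ndarray, eps: float = EPS) -> float:
    """Mean binary cross-entropy over the M (patient, time) predictions."""
    y = np.asarray(y, dtype=float)
    yh = np.clip(np.asarray(y_hat, dtype=float), eps, 1.0 - eps)
    if yh.ndim == 2 and y.ndim == 1:
        y = y[:, None]
    bce = -(y * np.log(yh) + (1.0 - y) * np.log(1.0 - yh))
    return float(bce.mean())


def cvae_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(N(m, s²) ‖ N(0, I)) = ½ Σ (m² + s² − 1 − log s²), averaged over samples."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if not np.all(np.isfinite(logvar)):
        raise ValueError("non-finite log-variance")
    per = 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=-1)
    return float(per.mean())


def total_loss(
    components: dict[str, float],
    weights: tuple[float, float, float, float],
    use_LC: bool = True,
    use_LAR: bool = True,
    use_CVAE: bool = True,
    use_LS: bool = True,
):
    """Composite L = L_G + α·L_C + β·L_AR + γ·L_CVAE + σ·L_S (ablatable)."""
    alpha, beta, gamma, sigma = weights
    if any(w < 0 for w in (alpha, beta, gamma, sigma)):
        raise ValueError("loss weights must be non-negative")
    L = components.get("LG", 0.0)
    if use_LC:
        L = L + alpha * components.get("LC", 0.0)
    if use_LAR:
        L = L + beta * components.get("LAR", 0.0)
    if use_CVAE:
        L = L + gamma * components.get("LCVAE", 0.0)
    if use_LS:
        L = L + sigma * components.get("LS", 0.0)
    return L


# --------------------------------------------------------------------------
# tensor-side variants used inside the training graph
# --------------------------------------------------------------------------
def _t_soft_assign(Z: Tensor, mu: Tensor) -> Tensor:
    K = mu.shape[0]
    d2s = []
    for j in range(K):
        diff = Z - mu[j]
        d2s.append((diff**2).sum(axis=-1, keepdims=True))
    d2 = concat(d2s, axis=-1)
    s = (d2 + 1.0) ** -1.0
    return s / s.sum(axis=-1, keepdims=True)


def _t_kl(P: np.ndarray, Q: Tensor) -> Tensor:
    """Mean-per-row KL(P‖Q) with P constant (self-training target)."""
    Qc = Q.clip(EPS, 1.0)
    ll = Tensor(P) * Qc.log()
    const = float(np.where(P > 0, P * np.log(np.clip(P, EPS, None)), 0.0).sum())
    return (Tensor(const) - ll.sum()) * (1.0 / P.shape[0])


def _t_bce(target: np.ndarray, pred: Tensor) -> Tensor:
    p = pred.clip(EPS, 1.0 - EPS)
    t = Tensor(target)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------
class TemporalGraphClusterNet(nn.Module):
    def __init__(self, d_in: int, config: ModelConfig, rng: np.random.Generator):
        cfg = config
        d = cfg.d_latent
        self.config = cfg
        self.d_in = d_in
        self.embed = nn.Linear(d_in, d, rng)          # X_1 pooled -> LSTM input
        self.lstm = nn.LSTMCell(d, cfg.lstm_hidden, rng)
        self.outcome_head = nn.Linear(cfg.lstm_hidden, 1, rng)
        self.gat1 = nn.GATLayer(d_in, d, cfg.gat_heads, rng)
        self.cvae = nn.CVAE(d_in, 1, cfg.cvae_hidden, d, rng)
        self.fusion = nn.AttentionFusion(d, rng)
        self.gat2 = nn.GATLayer(d, d, cfg.gat_heads, rng, activation=None)

    def forward(
        self,
        X: np.ndarray,
        A: np.ndarray,
        eps_noise: np.ndarray | None = None,
        collect_nodes: bool = False,
    ) -> dict:
        """Run the temporal recurrence over a batch.

        ``X`` is (N, T, V, d_in); ``eps_noise`` (N, T, V, d_latent) enables
        variational sampling during training (deterministic mean when None).
        Returns tensors: y_hat (N, T), z / z_struct (N, d), per-step patient
        embeddings (N, T, d), the CVAE loss pieces, and (optionally) every
        node embedding per step.
        """
        cfg = self.config
        N, T, V, _ = X.shape
        d = cfg.d_latent
        use_cvae = cfg.use_CVAE

        h_l = Tensor(np.zeros((N, cfg.lstm_hidden)))
        c_l = Tensor(np.zeros((N, cfg.lstm_hidden)))
        ones_nodes = Tensor(np.ones((1, V, 1)))

        y_steps: list[Tensor] = []
        z_steps: list[Tensor] = []
        recon_terms: list[Tensor] = []
        kl_terms: list[Tensor] = []
        nodes_refined: list[Tensor] = []
        nodes_fused: list[Tensor] = []
        g_last: Tensor | None = None
        e_last: Tensor | None = None

        pooled_prev: Tensor | None = None
        for t in range(T):
            x_t = Tensor(X[:, t])                     # (N, V, d_in)
            if t == 0:
                lstm_in = self.embed(x_t.mean(axis=1))
            else:
                lstm_in = pooled_prev
            h_l, c_l = self.lstm(lstm_in, h_l, c_l)
            y_t = self.outcome_head(h_l).sigmoid()    # (N, 1)
            y_steps.append(y_t)

            g = self.gat1(x_t, A)                     # structural pathway
            if use_cvae:
                cond = y_t.reshape(N, 1, 1) * ones_nodes
                eps_t = eps_noise[:, t] if eps_noise is not None else None
                h_sem, x_hat, mu_q, logvar_q = self.cvae(x_t, cond, eps_t)
                fused, _ = self.fusion(h_sem, g)
                recon_terms.append(((x_hat - x_t) ** 2).mean())
                kl_terms.append(
                    (0.5 * ((mu_q**2) + logvar_q.exp() - 1.0 - logvar_q))
                    .sum(axis=-1)
                    .mean()
                )
            else:
                fused = g
            e = self.gat2(fused, A)                   # refined node embeddings
            pooled_prev = e.mean(axis=1)
            z_steps.append(fused.sum(axis=1))         # joint-embedding readout
            if collect_nodes:
                nodes_refined.append(e)
                nodes_fused.append(fused)
            g_last, e_last = g, e
        fused_last = fused

        from odtgc.autodiff import stack as t_stack

        out = {
            "y_hat": concat(y_steps, axis=-1),            # (N, T)
            "z": fused_last.sum(axis=1),                  # final patient embedding
            "z_struct": g_last.sum(axis=1),
            "z_steps": t_stack(z_steps, axis=1),          # (N, T, d)
            "node_embeddings_final": e_last,              # (N, V, d)
            "recon": (sum(recon_terms) * (1.0 / max(len(recon_terms), 1))
                      if recon_terms else Tensor(0.0)),
            "cvae_kl": (sum(kl_terms) * (1.0 / max(len(kl_terms), 1))
                        if kl_terms else Tensor(0.0)),
        }
        if collect_nodes:
            out["nodes_refined"] = t_stack(nodes_refined, axis=1)  # (N,T,V,d)
            out["nodes_fused"] = t_stack(nodes_fused, axis=1)
        return out

    def adjacency_bce(self, node_embeddings: Tensor, A: np.ndarray) -> Tensor:
        """Mean BCE between A and sigmoid(E Eᵀ), averaged over the batch."""
        logits = node_embeddings @ node_embeddings.swapaxes(-1, -2)
        a_hat = logits.sigmoid()
        return _t_bce(np.broadcast_to(A, a_hat.shape), a_hat)


# --------------------------------------------------------------------------
# fitted model container
# --------------------------------------------------------------------------
@dataclass
class FittedModel:
    network: TemporalGraphClusterNet
    centroids: CentroidSet
    config: ModelConfig
    d_in: int
    training_log: list[dict] = field(default_factory=list)
    stats_fingerprint: str | None = None

    # -- inference --------------------------------------------------------
    def embed(self, data: GraphDataset, collect_nodes: bool = True) -> EmbeddingSet:
        with no_grad():
            out = self.network.forward(data.X, data.A, collect_nodes=collect_nodes)
        return EmbeddingSet(
            Z=out["z"].data,
            Z_structural=out["z_struct"].data,
            H=out["nodes_refined"].data if collect_nodes else out["z_steps"].data,
            H_fused=out["nodes_fused"].data if collect_nodes else out["z_steps"].data,
            patient_ids=list(data.patient_ids),
        )

    def soft_assignment(self, data: GraphDataset) -> SoftAssignment:
        emb = self.embed(data, collect_nodes=False)
        Q = soft_assign(emb.Z, self.centroids.mu)
        return SoftAssignment(
            Q=Q,
            P=target_distribution(Q),
            Q_G=soft_assign(emb.Z_structural, self.centroids.mu),
        )

    def predict_outcomes(self, data: GraphDataset) -> np.ndarray:
        with no_grad():
            out = self.network.forward(data.X, data.A, collect_nodes=False)
        return out["y_hat"].data

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        meta = {
            "config": asdict(self.config),
            "d_in": self.d_in,
            "training_log": self.training_log,
            "stats_fingerprint": self.stats_fingerprint,
        }
        state = {f"param::{k}": v for k, v in self.network.state_dict().items()}
        np.savez(
            path,
            mu=self.centroids.mu,
            risk_order=self.centroids.risk_order,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **state,
        )

    @classmethod
    def load(cls, path: str) -> "FittedModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            cfg = ModelConfig(**{
                k: tuple(v) if k == "loss_weights" else v
                for k, v in meta["config"].items()
            })
            net = TemporalGraphClusterNet(meta["d_in"], cfg, np.random.default_rng(cfg.seed))
            net.load_state_dict(
                {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
            )
            return cls(
                network=net,
                centroids=CentroidSet(z["mu"], z["risk_order"]),
                config=cfg,
                d_in=meta["d_in"],
                training_log=meta["training_log"],
                stats_fingerprint=meta["stats_fingerprint"],
            )


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------
def _full_embeddings(net: TemporalGraphClusterNet, data: GraphDataset) -> tuple[np.ndarray, np.ndarray]:
    with no_grad():
        out = net.forward(data.X, data.A, collect_nodes=False)
    return out["z"].data, out["z_struct"].data


def fit(
    train_data: GraphDataset,
    y_train: np.ndarray,
    config: ModelConfig | None = None,
    val_data: GraphDataset | None = None,
) -> FittedModel:
    """Train the network end-to-end on a cohort of graph sequences.

    Phase 1 pretrains representations (reconstruction + outcome terms only);
    phase 2 initialises centroids with seeded K-Means on the current
    embeddings; phase 3 optimises the full composite loss, refreshing the
    auxiliary target P from Q once per epoch.  ``y_train`` is the binary
    in-hospital death label per patient (order matches the dataset).
    """
    cfg = config or ModelConfig()
    y_train = np.asarray(y_train, dtype=float)
    N = train_data.X.shape[0]
    if y_train.shape[0] != N:
        raise ValueError("y_train length must match the number of patients")
    rng = np.random.default_rng(cfg.seed)
    net = TemporalGraphClusterNet(train_data.X.shape[-1], cfg, rng)
    params = net.parameters()
    opt = nn.Adam(params, lr=cfg.lr)
    alpha, beta, gamma, sigma = cfg.loss_weights
    batch = cfg.batch_size if cfg.batch_size > 0 else N
    log: list[dict] = []
    A = train_data.A
    T, V = train_data.X.shape[1], train_data.X.shape[2]

    def minibatches(epoch_rng):
        order = epoch_rng.permutation(N)
        for start in range(0, N, batch):
            yield order[start:start + batch]

    def run_epoch(mu_param: Tensor | None, P_full: np.ndarray | None) -> dict:
        comps = {"LG": 0.0, "LC": 0.0, "LAR": 0.0, "LCVAE": 0.0, "LS": 0.0,
                 "L": 0.0}
        nb = 0
        for idx in minibatches(rng):
            Xb = train_data.X[idx]
            eps_noise = (
                rng.normal(size=(len(idx), T, V, cfg.d_latent))
                if cfg.use_CVAE else None
            )
            out = net.forward(Xb, A, eps_noise=eps_noise)
            loss = Tensor(0.0)
            piece = {}
            if cfg.use_LAR:
                lar = net.adjacency_bce(out["node_embeddings_final"], A)
                loss = loss + beta * lar
                piece["LAR"] = float(lar.data)
            if cfg.use_CVAE:
                lcv = out["recon"] + cfg.cvae_prior_weight * out["cvae_kl"]
                loss = loss + gamma * lcv
                piece["LCVAE"] = float(lcv.data)
            if cfg.use_LS:
                ls = _t_bce(np.repeat(y_train[idx, None], T, axis=1), out["y_hat"])
                loss = loss + sigma * ls
                piece["LS"] = float(ls.data)
            if mu_param is not None and P_full is not None:
                Pb = P_full[idx]
                q = _t_soft_assign(out["z"], mu_param)
                lg_q = _t_soft_assign(out["z_struct"], mu_param)
                lc = _t_kl(Pb, q)
                lg = _t_kl(Pb, lg_q)
                loss = loss + lg
                piece["LG"] = float(lg.data)
                if cfg.use_LC:
                    loss = loss + alpha * lc
                    piece["LC"] = float(lc.data)
            if not np.isfinite(loss.data):
                raise FloatingPointError("training diverged: non-finite loss")
            opt.zero_grad()
            loss.backward()
            nn.clip_gradients(params, cfg.grad_clip)
            opt.step()
            piece["L"] = float(loss.data)
            for k, v in piece.items():
                comps[k] += v
            nb += 1
        return {k: v / max(nb, 1) for k, v in comps.items()}

    # phase 1: pretraining without the clustering terms
    for epoch in range(cfg.pretrain_epochs):
        comps = run_epoch(None, None)
        comps["phase"] = "pretrain"
        log.append(comps)

    # phase 2: centroid initialisation by seeded K-Means
    Z, _ = _full_embeddings(net, train_data)
    km = KMeans(
        n_clusters=cfg.K, n_init=cfg.kmeans_restarts,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(Z)
    mu_param = Tensor(km.cluster_centers_.copy(), requires_grad=True)
    params = net.parameters() + [mu_param]
    opt = nn.Adam(params, lr=cfg.lr)

    # phase 3: joint optimisation, P refreshed from Q each epoch
    for epoch in range(cfg.epochs):
        Z, _ = _full_embeddings(net, train_data)
        Q = soft_assign(Z, mu_param.data)
        P_full = target_distribution(Q)
        comps = run_epoch(mu_param, P_full)
        comps["phase"] = "joint"
        log.append(comps)

    # final assignments and mortality-sorted cluster order
    Z, _ = _full_embeddings(net, train_data)
    Q = soft_assign(Z, mu_param.data)
    labels = Q.argmax(axis=1)
    mortality = np.array([
        y_train[labels == j].mean() if np.any(labels == j) else np.inf
        for j in range(cfg.K)
    ])
    # rank clusters by training mortality; risk_order[j] = level of cluster j
    order = np.argsort(mortality, kind="stable")
    risk_order = np.empty(cfg.K, dtype=int)
    risk_order[order] = np.arange(cfg.K)

    return FittedModel(
        network=net,
        centroids=CentroidSet(mu_param.data.copy(), risk_order),
        config=cfg,
        d_in=train_data.X.shape[-1],
        training_log=log,
    )


def assign(model: FittedModel, data: GraphDataset) -> np.ndarray:
    """Hard phenotype labels C = argmax_j q_ij (ties -> lowest cluster index)."""
    sa = model.soft_assignment(data)
    return sa.Q.argmax(axis=1)


def risk_trajectory(model: FittedModel, data: GraphDataset) -> np.ndarray:
    """Per-step ordinal risk levels in {0..K-1}, 0 = lowest-mortality cluster.

    The patient-node embedding at each step is soft-assigned against the
    centroids; the winning cluster maps through the mortality-sorted order.
    """
    with no_grad():
        out = model.network.forward(data.X, data.A, collect_nodes=False)
    z_steps = out["z_steps"].data          # (N, T, d)
    N, T, d = z_steps.shape
    Q = soft_assign(z_steps.reshape(N * T, d), model.centroids.mu)
    winners = Q.argmax(axis=1).reshape(N, T)
    return model.centroids.risk_order[winners]
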
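"""Patient-organ interaction graphs.

The topology is a fixed 13-node "star of stars": one patient node connected
to six organ-system nodes (circulatory, urinary, hematologic, hepatic,
respiratory, nervous), each system node connected to one clinical-feature
node that aggregates that system's laboratory tests and vital signs.  The
adjacency is shared by every patient; only node attributes vary over time.

Node attributes are heterogeneous — demographics on the patient node,
binary diagnosis vectors on system nodes, binned measurements on feature
nodes — and are zero-padded to a common width with a node-identity one-hot
appended so the encoder sees one feature matrix per time step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from odtgc.preprocess import FeatureTensor

logger = logging.getLogger(__name__)

__all__ = [
    "OrganGraphSchema",
    "TemporalGraphSequence",
    "GraphDataset",
    "default_schema",
    "encode_diagnoses",
    "build_sequences",
]

N_SYSTEMS = 6
N_NODES = 13  # 1 patient + 6 systems + 6 feature nodes
ROLE_PATIENT, ROLE_SYSTEM, ROLE_FEATURE = 0, 1, 2


@dataclass(frozen=True)
class OrganGraphSchema:
    """Fixed node ordering [patient, systems..., feature nodes...] + edges."""

    systems: tuple[str, ...]
    feature_map: dict[str, tuple[str, ...]]  # system -> clinical feature ids

    def __post_init__(self) -> None:
        if len(self.systems) != N_SYSTEMS:
            raise ValueError(f"exactly {N_SYSTEMS} systems required")
        unknown = set(self.feature_map) - set(self.systems)
        if unknown:
            raise ValueError(f"feature_map references unknown systems: {unknown}")
        for s in self.systems:
            if not self.feature_map.get(s):
                raise ValueError(f"system {s!r} has no mapped clinical features")

    @property
    def node_names(self) -> list[str]:
        return (
            ["patient"]
            + list(self.systems)
            + [f"{s}:features" for s in self.systems]
        )

    @property
    def node_roles(self) -> np.ndarray:
        return np.array([ROLE_PATIENT] + [ROLE_SYSTEM] * N_SYSTEMS
                        + [ROLE_FEATURE] * N_SYSTEMS)

    @property
    def edges(self) -> list[tuple[int, int]]:
        e = [(0, 1 + s) for s in range(N_SYSTEMS)]
        e += [(1 + s, 1 + N_SYSTEMS + s) for s in range(N_SYSTEMS)]
        return e

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency, zero diagonal (self-loops live in the encoder)."""
        a = np.zeros((N_NODES, N_NODES))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def system_node_index(self, system: str) -> int:
        return 1 + self.systems.index(system)

    def feature_node_index(self, system: str) -> int:
        return 1 + N_SYSTEMS + self.systems.index(system)


def default_schema(
    system_names: tuple[str, ...] | list[str],
    feature_map: dict[str, list[str] | tuple[str, ...]],
) -> OrganGraphSchema:
    """Build the 13-node schema; every clinical feature must map to one system."""
    systems = tuple(system_names)
    fm = {s: tuple(v) for s, v in feature_map.items()}
    seen: dict[str, str] = {}
    for s, feats in fm.items():
        for f in feats:
            if f in seen:
                raise ValueError(f"feature {f!r} mapped to both {seen[f]!r} and {s!r}")
            seen[f] = s
    return OrganGraphSchema(systems=systems, feature_map=fm)


def schema_from_feature_ids(feature_ids: list[str],
                            systems: tuple[str, ...]) -> OrganGraphSchema:
    """Infer the system of each ``<system>_f<k>``-style feature id by prefix."""
    fm: dict[str, list[str]] = {s: [] for s in systems}
    for fid in feature_ids:
        for s in systems:
            if fid.startswith(s):
                fm[s].append(fid)
                break
        else:
            raise ValueError(f"feature {fid!r} matches no known system prefix")
    return default_schema(systems, fm)


@dataclass
class TemporalGraphSequence:
    """Per-patient sequence {G_1..G_T}: shared topology, time-varying attributes."""

    schema: OrganGraphSchema
    A: np.ndarray          # (13, 13)
    X: np.ndarray          # (T, 13, d)
    patient_id: str

    def __post_init__(self) -> None:
        if self.A.shape != (N_NODES, N_NODES):
            raise ValueError("adjacency must be 13x13")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("node features must be finite (impute first)")

    @property
    def T(self) -> int:
        return self.X.shape[0]


@dataclass
class GraphDataset:
    """A cohort of temporal graph sequences stacked for batched training."""

    schema: OrganGraphSchema
    A: np.ndarray              # (13, 13) shared
    X: np.ndarray              # (N, T, 13, d)
    patient_ids: list[str]

    def __getitem__(self, patient_id: str) -> TemporalGraphSequence:
        i = self.patient_ids.index(patient_id)
        return TemporalGraphSequence(self.schema, self.A, self.X[i], patient_id)

    def sequences(self) -> list[TemporalGraphSequence]:
        return [
            TemporalGraphSequence(self.schema, self.A, self.X[i], p)
            for i, p in enumerate(self.patient_ids)
        ]

    def subset(self, patient_ids: list[str]) -> "GraphDataset":
        index = {p: i for i, p in enumerate(self.patient_ids)}
        rows = [index[p] for p in patient_ids]
        return GraphDataset(self.schema, self.A, self.X[rows], list(patient_ids))

    def save(self, path: str) -> None:
        np.savez(
            path, A=self.A, X=self.X,
            patient_ids=np.asarray(self.patient_ids, dtype=object),
            systems=np.asarray(self.schema.systems, dtype=object),
            feature_map=np.asarray(
                [(s, f) for s, fs in self.schema.feature_map.items() for f in fs],
                dtype=object,
            ),
        )

    @classmethod
    def load(cls, path: str) -> "GraphDataset":
        with np.load(path, allow_pickle=True) as z:
            fm: dict[str, list[str]] = {}
            for s, f in z["feature_map"]:
                fm.setdefault(str(s), []).append(str(f))
            schema = default_schema(tuple(str(s) for s in z["systems"]), fm)
            return cls(schema, z["A"], z["X"], [str(p) for p in z["patient_ids"]])


def encode_diagnoses(
    diagnoses: pd.DataFrame,
    min_count: int = 1000,
    counts: dict[str, int] | None = None,
) -> tuple[dict[str, list[str]], dict[str, dict[str, np.ndarray]]]:
    """Binary disease encoding with a frequency-thresholded vocabulary.

    Codes occurring more than ``min_count`` times in the cohort (counts may
    be supplied from the training cohort) are retained; each patient gets a
    0/1 vector per system over the retained codes.  Returns
    ``(vocabulary, vectors)`` with ``vectors[patient_id][system]``.
    """
    present = diagnoses[diagnoses["present"] == 1]
    if counts is None:
        counts = present.groupby("code").size().to_dict()

    systems = sorted(diagnoses["system"].unique())
    vocab: dict[str, list[str]] = {}
    for s in systems:
        codes = sorted(diagnoses.loc[diagnoses["system"] == s, "code"].unique())
        vocab[s] = [c for c in codes if counts.get(c, 0) > min_count]
    if all(len(v) == 0 for v in vocab.values()):
        logger.warning("diagnosis vocabulary empty at min_count=%d", min_count)

    patient_codes = present.groupby("patient_id")["code"].agg(set).to_dict()
    vectors: dict[str, dict[str, np.ndarray]] = {}
    for pid in diagnoses["patient_id"].unique():
        codes = patient_codes.get(pid, set())
        vectors[pid] = {
            s: np.array([1.0 if c in codes else 0.0 for c in vocab[s]])
            for s in systems
        }
    return vocab, vectors


def build_sequences(
    tensor: FeatureTensor,
    demographics: pd.DataFrame,
    dx_vectors: dict[str, dict[str, np.ndarray]],
    schema: OrganGraphSchema,
    demo_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> GraphDataset:
    """Assemble per-patient temporal attributed graphs.

    Patient-node features are (age, gender, weight), constant over time and
    z-scored (``demo_stats`` = (mean, sd) from the training split; computed
    from ``demographics`` when omitted).  System nodes carry their binary
    diagnosis vectors, constant over time.  Feature nodes carry the system's
    preprocessed measurements at each bin.  All attribute vectors are
    zero-padded to a common width with a 13-way node-identity one-hot
    appended (distinct identities keep unrelated nodes' attribute vectors
    from sharing a large common component, which would otherwise dominate
    cosine-based coupling analyses).
    """
    demo = demographics.set_index("patient_id")
    missing = [p for p in tensor.patient_ids if p not in demo.index]
    if missing:
        raise ValueError(f"patients missing demographics: {missing[:5]}...")

    f_index = {f: i for i, f in enumerate(tensor.feature_ids)}
    for s in schema.systems:
        for f in schema.feature_map[s]:
            if f not in f_index:
                raise ValueError(f"mapped feature {f!r} absent from tensor")

    dx_width = max(
        (len(next(iter(dx_vectors.values()))[s]) if dx_vectors else 0)
        for s in schema.systems
    ) if dx_vectors else 0
    feat_width = max(len(schema.feature_map[s]) for s in schema.systems)
    d_attr = max(3, dx_width, feat_width)
    d = d_attr + N_NODES  # + node-identity one-hot

    N, T = tensor.n_patients, tensor.n_bins
    X = np.zeros((N, T, N_NODES, d))

    demo_block = demo.loc[tensor.patient_ids, ["age", "gender", "weight_kg"]].to_numpy(
        dtype=float
    )
    if demo_stats is None:
        mu, sd = demo_block.mean(axis=0), demo_block.std(axis=0)
    else:
        mu, sd = demo_stats
    sd = np.where(sd > 0, sd, 1.0)
    demo_z = (demo_block - mu) / sd

    for v in range(N_NODES):
        X[:, :, v, d_attr + v] = 1.0

    X[:, :, 0, :3] = demo_z[:, None, :]

    for s_idx, system in enumerate(schema.systems):
        node = 1 + s_idx
        if dx_vectors:
            dx = np.stack([dx_vectors[p][system] for p in tensor.patient_ids])
            if dx.shape[1]:
                X[:, :, node, : dx.shape[1]] = dx[:, None, :]
        fnode = 1 + N_SYSTEMS + s_idx
        cols = [f_index[f] for f in schema.feature_map[system]]
        X[:, :, fnode, : len(cols)] = tensor.values[:, :, cols]

    return GraphDataset(schema, schema.adjacency(), X, list(tensor.patient_ids))
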
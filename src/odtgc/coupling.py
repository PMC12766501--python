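"""Organ-state coupling analytics.

A patient's organ-system functional state at each time bin is represented
by the system node's fused deep embedding g'.  Coupling strength between
two organ systems is the cosine similarity of their state embeddings: high
coupling means similar, synchronous functional states; low coupling means
decoupled, asynchronous states.

Three views are provided per phenotype: synchronous 6x6 matrices at chosen
hours (e.g. 4, 12 and 48 h), the temporal evolution of one target system's
coupling with the other five, and asynchronous coupling of the target
system's final (48-h) state against the other systems' earlier states.
Phenotype-level values average the per-patient cosines, preserving
per-patient geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from odtgc.graphs import GraphDataset, N_SYSTEMS
from odtgc.model import EmbeddingSet, FittedModel

__all__ = [
    "CouplingMatrix",
    "hours_to_bin",
    "organ_embeddings",
    "coupling_strength",
    "synchronous_matrix",
    "temporal_coupling",
    "asynchronous_coupling",
    "coupling_long_table",
]


@dataclass
class CouplingMatrix:
    systems: tuple[str, ...]
    t_row: float
    t_col: float
    values: np.ndarray     # (6, 6) mean cosine similarities
    phenotype: str | None
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SYSTEMS, N_SYSTEMS):
            raise ValueError("coupling matrix must be 6x6")
        if np.any(self.values < -1 - 1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("cosine similarities must lie in [-1, 1]")

    def mean_off_diagonal(self) -> float:
        iu = np.triu_indices(N_SYSTEMS, k=1)
        return float(self.values[iu].mean())


def hours_to_bin(t_hours: float, bin_h: float = 4.0) -> int:
    """Map an hour mark to its 1-based bin (4 h -> 1, 12 h -> 3, 48 h -> 12)."""
    b = t_hours / bin_h
    if abs(b - round(b)) > 1e-9 or b < 1:
        raise ValueError(f"{t_hours} h is not a bin boundary at bin width {bin_h} h")
    return int(round(b))


def _system_states(emb: EmbeddingSet, t_bin: int) -> np.ndarray:
    """(N, 6, d) fused system-node embeddings at a 1-based bin."""
    T = emb.H_fused.shape[1]
    if not 1 <= t_bin <= T:
        raise ValueError(f"bin {t_bin} outside window (1..{T})")
    return emb.H_fused[:, t_bin - 1, 1:1 + N_SYSTEMS, :]


def organ_embeddings(
    model: FittedModel,
    data: GraphDataset,
    patient_id: str,
    t_hours: float,
    bin_h: float = 4.0,
    embeddings: EmbeddingSet | None = None,
) -> np.ndarray:
    """The six fused system-state vectors g' of one patient at ``t_hours``."""
    emb = embeddings or model.embed(data)
    i = emb.patient_ids.index(patient_id)
    return _system_states(emb, hours_to_bin(t_hours, bin_h))[i]


def coupling_strength(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two organ-state embeddings, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("coupling strength undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _pairwise_cosines(states_a: np.ndarray, states_b: np.ndarray) -> np.ndarray:
    """Mean over patients of cosine(states_a[:, i], states_b[:, j]) -> (6, 6)."""
    na = np.linalg.norm(states_a, axis=-1, keepdims=True)
    nb = np.linalg.norm(states_b, axis=-1, keepdims=True)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero organ-state embedding encountered")
    ua, ub = states_a / na, states_b / nb
    cos = np.einsum("nid,njd->nij", ua, ub)
    return np.clip(cos, -1.0, 1.0).mean(axis=0)


def synchronous_matrix(
    model: FittedModel,
    data: GraphDataset,
    t_hours: float,
    phenotype: str | None = None,
    bin_h: float = 4.0,
    embeddings: EmbeddingSet | None = None,
) -> CouplingMatrix:
    """Mean inter-organ coupling matrix at one time point.

    Entry (a, b) averages, over the (already phenotype-subset) patients,
    the cosine similarity of systems a and b at ``t_hours``; the diagonal
    is exactly 1 and the matrix symmetric.
    """
    if data.X.shape[0] == 0:
        raise ValueError("empty patient subset")
    emb = embeddings or model.embed(data)
    states = _system_states(emb, hours_to_bin(t_hours, bin_h))
    values = _pairwise_cosines(states, states)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)
    return CouplingMatrix(
        systems=tuple(data.schema.systems),
        t_row=t_hours,
        t_col=t_hours,
        values=values,
        phenotype=phenotype,
        n=states.shape[0],
    )


def temporal_coupling(
    model: FittedModel,
    data: GraphDataset,
    target_system: str,
    times_hours: list[float],
    bin_h: float = 4.0,
    embeddings: EmbeddingSet | None = None,
) -> pd.DataFrame:
    """Coupling of one target system with the other five over time.

    Returns a tidy frame (t_hours, system, coupling), one row per time and
    non-target system.
    """
    systems = tuple(data.schema.systems)
    if target_system not in systems:
        raise ValueError(f"unknown system {target_system!r}")
    k = systems.index(target_system)
    emb = embeddings or model.embed(data)
    rows = []
    for t in times_hours:
        states = _system_states(emb, hours_to_bin(t, bin_h))
        cos = _pairwise_cosines(states, states)
        for j, s in enumerate(systems):
            if j != k:
                rows.append({"t_hours": t, "system": s, "coupling": cos[k, j]})
    return pd.DataFrame(rows)


def asynchronous_coupling(
    model: FittedModel,
    data: GraphDataset,
    target_system: str,
    earlier_times: list[float],
    t_ref_hours: float = 48.0,
    bin_h: float = 4.0,
    embeddings: EmbeddingSet | None = None,
) -> pd.DataFrame:
    """Cross-time coupling: the target's state at ``t_ref_hours`` vs the
    other systems' states at earlier time points.

    With an earlier time equal to the reference the row reduces to the
    synchronous couplings.
    """
    systems = tuple(data.schema.systems)
    if target_system not in systems:
        raise ValueError(f"unknown system {target_system!r}")
    if any(t > t_ref_hours for t in earlier_times):
        raise ValueError("earlier_times must not exceed the reference time")
    k = systems.index(target_system)
    emb = embeddings or model.embed(data)
    ref_states = _system_states(emb, hours_to_bin(t_ref_hours, bin_h))
    rows = []
    for t in earlier_times:
        states = _system_states(emb, hours_to_bin(t, bin_h))
        cos = _pairwise_cosines(ref_states, states)
        for j, s in enumerate(systems):
            if j != k:
                rows.append({
                    "t_ref_hours": t_ref_hours, "t_hours": t,
                    "system": s, "coupling": cos[k, j],
                })
    return pd.DataFrame(rows)


def coupling_long_table(matrices: list[CouplingMatrix]) -> pd.DataFrame:
    """Flatten coupling matrices to a long table; values are copied verbatim."""
    rows = []
    for m in matrices:
        for i, a in enumerate(m.systems):
            for j, b in enumerate(m.systems):
                rows.append({
                    "phenotype": m.phenotype,
                    "t_row": m.t_row, "t_col": m.t_col,
                    "system_a": a, "system_b": b,
                    "value": m.values[i, j], "n": m.n,
                })
    return pd.DataFrame(rows)


def plot_heatmap(matrix: CouplingMatrix, path: str) -> None:
    """Save a heatmap PNG of a coupling matrix (values unmodified)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(N_SYSTEMS), matrix.systems, rotation=45, ha="right")
    ax.set_yticks(range(N_SYSTEMS), matrix.systems)
    label = f"{matrix.phenotype or 'all'} @ {matrix.t_row:g} h (n={matrix.n})"
    ax.set_title(f"Organ coupling strength — {label}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
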
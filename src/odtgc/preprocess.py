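"""Preprocessing of long-format clinical event tables.

Turns raw ``(patient_id, t_hours, feature_id, value)`` event rows into
fixed-length, imputed, normalized per-patient feature tensors with
observation masks.  The pipeline order is fixed:

    bin -> filter (features, patients, essential monitoring)
        -> IQR outlier censoring -> forward/backward-fill imputation
        -> z-score normalization

All transform statistics (means, standard deviations, quartiles) are
computed on the training split only and reused for validation/test, so no
test-split value ever influences a transform.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTensor",
    "PreprocessStats",
    "bin_events",
    "compute_stats",
    "filter_missing",
    "censor_outliers_iqr",
    "impute",
    "normalize",
    "split_cohort",
    "preprocess_events",
    "flatten_trajectories",
]


@dataclass
class FeatureTensor:
    """Binned per-patient feature series.

    ``values`` has shape (N, T, F) with NaN where unobserved; ``mask`` is 1
    where a value was observed in the source events.
    """

    values: np.ndarray
    mask: np.ndarray
    bin_edges: np.ndarray
    feature_ids: list[str]
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        n, t, f = self.values.shape
        if len(self.bin_edges) != t + 1:
            raise ValueError("bin_edges must have length T + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.feature_ids) != f or len(self.patient_ids) != n:
            raise ValueError("feature_ids/patient_ids lengths inconsistent")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def copy(self) -> "FeatureTensor":
        return FeatureTensor(
            self.values.copy(),
            self.mask.copy(),
            self.bin_edges.copy(),
            list(self.feature_ids),
            list(self.patient_ids),
        )

    def subset_patients(self, patient_ids: list[str]) -> "FeatureTensor":
        index = {p: i for i, p in enumerate(self.patient_ids)}
        rows = [index[p] for p in patient_ids]
        return FeatureTensor(
            self.values[rows], self.mask[rows], self.bin_edges,
            list(self.feature_ids), list(patient_ids),
        )

    def save(self, path: str) -> None:
        np.savez(
            path,
            values=self.values,
            mask=self.mask,
            bin_edges=self.bin_edges,
            feature_ids=np.asarray(self.feature_ids, dtype=object),
            patient_ids=np.asarray(self.patient_ids, dtype=object),
        )

    @classmethod
    def load(cls, path: str) -> "FeatureTensor":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                z["values"], z["mask"], z["bin_edges"],
                list(z["feature_ids"]), list(z["patient_ids"]),
            )


@dataclass
class PreprocessStats:
    """Train-split transform statistics plus the filtering audit trail."""

    feature_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    feature_missing_rates: dict[str, float] = field(default_factory=dict)
    dropped_features: list[str] = field(default_factory=list)
    dropped_patients: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.q1 = np.asarray(self.q1, dtype=float)
        self.q3 = np.asarray(self.q3, dtype=float)
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")
        if np.any(self.q1 > self.q3):
            raise ValueError("Q1 must not exceed Q3")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_ids": self.feature_ids,
                    "mean": self.mean.tolist(),
                    "sd": self.sd.tolist(),
                    "q1": self.q1.tolist(),
                    "q3": self.q3.tolist(),
                    "feature_missing_rates": self.feature_missing_rates,
                    "dropped_features": self.dropped_features,
                    "dropped_patients": self.dropped_patients,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "PreprocessStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["feature_ids"], d["mean"], d["sd"], d["q1"], d["q3"],
            d.get("feature_missing_rates", {}),
            d.get("dropped_features", []),
            d.get("dropped_patients", []),
        )


def bin_events(
    events: pd.DataFrame,
    window_h: float,
    bin_h: float,
    feature_ids: list[str] | None = None,
    patient_ids: list[str] | None = None,
) -> FeatureTensor:
    """Average event values into half-open time bins ``[edge, edge + bin_h)``.

    The final bin is closed at the window end so a measurement exactly at
    ``window_h`` is kept.  Rows with timestamps outside ``[0, window_h]``
    are rejected with a logged warning.  A 48-h window at 4-h bins yields
    12 steps.
    """
    if bin_h <= 0 or window_h <= 0:
        raise ValueError("window_h and bin_h must be positive")
    n_bins_f = window_h / bin_h
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError("window_h must be divisible by bin_h")
    T = int(round(n_bins_f))

    ev = events.copy()
    bad = (ev["t_hours"] < 0) | (ev["t_hours"] > window_h)
    if bad.any():
        logger.warning("rejecting %d event rows with timestamps outside [0, %g] h",
                       int(bad.sum()), window_h)
        ev = ev[~bad]

    if feature_ids is None:
        feature_ids = sorted(ev["feature_id"].unique())
    if patient_ids is None:
        patient_ids = sorted(ev["patient_id"].unique())
    f_index = {f: i for i, f in enumerate(feature_ids)}
    p_index = {p: i for i, p in enumerate(patient_ids)}

    ev = ev[ev["feature_id"].isin(f_index) & ev["patient_id"].isin(p_index)]
    bins = np.minimum((ev["t_hours"].to_numpy() / bin_h).astype(int), T - 1)

    sums = np.zeros((len(patient_ids), T, len(feature_ids)))
    counts = np.zeros_like(sums)
    pi = ev["patient_id"].map(p_index).to_numpy()
    fi = ev["feature_id"].map(f_index).to_numpy()
    np.add.at(sums, (pi, bins, fi), ev["value"].to_numpy())
    np.add.at(counts, (pi, bins, fi), 1.0)

    mask = (counts > 0).astype(np.uint8)
    with np.errstate(invalid="ignore"):
        values = np.where(mask, sums / np.maximum(counts, 1.0), np.nan)

    edges = np.arange(T + 1) * bin_h
    return FeatureTensor(values, mask, edges, list(feature_ids), list(patient_ids))


def compute_stats(tensor: FeatureTensor, train_patient_ids: list[str]) -> PreprocessStats:
    """Per-feature mean/sd/quartiles over observed cells of the training split."""
    train = tensor.subset_patients(list(train_patient_ids))
    vals = np.where(train.mask > 0, train.values, np.nan).reshape(-1, train.n_features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0)
        q1 = np.nanpercentile(vals, 25, axis=0)
        q3 = np.nanpercentile(vals, 75, axis=0)
    mean = np.nan_to_num(mean)
    sd = np.nan_to_num(sd)
    q1 = np.nan_to_num(q1)
    q3 = np.nan_to_num(np.maximum(q1, q3))
    miss = 1.0 - tensor.mask.reshape(-1, tensor.n_features).mean(axis=0)
    return PreprocessStats(
        list(tensor.feature_ids), mean, sd, q1, q3,
        {f: float(m) for f, m in zip(tensor.feature_ids, miss)},
    )


def filter_missing(
    tensor: FeatureTensor,
    feature_thresh: float = 0.4,
    patient_thresh: float = 0.4,
    essential_features: list[str] | None = None,
    essential_window_h: float = 24.0,
) -> tuple[FeatureTensor, PreprocessStats]:
    """Apply the cohort missingness filters.

    Features whose cohort missing rate exceeds ``feature_thresh`` are dropped
    first; then patients missing more than ``patient_thresh`` of the
    remaining cells; finally patients with zero observations of any
    essential monitoring feature within ``[0, essential_window_h)``.
    """
    if not 0 < feature_thresh <= 1 or not 0 < patient_thresh <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    t = tensor
    miss_by_feature = 1.0 - t.mask.reshape(-1, t.n_features).mean(axis=0)
    keep_f = miss_by_feature <= feature_thresh
    dropped_features = [f for f, k in zip(t.feature_ids, keep_f) if not k]
    if not keep_f.any():
        raise ValueError("all features exceed the missing-rate threshold")

    values = t.values[:, :, keep_f]
    mask = t.mask[:, :, keep_f]
    feature_ids = [f for f, k in zip(t.feature_ids, keep_f) if k]

    miss_by_patient = 1.0 - mask.reshape(t.n_patients, -1).mean(axis=1)
    keep_p = miss_by_patient <= patient_thresh

    if essential_features:
        f_index = {f: i for i, f in enumerate(feature_ids)}
        missing_essentials = [f for f in essential_features if f not in f_index]
        if missing_essentials:
            logger.warning("essential features %s not present after filtering",
                           missing_essentials)
        ess_cols = [f_index[f] for f in essential_features if f in f_index]
        n_ess_bins = int(np.searchsorted(t.bin_edges, essential_window_h, side="left")) - 0
        n_ess_bins = max(1, min(n_ess_bins, t.n_bins))
        # count bins whose start lies in [0, essential_window_h)
        n_ess_bins = int(np.sum(t.bin_edges[:-1] < essential_window_h))
        for c in ess_cols:
            has_obs = mask[:, :n_ess_bins, c].any(axis=1)
            keep_p &= has_obs

    dropped_patients = [p for p, k in zip(t.patient_ids, keep_p) if not k]
    patient_ids = [p for p, k in zip(t.patient_ids, keep_p) if k]

    out = FeatureTensor(values[keep_p], mask[keep_p], t.bin_edges, feature_ids, patient_ids)
    stats = compute_stats(out, patient_ids)
    stats.dropped_features = dropped_features
    stats.dropped_patients = dropped_patients
    stats.feature_missing_rates = {
        f: float(m) for f, m in zip(t.feature_ids, miss_by_feature)
    }
    return out, stats


def censor_outliers_iqr(
    tensor: FeatureTensor, stats: PreprocessStats, k: float = 1.5
) -> FeatureTensor:
    """Set observed values outside the Tukey fences to missing.

    Fences are the closed interval ``[Q1 - k*IQR, Q3 + k*IQR]`` from the
    training split; values exactly at a fence are retained.  Features with
    zero IQR are left untouched (warning logged).
    """
    out = tensor.copy()
    iqr = stats.q3 - stats.q1
    degenerate = iqr <= 0
    if degenerate.any():
        logger.warning("IQR is zero for %d feature(s); left uncensored",
                       int(degenerate.sum()))
    lo = stats.q1 - k * iqr
    hi = stats.q3 + k * iqr
    observed = out.mask > 0
    outlier = observed & ((out.values < lo) | (out.values > hi)) & ~degenerate
    out.values[outlier] = np.nan
    out.mask[outlier] = 0
    return out


def impute(tensor: FeatureTensor, stats: PreprocessStats) -> FeatureTensor:
    """Forward fill, then backward fill, along time per patient-feature series.

    Series with no observation at all are filled with the training-cohort
    feature mean.  The mask keeps the original observation pattern.
    """
    out = tensor.copy()
    n, T, F = out.values.shape
    vals = out.values  # NaN where unobserved

    # forward fill along axis 1
    idx = np.where(~np.isnan(vals), np.arange(T)[None, :, None], 0)
    np.maximum.accumulate(idx, axis=1, out=idx)
    filled = np.take_along_axis(vals, idx, axis=1)
    # backward fill remaining leading NaNs
    idx = np.where(~np.isnan(filled), np.arange(T)[None, :, None], T - 1)
    idx = np.minimum.accumulate(idx[:, ::-1, :], axis=1)[:, ::-1, :]
    filled = np.take_along_axis(filled, idx, axis=1)
    # all-missing series -> train cohort mean
    all_missing = np.isnan(filled)
    if all_missing.any():
        mean_grid = np.broadcast_to(stats.mean[None, None, :], filled.shape)
        filled = np.where(all_missing, mean_grid, filled)

    out.values = filled
    return out


def normalize(tensor: FeatureTensor, stats: PreprocessStats) -> FeatureTensor:
    """Z-score each feature with the training-split mean/sd (sd=0 maps to 0)."""
    out = tensor.copy()
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    out.values = (out.values - stats.mean[None, None, :]) / sd[None, None, :]
    out.values[:, :, stats.sd <= 0] = 0.0
    return out


def split_cohort(
    patient_ids: list[str],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Seed-deterministic disjoint train/validation/test id lists (6:2:2)."""
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    total = float(sum(ratios))
    norm = [r / total for r in ratios]
    n = len(patient_ids)
    cut1 = int(round(norm[0] * n))
    cut2 = int(round((norm[0] + norm[1]) * n))
    if cut1 == 0 or cut2 == cut1 or cut2 == n:
        raise ValueError(f"cohort of size {n} too small for split ratios {ratios}")
    perm = np.random.default_rng(seed).permutation(n)
    ids = np.asarray(patient_ids, dtype=object)[perm]
    return list(ids[:cut1]), list(ids[cut1:cut2]), list(ids[cut2:])


def preprocess_events(
    events: pd.DataFrame,
    window_h: float = 48.0,
    bin_h: float = 4.0,
    feature_thresh: float = 0.4,
    patient_thresh: float = 0.4,
    essential_features: list[str] | None = None,
    essential_window_h: float = 24.0,
    iqr_k: float = 1.5,
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[FeatureTensor, PreprocessStats, tuple[list[str], list[str], list[str]]]:
    """Run the full pipeline: bin, filter, censor, impute, normalize.

    Train-split statistics are computed after filtering and reused for every
    split.  Returns the normalized tensor (all retained patients), the
    statistics, and the (train, val, test) id lists.
    """
    tensor = bin_events(events, window_h, bin_h)
    tensor, stats = filter_missing(
        tensor, feature_thresh, patient_thresh, essential_features, essential_window_h
    )
    splits = split_cohort(tensor.patient_ids, split_ratios, seed)
    train_ids = splits[0]
    stats_train = compute_stats(tensor, train_ids)
    stats_train.dropped_features = stats.dropped_features
    stats_train.dropped_patients = stats.dropped_patients
    stats_train.feature_missing_rates = stats.feature_missing_rates

    tensor = censor_outliers_iqr(tensor, stats_train, iqr_k)
    # quartiles/means move after censoring; refresh location/scale on train
    stats_train2 = compute_stats(tensor, train_ids)
    stats_train.mean, stats_train.sd = stats_train2.mean, stats_train2.sd
    tensor = impute(tensor, stats_train)
    tensor = normalize(tensor, stats_train)
    return tensor, stats_train, splits


def flatten_trajectories(tensor: FeatureTensor) -> np.ndarray:
    """Flatten to an (N, T*F) matrix, e.g. for baseline K-Means/elbow runs."""
    n = tensor.n_patients
    return tensor.values.reshape(n, -1)
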
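"""Synthetic sepsis-like cohort generator.

Emulates the statistical structure the clustering model assumes: six organ
systems observed through time-varying features over a 48-h window, three
planted phenotype trajectory archetypes, phenotype-dependent in-hospital
mortality, MCAR missingness, binary comorbidity indicators, and per-window
intravenous fluid volumes.  The archetypes are

* **A** — all six system latent trajectories share one improving latent
  factor (synchronous improvement, high cross-system correlation);
* **B** — each system is driven by an independent latent factor
  (persistent decoupling, near-zero cross-system correlation);
* **C** — independent factors over the first half of the window, then all
  systems collapse onto one deteriorating shared factor (early asynchrony
  followed by synchronized deterioration).

Latent factors are stationary AR(1) processes; observed features are
``latent x loading + Gaussian noise``.  Everything is driven by a single
seeded generator so a given configuration regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SYSTEMS",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "cross_system_correlation",
]

DEFAULT_SYSTEMS: tuple[str, ...] = (
    "circulatory",
    "urinary",
    "hematologic",
    "hepatic",
    "respiratory",
    "nervous",
)

#: Phenotype labels in fixed risk order (lowest to highest mortality).
PHENOTYPE_LABELS: tuple[str, ...] = ("A", "B", "C")

# Archetype mean trajectories (z-scale), evaluated on T bins.
_A_TREND_RANGE = (1.5, 3.0)    # improving monotonically over the window
_C_TREND_FLOOR = -3.0          # late synchronized deterioration
_AR_RHO = 0.9                  # latent factor autocorrelation per bin
_FACTOR_SCALE = 0.3            # shared (synchronizing) factor amplitude
_INDEP_SCALE = 0.8             # independent (decoupled) factor amplitude

# Phenotype-graded auxiliary distributions (A, B, C).
_AGE_MEAN = (62.3, 66.3, 70.6)
_AGE_SD = 16.0
_WEIGHT_MEAN = (86.2, 82.3, 77.8)
_WEIGHT_SD = 20.0
_MALE_PROP = (0.604, 0.553, 0.556)
_SOFA_MEAN = (4.5, 4.9, 6.2)
_SOFA_SD = 2.7
_DX_PREVALENCE = (0.15, 0.30, 0.50)
_FLUID_MLKG_LOGMEAN = np.log(35.0)
_FLUID_MLKG_LOGSD = 0.5
_FOLLOWUP_DAYS = 28.0

FLUID_WINDOWS: tuple[str, ...] = ("0-12h", "12-24h")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the development-cohort composition: phenotype
    proportions 1127:751:554 and per-phenotype in-hospital mortality
    (5.68%, 14.38%, 38.27%), sampled every 4 h over 48 h.
    """

    n_patients: int = 600
    n_phenotypes: int = 3
    phenotype_props: tuple[float, ...] = (1127 / 2432, 751 / 2432, 554 / 2432)
    mortality_probs: tuple[float, ...] = (0.0568, 0.1438, 0.3827)
    window_h: float = 48.0
    bin_h: float = 4.0
    systems: tuple[str, ...] = DEFAULT_SYSTEMS
    features_per_system: int = 2
    missing_rate: float = 0.1
    noise_sd: float = 0.4
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if len(self.phenotype_props) != self.n_phenotypes:
            raise ValueError("phenotype_props length must equal n_phenotypes")
        if abs(sum(self.phenotype_props) - 1.0) > 1e-9:
            raise ValueError("phenotype_props must sum to 1 (within 1e-9)")
        if any(p < 0 for p in self.phenotype_props):
            raise ValueError("phenotype_props must be non-negative")
        if len(self.mortality_probs) != self.n_phenotypes:
            raise ValueError("mortality_probs length must equal n_phenotypes")
        if any(not 0.0 <= p <= 1.0 for p in self.mortality_probs):
            raise ValueError("mortality_probs must lie in [0, 1]")
        if self.window_h <= 0 or self.bin_h <= 0:
            raise ValueError("window_h and bin_h must be positive")
        if abs(self.window_h / self.bin_h - round(self.window_h / self.bin_h)) > 1e-9:
            raise ValueError("window_h must be divisible by bin_h")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.systems) != 6:
            raise ValueError("exactly 6 organ systems are required")
        if self.features_per_system < 1:
            raise ValueError("features_per_system must be positive")

    @property
    def n_bins(self) -> int:
        return int(round(self.window_h / self.bin_h))

    @property
    def feature_ids(self) -> list[str]:
        return [
            f"{system}_f{j}"
            for system in self.systems
            for j in range(self.features_per_system)
        ]

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    """Generated cohort tables plus the ground-truth phenotype labels."""

    events: pd.DataFrame        # patient_id, t_hours, feature_id, value
    demographics: pd.DataFrame  # patient_id, age, gender, weight_kg, sofa
    diagnoses: pd.DataFrame     # patient_id, system, code, present
    outcomes: pd.DataFrame      # patient_id, death, time_to_event_days, censored
    fluids: pd.DataFrame        # patient_id, window, volume_mL
    truth: pd.DataFrame         # patient_id, phenotype
    config: CohortConfig = field(repr=False, default_factory=CohortConfig)

    @property
    def patient_ids(self) -> list[str]:
        return self.truth["patient_id"].tolist()


def _ar1_paths(rng: np.random.Generator, shape: tuple[int, ...], rho: float) -> np.ndarray:
    """Stationary AR(1) paths with unit marginal variance; last axis is time."""
    out = np.empty(shape)
    out[..., 0] = rng.normal(size=shape[:-1])
    innov_sd = np.sqrt(1.0 - rho**2)
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + innov_sd * rng.normal(size=shape[:-1])
    return out


def _system_latents(
    rng: np.random.Generator, phenotype_idx: np.ndarray, n_systems: int, T: int
) -> np.ndarray:
    """Per-patient per-system latent trajectories, shape (N, n_systems, T)."""
    n = phenotype_idx.size
    latents = np.empty((n, n_systems, T))
    half = T // 2

    a_trend = np.linspace(*_A_TREND_RANGE, T)
    c_trend = np.concatenate(
        [np.zeros(T - half), np.linspace(0.0, _C_TREND_FLOOR, half)]
    )

    # Draw-once-per-patient factors; order is fixed for determinism.  The
    # decoupled archetypes fluctuate with larger independent amplitude
    # (dysregulation) than the shared synchronizing factor.
    shared = _FACTOR_SCALE * _ar1_paths(rng, (n, T), _AR_RHO)
    independent = _INDEP_SCALE * _ar1_paths(rng, (n, n_systems, T), _AR_RHO)

    for i in range(n):
        ph = phenotype_idx[i]
        if ph == 0:      # A: one improving shared factor
            latents[i] = a_trend + shared[i]
        elif ph == 1:    # B: independent factors throughout
            latents[i] = independent[i]
        else:            # C: asynchrony then synchronized deterioration
            latents[i, :, :T - half] = independent[i, :, :T - half]
            latents[i, :, T - half:] = (c_trend + shared[i])[T - half:]
    return latents


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a synthetic cohort under ``config`` (defaults if None).

    The same configuration (including seed) always yields bit-identical
    tables.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_patients, cfg.n_bins
    n_sys, n_feat = len(cfg.systems), cfg.features_per_system
    patient_ids = [f"p{i:05d}" for i in range(n)]

    phenotype_idx = rng.choice(cfg.n_phenotypes, size=n, p=cfg.phenotype_props)
    latents = _system_latents(rng, phenotype_idx, n_sys, T)

    # Loadings drawn once per feature (cohort-level), then observation noise.
    loadings = rng.uniform(0.5, 1.5, size=(n_sys, n_feat))
    noise = rng.normal(scale=cfg.noise_sd, size=(n, n_sys, n_feat, T))
    values = latents[:, :, None, :] * loadings[None, :, :, None] + noise

    observed = rng.random((n, n_sys, n_feat, T)) >= cfg.missing_rate
    bin_mid = (np.arange(T) + 0.5) * cfg.bin_h

    pi, si, fi, ti = np.nonzero(observed)
    events = pd.DataFrame(
        {
            "patient_id": np.asarray(patient_ids, dtype=object)[pi],
            "t_hours": bin_mid[ti],
            "feature_id": [
                f"{cfg.systems[s]}_f{f}" for s, f in zip(si, fi)
            ],
            "value": values[pi, si, fi, ti],
        }
    )

    age = np.clip(
        rng.normal(np.take(_AGE_MEAN, phenotype_idx), _AGE_SD), 18.0, 95.0
    )
    weight = np.clip(
        rng.normal(np.take(_WEIGHT_MEAN, phenotype_idx), _WEIGHT_SD), 40.0, 160.0
    )
    gender = (rng.random(n) < np.take(_MALE_PROP, phenotype_idx)).astype(int)
    sofa = np.clip(
        np.rint(rng.normal(np.take(_SOFA_MEAN, phenotype_idx), _SOFA_SD)), 2, 24
    ).astype(int)
    demographics = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age": age,
            "gender": gender,
            "weight_kg": weight,
            "sofa": sofa,
        }
    )

    dx_rows = []
    dx_draw = rng.random((n, n_sys))
    prev = np.take(_DX_PREVALENCE, phenotype_idx)
    for s, system in enumerate(cfg.systems):
        present = (dx_draw[:, s] < prev).astype(int)
        dx_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids,
                    "system": system,
                    "code": f"{system}_dx",
                    "present": present,
                }
            )
        )
    diagnoses = pd.concat(dx_rows, ignore_index=True)

    death = (rng.random(n) < np.take(cfg.mortality_probs, phenotype_idx)).astype(int)
    death_time = rng.uniform(0.0, _FOLLOWUP_DAYS, size=n)
    time_to_event = np.where(death == 1, death_time, _FOLLOWUP_DAYS)
    outcomes = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "death": death,
            "time_to_event_days": time_to_event,
            "censored": 1 - death,
        }
    )

    fluid_rows = []
    for window in FLUID_WINDOWS:
        mlkg = rng.lognormal(_FLUID_MLKG_LOGMEAN, _FLUID_MLKG_LOGSD, size=n)
        fluid_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids,
                    "window": window,
                    "volume_mL": mlkg * weight,
                }
            )
        )
    fluids = pd.concat(fluid_rows, ignore_index=True)

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "phenotype": [PHENOTYPE_LABELS[k] for k in phenotype_idx],
        }
    )

    return SyntheticCohort(
        events=events,
        demographics=demographics,
        diagnoses=diagnoses,
        outcomes=outcomes,
        fluids=fluids,
        truth=truth,
        config=cfg,
    )


def cross_system_correlation(
    cohort: SyntheticCohort,
    phenotype: str,
    bin_range: tuple[int, int] | None = None,
) -> float:
    """Mean absolute pairwise Pearson correlation of system-mean trajectories.

    For every patient of ``phenotype``, each system's features are averaged
    per time bin to a single trajectory; the absolute Pearson correlation is
    computed for every system pair over ``bin_range`` (1-based, inclusive)
    and averaged over pairs and patients.  A generator self-check: the
    shared-factor archetype approaches 1, independent factors stay low.
    """
    cfg = cohort.config
    T = cfg.n_bins
    lo, hi = bin_range if bin_range is not None else (1, T)
    if not 1 <= lo <= hi <= T:
        raise ValueError(f"bin_range must lie within [1, {T}]")

    ids = cohort.truth.loc[cohort.truth["phenotype"] == phenotype, "patient_id"]
    if ids.empty:
        raise ValueError(f"no patients with phenotype {phenotype!r}")

    ev = cohort.events[cohort.events["patient_id"].isin(set(ids))].copy()
    ev["bin"] = np.minimum(
        (ev["t_hours"] // cfg.bin_h).astype(int), T - 1
    )
    ev["system"] = ev["feature_id"].str.rsplit("_", n=1).str[0]
    ev = ev[(ev["bin"] >= lo - 1) & (ev["bin"] <= hi - 1)]

    traj = (
        ev.groupby(["patient_id", "system", "bin"])["value"]
        .mean()
        .unstack("bin")
    )

    vals: list[float] = []
    for _, block in traj.groupby(level="patient_id"):
        mat = block.to_numpy()
        if mat.shape[0] < 2:
            continue
        with np.errstate(invalid="ignore"):
            corr = np.ma.corrcoef(np.ma.masked_invalid(mat)).filled(np.nan)
        iu = np.triu_indices(mat.shape[0], k=1)
        pair = np.abs(corr[iu])
        pair = pair[np.isfinite(pair)]
        if pair.size:
            vals.append(float(pair.mean()))
    if not vals:
        raise ValueError("no usable trajectories in the selected bins")
    return float(np.mean(vals))
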
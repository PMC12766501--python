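"""Convenience pipeline: synthetic cohort -> tensors -> graphs -> fitted model.

Wires the stages together with the package defaults so examples, tests and
scripts share one code path.  Each stage remains available individually in
its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from odtgc.graphs import GraphDataset, encode_diagnoses, build_sequences, schema_from_feature_ids
from odtgc.model import FittedModel, ModelConfig, fit
from odtgc.preprocess import FeatureTensor, PreprocessStats, preprocess_events
from odtgc.synthcohort import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["PreparedCohort", "prepare_cohort", "fit_cohort"]

#: Diagnosis-code frequency threshold used at synthetic-cohort scale.  The
#: vocabulary rule is "more than ``min_count`` occurrences in the cohort";
#: 1000 suits registry-scale cohorts, 50 keeps the synthetic codes.
SYNTHETIC_DX_MIN_COUNT = 50


@dataclass
class PreparedCohort:
    """All aligned inputs the model consumes, plus ground truth."""

    cohort: SyntheticCohort
    tensor: FeatureTensor
    stats: PreprocessStats
    data: GraphDataset
    splits: tuple[list[str], list[str], list[str]]
    y: np.ndarray                 # death labels aligned to data.patient_ids
    truth: pd.Series              # phenotype labels aligned likewise


def prepare_cohort(
    cohort: SyntheticCohort | None = None,
    cohort_config: CohortConfig | None = None,
    dx_min_count: int = SYNTHETIC_DX_MIN_COUNT,
    split_seed: int | None = None,
) -> PreparedCohort:
    """Generate (if needed) and preprocess a cohort into graph sequences."""
    c = cohort or generate_cohort(cohort_config)
    cfg = c.config
    seed = split_seed if split_seed is not None else cfg.seed
    tensor, stats, splits = preprocess_events(
        c.events, window_h=cfg.window_h, bin_h=cfg.bin_h, seed=seed
    )
    schema = schema_from_feature_ids(tensor.feature_ids, cfg.systems)
    _, dx_vectors = encode_diagnoses(c.diagnoses, min_count=dx_min_count)
    data = build_sequences(tensor, c.demographics, dx_vectors, schema)
    outcomes = c.outcomes.set_index("patient_id")
    y = outcomes.loc[data.patient_ids, "death"].to_numpy()
    truth = c.truth.set_index("patient_id").loc[data.patient_ids, "phenotype"]
    return PreparedCohort(c, tensor, stats, data, splits, y, truth)


def fit_cohort(
    prepared: PreparedCohort,
    model_config: ModelConfig | None = None,
) -> FittedModel:
    """Train the clustering network on a prepared cohort."""
    return fit(prepared.data, prepared.y, model_config)
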
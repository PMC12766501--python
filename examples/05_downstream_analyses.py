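"""Downstream clinical analyses on the phenotype assignments.

Covers 28-day Kaplan-Meier stratification, the 4-h early phenotype
classifier, prognostic comparison against a severity score, and the
fluid-strategy heterogeneous-treatment-effect model with stabilized IPW.
"""

import numpy as np
import pandas as pd

from odtgc.downstream import (
    fit_phenotype_classifier,
    fluid_effect_model,
    fluid_records,
    km_estimate,
    prognostic_compare,
    propensity_weights,
    survival_at,
)
from odtgc.model import ModelConfig, assign
from odtgc.pipeline import fit_cohort, prepare_cohort
from odtgc.synthcohort import CohortConfig

prep = prepare_cohort(cohort_config=CohortConfig(n_patients=240, seed=11))
model = fit_cohort(prep, ModelConfig(epochs=12, pretrain_epochs=4, seed=3))
labels = np.array(list("ABC"))[
    model.centroids.risk_order[assign(model, prep.data)]
]
cohort = prep.cohort

# --- 28-day survival by assigned phenotype -------------------------------
oc = cohort.outcomes.set_index("patient_id").loc[prep.data.patient_ids]
curves = km_estimate(oc["time_to_event_days"].to_numpy(),
                     oc["death"].to_numpy(), labels)
s28 = {g: round(survival_at(c, 28.0), 3) for g, c in sorted(curves.items())}
print("28-day survival by phenotype:", s28, " (A above B above C)")

# --- early classifier on 4-h features ------------------------------------
first_bin = prep.tensor.values[:, 0, :]          # the 0-4 h bin only
demo = cohort.demographics.set_index("patient_id").loc[prep.data.patient_ids]
X4 = np.column_stack([first_bin, demo[["age", "gender", "weight_kg"]]])
clf = fit_phenotype_classifier(X4, labels, n_folds=5, seed=0, n_bootstrap=100)
print(f"4-h classifier macro AUROC {clf['auroc']:.3f} "
      f"(95% CI {clf['auroc_ci'][0]:.3f}-{clf['auroc_ci'][1]:.3f}), "
      f"AUPRC {clf['auprc']:.3f}")

# --- prognostic value vs a severity score --------------------------------
prog = prognostic_compare(
    {"phenotype": pd.Series(labels), "sofa": demo["sofa"].astype(float)},
    oc["death"].to_numpy(),
)
print(prog.round(3).to_string(index=False))
print("  (phenotype discriminates mortality better than the severity score)")

# --- fluid-strategy heterogeneous treatment effect -----------------------
rec = fluid_records(cohort.fluids, cohort.demographics, cohort.outcomes)
rec = rec.merge(demo.reset_index()[["patient_id", "age", "gender", "sofa"]],
                on="patient_id")
rec["death"] = oc.loc[rec["patient_id"], "death"].to_numpy()
rec["phenotype"] = pd.Series(labels, index=prep.data.patient_ids)[
    rec["patient_id"]].to_numpy()
covs = rec[["age", "gender", "sofa"]]
w = propensity_weights(covs.to_numpy(), rec["strategy_0_12h"].to_numpy())
print(f"\nstabilized IPW: mean {w.mean():.3f} (should be ~1), "
      f"max {w.max():.2f}")
res = fluid_effect_model(rec["death"].to_numpy(),
                         rec["strategy_0_12h"].to_numpy(),
                         rec["phenotype"].to_numpy(), covs, w)
print(res.table.round(3).to_string(index=False))
print(f"interaction LRT: stat {res.lrt_stat:.2f}, df {res.lrt_df}, "
      f"p {res.lrt_p:.3f}")
print("  (tests whether fluid-strategy effects differ across phenotypes)")
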
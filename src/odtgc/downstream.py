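"""Downstream clinical analyses built on the phenotype assignments.

* Early phenotype classification: a gradient-boosted (XGBoost) multiclass
  classifier trained on 4-h patient features against the model's phenotype
  labels, evaluated with stratified 5-fold cross-validation (one-vs-rest
  AUROC and AUPRC with bootstrap confidence intervals).
* Survival: Kaplan-Meier product-limit curves over 28 days per phenotype.
* Prognostic value: univariate logistic models per predictor compared on
  AUROC, recall, precision, F1 and specificity.
* Fluid-strategy heterogeneous treatment effects: intravenous volumes in
  the 0-12 h and 12-24 h windows are banded into three weight-indexed
  strategies (0: <30 mL/kg, 1: 30-50 mL/kg, 2: >50 mL/kg); a multinomial
  propensity model yields stabilized inverse probability weights
  Pr(T)/Pr(T|X); a weighted logistic outcome model with a
  strategy x phenotype interaction is compared against the reduced
  additive model by likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "FluidRecord",
    "WeightedModelResult",
    "fluid_strategy",
    "sofa_stratum",
    "fluid_records",
    "propensity_weights",
    "fluid_effect_model",
    "km_estimate",
    "fit_phenotype_classifier",
    "prognostic_compare",
]


# --------------------------------------------------------------------------
# fluid strategies and SOFA strata
# --------------------------------------------------------------------------
def fluid_strategy(volume_mL: float, weight_kg: float) -> int:
    """Band a fluid volume into strategy 0/1/2 by weight-indexed dose.

    <30 mL/kg -> 0 (low); 30-50 mL/kg inclusive -> 1 (moderate);
    >50 mL/kg -> 2 (high).
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if volume_mL < 0:
        raise ValueError("volume must be non-negative")
    mlkg = volume_mL / weight_kg
    if mlkg < 30.0:
        return 0
    if mlkg <= 50.0:
        return 1
    return 2


def sofa_stratum(score: int) -> str:
    """SOFA severity band: '2-6', '7-10' or '>=11' (scores below 2 are
    outside the sepsis cohort definition)."""
    score = int(score)
    if score < 2:
        raise ValueError("SOFA score below 2 is outside the cohort definition")
    if score <= 6:
        return "2-6"
    if score <= 10:
        return "7-10"
    return ">=11"


@dataclass
class FluidRecord:
    patient_id: str
    volume_0_12h_mL: float
    volume_12_24h_mL: float
    weight_kg: float
    strategy_0_12h: int = field(init=False)
    strategy_12_24h: int = field(init=False)

    def __post_init__(self) -> None:
        self.strategy_0_12h = fluid_strategy(self.volume_0_12h_mL, self.weight_kg)
        self.strategy_12_24h = fluid_strategy(self.volume_12_24h_mL, self.weight_kg)


def fluid_records(
    fluids: pd.DataFrame,
    demographics: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    min_survival_days: float = 1.0,
) -> pd.DataFrame:
    """Per-patient fluid volumes, weight and strategy bands.

    Patients who die within ``min_survival_days`` are excluded when
    ``outcomes`` is given (treatment-duration filter guarding against
    immortal-time artefacts).
    """
    wide = fluids.pivot_table(
        index="patient_id", columns="window", values="volume_mL", aggfunc="sum"
    ).rename(columns={"0-12h": "volume_0_12h_mL", "12-24h": "volume_12_24h_mL"})
    demo = demographics.set_index("patient_id")
    out = wide.join(demo[["weight_kg"]], how="inner").reset_index()
    if outcomes is not None:
        oc = outcomes.set_index("patient_id")
        survived = (oc["death"] == 0) | (oc["time_to_event_days"] >= min_survival_days)
        out = out[out["patient_id"].map(survived)].reset_index(drop=True)
    for win in ("0_12h", "12_24h"):
        out[f"strategy_{win}"] = [
            fluid_strategy(v, w)
            for v, w in zip(out[f"volume_{win}_mL"], out["weight_kg"])
        ]
    return out


# --------------------------------------------------------------------------
# stabilized inverse probability weighting
# --------------------------------------------------------------------------
def propensity_weights(
    X: np.ndarray | pd.DataFrame,
    treatment: np.ndarray,
    truncate_percentile: float | None = 99.0,
    seed: int = 0,
) -> np.ndarray:
    """Stabilized IPW for a categorical treatment.

    A multinomial logistic model of treatment on baseline covariates gives
    the denominator Pr(T = t_i | X_i); the marginal frequencies give the
    stabilising numerator Pr(T = t_i).  Weights are positive with mean ~1;
    extreme weights (near-separation) are truncated at the configured
    percentile with a logged message.
    """
    X = np.asarray(X, dtype=float)
    treatment = np.asarray(treatment)
    levels, counts = np.unique(treatment, return_counts=True)
    if len(levels) < 2:
        raise ValueError("treatment must have at least 2 observed levels")
    marginal = dict(zip(levels, counts / counts.sum()))

    Xs = StandardScaler().fit_transform(X)
    ps_model = LogisticRegression(max_iter=2000, C=1e4, random_state=seed)
    ps_model.fit(Xs, treatment)
    prob = ps_model.predict_proba(Xs)
    level_col = {lv: j for j, lv in enumerate(ps_model.classes_)}
    denom = np.array([prob[i, level_col[t]] for i, t in enumerate(treatment)])
    if np.any(denom < 1e-6):
        logger.warning("near-separation: %d propensities < 1e-6 clamped",
                       int((denom < 1e-6).sum()))
        denom = np.clip(denom, 1e-6, None)
    numer = np.array([marginal[t] for t in treatment])
    w = numer / denom
    if truncate_percentile is not None:
        cap = np.percentile(w, truncate_percentile)
        n_trunc = int((w > cap).sum())
        if n_trunc:
            logger.info("truncating %d weights above the %gth percentile",
                        n_trunc, truncate_percentile)
        w = np.minimum(w, cap)
    return w


# --------------------------------------------------------------------------
# weighted outcome model + likelihood ratio test
# --------------------------------------------------------------------------
@dataclass
class WeightedModelResult:
    table: pd.DataFrame          # term, OR, ci_low, ci_high, p
    llf_full: float
    llf_reduced: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float

    def __post_init__(self) -> None:
        if self.lrt_stat < -1e-8:
            raise ValueError("LRT statistic must be non-negative")
        self.lrt_stat = max(self.lrt_stat, 0.0)


def _design(
    strategy: np.ndarray, phenotype: np.ndarray,
    covariates: pd.DataFrame | None, interaction: bool,
) -> pd.DataFrame:
    df = pd.DataFrame({
        "strategy": pd.Categorical(strategy),
        "phenotype": pd.Categorical(phenotype),
    })
    S = pd.get_dummies(df["strategy"], prefix="strategy", drop_first=True, dtype=float)
    P = pd.get_dummies(df["phenotype"], prefix="phenotype", drop_first=True, dtype=float)
    parts = [S, P]
    if interaction:
        inter = {}
        for sc in S.columns:
            for pc in P.columns:
                inter[f"{sc}:{pc}"] = S[sc] * P[pc]
        parts.append(pd.DataFrame(inter))
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True).astype(float))
    X = pd.concat(parts, axis=1)
    X.insert(0, "intercept", 1.0)
    return X


def fluid_effect_model(
    outcome: np.ndarray,
    strategy: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    weights: np.ndarray | None = None,
) -> WeightedModelResult:
    """Weighted logistic model of mortality on strategy, phenotype and their
    interaction, with strategy 0 (low volume) as reference.

    Odds ratios carry robust (sandwich) Wald 95% CIs; the likelihood-ratio
    test compares against the reduced model without the interaction.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    weights = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    X_full = _design(strategy, phenotype, covariates, interaction=True)
    X_red = _design(strategy, phenotype, covariates, interaction=False)
    cells = pd.crosstab(strategy, phenotype)
    if (cells == 0).any().any():
        logger.warning("empty treatment-by-phenotype cell(s): %s",
                       cells[cells == 0].stack().index.tolist())

    def fit_glm(X):
        model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial(),
                       freq_weights=weights)
        res = model.fit(cov_type="HC1")
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError("weighted logistic fit failed to converge")
        return res

    full = fit_glm(X_full)
    red = fit_glm(X_red)

    se = np.sqrt(np.diag(full.cov_params()))
    coefs = full.params
    table = pd.DataFrame({
        "term": X_full.columns,
        "OR": np.exp(coefs),
        "ci_low": np.exp(coefs - 1.959963984540054 * se),
        "ci_high": np.exp(coefs + 1.959963984540054 * se),
        "p": 2 * sps.norm.sf(np.abs(coefs / se)),
    })
    lrt = 2.0 * (full.llf - red.llf)
    df = X_full.shape[1] - X_red.shape[1]
    return WeightedModelResult(
        table=table,
        llf_full=float(full.llf),
        llf_reduced=float(red.llf),
        lrt_stat=float(max(lrt, 0.0)),
        lrt_df=int(df),
        lrt_p=float(sps.chi2.sf(max(lrt, 0.0), df)) if df > 0 else 1.0,
    )


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------
def km_estimate(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit survival curves per group.

    Returns, per group label, a frame (time, survival) of the stepwise
    estimate; ``events`` is 1 for death, 0 for censoring.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival data")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    groups = np.zeros(len(times), dtype=int) if groups is None else np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        m = groups == g
        if not m.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[str(g)] = sf
    return out


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Step-function lookup S(t) on a km_estimate curve."""
    below = curve[curve["time"] <= t]
    return float(below["survival"].iloc[-1]) if len(below) else 1.0


# --------------------------------------------------------------------------
# early phenotype classifier
# --------------------------------------------------------------------------
def fit_phenotype_classifier(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    n_bootstrap: int = 200,
    max_depth: int = 4,
    n_estimators: int = 200,
    learning_rate: float = 0.1,
) -> dict:
    """Gradient-boosted multiclass phenotype classifier with stratified CV.

    Returns pooled out-of-fold one-vs-rest macro AUROC and AUPRC with
    bootstrap 95% CIs, the per-fold metrics, and a final model refit on all
    data.  Deterministic for a fixed seed.
    """
    from xgboost import XGBClassifier

    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if np.min(np.bincount(y)) < n_folds:
        raise ValueError("each class needs at least n_folds members")

    def make_model():
        return XGBClassifier(
            max_depth=max_depth, n_estimators=n_estimators,
            learning_rate=learning_rate, random_state=seed,
            eval_metric="mlogloss", n_jobs=1, verbosity=0,
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.zeros((len(y), len(classes)))
    fold_rows = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        model = make_model()
        model.fit(X[tr], y[tr])
        prob = model.predict_proba(X[te])
        oof[te] = prob
        fold_rows.append({
            "fold": f,
            "auroc": roc_auc_score(y[te], prob, multi_class="ovr", average="macro"),
            "auprc": _macro_auprc(y[te], prob, len(classes)),
        })

    auroc = roc_auc_score(y, oof, multi_class="ovr", average="macro")
    auprc = _macro_auprc(y, oof, len(classes))
    rng = np.random.default_rng(seed)
    boot_roc, boot_prc = [], []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(y), len(y))
        if len(np.unique(y[idx])) < len(classes):
            continue
        boot_roc.append(
            roc_auc_score(y[idx], oof[idx], multi_class="ovr", average="macro")
        )
        boot_prc.append(_macro_auprc(y[idx], oof[idx], len(classes)))

    final = make_model()
    final.fit(X, y)
    return {
        "classes": classes.tolist(),
        "auroc": float(auroc),
        "auroc_ci": (float(np.percentile(boot_roc, 2.5)),
                     float(np.percentile(boot_roc, 97.5))),
        "auprc": float(auprc),
        "auprc_ci": (float(np.percentile(boot_prc, 2.5)),
                     float(np.percentile(boot_prc, 97.5))),
        "folds": pd.DataFrame(fold_rows),
        "oof_proba": oof,
        "model": final,
    }


def _macro_auprc(y: np.ndarray, prob: np.ndarray, n_classes: int) -> float:
    vals = [
        average_precision_score((y == k).astype(int), prob[:, k])
        for k in range(n_classes)
    ]
    return float(np.mean(vals))


# --------------------------------------------------------------------------
# prognostic comparison
# --------------------------------------------------------------------------
def prognostic_compare(
    predictors: dict[str, np.ndarray | pd.Series],
    outcome: np.ndarray,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Univariate logistic model per predictor, compared on discrimination.

    Categorical predictors (e.g. phenotype labels) are one-hot encoded into
    a single logistic model.  Metrics: AUROC plus recall, precision, F1 and
    specificity at the probability threshold.  A lightly regularized solver
    keeps perfectly separating predictors well-defined.
    """
    y = np.asarray(outcome, dtype=int)
    rows = []
    for name, pred in predictors.items():
        s = pd.Series(pred)
        if s.nunique() < 2:
            raise ValueError(f"predictor {name!r} is constant")
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            X = pd.get_dummies(s, drop_first=True, dtype=float).to_numpy()
        else:
            X = s.to_numpy(dtype=float)[:, None]
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X, y)
        p = clf.predict_proba(X)[:, 1]
        pred_pos = p >= threshold
        tp = int(np.sum(pred_pos & (y == 1)))
        fp = int(np.sum(pred_pos & (y == 0)))
        fn = int(np.sum(~pred_pos & (y == 1)))
        tn = int(np.sum(~pred_pos & (y == 0)))
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        specificity = tn / (tn + fp) if tn + fp else 0.0
        rows.append({
            "predictor": name,
            "auroc": roc_auc_score(y, p),
            "recall": recall,
            "precision": precision,
            "f1": f1,
            "specificity": specificity,
        })
    return pd.DataFrame(rows)
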
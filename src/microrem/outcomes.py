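"""Downstream inference: Cox regression by score tertile, chi-square
association of score and LPS fold-change tertiles, and baseline
group-comparison tables.

Proportional-hazards models use lifelines with Efron tie handling and T1 as
the reference tertile; adjusted cumulative remission-probability curves are
model-based (baseline cumulative hazard evaluated at the covariate means of
each tertile). Contingency tests are Pearson chi-square without continuity
correction, which matches the convention of standard clinical baseline
tables; Yates correction is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

logger = logging.getLogger(__name__)

PRIMARY_ADJUSTMENT = (
    "age", "bmi", "gender_male", "diet_mediterranean", "hdl",
    "triglycerides", "statin_intensity",
)
EXTENDED_ADJUSTMENT = PRIMARY_ADJUSTMENT + (
    "smoking", "history_mi", "history_stroke_tia", "history_pvd",
    "hypertension", "history_cabg", "history_pci",
)


class FitError(RuntimeError):
    """Raised when a survival model cannot be estimated."""


class ContingencyTestError(ValueError):
    """Raised when a contingency test is undefined (zero margin)."""


@dataclass(frozen=True)
class CoxTertileResult:
    """Hazard ratios (T1 reference) and adjusted remission curves."""

    adjustment_set: str
    summary: pd.DataFrame  # index T2, T3; columns hr, hr_lower, hr_upper, p
    curves: pd.DataFrame  # index time; columns T1, T2, T3 (cumulative remission prob.)
    n_events: int


def cox_by_score_tertile(
    data: pd.DataFrame,
    tertiles: pd.Series,
    adjustment_set: str = "primary",
    duration_col: str = "time_years",
    event_col: str = "event",
) -> CoxTertileResult:
    """Cox proportional-hazards fit of remission on score tertile.

    ``data`` carries durations, events and adjustment covariates per sample;
    ``tertiles`` the T1/T2/T3 assignment. The extended adjustment set adds
    the cardiovascular-history covariates to the primary set.
    """
    covs = {"primary": PRIMARY_ADJUSTMENT, "extended": EXTENDED_ADJUSTMENT}.get(
        adjustment_set
    )
    if covs is None:
        raise ValueError(f"unknown adjustment set {adjustment_set!r}")
    tertiles = tertiles.reindex(data.index)
    counts = tertiles.value_counts()
    empty = [t for t in ("T1", "T2", "T3") if counts.get(t, 0) == 0]
    if empty or tertiles.isna().any():
        raise ValueError(f"empty or unassigned score tertiles: {empty}")
    missing = [c for c in covs if c not in data.columns]
    if missing:
        raise ValueError(f"adjustment covariates absent: {missing}")
    if int(data[event_col].sum()) == 0:
        raise FitError("no remission events observed; Cox model is not estimable")
    events_per_tertile = data.groupby(tertiles, observed=False)[event_col].sum()
    if (events_per_tertile == 0).any():
        logger.warning(
            "tertiles without events: %s; hazard ratios may be unstable",
            events_per_tertile[events_per_tertile == 0].index.tolist(),
        )

    design = data[[duration_col, event_col, *covs]].copy()
    design["tertile_T2"] = (tertiles == "T2").astype(float)
    design["tertile_T3"] = (tertiles == "T3").astype(float)
    # drop covariates constant in this cohort (inestimable coefficients)
    for c in list(covs):
        if design[c].nunique() < 2:
            logger.warning("dropping constant adjustment covariate %s", c)
            design = design.drop(columns=c)

    cph = None
    last_exc: Exception | None = None
    # retry with increasing ridge penalties: strongly predictive tertiles can
    # completely separate events, where the unpenalized MLE diverges
    for penalizer in (0.0, 0.1, 1.0):
        candidate = CoxPHFitter(penalizer=penalizer)
        try:
            candidate.fit(
                design,
                duration_col=duration_col,
                event_col=event_col,
                show_progress=False,
            )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
        if penalizer > 0:
            logger.warning("Cox fit required ridge penalizer %.2f", penalizer)
        cph = candidate
        break
    if cph is None:
        raise FitError(f"Cox model failed to converge: {last_exc}") from last_exc

    rows = {}
    for name, label in (("tertile_T2", "T2"), ("tertile_T3", "T3")):
        s = cph.summary.loc[name]
        rows[label] = {
            "hr": float(s["exp(coef)"]),
            "hr_lower": float(s["exp(coef) lower 95%"]),
            "hr_upper": float(s["exp(coef) upper 95%"]),
            "p": float(s["p"]),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")

    # adjusted curves at the covariate means of each tertile
    profiles = []
    for label in ("T1", "T2", "T3"):
        prof = design.loc[(tertiles == label).to_numpy()].drop(
            columns=[duration_col, event_col]
        ).mean()
        prof["tertile_T2"] = 1.0 if label == "T2" else 0.0
        prof["tertile_T3"] = 1.0 if label == "T3" else 0.0
        profiles.append(prof)
    profile_df = pd.DataFrame(profiles, index=["T1", "T2", "T3"])
    surv = cph.predict_survival_function(profile_df)
    curves = 1.0 - surv
    curves.columns = ["T1", "T2", "T3"]
    curves.index.name = "time_years"
    return CoxTertileResult(
        adjustment_set=adjustment_set,
        summary=summary,
        curves=curves,
        n_events=int(data[event_col].sum()),
    )


def lps_fold_change(lps: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Postprandial/fasting LPS ratio per subject, with tertile assignment.

    Subjects with non-positive or missing values are excluded (logged).
    Returns (fold_change, tertiles) indexed by the retained samples.
    """
    from .score import assign_tertiles, tertile_cutpoints

    fasting = lps["fasting_lps"]
    post = lps["postprandial_lps"]
    valid = (fasting > 0) & (post > 0) & fasting.notna() & post.notna()
    dropped = lps.index[~valid].tolist()
    if dropped:
        logger.warning("excluding samples with non-positive/missing LPS: %s", dropped)
    fold = (post[valid] / fasting[valid]).rename("lps_fold_change")
    lower, upper = tertile_cutpoints(fold)
    return fold, assign_tertiles(fold, lower, upper)


def chi2_test(
    table: pd.DataFrame | np.ndarray, correction: bool = False
) -> dict[str, float]:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction by default. Returns statistic, p-value and df.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ContingencyTestError("contingency table must be at least 2x2")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ContingencyTestError("contingency table must hold non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ContingencyTestError("zero row or column margin makes the test undefined")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=correction)
    return {"statistic": float(stat), "p_value": float(p), "df": int(df)}


def association_score_lps(
    score_tertiles: pd.Series, lps_tertiles: pd.Series
) -> dict[str, object]:
    """3x3 cross-tabulation of score vs LPS fold-change tertiles.

    Reports the Pearson chi-square test and a Spearman rank correlation
    between the two tertile indices as the directionality summary (the
    expected association is inverse: high score, low postprandial LPS rise).
    """
    common = score_tertiles.index.intersection(lps_tertiles.index)
    only_score = score_tertiles.index.difference(lps_tertiles.index).tolist()
    if only_score:
        logger.warning("samples without LPS tertile dropped: %s", only_score)
    if len(common) == 0:
        raise ValueError("score and LPS tertiles share no samples")
    s = score_tertiles.reindex(common).astype(str)
    l = lps_tertiles.reindex(common).astype(str)
    table = pd.crosstab(s, l).reindex(
        index=["T1", "T2", "T3"], columns=["T1", "T2", "T3"], fill_value=0
    )
    test = chi2_test(table)
    codes = {"T1": 1, "T2": 2, "T3": 3}
    rho, rho_p = stats.spearmanr(s.map(codes), l.map(codes))
    return {
        "table": table,
        "chi2": test["statistic"],
        "p_value": test["p_value"],
        "df": test["df"],
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }


def baseline_table(
    clinical: pd.DataFrame,
    labels: pd.Series,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Group comparison of baseline characteristics (mean +/- SEM style).

    Continuous variables get a two-group one-way ANOVA p-value (equivalent
    to the pooled-variance t-test); categorical variables a Pearson
    chi-square p-value. Variables with zero variance in both groups are
    reported with p = 1 and flagged.
    """
    labels = labels.reindex(clinical.index)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, got {groups}")
    if continuous is None:
        continuous = [
            c for c in clinical.columns
            if pd.api.types.is_numeric_dtype(clinical[c]) and clinical[c].nunique() > 2
        ]
    if categorical is None:
        categorical = [c for c in clinical.columns if c not in continuous]
    rows = []
    for col in continuous:
        a = clinical.loc[(labels == groups[0]).to_numpy(), col].dropna()
        b = clinical.loc[(labels == groups[1]).to_numpy(), col].dropna()
        degenerate = a.nunique() <= 1 and b.nunique() <= 1
        if degenerate:
            p = 1.0
        else:
            _, p = stats.f_oneway(a, b)
        rows.append(
            {
                "variable": col, "type": "continuous",
                f"mean_{groups[0]}": float(a.mean()),
                f"sem_{groups[0]}": float(a.sem()) if len(a) > 1 else np.nan,
                f"mean_{groups[1]}": float(b.mean()),
                f"sem_{groups[1]}": float(b.sem()) if len(b) > 1 else np.nan,
                "p_value": float(p), "degenerate": degenerate,
            }
        )
    for col in categorical:
        tab = pd.crosstab(labels, clinical[col])
        degenerate = tab.shape[1] < 2
        if degenerate:
            p = 1.0
        else:
            p = chi2_test(tab)["p_value"]
        prop = clinical.groupby(labels, observed=False)[col].mean() * 100
        rows.append(
            {
                "variable": col, "type": "categorical",
                f"mean_{groups[0]}": float(prop.get(groups[0], np.nan)),
                f"sem_{groups[0]}": np.nan,
                f"mean_{groups[1]}": float(prop.get(groups[1], np.nan)),
                f"sem_{groups[1]}": np.nan,
                "p_value": float(p), "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
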
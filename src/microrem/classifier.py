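"""Cross-validated random-forest remission classifiers.

Feature sets mirror the study design: "classic" type 2 diabetes risk
variables, OGTT-derived insulin indexes, the genus-level microbiome, and
their combinations, with the diet arm and statin-treatment intensity always
included as adjustment variables. Evaluation is stratified k-fold
cross-validation (default 10): per-fold ROC curves are vertically averaged
on a fixed specificity grid, AUC is reported mean +/- SD across folds, the
operating point is the Youden-optimal threshold on pooled out-of-fold
predictions, and variable importance is mean decrease in accuracy (MDA)
from held-out permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .profiles import AbundanceTable
from .simulate import (
    ADJUSTMENT_VARIABLES,
    CLASSIC_VARIABLES,
    OGTT_VARIABLES,
    CohortTable,
)

VARIANTS = ("classic", "ogtt", "classic_plus_ogtt", "microbiome", "combined")


class AlignmentError(ValueError):
    """Raised when sample ids disagree across input tables."""


class FoldError(ValueError):
    """Raised when the fold count exceeds the minority class size."""


class SelectionError(ValueError):
    """Raised when more top taxa are requested than genus features exist."""


@dataclass(frozen=True)
class FeatureSpec:
    """Which variables enter the design matrix.

    The adjustment variables are present in every variant.
    """

    variant: str = "combined"
    always_included: tuple[str, ...] = ADJUSTMENT_VARIABLES

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    def clinical_columns(self) -> tuple[str, ...]:
        if self.variant == "classic":
            return CLASSIC_VARIABLES
        if self.variant == "ogtt":
            return OGTT_VARIABLES
        if self.variant in ("classic_plus_ogtt", "combined"):
            return CLASSIC_VARIABLES + OGTT_VARIABLES
        return ()

    @property
    def uses_microbiome(self) -> bool:
        return self.variant in ("microbiome", "combined")


@dataclass(frozen=True)
class RfResult:
    """Cross-validation summary for one model variant."""

    variant: str
    oof_prob: pd.Series  # out-of-fold P(responder), one entry per sample
    roc_grid: pd.DataFrame  # columns: specificity, sensitivity_mean, sensitivity_sd
    auc_mean: float
    auc_sd: float
    threshold: float
    sensitivity: float
    specificity: float
    fold_assignment: pd.Series
    importance: pd.DataFrame | None = None  # columns: mda, mda_sd

    def __post_init__(self) -> None:
        for v in (self.auc_mean, self.sensitivity, self.specificity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("AUC / sensitivity / specificity must lie in [0, 1]")


def build_features(
    abundance: AbundanceTable | None,
    cohort: CohortTable,
    spec: FeatureSpec,
    impute_log: list | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the numeric design matrix and outcome vector for one variant.

    Sample order follows the cohort's clinical table; abundance rows are
    aligned to it. Missing clinical values are median-imputed (recorded in
    ``impute_log`` when given). Genus features keep their lineage-string
    column names so downstream stages can recognize them.
    """
    clinical = cohort.clinical
    y = cohort.outcomes["responder"].reindex(clinical.index)
    if y.isna().any():
        raise AlignmentError(
            f"outcomes missing for samples: {clinical.index[y.isna()].tolist()}"
        )
    wanted = list(spec.clinical_columns()) + list(spec.always_included)
    missing_cols = [c for c in wanted if c not in clinical.columns]
    if missing_cols:
        raise AlignmentError(f"clinical table lacks columns: {missing_cols}")
    X = clinical[wanted].copy()
    for col in X.columns:
        if X[col].isna().any():
            med = float(X[col].median())
            n_bad = int(X[col].isna().sum())
            X[col] = X[col].fillna(med)
            if impute_log is not None:
                impute_log.append({"column": col, "n_imputed": n_bad, "value": med})
    # one-hot encode any residual non-numeric covariates
    obj_cols = X.columns[[not pd.api.types.is_numeric_dtype(X[c]) for c in X.columns]]
    if len(obj_cols):
        X = pd.get_dummies(X, columns=list(obj_cols), drop_first=True, dtype=float)

    if spec.uses_microbiome:
        if abundance is None:
            raise AlignmentError(f"variant {spec.variant!r} requires an abundance table")
        extra = [s for s in clinical.index if s not in abundance.data.index]
        if extra:
            raise AlignmentError(f"abundance table lacks samples: {extra}")
        genus = abundance.data.reindex(clinical.index)
        X = pd.concat([X, genus], axis=1)
    return X.astype(float), y.astype(int)


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )


SPECIFICITY_GRID = np.linspace(0.0, 1.0, 101)


def cv_random_forest(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 10,
    n_trees: int = 1000,
    seed: int = 0,
    variant: str = "custom",
) -> RfResult:
    """Stratified k-fold random-forest evaluation.

    Every sample receives exactly one out-of-fold predicted probability.
    The ROC is averaged vertically (mean +/- SD of sensitivity at each point
    of a 101-point specificity grid) and AUC is reported mean +/- SD across
    folds. Deterministic for a fixed seed.
    """
    y_arr = y.to_numpy()
    minority = min(int(y_arr.sum()), int(len(y_arr) - y_arr.sum()))
    if k > minority:
        raise FoldError(f"k={k} folds exceed minority class size {minority}")
    ss = np.random.SeedSequence(seed)
    cv_seed, forest_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cv_seed)

    oof = np.full(len(y_arr), np.nan)
    fold_of = np.full(len(y_arr), -1)
    sens_curves, aucs = [], []
    for fold, (train, test) in enumerate(skf.split(X, y_arr)):
        forest = _forest(n_trees, forest_seed + fold)
        forest.fit(X.iloc[train], y_arr[train])
        prob = forest.predict_proba(X.iloc[test])[:, list(forest.classes_).index(1)]
        oof[test] = prob
        fold_of[test] = fold
        if len(np.unique(y_arr[test])) == 2:
            aucs.append(roc_auc_score(y_arr[test], prob))
            fpr, tpr, _ = roc_curve(y_arr[test], prob)
            # sensitivity at each grid specificity (= 1 - fpr)
            sens = np.interp(1.0 - SPECIFICITY_GRID, fpr, tpr)
            sens_curves.append(sens)
    sens_curves = np.array(sens_curves)
    roc_grid = pd.DataFrame(
        {
            "specificity": SPECIFICITY_GRID,
            "sensitivity_mean": sens_curves.mean(axis=0),
            "sensitivity_sd": sens_curves.std(axis=0, ddof=1),
        }
    )
    threshold, sens, spec_ = _youden_operating_point(y_arr, oof)
    return RfResult(
        variant=variant,
        oof_prob=pd.Series(oof, index=X.index, name="oof_prob"),
        roc_grid=roc_grid,
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs, ddof=1)),
        threshold=threshold,
        sensitivity=sens,
        specificity=spec_,
        fold_assignment=pd.Series(fold_of, index=X.index, name="fold"),
    )


def _youden_operating_point(y: np.ndarray, prob: np.ndarray) -> tuple[float, float, float]:
    fpr, tpr, thresholds = roc_curve(y, prob)
    j = tpr - fpr
    best = int(np.argmax(j))
    threshold = float(thresholds[best])
    pred = prob >= threshold
    pos, neg = y == 1, y == 0
    sensitivity = float(pred[pos].mean())
    specificity = float((~pred[neg]).mean())
    return threshold, sensitivity, specificity


def mda_importance(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 10,
    n_trees: int = 1000,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean decrease in accuracy by held-out permutation.

    For each fold, each feature column of the held-out split is permuted
    ``n_repeats`` times and the drop in held-out accuracy recorded; the MDA
    is the mean drop over repeats and folds (accuracy-proportion points),
    reported with its SD over fold-level means.
    """
    y_arr = y.to_numpy()
    minority = min(int(y_arr.sum()), int(len(y_arr) - y_arr.sum()))
    if k > minority:
        raise FoldError(f"k={k} folds exceed minority class size {minority}")
    ss = np.random.SeedSequence(seed)
    cv_seed, forest_seed, perm_root = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cv_seed)
    p = X.shape[1]
    X_arr = X.to_numpy(dtype=float)
    drops = np.zeros((k, p))
    for fold, (train, test) in enumerate(skf.split(X_arr, y_arr)):
        forest = _forest(n_trees, forest_seed + fold)
        forest.fit(X_arr[train], y_arr[train])
        X_test = X_arr[test]
        y_test = y_arr[test]
        base_acc = (forest.predict(X_test) == y_test).mean()
        # one batched predict per fold: stack every (feature, repeat) copy
        n_test = len(test)
        stacked = np.tile(X_test, (p * n_repeats, 1, 1))
        for f in range(p):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=perm_root, spawn_key=(fold, f))
            )
            for r in range(n_repeats):
                stacked[f * n_repeats + r, :, f] = rng.permutation(X_test[:, f])
        pred = forest.predict(stacked.reshape(-1, p)).reshape(p * n_repeats, n_test)
        acc = (pred == y_test[None, :]).mean(axis=1).reshape(p, n_repeats)
        drops[fold] = base_acc - acc.mean(axis=1)
    return pd.DataFrame(
        {"mda": drops.mean(axis=0), "mda_sd": drops.std(axis=0, ddof=1)},
        index=X.columns,
    ).rename_axis("feature")


def top_taxa(
    importance: pd.DataFrame,
    m: int = 10,
    genus_features: list[str] | None = None,
) -> pd.DataFrame:
    """The m most important genus-level features by MDA.

    Only genus features are eligible (``genus_features`` defaults to every
    feature whose name parses as a lineage with an assigned genus). Ties are
    broken lexicographically by feature name and the order is stable.
    """
    from ._taxonomy import parse_lineage

    if genus_features is None:
        genus_features = [
            f
            for f in importance.index
            if ";" in str(f) and "genus" not in parse_lineage(str(f)).missing
        ]
    eligible = importance.loc[[f for f in importance.index if f in set(genus_features)]]
    if m > len(eligible):
        raise SelectionError(
            f"requested top {m} taxa but only {len(eligible)} genus features exist"
        )
    ranked = (
        eligible.assign(_name=eligible.index.astype(str))
        .sort_values(["mda", "_name"], ascending=[False, True], kind="mergesort")
        .drop(columns="_name")
    )
    return ranked.head(m)
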
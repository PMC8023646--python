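"""The microbiome-based response prediction score.

For each of the top-m discriminant genera, a direction is set by comparing
mean baseline relative abundance between responders and nonresponders
(higher in responders -> beneficial, higher in nonresponders ->
detrimental). Each patient's abundance of the genus is coded by cohort-wide
tertiles: for a detrimental genus T1 scores +1 (protective), T2 scores 0,
T3 scores -1 (risk); for a beneficial genus the coding is reversed. The
patient's score is the sum of these signs weighted by each genus's mean
decrease in accuracy (MDA), so |score| <= sum of the MDA weights. Patients
are finally grouped into ascending score tertiles T1 < T2 < T3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import AbundanceTable, GroupingError, normalize

logger = logging.getLogger(__name__)


class DegenerateTaxonError(ValueError):
    """Raised when a taxon has too few distinct values to form tertiles."""


@dataclass(frozen=True)
class TaxonScoreRule:
    """Direction, weight and tertile cutpoints for one scored taxon."""

    taxon: str
    mda: float
    direction: str  # beneficial | detrimental | excluded
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.direction not in ("beneficial", "detrimental", "excluded"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.lower > self.upper:
            raise ValueError("tertile cutpoints must satisfy lower <= upper")


@dataclass(frozen=True)
class ScoreResult:
    """Per-patient score, per-taxon signs and ascending score tertile."""

    scores: pd.Series
    signs: pd.DataFrame  # samples x taxa, entries in {-1, 0, +1}
    tertiles: pd.Series  # labels T1/T2/T3
    rules: tuple[TaxonScoreRule, ...]

    def __post_init__(self) -> None:
        weights = pd.Series({r.taxon: r.mda for r in self.rules})
        recomputed = self.signs.mul(weights, axis=1).sum(axis=1)
        if not np.allclose(recomputed, self.scores, rtol=0, atol=0):
            raise ValueError("scores must equal the sign-weighted MDA sum exactly")
        bound = weights.abs().sum()
        if (self.scores.abs() > bound + 1e-12).any():
            raise ValueError("score exceeds the +/- sum-of-MDA bound")


def taxon_direction(
    abundance: AbundanceTable, labels: pd.Series | dict | np.ndarray
) -> pd.Series:
    """Beneficial/detrimental direction per taxon from class mean abundances.

    Labels code responders as 1 and nonresponders as 0. An exact tie of the
    class means excludes the taxon (it will contribute 0 to every score).
    """
    labels = pd.Series(labels).reindex(abundance.data.index)
    if labels.isna().any():
        raise GroupingError(
            f"labels missing for samples: {abundance.data.index[labels.isna()].tolist()}"
        )
    resp = labels == 1
    if resp.sum() == 0 or (~resp).sum() == 0:
        raise GroupingError("both responder and nonresponder classes must be non-empty")
    rel = normalize(abundance, "relative")
    mean_resp = rel.data[resp.to_numpy()].mean(axis=0)
    mean_nonresp = rel.data[(~resp).to_numpy()].mean(axis=0)
    out = pd.Series("excluded", index=rel.data.columns, dtype=object)
    out[mean_resp > mean_nonresp] = "beneficial"
    out[mean_resp < mean_nonresp] = "detrimental"
    ties = out.index[out == "excluded"].tolist()
    if ties:
        logger.warning("taxa with exactly tied class means excluded from score: %s", ties)
    return out


def tertile_cutpoints(values: pd.Series | np.ndarray) -> tuple[float, float]:
    """Empirical 1/3 and 2/3 quantiles (linear interpolation).

    Assignment downstream is: value <= lower -> T1, <= upper -> T2, else T3.
    Fewer than 3 distinct values leave tertiles undefined.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(np.unique(arr)) < 3:
        raise DegenerateTaxonError(
            f"need >= 3 distinct values to form tertiles, got {len(np.unique(arr))}"
        )
    lower, upper = np.quantile(arr, [1 / 3, 2 / 3])
    return float(lower), float(upper)


def assign_tertiles(values: pd.Series, lower: float, upper: float) -> pd.Series:
    """Map values to labels T1/T2/T3 using <=lower / <=upper boundaries."""
    arr = values.to_numpy(dtype=float)
    labels = np.where(arr <= lower, "T1", np.where(arr <= upper, "T2", "T3"))
    return pd.Series(
        pd.Categorical(labels, categories=["T1", "T2", "T3"], ordered=True),
        index=values.index,
        name=values.name,
    )


def build_score_rules(
    abundance: AbundanceTable,
    labels: pd.Series | dict | np.ndarray,
    importance: pd.DataFrame,
    taxa: list[str] | None = None,
) -> list[TaxonScoreRule]:
    """Combine directions, MDA weights and tertile cutpoints into score rules.

    ``importance`` is the MDA frame from the classifier stage (index =
    feature names, column ``mda``); ``taxa`` defaults to its full index.
    Taxa whose abundance has fewer than 3 distinct values are dropped with a
    log entry, matching the degenerate-tertile contract.
    """
    if taxa is None:
        taxa = list(importance.index)
    missing = [t for t in taxa if t not in abundance.data.columns]
    if missing:
        raise KeyError(f"rule taxa absent from abundance table: {missing}")
    rel = normalize(abundance, "relative")
    directions = taxon_direction(rel, labels)
    rules = []
    for taxon in taxa:
        try:
            lower, upper = tertile_cutpoints(rel.data[taxon])
        except DegenerateTaxonError:
            logger.warning("taxon %s dropped: fewer than 3 distinct abundances", taxon)
            continue
        rules.append(
            TaxonScoreRule(
                taxon=taxon,
                mda=float(importance.loc[taxon, "mda"]),
                direction=str(directions[taxon]),
                lower=lower,
                upper=upper,
            )
        )
    return rules


_SIGN = {
    # direction -> {tertile: sign}; protective tertiles score +1
    "detrimental": {"T1": 1, "T2": 0, "T3": -1},
    "beneficial": {"T1": -1, "T2": 0, "T3": 1},
    "excluded": {"T1": 0, "T2": 0, "T3": 0},
}


def patient_score(
    abundance: AbundanceTable, rules: list[TaxonScoreRule]
) -> ScoreResult:
    """Score every patient and assign ascending score tertiles."""
    if not rules:
        raise ValueError("at least one score rule is required")
    rel = normalize(abundance, "relative")
    missing = [r.taxon for r in rules if r.taxon not in rel.data.columns]
    if missing:
        raise KeyError(f"rule taxa absent from abundance table: {missing}")
    signs = pd.DataFrame(0, index=rel.data.index, columns=[r.taxon for r in rules])
    for rule in rules:
        tert = assign_tertiles(rel.data[rule.taxon], rule.lower, rule.upper)
        signs[rule.taxon] = tert.map(_SIGN[rule.direction]).astype(int)
    weights = pd.Series({r.taxon: r.mda for r in rules})
    scores = signs.mul(weights, axis=1).sum(axis=1)
    scores.name = "score"
    tertiles = score_tertiles(scores)
    return ScoreResult(scores=scores, signs=signs, tertiles=tertiles, rules=tuple(rules))


def score_tertiles(scores: pd.Series) -> pd.Series:
    """Ascending tertiles of the patient scores (same quantile rule as taxa).

    With fewer than 3 distinct scores the quantile rule degenerates; the
    assignment then falls back to ranks, with tied scores sharing a tertile.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 patients for score tertiles")
    try:
        lower, upper = tertile_cutpoints(scores)
    except DegenerateTaxonError:
        logger.warning("fewer than 3 distinct scores; assigning tertiles by rank")
        order = scores.rank(method="min")
        lower, upper = np.quantile(order.to_numpy(), [1 / 3, 2 / 3])
        return assign_tertiles(order, float(lower), float(upper))
    return assign_tertiles(scores, lower, upper)


def rules_frame(rules: list[TaxonScoreRule]) -> pd.DataFrame:
    """Tabular form of the rules (for rules.tsv)."""
    return pd.DataFrame(
        [
            {"taxon": r.taxon, "mda": r.mda, "direction": r.direction,
             "lower": r.lower, "upper": r.upper}
            for r in rules
        ]
    ).set_index("taxon")


def scores_frame(result: ScoreResult) -> pd.DataFrame:
    """Tabular form of per-patient scores (for scores.tsv)."""
    out = pd.DataFrame(
        {"score": result.scores, "tertile": result.tertiles.astype(str)}
    )
    signs = result.signs.add_prefix("sign:")
    return pd.concat([out, signs], axis=1).rename_axis("sample_id")
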
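"""Two-class differential abundance in the style of LDA Effect Size (LEfSe).

The procedure has two stages. A nonparametric Kruskal-Wallis screen (with
midrank tie correction; exact permutation enumeration at small combined n)
retains taxa with p below alpha. The survivors then get an effect size from
repeated regularized linear discriminant fits on class-subsampled data: per
bootstrap, the per-feature effect combines the feature's contribution along
the discriminant axis with its raw class-mean difference,

    e_f = |w_f * (m1 - m2)_proj + (m1_f - m2_f)| / 2,

averaged over bootstraps and reported as a signed log10 score on the
per-million abundance scale. Only taxa with p < alpha and |score| above the
threshold (default 2) "pass", as in standard LEfSe reporting.

This is a faithful re-implementation of the published procedure for the
two-class case (no subclass stage), not a bit-exact clone of the original
tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .profiles import AbundanceTable, GroupingError, normalize

EXACT_N_MAX = 20


class SubsamplingError(ValueError):
    """Raised when a bootstrap subsample leaves a class with < 3 members."""


@dataclass(frozen=True)
class LdaResult:
    """Per-taxon differential-abundance result."""

    taxon: str
    kw_p: float
    lda_score: float
    enriched_class: str | None
    passed: bool
    degenerate: bool = False


def _kw_h(values: np.ndarray, mask_a: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H with midrank tie correction for a two-class split.

    Returns (H, tie-correction divisor). H is 0 when all values tie.
    """
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    n_a = int(mask_a.sum())
    n_b = n - n_a
    r_a = ranks[mask_a].sum()
    r_b = ranks[~mask_a].sum()
    h = 12.0 / (n * (n + 1)) * (r_a**2 / n_a + r_b**2 / n_b) - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h, tie


def kruskal_wallis_screen(
    table: AbundanceTable,
    labels: pd.Series | dict | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon two-class Kruskal-Wallis p-values.

    For combined n <= 20 the p-value is computed by exact enumeration of all
    label assignments (rank permutations); otherwise the chi-square
    approximation with midrank tie correction is used. Constant taxa get
    p = 1 and are flagged degenerate.

    Returns a frame with columns ``kw_p``, ``significant``, ``degenerate``.
    """
    labels = pd.Series(labels).reindex(table.data.index)
    if labels.isna().any():
        raise GroupingError(
            f"labels missing for samples: {table.data.index[labels.isna()].tolist()}"
        )
    classes = sorted(labels.unique())
    if len(classes) != 2 or (labels == classes[0]).sum() == 0:
        raise GroupingError(f"need exactly two non-empty classes, got {classes}")
    mask_a = (labels == classes[0]).to_numpy()
    n = len(labels)
    exact = n <= EXACT_N_MAX

    rows = []
    values = table.values
    for j, taxon in enumerate(table.taxa):
        col = values[:, j]
        if np.all(col == col[0]):
            rows.append((taxon, 1.0, False, True))
            continue
        h_obs, tie = _kw_h(col, mask_a)
        if exact:
            p = _exact_kw_p(col, int(mask_a.sum()), h_obs)
        else:
            h_corr = h_obs / tie if tie > 0 else 0.0
            p = float(stats.chi2.sf(h_corr, df=1))
        rows.append((taxon, min(p, 1.0), p < alpha, False))
    return pd.DataFrame(
        rows, columns=["taxon", "kw_p", "significant", "degenerate"]
    ).set_index("taxon")


def _exact_kw_p(values: np.ndarray, n_a: int, h_obs: float) -> float:
    """Exact permutation p: fraction of C(n, n_a) splits with H >= observed."""
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    total = ranks.sum()
    n_b = n - n_a
    const = 12.0 / (n * (n + 1))
    count = 0
    n_splits = 0
    for idx in combinations(range(n), n_a):
        r_a = ranks[list(idx)].sum()
        r_b = total - r_a
        h = const * (r_a**2 / n_a + r_b**2 / n_b) - 3 * (n + 1)
        if h >= h_obs - 1e-12:
            count += 1
        n_splits += 1
    return count / n_splits


def lda_effect_size(
    table: AbundanceTable,
    labels: pd.Series | dict | np.ndarray,
    survivors: list[str],
    n_boot: int = 30,
    subsample_fraction: float = 2 / 3,
    seed: int = 0,
    alpha: float = 0.05,
    threshold: float = 2.0,
    kw_p: pd.Series | None = None,
) -> list[LdaResult]:
    """Bootstrap-averaged LDA effect sizes for the screened taxa.

    The table is brought to the per-million scale before fitting. Each
    bootstrap subsamples both classes without replacement at
    ``subsample_fraction`` (never below 3 per class) and fits a two-class
    linear discriminant with shrinkage-regularized covariance. The signed
    log10 score's sign encodes the enriched class: positive for the
    lexicographically first class label.
    """
    if not survivors:
        return []
    labels = pd.Series(labels).reindex(table.data.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise GroupingError(f"need exactly two classes, got {classes}")
    table = normalize(table, "per_million")
    missing = [t for t in survivors if t not in table.data.columns]
    if missing:
        raise KeyError(f"survivors absent from table: {missing}")
    X = table.data[survivors].to_numpy(dtype=float)
    y = (labels == classes[0]).to_numpy()

    n_a, n_b = int(y.sum()), int((~y).sum())
    k_a = max(3, int(round(subsample_fraction * n_a)))
    k_b = max(3, int(round(subsample_fraction * n_b)))
    if k_a > n_a or k_b > n_b:
        raise SubsamplingError(
            f"subsampling would leave a class with < 3 members (sizes {n_a}, {n_b})"
        )

    idx_a = np.flatnonzero(y)
    idx_b = np.flatnonzero(~y)
    ss = np.random.SeedSequence(seed)
    effects = np.zeros((n_boot, len(survivors)))
    for b, child in enumerate(ss.spawn(n_boot)):
        # one substream per class, assigned by sample membership (not by
        # label) so that relabeling the classes reuses identical subsamples
        s0, s1 = child.spawn(2)
        first_is_a = idx_a.min() < idx_b.min()
        rng_a = np.random.default_rng(s0 if first_is_a else s1)
        rng_b = np.random.default_rng(s1 if first_is_a else s0)
        sub = np.concatenate(
            [rng_a.choice(idx_a, size=k_a, replace=False),
             rng_b.choice(idx_b, size=k_b, replace=False)]
        )
        effects[b] = _single_lda_effect(X[sub], y[sub])
    mean_effect = effects.mean(axis=0)

    mean_a = X[y].mean(axis=0)
    mean_b = X[~y].mean(axis=0)
    sign = np.sign(mean_a - mean_b)

    kw_lookup = kw_p if kw_p is not None else pd.Series(0.0, index=survivors)
    results = []
    for f, taxon in enumerate(survivors):
        score = float(sign[f] * np.log10(max(mean_effect[f], 1.0)))
        p = float(kw_lookup.get(taxon, 0.0))
        enriched = classes[0] if score > 0 else classes[1] if score < 0 else None
        results.append(
            LdaResult(
                taxon=taxon,
                kw_p=p,
                lda_score=score,
                enriched_class=enriched,
                passed=bool(p < alpha and abs(score) > threshold),
            )
        )
    return results


def _single_lda_effect(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature effect from one regularized LDA fit."""
    m1 = X[y].mean(axis=0)
    m2 = X[~y].mean(axis=0)
    dmean = m1 - m2
    keep = X.std(axis=0) > 0
    w = np.zeros(X.shape[1])
    if keep.any():
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        try:
            lda.fit(X[:, keep], y.astype(int))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by shrinkage
            raise np.linalg.LinAlgError(
                f"singular within-class covariance on feature block {np.flatnonzero(keep)}"
            ) from exc
        coef = lda.coef_[0]
        norm = np.linalg.norm(coef)
        if norm > 0:
            w[keep] = coef / norm
    proj = float(w @ dmean)
    return np.abs(w * proj + dmean) / 2.0


def run_lefse(
    table: AbundanceTable,
    labels: pd.Series | dict | np.ndarray,
    alpha: float = 0.05,
    threshold: float = 2.0,
    n_boot: int = 30,
    subsample_fraction: float = 2 / 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Full two-stage procedure; returns one row per screened taxon.

    Columns: kw_p, lda_score, enriched_class, passed, degenerate.
    """
    table_pm = normalize(table, "per_million")
    screen = kruskal_wallis_screen(table_pm, labels, alpha=alpha)
    survivors = screen.index[screen["significant"]].tolist()
    results = lda_effect_size(
        table_pm, labels, survivors,
        n_boot=n_boot, subsample_fraction=subsample_fraction, seed=seed,
        alpha=alpha, threshold=threshold, kw_p=screen["kw_p"],
    )
    frame = screen.copy()
    frame["lda_score"] = 0.0
    frame["enriched_class"] = None
    frame["passed"] = False
    for r in results:
        frame.loc[r.taxon, ["lda_score", "enriched_class", "passed"]] = (
            r.lda_score, r.enriched_class, r.passed,
        )
    return frame[["kw_p", "lda_score", "enriched_class", "passed", "degenerate"]]


def cladogram_table(results: list[LdaResult] | pd.DataFrame) -> pd.DataFrame:
    """Rank-nested table of passed taxa for cladogram rendering.

    One row per passed taxon with its full phylum->genus path, enriched
    class and |score|-descending order (ties broken lexicographically by
    lineage).
    """
    from ._taxonomy import RANKS, parse_lineage

    if isinstance(results, pd.DataFrame):
        rows = [
            (taxon, float(r["kw_p"]), float(r["lda_score"]), r["enriched_class"])
            for taxon, r in results[results["passed"]].iterrows()
        ]
    else:
        rows = [
            (r.taxon, r.kw_p, r.lda_score, r.enriched_class)
            for r in results
            if r.passed
        ]
    records = []
    for taxon, kw_p, score, enriched in rows:
        lin = parse_lineage(taxon)
        rec = {"lineage": taxon}
        rec.update({rank: lin.rank(rank) for rank in RANKS})
        rec.update(
            {"kw_p": kw_p, "lda_score": score, "enriched_class": enriched}
        )
        records.append(rec)
    cols = ["lineage", *RANKS, "kw_p", "lda_score", "enriched_class"]
    frame = pd.DataFrame(records, columns=cols)
    if len(frame):
        frame = frame.sort_values(
            by=["lda_score", "lineage"],
            key=lambda s: s.abs() if s.name == "lda_score" else s,
            ascending=[False, True],
        ).reset_index(drop=True)
    return frame
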
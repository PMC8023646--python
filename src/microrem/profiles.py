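"""Genus-level abundance tables and within-sample (alpha) diversity.

The central container is :class:`AbundanceTable`, a sample-by-taxon
non-negative matrix whose columns are taxonomy lineage strings and whose
normalization state is tracked explicitly (``raw_counts``, ``relative`` or
``per_million``). Alpha diversity covers the canonical 16S set: observed
richness, Chao1, Shannon (natural log by default) and Simpson (1 - sum p^2),
with a Mann-Whitney two-class comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._taxonomy import Lineage, parse_lineage

REL_TOL = 1e-9
PPM_TOL = 1e-3


class FormatError(ValueError):
    """Raised when an input table violates the abundance-table contract."""


class DegenerateSampleError(ValueError):
    """Raised when a sample has zero total abundance."""


class GroupingError(ValueError):
    """Raised when a two-class comparison receives an empty class."""


@dataclass(frozen=True)
class AbundanceTable:
    """Sample-by-taxon abundance matrix with taxonomy lineages.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with lineage-string columns.
    normalization:
        One of ``raw_counts``, ``relative``, ``per_million``.
    """

    data: pd.DataFrame
    normalization: str = "relative"
    lineages: tuple[Lineage, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicated sample_ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].tolist()
            raise FormatError(f"duplicated taxa: {dup}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing value at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative abundance at sample {df.index[r]!r}, "
                f"taxon {df.columns[c]!r}: {values[r, c]}"
            )
        if self.normalization == "relative":
            bad = np.abs(values.sum(axis=1) - 1.0) > REL_TOL
            if bad.any():
                raise FormatError(
                    f"relative table rows must sum to 1: {df.index[bad].tolist()}"
                )
        elif self.normalization == "per_million":
            bad = np.abs(values.sum(axis=1) - 1e6) > PPM_TOL
            if bad.any():
                raise FormatError(
                    f"per_million table rows must sum to 1e6: {df.index[bad].tolist()}"
                )
        elif self.normalization != "raw_counts":
            raise FormatError(f"unknown normalization state {self.normalization!r}")
        object.__setattr__(
            self, "lineages", tuple(parse_lineage(c) for c in df.columns)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def genus_names(self) -> list[str]:
        return [lin.genus for lin in self.lineages]


def read_abundance(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read an abundance table from TSV (or BIOM when the reader is installed).

    The TSV dialect has ``sample_id`` as the first column and lineage strings
    as the remaining headers. The normalization state is inferred: rows
    summing to ~1 -> ``relative``, ~1e6 -> ``per_million``, all-integer
    values -> ``raw_counts``.
    """
    path = Path(path)
    if format == "biom":
        try:
            import biom  # type: ignore[import-not-found]
        except ImportError as exc:  # pragma: no cover - optional reader
            raise ImportError(
                "BIOM input requires the optional 'biom-format' package"
            ) from exc
        table = biom.load_table(str(path))
        df = table.to_dataframe(dense=True).T
        df.index.name = "sample_id"
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown format {format!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric abundance values in {path}: {exc}") from exc
    return AbundanceTable(data=df, normalization=_infer_state(values))


def _infer_state(values: np.ndarray) -> str:
    sums = values.sum(axis=1)
    if np.all(np.abs(sums - 1.0) <= REL_TOL):
        return "relative"
    if np.all(np.abs(sums - 1e6) <= PPM_TOL):
        return "per_million"
    return "raw_counts"


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_abundance`."""
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def normalize(table: AbundanceTable, target: str = "relative") -> AbundanceTable:
    """Rescale every sample to the target normalization state.

    Rescaling preserves within-sample abundance ratios; zero-sum samples are
    rejected because they have no defined composition.
    """
    if target not in ("relative", "per_million"):
        raise ValueError(f"unknown normalization target {target!r}")
    values = table.values
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = table.data.index[sums <= 0].tolist()
        raise DegenerateSampleError(f"zero-sum samples cannot be normalized: {bad}")
    scale = 1.0 if target == "relative" else 1e6
    out = values / sums[:, None] * scale
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(data=df, normalization=target)


@dataclass(frozen=True)
class AlphaDiversity:
    """Per-sample alpha-diversity indexes.

    ``chao1`` is NaN when the table is not raw counts (the estimator needs
    singleton/doubleton counts, which relative data do not carry).
    """

    frame: pd.DataFrame  # columns: observed, shannon, simpson, chao1

    def __post_init__(self) -> None:
        f = self.frame
        if (f["shannon"] < -1e-12).any():
            raise ValueError("Shannon index must be non-negative")
        if ((f["simpson"] < -1e-12) | (f["simpson"] >= 1 + 1e-12)).any():
            raise ValueError("Simpson index must lie in [0, 1)")
        chao = f["chao1"].dropna()
        if (chao + 1e-9 < f.loc[chao.index, "observed"]).any():
            raise ValueError("Chao1 must be >= observed richness")

    @property
    def indexes(self) -> list[str]:
        return [c for c in self.frame.columns if not self.frame[c].isna().all()]


def _shannon(p: np.ndarray, base: float | None) -> float:
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def alpha_diversity(table: AbundanceTable, log_base: float | None = None) -> AlphaDiversity:
    """Observed richness, Shannon, Simpson and (for counts) Chao1 per sample.

    Shannon is in nats unless ``log_base`` is given (2 for bits, 10 for dits).
    """
    values = table.values
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = table.data.index[sums <= 0].tolist()
        raise DegenerateSampleError(f"zero-sum samples have no diversity: {bad}")
    props = values / sums[:, None]
    observed = (values > 0).sum(axis=1).astype(float)
    shannon = np.array([_shannon(row, log_base) for row in props])
    simpson = 1.0 - (props**2).sum(axis=1)
    if table.normalization == "raw_counts":
        chao1 = np.array([_chao1(row) for row in values])
    else:
        chao1 = np.full(len(values), np.nan)
    frame = pd.DataFrame(
        {"observed": observed, "shannon": shannon, "simpson": simpson, "chao1": chao1},
        index=table.data.index,
    )
    return AlphaDiversity(frame=frame)


def compare_alpha(
    div: AlphaDiversity, labels: pd.Series | dict | np.ndarray
) -> pd.DataFrame:
    """Two-class Mann-Whitney U comparison of each diversity index.

    Returns a frame indexed by diversity index with the two class medians,
    the U statistic and the two-sided p-value (exact method for small
    tie-free samples, normal approximation otherwise — scipy's 'auto' rule).
    """
    labels = pd.Series(labels).reindex(div.frame.index)
    if labels.isna().any():
        raise GroupingError(
            f"labels missing for samples: {div.frame.index[labels.isna()].tolist()}"
        )
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise GroupingError(f"expected exactly two classes, got {classes}")
    rows = {}
    for index in div.indexes:
        vals = div.frame[index]
        a = vals[labels == classes[0]].to_numpy()
        b = vals[labels == classes[1]].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise GroupingError("each class needs >= 2 samples")
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows[index] = {
            f"median_{classes[0]}": float(np.median(a)),
            f"median_{classes[1]}": float(np.median(b)),
            "statistic": float(u),
            "p_value": float(p),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def subset_samples(table: AbundanceTable, sample_ids) -> AbundanceTable:
    """Row subset preserving order of ``sample_ids``."""
    missing = [s for s in sample_ids if s not in table.data.index]
    if missing:
        raise KeyError(f"samples absent from abundance table: {missing}")
    return dataclasses.replace(table, data=table.data.loc[list(sample_ids)])
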
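"""Synthetic cohorts with the statistical structure of a dietary-intervention
type 2 diabetes remission study.

The generator emulates a cohort of newly diagnosed type 2 diabetes patients
followed for five years under a dietary intervention: a compositional
genus-level gut-microbiota table with a small set of planted
responder-enriched ("beneficial") and nonresponder-enriched ("detrimental")
genera, correlated clinical covariates with realistic group mean shifts,
remission event times, and postprandial plasma LPS (lipopolysaccharide)
fold changes whose ranks are inversely coupled to the beneficial-taxon
burden through a Gaussian copula.

Model
-----
Genus abundances follow a logistic-normal composition: per-genus baseline
log-intensities are drawn once per cohort (heavy-tailed across genera), a
planted genus gets ``+log(effect_fold)`` added in its enriched group, and
per-sample log-normal noise with SD ``overdispersion`` is added before
closure to 1. "Fold change" is therefore defined pre-compositionally, on
the intensity scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import AbundanceTable

FOLLOWUP_YEARS = 5.0


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# Default covariate distributions, calibrated to the magnitudes of a
# 110-patient cohort (44 responders / 66 nonresponders): values are
# (nonresponder mean, within-group SD, responder-minus-nonresponder shift).
# SDs are on the SEM*sqrt(n) scale of such cohorts.
CONTINUOUS_COVARIATES: dict[str, tuple[float, float, float]] = {
    "age": (57.7, 9.5, 2.4),
    "weight": (88.0, 14.0, -9.8),
    "bmi": (31.7, 4.0, -2.5),
    "hdl": (1.04, 0.28, 0.08),
    "triglycerides": (1.71, 0.80, -0.11),
    "hba1c": (6.79, 0.95, -0.24),
    "glucose": (6.47, 1.40, -0.88),
    "physical_activity": (18.0, 10.0, 2.0),
    "fruit_veg": (3.0, 1.5, 0.2),
    "homa_ir": (4.76, 3.80, -0.83),
    "disposition_index": (0.46, 0.28, 0.19),
    "hepatic_ir_index": (1943.0, 1550.0, -327.0),
    "insulin_sensitivity_index": (2.47, 1.50, 0.55),
    "muscle_insulin_sensitivity_index": (2.23, 2.60, -0.49),
    "insulinogenic_index": (0.80, 1.70, 0.09),
}

# Non-negative clinical quantities are floored at a small positive value.
_FLOORS: dict[str, float] = {
    "weight": 40.0, "bmi": 16.0, "hdl": 0.3, "triglycerides": 0.3,
    "hba1c": 4.5, "glucose": 3.0, "physical_activity": 0.0, "fruit_veg": 0.0,
    "homa_ir": 0.2, "disposition_index": 0.02, "hepatic_ir_index": 100.0,
    "insulin_sensitivity_index": 0.2, "muscle_insulin_sensitivity_index": 0.02,
    "insulinogenic_index": 0.02,
}

# Bernoulli rates (responder, nonresponder).
BINARY_COVARIATES: dict[str, tuple[float, float]] = {
    "gender_male": (0.82, 0.85),
    "antihypertensive_med": (0.57, 0.68),
    "family_history_diabetes": (0.40, 0.45),
    "smoking": (0.12, 0.12),
    "hypertension": (0.61, 0.61),
    "history_mi": (0.57, 0.58),
    "history_stroke_tia": (0.045, 0.045),
    "history_pvd": (0.02, 0.06),
    "history_cabg": (0.07, 0.015),
    "history_pci": (0.91, 0.98),
    "diet_mediterranean": (0.5, 0.5),
}

# 3-level ordinal statin-treatment intensity (low/moderate/high).
STATIN_INTENSITY_PROBS = (0.15, 0.55, 0.30)

CLASSIC_VARIABLES = (
    "gender_male", "age", "bmi", "hdl", "triglycerides", "hba1c",
    "physical_activity", "fruit_veg", "antihypertensive_med",
    "family_history_diabetes",
)
OGTT_VARIABLES = (
    "homa_ir", "disposition_index", "hepatic_ir_index",
    "insulin_sensitivity_index", "muscle_insulin_sensitivity_index",
    "insulinogenic_index",
)
ADJUSTMENT_VARIABLES = ("diet_mediterranean", "statin_intensity")

# Phylum/family scaffolding for generated lineage strings.
_PHYLA = (
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``effect_fold`` is the multiplicative fold change applied to a planted
    genus's log-scale intensity in its enriched group (responders for
    beneficial genera, nonresponders for detrimental ones).
    ``overdispersion`` is the per-sample log-scale SD of genus intensities.
    ``lps_coupling`` in [-1, 0] is the target Spearman correlation between
    the postprandial LPS fold change and the per-sample beneficial-minus-
    detrimental abundance contrast.
    """

    n_subjects: int = 110
    responder_fraction: float = 0.4
    n_genera: int = 60
    n_beneficial: int = 5
    n_detrimental: int = 5
    effect_fold: float = 2.0
    overdispersion: float = 1.0
    covariate_shift: Mapping[str, float] = field(default_factory=dict)
    followup_years: float = FOLLOWUP_YEARS
    lps_coupling: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigError("responder_fraction must lie in [0, 1]")
        if self.n_genera <= 0:
            raise ConfigError("n_genera must be positive")
        if self.n_beneficial < 0 or self.n_detrimental < 0:
            raise ConfigError("n_beneficial and n_detrimental must be non-negative")
        if self.n_beneficial + self.n_detrimental > self.n_genera:
            raise ConfigError(
                "n_beneficial + n_detrimental must not exceed n_genera"
            )
        if self.effect_fold < 1.0:
            raise ConfigError("effect_fold must be >= 1")
        if self.overdispersion <= 0:
            raise ConfigError("overdispersion must be positive")
        if self.followup_years <= 0:
            raise ConfigError("followup_years must be positive")
        if not -1.0 <= self.lps_coupling <= 0.0:
            raise ConfigError("lps_coupling must lie in [-1, 0]")
        n_resp = round(self.responder_fraction * self.n_subjects)
        if min(n_resp, self.n_subjects - n_resp) < 2:
            raise ConfigError(
                "responder_fraction yields a group with fewer than 2 subjects"
            )
        unknown = set(self.covariate_shift) - set(CONTINUOUS_COVARIATES)
        if unknown:
            raise ConfigError(f"covariate_shift names unknown covariates: {sorted(unknown)}")

    @property
    def n_responders(self) -> int:
        return round(self.responder_fraction * self.n_subjects)


@dataclass(frozen=True)
class CohortTable:
    """Clinical covariates, outcomes and LPS measures, one row per sample."""

    clinical: pd.DataFrame
    outcomes: pd.DataFrame  # columns: responder, time_years, event
    lps: pd.DataFrame  # columns: fasting_lps, postprandial_lps

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def responder(self) -> pd.Series:
        return self.outcomes["responder"]


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the planted ground truth used by recovery tests."""

    abundance: AbundanceTable
    cohort: CohortTable
    truth: dict[str, dict[str, object]]

    def __post_init__(self) -> None:
        missing = [t for t in self.truth if t not in self.abundance.data.columns]
        if missing:
            raise ValueError(f"planted genera absent from abundance table: {missing}")


def _lineage_string(i: int, rng: np.random.Generator) -> str:
    phylum, class_, order, family = _PHYLA[i % len(_PHYLA)]
    return f"p__{phylum};c__{class_};o__{order};f__{family};g__Genus{i:03d}"


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort. Identical config (incl. seed) is bit-reproducible."""
    ss = np.random.SeedSequence(config.seed)
    rng_ab, rng_cov, rng_time, rng_lps = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n = config.n_subjects
    n_resp = config.n_responders
    responder = np.zeros(n, dtype=int)
    responder[:n_resp] = 1
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    taxa = [_lineage_string(i, rng_ab) for i in range(config.n_genera)]
    planted_idx = rng_ab.choice(
        config.n_genera, size=config.n_beneficial + config.n_detrimental, replace=False
    )
    beneficial = planted_idx[: config.n_beneficial]
    detrimental = planted_idx[config.n_beneficial:]

    # logistic-normal composition: heavy-tailed baseline + planted shift + noise
    base_log = rng_ab.normal(0.0, 2.0, size=config.n_genera)
    delta = np.zeros((2, config.n_genera))  # rows: nonresponder, responder
    log_fold = np.log(config.effect_fold)
    delta[1, beneficial] = log_fold
    delta[0, detrimental] = log_fold
    noise = rng_ab.normal(0.0, config.overdispersion, size=(n, config.n_genera))
    log_intensity = base_log[None, :] + delta[responder] + noise
    intensity = np.exp(log_intensity)
    abundance_values = intensity / intensity.sum(axis=1, keepdims=True)
    abundance = AbundanceTable(
        data=pd.DataFrame(abundance_values, index=sample_ids, columns=taxa).rename_axis(
            "sample_id"
        ),
        normalization="relative",
    )

    clinical = _draw_clinical(config, responder, sample_ids, rng_cov)
    outcomes = _draw_outcomes(config, responder, sample_ids, rng_time)
    lps = _draw_lps(config, abundance_values, beneficial, detrimental, sample_ids, rng_lps)

    truth = {
        taxa[i]: {"direction": "beneficial", "fold": float(config.effect_fold)}
        for i in sorted(beneficial)
    }
    truth.update(
        {
            taxa[i]: {"direction": "detrimental", "fold": float(config.effect_fold)}
            for i in sorted(detrimental)
        }
    )
    cohort = CohortTable(clinical=clinical, outcomes=outcomes, lps=lps)
    return SyntheticCohort(abundance=abundance, cohort=cohort, truth=truth)


def _draw_clinical(
    config: SimulationConfig,
    responder: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(responder)
    cols: dict[str, np.ndarray] = {}
    # one shared latent factor induces mild positive correlation among the
    # continuous metabolic covariates (equicorrelation ~0.2)
    shared = rng.normal(size=n)
    w = np.sqrt(0.2)
    for name, (nr_mean, sd, default_shift) in CONTINUOUS_COVARIATES.items():
        shift = config.covariate_shift.get(name, default_shift)
        mean = nr_mean + shift * responder
        z = w * shared + np.sqrt(1 - w**2) * rng.normal(size=n)
        vals = mean + sd * z
        floor = _FLOORS.get(name)
        if floor is not None:
            vals = np.maximum(vals, floor)
        cols[name] = vals
    for name, (p_resp, p_nonresp) in BINARY_COVARIATES.items():
        p = np.where(responder == 1, p_resp, p_nonresp)
        cols[name] = (rng.random(n) < p).astype(int)
    cols["statin_intensity"] = rng.choice(3, size=n, p=STATIN_INTENSITY_PROBS)
    return pd.DataFrame(cols, index=sample_ids).rename_axis("sample_id")


def _draw_outcomes(
    config: SimulationConfig,
    responder: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(responder)
    horizon = config.followup_years
    # remission times uniform over follow-up; nonresponders censored at horizon
    time = np.full(n, horizon, dtype=float)
    u = rng.random(n)  # drawn for all subjects to keep the stream stable
    is_resp = responder == 1
    time[is_resp] = u[is_resp] * horizon
    time[is_resp & (time == 0.0)] = horizon * 1e-9
    return pd.DataFrame(
        {"responder": responder, "time_years": time, "event": responder},
        index=sample_ids,
    ).rename_axis("sample_id")


def _draw_lps(
    config: SimulationConfig,
    abundance: np.ndarray,
    beneficial: np.ndarray,
    detrimental: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = abundance.shape[0]
    contrast = abundance[:, beneficial].sum(axis=1) - abundance[:, detrimental].sum(axis=1)
    # Gaussian copula on ranks: choose the latent Pearson rho whose implied
    # Spearman correlation equals lps_coupling
    rho = 2.0 * np.sin(np.pi * config.lps_coupling / 6.0)
    ranks = stats.rankdata(contrast, method="average")
    z_contrast = stats.norm.ppf(ranks / (n + 1))
    z_lps = rho * z_contrast + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
    fasting = np.exp(rng.normal(-1.0, 0.3, size=n))  # ~0.37 EU/ml typical
    fold = np.exp(0.45 + 0.40 * z_lps)  # postprandial rise, median ~1.6-fold
    return pd.DataFrame(
        {"fasting_lps": fasting, "postprandial_lps": fasting * fold},
        index=sample_ids,
    ).rename_axis("sample_id")


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write abundance TSV, clinical/outcomes/LPS CSVs and truth JSON.

    The directory is created on demand; a reread with :func:`read_cohort`
    round-trips exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": directory / "abundance.tsv",
        "clinical": directory / "clinical.csv",
        "outcomes": directory / "outcomes.csv",
        "lps": directory / "lps.csv",
        "truth": directory / "truth.json",
    }
    cohort.abundance.data.to_csv(paths["abundance"], sep="\t", index_label="sample_id")
    cohort.cohort.clinical.to_csv(paths["clinical"], index_label="sample_id")
    cohort.cohort.outcomes.to_csv(paths["outcomes"], index_label="sample_id")
    cohort.cohort.lps.to_csv(paths["lps"], index_label="sample_id")
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    from .profiles import read_abundance

    abundance = read_abundance(directory / "abundance.tsv", format="tsv")
    clinical = pd.read_csv(directory / "clinical.csv", index_col="sample_id")
    outcomes = pd.read_csv(directory / "outcomes.csv", index_col="sample_id")
    lps = pd.read_csv(directory / "lps.csv", index_col="sample_id")
    truth = json.loads((directory / "truth.json").read_text())
    cohort = CohortTable(clinical=clinical, outcomes=outcomes, lps=lps)
    return SyntheticCohort(abundance=abundance, cohort=cohort, truth=truth)


def simulate_tertile_survival(
    n: int,
    rate_ratio: float = 2.0,
    base_rate: float = 0.35,
    horizon: float = FOLLOWUP_YEARS,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential-hazard survival data with a known hazard ratio across tertiles.

    Subjects are split equally into tertiles T1/T2/T3 with hazards
    ``base_rate * rate_ratio**(t-1)``; events after ``horizon`` are censored.
    Used for proportional-hazards parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    tertile = np.repeat([1, 2, 3], [n - 2 * (n // 3), n // 3, n // 3])
    rate = base_rate * rate_ratio ** (tertile - 1.0)
    t = rng.exponential(1.0 / rate)
    event = (t <= horizon).astype(int)
    time = np.minimum(t, horizon)
    return pd.DataFrame(
        {
            "tertile": pd.Categorical.from_codes(tertile - 1, ["T1", "T2", "T3"]),
            "time_years": time,
            "event": event,
        },
        index=[f"S{i + 1:04d}" for i in range(n)],
    ).rename_axis("sample_id")
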
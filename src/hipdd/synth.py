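"""Synthetic municipality registry generator.

Emulates a national hospital-admission registry aggregated to an annual
municipality panel of hip-fracture incidence among residents aged 65+:
~420 municipalities with heterogeneous baseline rates and linear secular
trends, a small treated group receiving an additive rate change from the
intervention year onward, age (65-79 / 80+) and sex strata, and Poisson
(optionally overdispersed) counts.  Every quantity the estimators later
try to recover is returned as explicit ground truth, so the whole
downstream pipeline is testable without access to confidential registry
data.

Counts for municipality *i*, year *t* and stratum cell *c* are drawn as

    cases ~ Poisson( pop_c * max(m_c * (b_i + s_i*(t - t0) + delta*D_it), 0) / 1e5 )

where ``b_i`` is the municipality baseline rate per 100,000 person-years,
``s_i`` its linear slope, ``delta`` the injected additive effect,
``D_it`` the treated-and-post indicator and ``m_c`` a stratum rate
multiplier normalised so the population-weighted mean over cells is 1
(hence ``delta`` is the additive effect on the aggregate 65+ rate).

Seeding uses one master seed with per-municipality ``SeedSequence``
substreams, so enlarging the panel never perturbs existing units, and the
record-level generator consumes the count substream identically to the
panel generator: applying the case definition to a decoy-free admission
table reproduces the panel counts exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_panel",
    "simulate_admissions",
    "AGE_GROUPS",
    "SEXES",
    "ANALYSIS_STRATA",
]

#: fine population cells, in generation order
AGE_GROUPS = ("65-79", "80+")
SEXES = ("male", "female")
_CELLS = tuple((a, s) for a in AGE_GROUPS for s in SEXES)

#: the six analysis strata of the incidence panel, as (age_group, sex)
ANALYSIS_STRATA = (
    ("65+", "both"),
    ("80+", "both"),
    ("65+", "male"),
    ("65+", "female"),
    ("80+", "male"),
    ("80+", "female"),
)

# cell membership of each analysis stratum, as indices into _CELLS
_STRATUM_CELLS = {
    ("65+", "both"): (0, 1, 2, 3),
    ("80+", "both"): (2, 3),
    ("65+", "male"): (0, 2),
    ("65+", "female"): (1, 3),
    ("80+", "male"): (2,),
    ("80+", "female"): (3,),
}

# qualifying code pools the record generator samples from
_DIAGNOSES = ("S72.0", "S72.1", "S72.2")
_PROCEDURES = tuple(
    [f"NFJ{x}{y}" for x in range(10) for y in range(3)]
    + [f"NFB{x}{y}" for x in range(5) for y in range(3)]
    + ["NFB62"]
)
# non-qualifying admissions: femoral-shaft fracture, diagnosis-only,
# procedure-only, qualifying diagnosis with non-qualifying procedure,
# osteoporosis with a qualifying-looking procedure, y=3 procedure digit
_DECOYS = (
    ("S72.3", "NFJ00"),
    ("S72.0", ""),
    ("", "NFJ10"),
    ("S72.0", "NFB50"),
    ("M80.0", "NFB20"),
    ("S72.1", "NFJ93"),
)
_NOISE_CODES = ("I10", "E11.9", "M81.9", "Z50.1")


class ConfigError(ValueError):
    """A simulation configuration field violates its constraints."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic registry.

    Rates are per 100,000 person-years; populations are residents aged
    65+ per municipality, held fixed over the study window.
    """

    n_municipalities: int = 420
    n_treated: int = 15
    year_start: int = 1999
    year_end: int = 2014
    intervention_year: int = 2007  # first post-intervention year
    baseline_rate_mean: float = 1200.0
    baseline_rate_sd: float = 450.0
    trend_mean: float = -12.0
    trend_sd: float = 8.0
    #: additive change in the aggregate 65+ rate for treated units, post
    effect: float = 0.0
    population_mean: float = 1800.0
    population_sd: float = 1500.0
    population_min: float = 150.0
    #: fraction of the 65+ population aged 80+ / female
    share_80plus: float = 0.28
    share_female: float = 0.55
    #: rate ratios shaping the stratum multipliers
    rate_ratio_80plus: float = 2.25
    rate_ratio_female_male: float = 1.86
    #: variance/mean of counts; 1 = Poisson, >1 = gamma-Poisson mixture
    overdispersion: float = 1.0
    #: optional AR(1) multiplicative noise on the log rate (default off)
    ar1_rho: float = 0.0
    ar1_sigma: float = 0.0
    #: expected non-qualifying admissions per qualifying admission
    decoy_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_municipalities < 2:
            raise ConfigError("n_municipalities: need at least 2 municipalities")
        if not 0 < self.n_treated < self.n_municipalities:
            raise ConfigError("n_treated: must satisfy 0 < n_treated < n_municipalities")
        if self.year_end < self.year_start:
            raise ConfigError("year_end: must be >= year_start")
        if self.year_end > self.year_start:  # multi-year panels need a valid split
            if self.intervention_year - self.year_start < 3:
                raise ConfigError("intervention_year: need >= 3 pre-intervention years")
            if self.intervention_year > self.year_end:
                raise ConfigError("intervention_year: need >= 1 post-intervention year")
        for name in ("baseline_rate_mean", "baseline_rate_sd", "trend_sd",
                     "population_mean", "population_sd", "population_min",
                     "decoy_rate", "ar1_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative")
        for name in ("share_80plus", "share_female"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigError(f"{name}: must lie strictly in (0, 1)")
        if self.overdispersion < 1.0:
            raise ConfigError("overdispersion: must be >= 1 (1 = Poisson)")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho: must lie in [0, 1)")
        if self.share_80plus * self.rate_ratio_80plus >= 1.0:
            raise ConfigError("rate_ratio_80plus: share_80plus * ratio must be < 1")

    # -- derived structure ------------------------------------------------

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def pre_years(self) -> tuple[int, ...]:
        return tuple(range(self.year_start, self.intervention_year))

    @property
    def post_years(self) -> tuple[int, ...]:
        return tuple(range(self.intervention_year, self.year_end + 1))

    def cell_shares(self) -> np.ndarray:
        """Population share of each fine cell, in `_CELLS` order."""
        p80, pf = self.share_80plus, self.share_female
        age = {"65-79": 1 - p80, "80+": p80}
        sex = {"male": 1 - pf, "female": pf}
        return np.array([age[a] * sex[s] for a, s in _CELLS])

    def cell_multipliers(self) -> np.ndarray:
        """Stratum rate multipliers, population-weighted mean exactly 1."""
        p80, pf = self.share_80plus, self.share_female
        m_age = {"80+": self.rate_ratio_80plus,
                 "65-79": (1 - p80 * self.rate_ratio_80plus) / (1 - p80)}
        r = self.rate_ratio_female_male
        m_male = 1.0 / ((1 - pf) + pf * r)
        m_sex = {"male": m_male, "female": r * m_male}
        mult = np.array([m_age[a] * m_sex[s] for a, s in _CELLS])
        return mult / float(mult @ self.cell_shares())

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class GroundTruth:
    """The generator parameters the estimators try to recover."""

    municipality_ids: np.ndarray  # int ids, 1..N
    treated_ids: np.ndarray
    baseline: np.ndarray  # per-municipality baseline rate /100k
    slope: np.ndarray  # per-municipality linear trend /100k/yr
    population: np.ndarray  # residents 65+ per municipality
    effect: float  # additive effect on the aggregate 65+ rate; 0 for untreated
    effect_by_stratum: dict  # (age_group, sex) -> additive effect /100k


def _municipality_streams(config: SimulationConfig) -> Iterator[tuple[np.random.Generator, np.random.SeedSequence]]:
    """Per-municipality (count stream, record-detail seed) pairs.

    ``SeedSequence.spawn`` is prefix-stable, so municipality *i*'s streams
    do not depend on how many municipalities follow it.
    """
    for child in np.random.SeedSequence(config.seed).spawn(config.n_municipalities):
        core, detail = child.spawn(2)
        yield np.random.default_rng(core), detail


def _draw_counts(config: SimulationConfig):
    """Draw parameters, cell populations and counts for every municipality.

    Returns (truth, cell_pops [N,4], counts [N, n_years, 4]).  This is the
    single source of randomness shared by `simulate_panel` and
    `simulate_admissions`, which is what makes their counts identical
    under the same seed.
    """
    years = config.years
    t = years - config.year_start
    shares = config.cell_shares()
    mult = config.cell_multipliers()
    n = config.n_municipalities
    ids = np.arange(1, n + 1)
    treated_ids = ids[: config.n_treated]
    post = years >= config.intervention_year

    baseline = np.empty(n)
    slope = np.empty(n)
    pop = np.empty(n, dtype=np.int64)
    cell_pops = np.empty((n, len(_CELLS)), dtype=np.int64)
    counts = np.empty((n, len(years), len(_CELLS)), dtype=np.int64)
    detail_seeds = []

    for i, (rng, detail) in enumerate(_municipality_streams(config)):
        detail_seeds.append(detail)
        b = max(config.baseline_rate_mean + config.baseline_rate_sd * rng.standard_normal(), 0.0)
        s = config.trend_mean + config.trend_sd * rng.standard_normal()
        p = max(config.population_mean + config.population_sd * rng.standard_normal(),
                config.population_min)
        baseline[i], slope[i] = b, s
        pop[i] = int(round(p))
        cp = np.maximum(np.round(pop[i] * shares), 1).astype(np.int64)
        cell_pops[i] = cp

        delta = config.effect if ids[i] in treated_ids else 0.0
        rate = b + s * t + delta * post  # aggregate 65+ rate by year
        cell_rate = np.maximum(rate[:, None] * mult[None, :], 0.0)
        if config.ar1_rho > 0.0 or config.ar1_sigma > 0.0:
            u = np.empty(len(years))
            innov = rng.standard_normal(len(years))
            u[0] = innov[0] * config.ar1_sigma / np.sqrt(1 - config.ar1_rho**2 or 1.0)
            for j in range(1, len(years)):
                u[j] = config.ar1_rho * u[j - 1] + config.ar1_sigma * innov[j]
            cell_rate = cell_rate * np.exp(u)[:, None]
        mean = cp[None, :] * cell_rate / 1e5
        if config.overdispersion > 1.0:
            # gamma-Poisson mixture with variance = overdispersion * mean
            shape = np.where(mean > 0, mean / (config.overdispersion - 1.0), 1.0)
            g = rng.gamma(shape=shape, scale=(config.overdispersion - 1.0))
            counts[i] = rng.poisson(np.where(mean > 0, g, 0.0))
        else:
            counts[i] = rng.poisson(mean)

    effect_by_stratum = {}
    w = shares * mult
    for stratum, cells in _STRATUM_CELLS.items():
        idx = list(cells)
        effect_by_stratum[stratum] = float(config.effect * w[idx].sum() / shares[idx].sum())

    truth = GroundTruth(
        municipality_ids=ids,
        treated_ids=treated_ids,
        baseline=baseline,
        slope=slope,
        population=pop,
        effect=config.effect,
        effect_by_stratum=effect_by_stratum,
    )
    return truth, cell_pops, counts, detail_seeds


def simulate_panel(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the municipality x year x stratum incidence panel.

    Returns a long DataFrame with one row per municipality, year and
    analysis stratum (columns ``municipality_id, year, age_group, sex,
    cases, population, rate, treated``) plus the generating truth.
    Deterministic under a fixed ``config.seed``.
    """
    truth, cell_pops, counts, _ = _draw_counts(config)
    years = config.years
    n, ny = config.n_municipalities, len(years)

    frames = []
    treated_set = set(truth.treated_ids.tolist())
    for stratum, cells in _STRATUM_CELLS.items():
        idx = list(cells)
        cases = counts[:, :, idx].sum(axis=2)  # [N, ny]
        popc = cell_pops[:, idx].sum(axis=1)  # [N]
        frames.append(pd.DataFrame({
            "municipality_id": np.repeat(truth.municipality_ids, ny),
            "year": np.tile(years, n),
            "age_group": stratum[0],
            "sex": stratum[1],
            "cases": cases.ravel(),
            "population": np.repeat(popc, ny),
        }))
    panel = pd.concat(frames, ignore_index=True)
    panel["rate"] = panel["cases"] / panel["population"] * 1e5
    panel["treated"] = panel["municipality_id"].isin(treated_set)
    panel = panel.sort_values(
        ["age_group", "sex", "municipality_id", "year"], kind="stable"
    ).reset_index(drop=True)
    return panel, truth


def simulate_admissions(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate individual admission records plus the population table.

    The number of *qualifying* records per municipality-year-cell equals
    the count `simulate_panel` draws for the same seed; decoy admissions
    (non-qualifying code combinations) are added at ``config.decoy_rate``
    per expected case from an independent substream.

    Returns ``(records, populations, truth)`` where ``records`` has
    columns ``record_id, patient_id, municipality_id, year, age, sex,
    icd10_codes, procedure_codes`` (codes ';'-separated) and
    ``populations`` has ``municipality_id, year, age_group, sex,
    population``.
    """
    truth, cell_pops, counts, detail_seeds = _draw_counts(config)
    years = config.years
    mult = config.cell_multipliers()

    rows: list[tuple] = []
    for i, mid in enumerate(truth.municipality_ids):
        rng = np.random.default_rng(detail_seeds[i])
        for j, year in enumerate(years):
            rate = truth.baseline[i] + truth.slope[i] * (year - config.year_start)
            if mid in truth.treated_ids and year >= config.intervention_year:
                rate += config.effect
            for c, (age_group, sex) in enumerate(_CELLS):
                k = counts[i, j, c]
                lo, hi = (65, 80) if age_group == "65-79" else (80, 96)
                for _ in range(int(k)):
                    age = int(rng.integers(lo, hi))
                    diag = [str(rng.choice(_DIAGNOSES))]
                    proc = [str(rng.choice(_PROCEDURES))]
                    if rng.random() < 0.3:
                        diag.append(str(rng.choice(_NOISE_CODES)))
                    rows.append((mid, year, age, sex, ";".join(diag), ";".join(proc)))
                mean = cell_pops[i, c] * max(rate * mult[c], 0.0) / 1e5
                n_decoys = rng.poisson(config.decoy_rate * mean)
                for _ in range(int(n_decoys)):
                    age = int(rng.integers(lo, hi))
                    d, p = _DECOYS[int(rng.integers(len(_DECOYS)))]
                    rows.append((mid, year, age, sex, d, p))

    records = pd.DataFrame(
        rows,
        columns=["municipality_id", "year", "age", "sex",
                 "icd10_codes", "procedure_codes"],
    )
    records.insert(0, "record_id", np.arange(1, len(records) + 1))
    records.insert(1, "patient_id", [f"P{r:07d}" for r in records["record_id"]])

    pop_rows = []
    for i, mid in enumerate(truth.municipality_ids):
        for year in years:
            for c, (age_group, sex) in enumerate(_CELLS):
                pop_rows.append((mid, int(year), age_group, sex, int(cell_pops[i, c])))
    populations = pd.DataFrame(
        pop_rows,
        columns=["municipality_id", "year", "age_group", "sex", "population"],
    )
    return records, populations, truth
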
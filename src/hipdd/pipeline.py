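"""End-to-end scenario runner: simulate/load, match, estimate, pool.

A scenario reproduces the full evaluation design on one input panel:

1. obtain admission records and populations (synthetic or from CSV);
2. apply the case definition and build the six-stratum incidence panel;
3. drop municipalities with incomplete series;
4. per stratum, match the pooled treated group to cross-validated
   nearest-neighbour donors and compute DD / dynamic / IRR / CE with
   design-effect-adjusted Poisson intervals;
5. re-match and estimate per treated municipality on the primary
   stratum (65+, both sexes) and pool the log-IRRs in a fixed-effects
   meta-analysis with Cochran's Q.

Outputs are plain CSV/JSON files plus a run log; re-running with the
same configuration and seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cases, effects, matching, meta, synth

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_scenario",
           "analyse_stratum", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"
PRIMARY_STRATUM = ("65+", "both")


class PipelineError(ValueError):
    """Configuration or orchestration failure."""


_SIM_KEYS = {f.name for f in dataclasses.fields(synth.SimulationConfig)}
_MATCH_KEYS = {"k_max", "distance", "n_validation_years", "final_rank_years"}
_ANALYSIS_KEYS = {"post_start", "level", "control_variance", "ce_ci", "strata"}
_INPUT_KEYS = {"records", "population", "treated"}
_TOP_KEYS = {"simulation", "inputs", "match", "analysis", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """A validated, defaulted scenario configuration."""

    simulation: synth.SimulationConfig | None
    inputs: dict | None  # paths: records, population, treated
    k_max: int = 50
    distance: str = "level-mse"
    n_validation_years: int = 3
    final_rank_years: str = "all-pre"
    post_start: int | None = None  # default: simulation.intervention_year
    level: float = 0.95
    control_variance: str = "donor-wise"
    ce_ci: str = "independent"
    strata: tuple = synth.ANALYSIS_STRATA
    seed: int = 0


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    for key in section:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f"; did you mean '{hint[0]}'?" if hint else ""
            raise PipelineError(f"unknown key '{key}' in {where}{suffix}")


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and schema-check a YAML scenario configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise PipelineError("config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")

    sim_cfg = None
    if "inputs" in raw:
        _reject_unknown(raw["inputs"], _INPUT_KEYS, "inputs")
        missing = _INPUT_KEYS - set(raw["inputs"])
        if missing:
            raise PipelineError(f"inputs: missing key(s) {sorted(missing)}")
        inputs = {k: str(raw["inputs"][k]) for k in _INPUT_KEYS}
    else:
        inputs = None
        sim_section = raw.get("simulation", {}) or {}
        _reject_unknown(sim_section, _SIM_KEYS, "simulation")
        try:
            sim_cfg = synth.SimulationConfig(**sim_section)
        except synth.ConfigError as err:
            raise PipelineError(f"simulation: {err}") from err

    match_section = raw.get("match", {}) or {}
    _reject_unknown(match_section, _MATCH_KEYS, "match")
    analysis = raw.get("analysis", {}) or {}
    _reject_unknown(analysis, _ANALYSIS_KEYS, "analysis")

    strata = analysis.get("strata")
    if strata is None:
        strata = synth.ANALYSIS_STRATA
    else:
        strata = tuple((s[0], s[1]) for s in strata)
        for s in strata:
            if s not in synth.ANALYSIS_STRATA:
                raise PipelineError(f"analysis.strata: unknown stratum {s}")

    cfg = RunConfig(
        simulation=sim_cfg,
        inputs=inputs,
        k_max=int(match_section.get("k_max", 50)),
        distance=str(match_section.get("distance", "level-mse")),
        n_validation_years=int(match_section.get("n_validation_years", 3)),
        final_rank_years=str(match_section.get("final_rank_years", "all-pre")),
        post_start=analysis.get("post_start"),
        level=float(analysis.get("level", 0.95)),
        control_variance=str(analysis.get("control_variance", "donor-wise")),
        ce_ci=str(analysis.get("ce_ci", "independent")),
        strata=strata,
        seed=int(raw.get("seed", 0)),
    )
    if cfg.level <= 0 or cfg.level >= 1:
        raise PipelineError("analysis.level: must lie in (0, 1)")
    if cfg.n_validation_years < 1:
        raise PipelineError("match.n_validation_years: must be >= 1")
    return cfg


def _match_spec(pre_years: Sequence[int], cfg: RunConfig, mode: str) -> matching.MatchSpec:
    pre = tuple(sorted(pre_years))
    n_val = min(cfg.n_validation_years, len(pre) - 2)
    if n_val < 1:
        raise PipelineError("too few pre-intervention years for cross-validation")
    return matching.MatchSpec(
        pre_years=pre,
        validation_years=pre[-n_val:],
        k_max=cfg.k_max,
        distance=cfg.distance,
        treated_mode=mode,
        final_rank_years=cfg.final_rank_years,
    )


def analyse_stratum(
    panel: pd.DataFrame,
    age_group: str,
    sex: str,
    post_start: int,
    cfg: RunConfig,
    treated_ids: Sequence[int] | None = None,
    mode: str = "pooled",
):
    """Match and estimate one stratum; returns (EffectEstimate, MatchResult)."""
    sl = panel[(panel["age_group"] == age_group) & (panel["sex"] == sex)]
    if sl.empty:
        raise PipelineError(f"stratum ({age_group}, {sex}) not present in panel")
    years = sorted(sl["year"].unique())
    pre = [y for y in years if y < post_start]
    post = [y for y in years if y >= post_start]
    if not post:
        raise PipelineError("post_start leaves no post-intervention years")
    if treated_ids is None:
        treated_ids = sorted(sl.loc[sl["treated"], "municipality_id"].unique())
    spec = _match_spec(pre, cfg, mode)
    mres = matching.match(sl, treated_ids, spec)
    est = effects.estimate_effects(
        sl, mres, pre, post,
        level=cfg.level,
        control_variance=cfg.control_variance,
        ce_ci=cfg.ce_ci,
        age_group=age_group, sex=sex,
    )
    return est, mres


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_scenario(cfg: RunConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute a full scenario and write all result tables.

    Returns the machine-readable summary (also written as
    ``summary.json``).  ``seed`` overrides the configured seed for every
    source of randomness.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    collected_warnings: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # -- stage: inputs ------------------------------------------------
        truth = None
        if cfg.inputs is not None:
            log("stage inputs: reading CSV inputs")
            records = pd.read_csv(cfg.inputs["records"])
            populations = pd.read_csv(cfg.inputs["population"])
            treated_ids = [
                int(line)
                for line in Path(cfg.inputs["treated"]).read_text().split()
                if line.strip()
            ]
        else:
            sim = cfg.simulation.replace(seed=cfg.seed)
            log(f"stage simulate: {sim.n_municipalities} municipalities, "
                f"{sim.n_treated} treated, {sim.year_start}-{sim.year_end}, "
                f"effect {sim.effect:+g}/100k, seed {sim.seed}")
            records, populations, truth = synth.simulate_admissions(sim)
            _write_csv(records, out / "admissions.csv")
            _write_csv(populations, out / "population.csv")
            treated_ids = [int(m) for m in truth.treated_ids]
            truth_doc = {
                "effect": truth.effect,
                "effect_by_stratum": {
                    f"{a}|{s}": v for (a, s), v in truth.effect_by_stratum.items()
                },
                "treated_ids": treated_ids,
            }
            (out / "truth.json").write_text(
                json.dumps(truth_doc, indent=2, sort_keys=True) + "\n"
            )

        # -- stage: panel -------------------------------------------------
        log("stage build-panel: applying case definition")
        panel = cases.build_panel(records, populations, treated_ids)
        required_years = sorted(panel["year"].unique())
        panel, dropped = cases.completeness_filter(panel, required_years)
        log(f"stage completeness-filter: dropped {len(dropped)} municipalities")
        _write_csv(panel, out / "panel.csv")

        post_start = cfg.post_start
        if post_start is None:
            if cfg.simulation is None:
                raise PipelineError("analysis.post_start is required with CSV inputs")
            post_start = cfg.simulation.intervention_year
        if not (required_years[0] < post_start <= required_years[-1]):
            raise PipelineError(
                f"post_start {post_start} outside the panel years "
                f"{required_years[0]}-{required_years[-1]}"
            )

        # -- stage: per-stratum analyses ----------------------------------
        estimates = []
        matched_rows = []
        for age_group, sex in cfg.strata:
            est, mres = analyse_stratum(panel, age_group, sex, post_start, cfg)
            estimates.append(est)
            log(f"stage estimate ({age_group}, {sex}): n={mres.n}, "
                f"DD={est.dd:.1f}, IRR={est.irr:.3f}")
            for year in mres.treated.index:
                matched_rows.append({
                    "age_group": age_group, "sex": sex, "year": int(year),
                    "treated_rate": mres.treated.loc[year],
                    "matched_rate": mres.matched.loc[year],
                })
        table = effects.effects_table(estimates)
        _write_csv(table, out / "effects.csv")
        _write_csv(pd.DataFrame(matched_rows), out / "matched_series.csv")

        # -- stage: municipality-specific effects + meta -------------------
        age_group, sex = PRIMARY_STRATUM
        untreated_panel = panel[~panel["treated"]]
        unit_rows = []
        for mid in treated_ids:
            if mid in dropped:
                continue
            sub = pd.concat([
                panel[(panel["municipality_id"] == mid)],
                untreated_panel,
            ])
            est, mres = analyse_stratum(
                sub, age_group, sex, post_start, cfg,
                treated_ids=[mid], mode="single",
            )
            unit_rows.append({
                "municipality_id": mid,
                "log_irr": est.log_irr, "se": est.log_irr_se,
                "irr": est.irr, "irr_lo": est.irr_ci[0], "irr_hi": est.irr_ci[1],
                "dd": est.dd, "n": est.n,
            })
        unit_df = pd.DataFrame(unit_rows)
        _write_csv(unit_df, out / "municipality_effects.csv")

        mres_meta = meta.meta_analyse(
            unit_df["log_irr"], unit_df["se"], labels=unit_df["municipality_id"]
        )
        _write_csv(mres_meta.to_frame(), out / "forest.csv")
        log(f"stage meta: pooled IRR {mres_meta.pooled_irr:.3f} "
            f"({100 * (mres_meta.pooled_irr - 1):+.1f}%), "
            f"Q({mres_meta.df}) = {mres_meta.q:.2f}, p = {mres_meta.p_value:.2f}")

        collected_warnings = sorted({str(w.message) for w in wrec})

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "post_start": post_start,
        "dropped_municipalities": [int(d) for d in dropped],
        "strata": [
            {
                "age_group": e.age_group, "sex": e.sex,
                "dd": e.dd, "dd_ci": list(e.dd_ci),
                "ce": e.ce, "ce_ci": list(e.ce_ci),
                "irr": e.irr, "irr_ci": list(e.irr_ci),
                "p_value": e.p_value, "icc": e.icc, "deff": e.deff, "n": e.n,
            }
            for e in estimates
        ],
        "meta": {
            "pooled_irr": mres_meta.pooled_irr,
            "pooled_irr_ci": list(mres_meta.pooled_ci),
            "pooled_pct_change": 100 * (mres_meta.pooled_irr - 1),
            "q": mres_meta.q, "df": mres_meta.df, "p_value": mres_meta.p_value,
            "k": int(len(mres_meta.estimates)),
        },
        "true_effect": None if truth is None else truth.effect,
        "warnings": collected_warnings,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log_lines.extend(f"warning: {w}" for w in collected_warnings)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
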
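"""Scenario serialization: a single JSON document, or a directory of CSVs.

JSON is the primary interchange format: one self-contained document with
every block of the scenario (mortality, interventions, coverage, births,
risk factors).  All proportions are decimals; age bands are referenced
by their labels ("0m", "1-5m", ...).  Serialization is deterministic
(sorted keys), so serialize → parse → serialize is the identity on
content.

The CSV form writes a directory of tidy tables — interventions.csv,
coverage.csv, mortality.csv, riskfactors.csv, plus meta.csv and
births.csv for the scalars the tabular blocks have no home for — and
reads it back to an equivalent scenario.
"""

from __future__ import annotations

import json
import math
import os
from typing import Any

import pandas as pd

from .anthropometry import RelativeRiskTable
from .core import (
    AgeBand,
    Cause,
    CoverageTrajectory,
    Effect,
    FeedingConfig,
    InterventionSpec,
    MortalityProfile,
    RiskFactorConfig,
    RiskFactorEffect,
    Scenario,
    TimingTier,
)
from .herd import HerdCurve

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "save_json",
    "load_json",
    "save_csv_dir",
    "load_csv_dir",
    "load_scenario",
]


# ---------------------------------------------------------------------------
# dict form
# ---------------------------------------------------------------------------


def _band_map_to_dict(m: dict[AgeBand, Any]) -> dict[str, Any]:
    return {band.label: v for band, v in m.items()}


def _band_map_from_dict(d: dict[str, Any]) -> dict[AgeBand, Any]:
    return {AgeBand.from_label(label): v for label, v in d.items()}


def _rr_table_to_list(table: RelativeRiskTable) -> list[dict[str, Any]]:
    rows = [
        {"cause": cause, "age_band": band.label, "z_band": z, "rr": rr}
        for (cause, band, z), rr in table.rr.items()
    ]
    rows.sort(key=lambda r: (r["cause"], r["age_band"], r["z_band"]))
    return rows


def _rr_table_from_list(rows: list[dict[str, Any]]) -> RelativeRiskTable:
    return RelativeRiskTable(
        rr={
            (r["cause"], AgeBand.from_label(r["age_band"]), int(r["z_band"])): float(r["rr"])
            for r in rows
        }
    )


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Plain-dict form of a scenario, JSON-ready."""
    interventions = {}
    for iid, spec in scenario.interventions.items():
        effects = [
            {
                "cause": cause,
                "age_band": band.label,
                "effectiveness": eff.effectiveness,
                "affected_fraction": eff.affected_fraction,
            }
            for (cause, band), eff in spec.effects.items()
        ]
        effects.sort(key=lambda e: (e["cause"], e["age_band"]))
        routes = [
            {
                "factor": r.factor,
                "odds_ratio": r.odds_ratio,
                "effectiveness": r.effectiveness,
                "affected_fraction": r.affected_fraction,
            }
            for r in spec.risk_factor_effects
        ]
        interventions[iid] = {
            "tier": spec.tier.name,
            "effects": effects,
            "herd": None
            if spec.herd is None
            else {"lower": spec.herd.lower, "upper": spec.herd.upper, "max": spec.herd.max_effect},
            "risk_factor_effects": routes,
        }

    rf = scenario.risk_factors
    risk_factors = {
        "stunting_prevalence": _band_map_to_dict(rf.stunting_prevalence),
        "severe_wasting_prevalence": _band_map_to_dict(rf.severe_wasting_prevalence),
        "iugr_fraction": rf.iugr_fraction,
        "diarrhoea_episodes": _band_map_to_dict(rf.diarrhoea_episodes),
        "diarrhoea_episode_or": rf.diarrhoea_episode_or,
        "carry_or": _band_map_to_dict(rf.carry_or),
        "iugr_stunting_or": rf.iugr_stunting_or,
        "feeding": None
        if rf.feeding is None
        else {
            "odds_ratios": list(rf.feeding.odds_ratios),
            "food_secure_fraction": rf.feeding.food_secure_fraction,
        },
        "stunting_rr": None if rf.stunting_rr is None else _rr_table_to_list(rf.stunting_rr),
        "wasting_rr": None if rf.wasting_rr is None else _rr_table_to_list(rf.wasting_rr),
        "iugr_rr": dict(sorted(rf.iugr_rr.items())),
        "breastfeeding_fractions": {
            band.label: dict(sorted(fr.items()))
            for band, fr in rf.breastfeeding_fractions.items()
        },
        "breastfeeding_rr": sorted(
            (
                {"cause": c, "age_band": b.label, "category": cat, "rr": rr}
                for (c, b, cat), rr in rf.breastfeeding_rr.items()
            ),
            key=lambda r: (r["cause"], r["age_band"], r["category"]),
        ),
        "supplemental_feeding_split": None
        if rf.supplemental_feeding_split is None
        else list(rf.supplemental_feeding_split),
    }

    return {
        "name": scenario.name,
        "baseline_year": scenario.baseline_year,
        "births": {str(year): n for year, n in sorted(scenario.births.items())},
        "mortality": {
            "band_risk": _band_map_to_dict(scenario.mortality.band_risk),
            "cause_fractions": {
                band.label: dict(sorted(fr.items()))
                for band, fr in scenario.mortality.cause_fractions.items()
            },
        },
        "interventions": interventions,
        "coverage": {
            iid: {
                "baseline_year": traj.baseline_year,
                "coverage": {str(year): c for year, c in sorted(traj.coverage.items())},
            }
            for iid, traj in scenario.coverage.items()
        },
        "risk_factors": risk_factors,
    }


def scenario_from_dict(data: dict[str, Any]) -> Scenario:
    """Rebuild a scenario from its plain-dict form."""
    interventions: dict[str, InterventionSpec] = {}
    for iid, d in data.get("interventions", {}).items():
        effects = {
            (e["cause"], AgeBand.from_label(e["age_band"])): Effect(
                effectiveness=float(e["effectiveness"]),
                affected_fraction=float(e.get("affected_fraction", 1.0)),
            )
            for e in d.get("effects", [])
        }
        herd = d.get("herd")
        routes = tuple(
            RiskFactorEffect(
                factor=r["factor"],
                odds_ratio=r.get("odds_ratio"),
                effectiveness=r.get("effectiveness"),
                affected_fraction=float(r.get("affected_fraction", 1.0)),
            )
            for r in d.get("risk_factor_effects", [])
        )
        interventions[iid] = InterventionSpec(
            id=iid,
            tier=TimingTier[d["tier"]],
            effects=effects,
            herd=None
            if herd is None
            else HerdCurve(lower=herd["lower"], upper=herd["upper"], max_effect=herd["max"]),
            risk_factor_effects=routes,
        )

    coverage = {
        iid: CoverageTrajectory(
            intervention_id=iid,
            baseline_year=int(d["baseline_year"]),
            coverage={int(y): float(c) for y, c in d["coverage"].items()},
        )
        for iid, d in data.get("coverage", {}).items()
    }

    rf_data = data.get("risk_factors", {})
    feeding = rf_data.get("feeding")
    risk_factors = RiskFactorConfig(
        stunting_prevalence=_band_map_from_dict(rf_data.get("stunting_prevalence", {})),
        severe_wasting_prevalence=_band_map_from_dict(
            rf_data.get("severe_wasting_prevalence", {})
        ),
        iugr_fraction=rf_data.get("iugr_fraction"),
        diarrhoea_episodes=_band_map_from_dict(rf_data.get("diarrhoea_episodes", {})),
        diarrhoea_episode_or=rf_data.get("diarrhoea_episode_or"),
        carry_or=_band_map_from_dict(rf_data.get("carry_or", {})),
        iugr_stunting_or=rf_data.get("iugr_stunting_or"),
        feeding=None
        if feeding is None
        else FeedingConfig(
            odds_ratios=tuple(feeding["odds_ratios"]),
            food_secure_fraction=float(feeding["food_secure_fraction"]),
        ),
        stunting_rr=None
        if rf_data.get("stunting_rr") is None
        else _rr_table_from_list(rf_data["stunting_rr"]),
        wasting_rr=None
        if rf_data.get("wasting_rr") is None
        else _rr_table_from_list(rf_data["wasting_rr"]),
        iugr_rr=dict(rf_data.get("iugr_rr", {})),
        breastfeeding_fractions={
            AgeBand.from_label(label): dict(fr)
            for label, fr in rf_data.get("breastfeeding_fractions", {}).items()
        },
        breastfeeding_rr={
            (r["cause"], AgeBand.from_label(r["age_band"]), r["category"]): float(r["rr"])
            for r in rf_data.get("breastfeeding_rr", [])
        },
        supplemental_feeding_split=None
        if rf_data.get("supplemental_feeding_split") is None
        else tuple(rf_data["supplemental_feeding_split"]),
    )

    return Scenario(
        name=data["name"],
        baseline_year=int(data["baseline_year"]),
        births={int(y): float(n) for y, n in data.get("births", {}).items()},
        mortality=MortalityProfile(
            band_risk=_band_map_from_dict(data["mortality"]["band_risk"]),
            cause_fractions={
                AgeBand.from_label(label): dict(fr)
                for label, fr in data["mortality"]["cause_fractions"].items()
            },
        ),
        interventions=interventions,
        coverage=coverage,
        risk_factors=risk_factors,
    )


def save_json(scenario: Scenario, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(scenario_to_dict(scenario), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_json(path: str) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# CSV directory form
# ---------------------------------------------------------------------------

_RF_COLUMNS = [
    "record", "intervention_id", "factor", "age_band", "cause",
    "category", "z_band", "key", "value",
]


def save_csv_dir(scenario: Scenario, dirpath: str) -> None:
    """Write the scenario as a directory of tidy CSV tables."""

    def _lossless(x) -> str:  # shortest round-trip float repr
        return repr(float(x))
    os.makedirs(dirpath, exist_ok=True)
    data = scenario_to_dict(scenario)

    pd.DataFrame(
        [{"key": "name", "value": data["name"]},
         {"key": "baseline_year", "value": data["baseline_year"]}]
    ).to_csv(os.path.join(dirpath, "meta.csv"), index=False, float_format=_lossless)

    pd.DataFrame(
        [{"year": int(y), "births": n} for y, n in data["births"].items()]
    ).to_csv(os.path.join(dirpath, "births.csv"), index=False, float_format=_lossless)

    mort_rows = []
    for band_label, fractions in data["mortality"]["cause_fractions"].items():
        risk = data["mortality"]["band_risk"][band_label]
        for cause, frac in fractions.items():
            mort_rows.append(
                {"age_band": band_label, "all_cause_risk": risk, "cause": cause, "fraction": frac}
            )
    pd.DataFrame(mort_rows).to_csv(os.path.join(dirpath, "mortality.csv"), index=False, float_format=_lossless)

    int_rows = []
    for iid, d in data["interventions"].items():
        herd = d["herd"] or {}
        base = {
            "id": iid, "tier": d["tier"],
            "herd_lower": herd.get("lower"), "herd_upper": herd.get("upper"),
            "herd_max": herd.get("max"),
        }
        if d["effects"]:
            for e in d["effects"]:
                int_rows.append({**base, **e})
        else:
            int_rows.append({**base, "cause": None, "age_band": None,
                             "effectiveness": None, "affected_fraction": None})
    pd.DataFrame(int_rows).to_csv(os.path.join(dirpath, "interventions.csv"), index=False, float_format=_lossless)

    cov_rows = [
        {"intervention_id": iid, "baseline_year": d["baseline_year"], "year": int(y), "coverage": c}
        for iid, d in data["coverage"].items()
        for y, c in d["coverage"].items()
    ]
    pd.DataFrame(cov_rows).to_csv(os.path.join(dirpath, "coverage.csv"), index=False, float_format=_lossless)

    rf = data["risk_factors"]
    rows: list[dict[str, Any]] = []

    def add(record: str, value: Any, **kw: Any) -> None:
        row = {c: None for c in _RF_COLUMNS}
        row.update(record=record, value=value, **kw)
        rows.append(row)

    for key in ("iugr_fraction", "diarrhoea_episode_or", "iugr_stunting_or"):
        if rf[key] is not None:
            add("config", rf[key], key=key)
    if rf["feeding"] is not None:
        add("config", rf["feeding"]["food_secure_fraction"], key="food_secure_fraction")
        for i, o in enumerate(rf["feeding"]["odds_ratios"]):
            add("config", o, key="feeding_odds_ratio", z_band=i)
    if rf["supplemental_feeding_split"] is not None:
        for i, s in enumerate(rf["supplemental_feeding_split"]):
            add("config", s, key="supplemental_feeding_split", z_band=i)
    for record in ("stunting_prevalence", "severe_wasting_prevalence",
                   "diarrhoea_episodes", "carry_or"):
        for band_label, v in rf[record].items():
            add(record, v, age_band=band_label)
    for record in ("stunting_rr", "wasting_rr"):
        for r in rf[record] or []:
            add(record, r["rr"], cause=r["cause"], age_band=r["age_band"], z_band=r["z_band"])
    for cause, v in rf["iugr_rr"].items():
        add("iugr_rr", v, cause=cause)
    for band_label, fractions in rf["breastfeeding_fractions"].items():
        for cat, v in fractions.items():
            add("breastfeeding_fractions", v, age_band=band_label, category=cat)
    for r in rf["breastfeeding_rr"]:
        add("breastfeeding_rr", r["rr"], cause=r["cause"], age_band=r["age_band"], category=r["category"])
    for iid, d in data["interventions"].items():
        for idx, route in enumerate(d["risk_factor_effects"]):
            for key in ("odds_ratio", "effectiveness", "affected_fraction"):
                if route.get(key) is not None:
                    add("route", route[key], intervention_id=iid,
                        factor=route["factor"], z_band=idx, key=key)
    pd.DataFrame(rows, columns=_RF_COLUMNS).to_csv(
        os.path.join(dirpath, "riskfactors.csv"), index=False, float_format=_lossless
    )


def load_csv_dir(dirpath: str) -> Scenario:
    """Read a scenario back from :func:`save_csv_dir` output."""
    meta = pd.read_csv(os.path.join(dirpath, "meta.csv"), dtype={"value": str})
    meta_map = dict(zip(meta["key"], meta["value"]))
    births = pd.read_csv(os.path.join(dirpath, "births.csv"), float_precision="round_trip")
    mortality = pd.read_csv(os.path.join(dirpath, "mortality.csv"), float_precision="round_trip")
    interventions = pd.read_csv(os.path.join(dirpath, "interventions.csv"), float_precision="round_trip")
    coverage = pd.read_csv(os.path.join(dirpath, "coverage.csv"), float_precision="round_trip")
    riskfactors = pd.read_csv(os.path.join(dirpath, "riskfactors.csv"), float_precision="round_trip")

    data: dict[str, Any] = {
        "name": meta_map["name"],
        "baseline_year": int(meta_map["baseline_year"]),
        "births": {str(int(r.year)): float(r.births) for r in births.itertuples()},
    }

    band_risk: dict[str, float] = {}
    fractions: dict[str, dict[str, float]] = {}
    for r in mortality.itertuples():
        band_risk[r.age_band] = float(r.all_cause_risk)
        fractions.setdefault(r.age_band, {})[r.cause] = float(r.fraction)
    data["mortality"] = {"band_risk": band_risk, "cause_fractions": fractions}

    ints: dict[str, Any] = {}
    for r in interventions.itertuples():
        d = ints.setdefault(
            r.id,
            {
                "tier": r.tier,
                "herd": None
                if pd.isna(r.herd_lower)
                else {"lower": float(r.herd_lower), "upper": float(r.herd_upper), "max": float(r.herd_max)},
                "effects": [],
                "risk_factor_effects": [],
            },
        )
        if isinstance(r.cause, str) and r.cause:
            d["effects"].append(
                {
                    "cause": r.cause,
                    "age_band": r.age_band,
                    "effectiveness": float(r.effectiveness),
                    "affected_fraction": float(r.affected_fraction),
                }
            )
    data["interventions"] = ints

    cov: dict[str, Any] = {}
    for r in coverage.itertuples():
        d = cov.setdefault(r.intervention_id, {"baseline_year": int(r.baseline_year), "coverage": {}})
        d["coverage"][str(int(r.year))] = float(r.coverage)
    data["coverage"] = cov

    rf: dict[str, Any] = {
        "stunting_prevalence": {}, "severe_wasting_prevalence": {},
        "iugr_fraction": None, "diarrhoea_episodes": {}, "diarrhoea_episode_or": None,
        "carry_or": {}, "iugr_stunting_or": None, "feeding": None,
        "stunting_rr": None, "wasting_rr": None, "iugr_rr": {},
        "breastfeeding_fractions": {}, "breastfeeding_rr": [],
        "supplemental_feeding_split": None,
    }
    feeding_ors: dict[int, float] = {}
    food_secure: float | None = None
    split: dict[int, float] = {}
    routes: dict[str, dict[int, dict[str, Any]]] = {}
    for r in riskfactors.itertuples():
        record, value = r.record, float(r.value)
        if record == "config":
            if r.key == "feeding_odds_ratio":
                feeding_ors[int(r.z_band)] = value
            elif r.key == "food_secure_fraction":
                food_secure = value
            elif r.key == "supplemental_feeding_split":
                split[int(r.z_band)] = value
            else:
                rf[r.key] = value
        elif record in ("stunting_prevalence", "severe_wasting_prevalence",
                        "diarrhoea_episodes", "carry_or"):
            rf[record][r.age_band] = value
        elif record in ("stunting_rr", "wasting_rr"):
            rf[record] = (rf[record] or []) + [
                {"cause": r.cause, "age_band": r.age_band, "z_band": int(r.z_band), "rr": value}
            ]
        elif record == "iugr_rr":
            rf["iugr_rr"][r.cause] = value
        elif record == "breastfeeding_fractions":
            rf["breastfeeding_fractions"].setdefault(r.age_band, {})[r.category] = value
        elif record == "breastfeeding_rr":
            rf["breastfeeding_rr"].append(
                {"cause": r.cause, "age_band": r.age_band, "category": r.category, "rr": value}
            )
        elif record == "route":
            routes.setdefault(r.intervention_id, {}).setdefault(
                int(r.z_band), {"factor": r.factor}
            )[r.key] = value
    if feeding_ors and food_secure is not None:
        rf["feeding"] = {
            "odds_ratios": [feeding_ors[i] for i in sorted(feeding_ors)],
            "food_secure_fraction": food_secure,
        }
    if split:
        rf["supplemental_feeding_split"] = [split[i] for i in sorted(split)]
    for iid, by_idx in routes.items():
        data["interventions"][iid]["risk_factor_effects"] = [
            by_idx[i] for i in sorted(by_idx)
        ]
    data["risk_factors"] = rf
    return scenario_from_dict(data)


def load_scenario(path: str) -> Scenario:
    """Load a scenario from a JSON file or a CSV directory."""
    if os.path.isdir(path):
        return load_csv_dir(path)
    return load_json(path)
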
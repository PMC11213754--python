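"""Percent-biodegradation computation and the end-to-end study pipeline.

Anaerobic biodegradation is the measured methane yield per gram of polymer
over its theoretical potential (BMP basis); aerobic biodegradation is the
blank-corrected oxygen consumed per gram over the theoretical oxygen demand
(ThOD basis). Both are reported as mean +/- SD over replicate bottles.
Values above 100% are reported unmodified and flagged, never truncated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gas as gasmod
from .gas import BottleSpec, FlushEvent, GasAccountingError, GasCurve, GasReading
from .stoichiometry import (
    ElementalFormula,
    TheoreticalPotentials,
    load_registry,
    parse_formula,
    potentials,
)

__all__ = [
    "PipelineError",
    "AssayGroup",
    "BiodegradationResult",
    "InoculumValidation",
    "VALIDATION_BAND",
    "biodegradation_anaerobic",
    "biodegradation_aerobic",
    "validate_inoculum",
    "load_config",
    "build_groups",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger(__name__)

#: inclusive anaerobic cellulose-control acceptance band, percent of theoretical
VALIDATION_BAND = (82.0, 95.0)

_CONDITION_MODE = {
    "anaerobic": "methane_production",
    "aerobic": "oxygen_consumption",
}


class PipelineError(ValueError):
    pass


@dataclass
class AssayGroup:
    """One assay condition: replicate sample bottles plus their blanks."""

    label: str
    condition: str  # "anaerobic" | "aerobic"
    polymer: ElementalFormula
    plastic_mass_g: float
    bottle: BottleSpec
    sample_curves: list[GasCurve]
    blank_curves: list[GasCurve]
    polymer_name: str = ""
    role: str = "sample"  # "sample" | "control"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in _CONDITION_MODE:
            raise PipelineError(f"unknown condition {self.condition!r}")
        if self.plastic_mass_g <= 0:
            raise PipelineError("plastic mass must be > 0 g")
        mode = _CONDITION_MODE[self.condition]
        for c in self.sample_curves + self.blank_curves:
            if c.mode != mode:
                raise PipelineError(
                    f"group {self.label!r}: curve mode {c.mode!r} does not match "
                    f"condition {self.condition!r}"
                )
        if len(self.sample_curves) != 3:
            self.warnings.append(
                f"group {self.label!r}: {len(self.sample_curves)} sample "
                "replicates (3 expected)"
            )


@dataclass(frozen=True)
class BiodegradationResult:
    """Percent biodegradation for one assay group."""

    label: str
    percent_mean: float
    percent_sd: float | None
    basis: str  # "BMP" | "ThOD"
    measured_per_g: float  # mean BMPexp (L/g) or O2 consumed (g/g)
    horizon_days: float
    replicate_percents: tuple[float, ...]
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "percent_mean": self.percent_mean,
            "percent_sd": self.percent_sd,
            "basis": self.basis,
            "measured_per_g": self.measured_per_g,
            "horizon_days": self.horizon_days,
            "replicate_percents": list(self.replicate_percents),
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class InoculumValidation:
    """Cellulose-control check: anaerobic pass/fail, aerobic descriptive only."""

    label: str
    condition: str
    percent_mean: float
    percent_sd: float | None
    passed: bool | None
    band: tuple[float, float] = VALIDATION_BAND


def _corrected_finals(group: AssayGroup, *, blank_corrected: bool) -> list[GasCurve]:
    if blank_corrected:
        if not group.blank_curves:
            raise PipelineError(f"group {group.label!r}: no blank curves")
        return [
            gasmod.blank_correct(c, group.blank_curves, end_hold=True)
            for c in group.sample_curves
        ]
    return list(group.sample_curves)


def _summarize(
    label: str,
    percents: list[float],
    basis: str,
    measured: list[float],
    horizon: float,
    flags: list[str],
) -> BiodegradationResult:
    mean = float(np.mean(percents))
    sd = float(np.std(percents, ddof=1)) if len(percents) > 1 else None
    if len(percents) < 2:
        flags = flags + ["single_replicate: SD undefined"]
    if mean > 100.0:
        flags = flags + ["exceeds_100_percent"]
    return BiodegradationResult(
        label=label,
        percent_mean=mean,
        percent_sd=sd,
        basis=basis,
        measured_per_g=float(np.mean(measured)),
        horizon_days=horizon,
        replicate_percents=tuple(percents),
        flags=tuple(flags),
    )


def biodegradation_anaerobic(
    group: AssayGroup,
    pots: TheoreticalPotentials,
    *,
    blank_corrected: bool = True,
) -> BiodegradationResult:
    """Percent biodegradation on the BMP basis.

    Per replicate: BMPexp = final blank-corrected cumulative CH4 (L STP) per
    g polymer; percent = 100 * BMPexp / BMP_theoric.
    """
    if group.condition != "anaerobic":
        raise PipelineError(f"group {group.label!r} is not anaerobic")
    if not group.sample_curves:
        raise PipelineError(f"group {group.label!r}: no sample curves")
    if pots.bmp_theoric <= 0:
        raise PipelineError("theoretical BMP must be > 0")
    curves = _corrected_finals(group, blank_corrected=blank_corrected)
    flags = sorted({f for c in curves for f in c.flags}) + group.warnings
    bmp_exp = [c.final_value / group.plastic_mass_g for c in curves]
    percents = [100.0 * v / pots.bmp_theoric for v in bmp_exp]
    horizon = max(c.horizon_days for c in curves)
    return _summarize(group.label, percents, "BMP", bmp_exp, horizon, flags)


def biodegradation_aerobic(
    group: AssayGroup,
    pots: TheoreticalPotentials,
    *,
    blank_corrected: bool = True,
) -> BiodegradationResult:
    """Percent biodegradation on the ThOD basis.

    Per replicate: net O2 consumed (g, blank-corrected) per g polymer,
    divided by ThOD, times 100.
    """
    if group.condition != "aerobic":
        raise PipelineError(f"group {group.label!r} is not aerobic")
    if not group.sample_curves:
        raise PipelineError(f"group {group.label!r}: no sample curves")
    if pots.thod is None or pots.thod <= 0:
        raise PipelineError("theoretical oxygen demand must be > 0")
    curves = _corrected_finals(group, blank_corrected=blank_corrected)
    flags = sorted({f for c in curves for f in c.flags}) + group.warnings
    o2_per_g = [
        gasmod.o2_liters_to_grams(c.final_value) / group.plastic_mass_g
        for c in curves
    ]
    percents = [100.0 * v / pots.thod for v in o2_per_g]
    horizon = max(c.horizon_days for c in curves)
    return _summarize(group.label, percents, "ThOD", o2_per_g, horizon, flags)


def validate_inoculum(
    group: AssayGroup,
    pots: TheoreticalPotentials,
    *,
    blank_corrected: bool = True,
) -> InoculumValidation:
    """Check a cellulose-control group against the validation band.

    The anaerobic criterion (conversion to methane within [82, 95]% of
    theoretical, inclusive) yields pass/fail; aerobic controls have no
    published band and are reported descriptively (``passed=None``).
    """
    if group.condition == "anaerobic":
        res = biodegradation_anaerobic(group, pots, blank_corrected=blank_corrected)
        lo, hi = VALIDATION_BAND
        passed: bool | None = lo <= res.percent_mean <= hi
    else:
        res = biodegradation_aerobic(group, pots, blank_corrected=blank_corrected)
        passed = None
    return InoculumValidation(
        label=group.label,
        condition=group.condition,
        percent_mean=res.percent_mean,
        percent_sd=res.percent_sd,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# config-driven execution


def load_config(source: str | Path | dict) -> dict:
    """Load a run config from YAML/JSON path or pass a dict through."""
    if isinstance(source, dict):
        return source
    text = Path(source).read_text()
    if str(source).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _read_gas_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"bottle_id", "time_days", "gas", "mole_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"gas CSV missing columns: {sorted(missing)}")
    return df


def _readings_for(df: pd.DataFrame, bottle_id: str, gas_name: str) -> list[GasReading]:
    rows = df[(df["bottle_id"] == bottle_id) & (df["gas"] == gas_name)]
    if rows.empty:
        raise PipelineError(f"no {gas_name} readings for bottle {bottle_id!r}")
    rows = rows.sort_values("time_days")
    has_p = "pressure_pa" in rows.columns
    return [
        GasReading(
            time_days=float(r.time_days),
            mole_fraction=float(r.mole_fraction),
            pressure_pa=(
                float(r.pressure_pa)
                if has_p and pd.notna(getattr(r, "pressure_pa", None))
                else None
            ),
        )
        for r in rows.itertuples()
    ]


def _flushes_for(df: pd.DataFrame | None, bottle_id: str) -> list[FlushEvent]:
    if df is None:
        return []
    rows = df[df["bottle_id"] == bottle_id].sort_values("time_days")
    return [
        FlushEvent(
            time_days=float(r.time_days),
            post_flush_fraction=float(r.post_flush_fraction),
            post_flush_pressure_pa=float(r.post_flush_pressure_pa),
        )
        for r in rows.itertuples()
    ]


def _curve_for_bottle(
    condition: str,
    bottle: BottleSpec,
    gas_df: pd.DataFrame,
    flush_df: pd.DataFrame | None,
    bottle_id: str,
) -> GasCurve:
    if condition == "anaerobic":
        return gasmod.cumulative_methane(bottle, _readings_for(gas_df, bottle_id, "CH4"))
    return gasmod.cumulative_o2_consumed(
        bottle,
        _readings_for(gas_df, bottle_id, "O2"),
        _flushes_for(flush_df, bottle_id),
    )


def _load_study_parts(config: dict, base_dir: str | Path):
    base = Path(base_dir)
    registry = dict(load_registry())
    for name, formula in (config.get("polymers") or {}).items():
        registry[name] = parse_formula(formula)
    bottles = {
        name: BottleSpec(**spec) for name, spec in (config.get("bottles") or {}).items()
    }
    gas_df = _read_gas_table(base / config["gas_readings"])
    flush_df = None
    if config.get("flush_events"):
        flush_df = pd.read_csv(base / config["flush_events"])
    return registry, bottles, gas_df, flush_df


def _build_group(
    g: dict,
    registry: dict[str, ElementalFormula],
    bottles: dict[str, BottleSpec],
    gas_df: pd.DataFrame,
    flush_df: pd.DataFrame | None,
) -> AssayGroup:
    polymer_name = g["polymer"]
    if polymer_name not in registry:
        raise PipelineError(f"unknown polymer {polymer_name!r}")
    bottle = bottles[g["bottle"]]
    condition = g["condition"]
    sample_curves = [
        _curve_for_bottle(condition, bottle, gas_df, flush_df, b)
        for b in g["sample_bottles"]
    ]
    blank_curves = [
        _curve_for_bottle(condition, bottle, gas_df, flush_df, b)
        for b in g.get("blank_bottles", [])
    ]
    return AssayGroup(
        label=g["label"],
        condition=condition,
        polymer=registry[polymer_name],
        polymer_name=polymer_name,
        plastic_mass_g=float(g["plastic_mass_g"]),
        bottle=bottle,
        sample_curves=sample_curves,
        blank_curves=blank_curves,
        role=g.get("role", "sample"),
    )


def build_groups(config: dict, base_dir: str | Path = ".") -> list[AssayGroup]:
    """Instantiate assay groups from a run config.

    The config maps polymer names to formulas (merged over the built-in
    registry), names bottle specs, points at the gas-readings CSV (columns
    bottle_id, time_days, gas, mole_fraction[, pressure_pa]) and optional
    flush-events CSV, and lists groups referencing those parts by name.
    """
    registry, bottles, gas_df, flush_df = _load_study_parts(config, base_dir)
    return [
        _build_group(g, registry, bottles, gas_df, flush_df)
        for g in config.get("groups") or []
    ]


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path | None = None,
    *,
    base_dir: str | Path | None = None,
) -> dict:
    """Execute the full study: stoichiometry -> curves -> blank correction ->
    percent biodegradation for every group, controls validated.

    Per-group failures are recorded under ``errors`` and do not stop the
    remaining groups. Returns the report dict; with ``out_dir`` also writes
    results.json, results.csv and warnings.log.
    """
    cfg = load_config(config)
    if base_dir is None:
        base_dir = Path(config).parent if isinstance(config, (str, Path)) else "."
    blank_corrected = bool(cfg.get("blank_correct", True))
    report: dict = {"results": [], "validation": [], "warnings": [], "errors": []}
    groups: list[AssayGroup] = []
    try:
        registry, bottles, gas_df, flush_df = _load_study_parts(cfg, base_dir)
    except (PipelineError, GasAccountingError, KeyError, FileNotFoundError) as exc:
        report["errors"].append({"stage": "load_inputs", "error": str(exc)})
    else:
        for g in cfg.get("groups") or []:
            try:
                groups.append(_build_group(g, registry, bottles, gas_df, flush_df))
            except (PipelineError, GasAccountingError, KeyError) as exc:
                report["errors"].append(
                    {
                        "stage": "build_group",
                        "group": g.get("label", "?"),
                        "error": str(exc),
                    }
                )
    if not groups and not report["errors"]:
        report["warnings"].append("empty group list: nothing to compute")
    curve_rows: list[dict] = []
    for group in groups:
        for kind, curves in (("sample", group.sample_curves), ("blank", group.blank_curves)):
            if not curves:
                continue
            try:
                agg = gasmod.aggregate_replicates(curves)
            except GasAccountingError as exc:
                report["warnings"].append(
                    f"group {group.label!r}: could not aggregate {kind} curves: {exc}"
                )
                continue
            for i, t in enumerate(agg.times):
                curve_rows.append(
                    {
                        "label": group.label,
                        "kind": kind,
                        "time_days": float(t),
                        "cumulative_L_STP": float(agg.mean[i]),
                        "sd": float(agg.sd[i]) if agg.sd is not None else None,
                    }
                )
    report["curves"] = curve_rows
    for group in groups:
        pots = potentials(group.polymer)
        try:
            if group.role == "control":
                val = validate_inoculum(group, pots, blank_corrected=blank_corrected)
                report["validation"].append(
                    {
                        "label": val.label,
                        "condition": val.condition,
                        "percent_mean": val.percent_mean,
                        "percent_sd": val.percent_sd,
                        "passed": val.passed,
                        "band": list(val.band),
                    }
                )
                if val.passed is None:
                    report["warnings"].append(
                        f"control {group.label!r}: no published aerobic band; "
                        "descriptive only"
                    )
                continue
            if group.condition == "anaerobic":
                res = biodegradation_anaerobic(
                    group, pots, blank_corrected=blank_corrected
                )
            else:
                res = biodegradation_aerobic(
                    group, pots, blank_corrected=blank_corrected
                )
            rec = res.to_dict()
            rec.update(
                {"condition": group.condition, "polymer": group.polymer_name or str(group.polymer)}
            )
            report["results"].append(rec)
            for fl in res.flags:
                report["warnings"].append(f"group {group.label!r}: {fl}")
        except (PipelineError, GasAccountingError) as exc:
            report["errors"].append(
                {"stage": "biodegradation", "group": group.label, "error": str(exc)}
            )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write results.json, results.csv and warnings.log under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves = report.get("curves", [])
    if curves:
        pd.DataFrame(curves).to_csv(out / "curves.csv", index=False)
    slim = {k: v for k, v in report.items() if k != "curves"}
    (out / "results.json").write_text(json.dumps(slim, indent=2) + "\n")
    rows = [
        {
            "label": r["label"],
            "condition": r["condition"],
            "polymer": r["polymer"],
            "basis": r["basis"],
            "percent_mean": r["percent_mean"],
            "percent_sd": r["percent_sd"],
            "horizon_days": r["horizon_days"],
        }
        for r in report["results"]
    ]
    pd.DataFrame(
        rows,
        columns=[
            "label", "condition", "polymer", "basis",
            "percent_mean", "percent_sd", "horizon_days",
        ],
    ).to_csv(out / "results.csv", index=False)
    lines = list(report["warnings"]) + [
        f"ERROR [{e.get('group', e['stage'])}]: {e['error']}" for e in report["errors"]
    ]
    (out / "warnings.log").write_text("\n".join(lines) + ("\n" if lines else ""))
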
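"""Synthetic closed-bottle assay data with known ground truth.

Gas curves follow a modified Gompertz rise (lag, maximum rate, asymptote)
on top of a shared blank component that mimics residual-substrate activity
in the inoculum; the analysis pipeline never fits this family, so the
choice cannot bias results. Measurement noise is multiplicative on
headspace mole fractions (GC-like) and truncated to [0, 1]. Identical
seeds produce bit-identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gas as gasmod
from .community import RANKS, UNASSIGNED, TaxonTable
from .gas import AMBIENT_O2_FRACTION, BottleSpec, FlushEvent, GasReading
from .pipeline import AssayGroup
from .stoichiometry import (
    MOLAR_VOLUME_STP_L,
    ElementalFormula,
    TheoreticalPotentials,
    load_registry,
    potentials,
)

__all__ = [
    "CurveModel",
    "SyntheticAssay",
    "DEFAULT_PLASTIC_MASS_G",
    "anaerobic_bottle",
    "aerobic_bottle",
    "twice_weekly_schedule",
    "generate_gas_curves",
    "generate_taxon_table",
    "write_taxon_table",
    "write_study",
    "FIG4_STYLE_ANAEROBIC_COMPOSITION",
]

#: study-design default: 62.5 mg plastic per bottle
DEFAULT_PLASTIC_MASS_G = 0.0625


def anaerobic_bottle(temperature_c: float = 55.0) -> BottleSpec:
    """120 mL bottle, 45 mL medium, N2/CO2 80:20 at 1.7e5 Pa."""
    return BottleSpec(
        total_volume_ml=120.0,
        liquid_volume_ml=45.0,
        temperature_c=temperature_c,
        initial_pressure_pa=1.7e5,
        initial_composition={"N2": 0.8, "CO2": 0.2},
    )


def aerobic_bottle(temperature_c: float = 37.0) -> BottleSpec:
    """120 mL bottle, 50 mL medium, pressurized air (1.7e5 Pa)."""
    return BottleSpec(
        total_volume_ml=120.0,
        liquid_volume_ml=50.0,
        temperature_c=temperature_c,
        initial_pressure_pa=1.7e5,
        initial_composition={
            "N2": 1.0 - AMBIENT_O2_FRACTION,
            "O2": AMBIENT_O2_FRACTION,
        },
    )


def twice_weekly_schedule(horizon_days: float = 60.0) -> np.ndarray:
    """Sampling times at days 0, 3.5, 7, ... up to the horizon."""
    return np.arange(0.0, horizon_days + 1e-9, 3.5)


@dataclass(frozen=True)
class CurveModel:
    """Ground-truth parameters for one synthetic assay group.

    ``target_fraction`` is the true biodegradation fraction f (the pipeline
    should report 100*f). ``rate`` is the maximum specific gas rate in
    L STP per day per g; ``blank_asymptote_l`` the residual-substrate gas
    (L STP) shared by sample and blank bottles; ``noise_sd`` the relative SD
    of the multiplicative mole-fraction noise.
    """

    target_fraction: float
    lag_days: float = 10.0
    rate: float = 0.05
    noise_sd: float = 0.02
    blank_asymptote_l: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_fraction <= 1.1:
            raise ValueError("target fraction must lie in [0, 1.1]")
        if self.lag_days < 0 or self.rate <= 0 or self.noise_sd < 0:
            raise ValueError("lag >= 0, rate > 0, noise_sd >= 0 required")


def _gompertz(t: np.ndarray, asymptote: float, max_rate: float, lag: float) -> np.ndarray:
    """Modified Gompertz cumulative curve; zero asymptote gives a flat zero."""
    if asymptote <= 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    z = max_rate * math.e / asymptote * (lag - np.asarray(t, dtype=float)) + 1.0
    return asymptote * np.exp(-np.exp(z))


@dataclass
class SyntheticAssay:
    """A generated assay group plus the raw inputs and ground truth."""

    group: AssayGroup
    readings: dict[str, list[GasReading]]
    flushes: dict[str, list[FlushEvent]]
    bottle: BottleSpec
    truth: dict
    warnings: list[str] = field(default_factory=list)


def _truth_liters(model: CurveModel, signal_asymptote_l: float, mass_g: float):
    blank_mu = model.blank_asymptote_l / 5.0 if model.blank_asymptote_l > 0 else 1.0

    def fn(t: np.ndarray) -> np.ndarray:
        blank = _gompertz(t, model.blank_asymptote_l, blank_mu, 1.0)
        signal = _gompertz(t, signal_asymptote_l, model.rate * mass_g, model.lag_days)
        return blank + signal

    return fn


def _noisy_fraction(rng: np.random.Generator, fraction: float, noise_sd: float) -> float:
    if noise_sd == 0:
        return float(np.clip(fraction, 0.0, 1.0))
    return float(np.clip(fraction * (1.0 + rng.normal(0.0, noise_sd)), 0.0, 1.0))


def _simulate_methane_bottle(
    rng: np.random.Generator,
    bottle: BottleSpec,
    truth_fn,
    schedule: np.ndarray,
    noise_sd: float,
) -> list[GasReading]:
    n_total = bottle.initial_pressure_pa * bottle.headspace_volume_ml * 1e-6 / (
        gasmod.R_GAS * bottle.temperature_k
    )
    readings = []
    for t in schedule:
        n_ch4 = truth_fn(np.asarray(t))[()] / MOLAR_VOLUME_STP_L
        fraction = float(n_ch4 / n_total)
        if fraction > 1:
            raise ValueError("simulated CH4 exceeds headspace capacity")
        readings.append(
            GasReading(time_days=float(t), mole_fraction=_noisy_fraction(rng, fraction, noise_sd))
        )
    return readings


def _simulate_o2_bottle(
    rng: np.random.Generator,
    bottle: BottleSpec,
    truth_fn,
    schedule: np.ndarray,
    noise_sd: float,
    floor_fraction: float = 0.02,
) -> tuple[list[GasReading], list[FlushEvent]]:
    """Simulate O2 readings with flushes triggered on the noise-free state.

    A flush (restoring ambient air at the bottle's initial pressure) is
    inserted right after a reading whenever the projected consumption up to
    the next reading would push the true O2 fraction below the floor.
    """
    n_total = bottle.initial_pressure_pa * bottle.headspace_volume_ml * 1e-6 / (
        gasmod.R_GAS * bottle.temperature_k
    )
    ambient_n = AMBIENT_O2_FRACTION * n_total
    cum = truth_fn(schedule) / MOLAR_VOLUME_STP_L  # consumed mol at each time
    seg_start_n = bottle.initial_composition.get("O2", 0.0) * n_total
    seg_start_cum = 0.0
    readings, flushes = [], []
    for i, t in enumerate(schedule):
        n_true = seg_start_n - (cum[i] - seg_start_cum)
        if n_true < 0:
            raise ValueError("simulated O2 consumption exceeded headspace supply")
        fraction = float(n_true / n_total)
        readings.append(
            GasReading(time_days=float(t), mole_fraction=_noisy_fraction(rng, fraction, noise_sd))
        )
        if i + 1 < len(schedule):
            projected = n_true - (cum[i + 1] - cum[i])
            if projected < floor_fraction * n_total:
                flushes.append(
                    FlushEvent(
                        time_days=float(t),
                        post_flush_fraction=AMBIENT_O2_FRACTION,
                        post_flush_pressure_pa=bottle.initial_pressure_pa,
                    )
                )
                seg_start_n = ambient_n
                seg_start_cum = float(cum[i])
    return readings, flushes


def generate_gas_curves(
    model: CurveModel,
    pots: TheoreticalPotentials,
    *,
    condition: str = "anaerobic",
    polymer: ElementalFormula,
    polymer_name: str = "",
    plastic_mass_g: float = DEFAULT_PLASTIC_MASS_G,
    bottle: BottleSpec | None = None,
    schedule: np.ndarray | None = None,
    n_replicates: int = 3,
    n_blanks: int = 3,
    label: str | None = None,
    role: str = "sample",
) -> SyntheticAssay:
    """Generate one assay group (samples + blanks) with known truth.

    The sample signal asymptote is ``f * potential * mass`` (methane volume
    for anaerobic, oxygen mass converted to STP volume for aerobic); blanks
    carry only the shared residual-substrate component. Curves are built by
    running the generated readings through the real gas-accounting code, so
    the returned group exercises the same path as measured data.
    """
    if condition not in ("anaerobic", "aerobic"):
        raise ValueError(f"unknown condition {condition!r}")
    if bottle is None:
        bottle = anaerobic_bottle() if condition == "anaerobic" else aerobic_bottle()
    if schedule is None:
        schedule = twice_weekly_schedule()
    schedule = np.asarray(schedule, dtype=float)
    rng = np.random.default_rng(model.seed)

    if condition == "anaerobic":
        signal_l = model.target_fraction * pots.bmp_theoric * plastic_mass_g
    else:
        if pots.thod is None:
            raise ValueError("aerobic generation needs a ThOD value")
        signal_l = gasmod.o2_grams_to_liters(
            model.target_fraction * pots.thod * plastic_mass_g
        )

    warnings = []
    rise_end = model.lag_days + (
        2.06 * signal_l / (model.rate * plastic_mass_g) if signal_l > 0 else 0.0
    )
    if rise_end > schedule[-1]:
        warnings.append(
            f"schedule horizon {schedule[-1]:.1f} d ends before the curve "
            f"plateaus (~{rise_end:.1f} d); truth may be unrecoverable"
        )

    readings: dict[str, list[GasReading]] = {}
    flushes: dict[str, list[FlushEvent]] = {}
    sample_curves, blank_curves = [], []
    bottle_ids = [(f"s{i + 1}", True) for i in range(n_replicates)] + [
        (f"b{i + 1}", False) for i in range(n_blanks)
    ]
    for bottle_id, is_sample in bottle_ids:
        truth_fn = _truth_liters(model, signal_l if is_sample else 0.0, plastic_mass_g)
        if condition == "anaerobic":
            r = _simulate_methane_bottle(rng, bottle, truth_fn, schedule, model.noise_sd)
            fl: list[FlushEvent] = []
            curve = gasmod.cumulative_methane(bottle, r)
        else:
            r, fl = _simulate_o2_bottle(rng, bottle, truth_fn, schedule, model.noise_sd)
            curve = gasmod.cumulative_o2_consumed(bottle, r, fl)
        readings[bottle_id] = r
        flushes[bottle_id] = fl
        (sample_curves if is_sample else blank_curves).append(curve)

    group = AssayGroup(
        label=label or f"{polymer_name or polymer}-{condition}",
        condition=condition,
        polymer=polymer,
        polymer_name=polymer_name or str(polymer),
        plastic_mass_g=plastic_mass_g,
        bottle=bottle,
        sample_curves=sample_curves,
        blank_curves=blank_curves,
        role=role,
    )
    truth = {
        "target_fraction": model.target_fraction,
        "expected_percent": 100.0 * model.target_fraction,
        "lag_days": model.lag_days,
        "rate": model.rate,
        "noise_sd": model.noise_sd,
        "blank_asymptote_l": model.blank_asymptote_l,
        "seed": model.seed,
        "condition": condition,
        "signal_asymptote_l": signal_l,
    }
    return SyntheticAssay(
        group=group, readings=readings, flushes=flushes, bottle=bottle,
        truth=truth, warnings=warnings,
    )


# ---------------------------------------------------------------------------
# taxon tables

#: generator targets loosely shaped like a thermophilic anaerobic digester
#: community (dominant hydrogenotrophic methanogen, proteolytic thermophiles,
#: a large kingdom-only bacterial fraction)
FIG4_STYLE_ANAEROBIC_COMPOSITION = {
    "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanothermobacter": 20.9,
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Caloramator": 11.0,
    "Bacteria;Coprothermobacterota;Coprothermobacteria;Coprothermobacterales;Coprothermobacteraceae;Coprothermobacter": 6.8,
    "Bacteria;Thermotogota;Thermotogae;Petrotogales;Petrotogaceae;Defluviitoga": 6.1,
    "Bacteria;Synergistota;Synergistia;Synergistales;Acetomicrobiaceae;Acetomicrobium": 2.3,
    "Bacteria;Actinobacteria;Actinomycetia;Micrococcales;Microbacteriaceae;Leucobacter": 1.5,
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus": 1.3,
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas": 0.6,
    "Bacteria": 31.0,
    "Archaea": 2.1,
    "Bacteria;Firmicutes": 16.4,
}


def generate_taxon_table(
    composition: dict[str, float],
    depth: int,
    *,
    overdispersion: float = 1000.0,
    seed: int = 0,
    n_samples: int = 1,
    sample_prefix: str = "S",
) -> tuple[TaxonTable, dict]:
    """Multinomial taxon counts around Dirichlet-perturbed target percentages.

    ``composition`` maps semicolon-delimited lineages (kingdom first, may be
    truncated) to target percentages summing to 100. Larger
    ``overdispersion`` concentrates samples tighter around the targets.
    """
    total = sum(composition.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"target percentages sum to {total}, expected 100")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    lineages = list(composition)
    targets = np.array([composition[k] for k in lineages]) / 100.0
    counts = {}
    for s in range(n_samples):
        p = rng.dirichlet(overdispersion * targets)
        counts[f"{sample_prefix}{s + 1}"] = rng.multinomial(depth, p)
    counts_df = pd.DataFrame(counts, index=pd.Index(lineages, name="taxon_id"))
    rows = []
    for lin in lineages:
        parts = [p.strip() for p in lin.split(";")][: len(RANKS)]
        parts += [UNASSIGNED] * (len(RANKS) - len(parts))
        rows.append([p if p else UNASSIGNED for p in parts])
    lineage_df = pd.DataFrame(rows, columns=list(RANKS), index=counts_df.index)
    table = TaxonTable(lineage=lineage_df, counts=counts_df)
    truth = {"composition": dict(composition), "depth": depth, "seed": seed,
             "overdispersion": overdispersion}
    return table, truth


def write_taxon_table(table: TaxonTable, path: str | Path) -> None:
    """Write a taxon table in the TSV dialect ``read_taxon_table`` accepts."""
    lineage = table.lineage.apply(
        lambda r: ";".join(v if v != UNASSIGNED else "" for v in r).rstrip(";"),
        axis=1,
    )
    out = table.counts.copy()
    out.insert(0, "lineage", lineage)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# full-study writer


def write_study(
    out_dir: str | Path,
    *,
    seed: int = 0,
    fractions: dict[tuple[str, str], float] | None = None,
    noise_sd: float = 0.02,
    horizon_days: float = 60.0,
    include_controls: bool = True,
) -> dict:
    """Write a complete synthetic study (gas CSV, flush CSV, run config,
    ground-truth manifest) mirroring the PE/PET/PCL x anaerobic/aerobic
    design with shared blanks per condition.

    ``fractions`` overrides the per-(polymer, condition) truth; the default
    has PE and PET inert and PCL extensively degraded. Returns the config
    dict (also written to ``study.yaml``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry()
    if fractions is None:
        fractions = {
            ("PE", "anaerobic"): 0.0,
            ("PET", "anaerobic"): 0.0,
            ("PCL", "anaerobic"): 0.87,
            ("PE", "aerobic"): 0.0,
            ("PET", "aerobic"): 0.0,
            ("PCL", "aerobic"): 0.99,
        }
    if include_controls:
        fractions = dict(fractions)
        fractions.setdefault(("cellulose", "anaerobic"), 0.88)
        fractions.setdefault(("cellulose", "aerobic"), 0.71)

    gas_rows, flush_rows, groups_cfg, manifest = [], [], [], {}
    rng_seed = np.random.default_rng(seed)
    conditions = sorted({cond for _, cond in fractions})
    for cond in conditions:
        prefix = "an" if cond == "anaerobic" else "ae"
        bottle = anaerobic_bottle() if cond == "anaerobic" else aerobic_bottle()
        gas_name = "CH4" if cond == "anaerobic" else "O2"
        rate = 0.05 if cond == "anaerobic" else 0.08
        blank_ids = [f"{prefix}-blank-{i + 1}" for i in range(3)]
        blank_written = False
        for (polymer_name, c), f in sorted(fractions.items()):
            if c != cond:
                continue
            model = CurveModel(
                target_fraction=f,
                rate=rate,
                noise_sd=noise_sd,
                seed=int(rng_seed.integers(0, 2**31)),
            )
            assay = generate_gas_curves(
                model,
                potentials(registry[polymer_name]),
                condition=cond,
                polymer=registry[polymer_name],
                polymer_name=polymer_name,
                schedule=twice_weekly_schedule(horizon_days),
                label=f"{polymer_name}-{cond}",
                role="control" if polymer_name == "cellulose" else "sample",
            )
            id_map = {}
            for i, local in enumerate(f"s{j + 1}" for j in range(3)):
                id_map[local] = f"{prefix}-{polymer_name}-s{i + 1}"
            for i, local in enumerate(f"b{j + 1}" for j in range(3)):
                id_map[local] = blank_ids[i]
            for local, bottle_id in id_map.items():
                if bottle_id in blank_ids and blank_written:
                    continue  # shared blanks written once per condition
                for r in assay.readings[local]:
                    gas_rows.append(
                        {
                            "bottle_id": bottle_id,
                            "time_days": r.time_days,
                            "gas": gas_name,
                            "mole_fraction": r.mole_fraction,
                        }
                    )
                for fl in assay.flushes[local]:
                    flush_rows.append(
                        {
                            "bottle_id": bottle_id,
                            "time_days": fl.time_days,
                            "post_flush_fraction": fl.post_flush_fraction,
                            "post_flush_pressure_pa": fl.post_flush_pressure_pa,
                        }
                    )
            blank_written = True
            groups_cfg.append(
                {
                    "label": assay.group.label,
                    "condition": cond,
                    "polymer": polymer_name,
                    "plastic_mass_g": DEFAULT_PLASTIC_MASS_G,
                    "bottle": cond,
                    "sample_bottles": [id_map[f"s{j + 1}"] for j in range(3)],
                    "blank_bottles": blank_ids,
                    "role": assay.group.role,
                }
            )
            manifest[assay.group.label] = dict(assay.truth, warnings=assay.warnings)

    pd.DataFrame(gas_rows).to_csv(out / "gas_readings.csv", index=False)
    pd.DataFrame(
        flush_rows,
        columns=["bottle_id", "time_days", "post_flush_fraction", "post_flush_pressure_pa"],
    ).to_csv(out / "flush_events.csv", index=False)
    config = {
        "bottles": {
            "anaerobic": asdict(anaerobic_bottle()),
            "aerobic": asdict(aerobic_bottle()),
        },
        "gas_readings": "gas_readings.csv",
        "flush_events": "flush_events.csv",
        "groups": groups_cfg,
    }
    (out / "study.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    (out / "manifest.json").write_text(json.dumps({"seed": seed, "groups": manifest}, indent=2) + "\n")
    return config
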
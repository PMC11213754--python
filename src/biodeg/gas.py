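"""Headspace gas accounting: per-bottle cumulative methane production or
oxygen consumption at STP, blank correction, and replicate aggregation.

Moles in the headspace follow the ideal gas law at incubation temperature;
cumulative amounts are reported as volumes at STP (22.4 L/mol) and, for
oxygen, convertible to grams via 31.9988 g/mol. Pressure defaults to the
bottle's configured initial pressure at every time point (per-reading
pressures override this); gas withdrawn during sampling and gas dissolved in
the liquid are neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .stoichiometry import MOLAR_VOLUME_STP_L, O2_MOLAR_MASS

__all__ = [
    "R_GAS",
    "ATM_PRESSURE_PA",
    "AMBIENT_O2_FRACTION",
    "GasAccountingError",
    "BottleSpec",
    "GasReading",
    "FlushEvent",
    "GasCurve",
    "AggregateCurve",
    "headspace_moles",
    "cumulative_methane",
    "cumulative_o2_consumed",
    "blank_correct",
    "aggregate_replicates",
    "o2_liters_to_grams",
    "o2_grams_to_liters",
]

R_GAS = 8.314  # J mol-1 K-1
ATM_PRESSURE_PA = 1.013e5
AMBIENT_O2_FRACTION = 0.2095

#: raw-curve decreases larger than this fraction of the running maximum are flagged
MONOTONICITY_TOLERANCE = 0.02

_GASES = ("N2", "CO2", "O2", "CH4")


class GasAccountingError(ValueError):
    """Raised on invalid bottle specs, reading order, or coverage problems."""


@dataclass(frozen=True)
class BottleSpec:
    """Geometry and initial state of one sealed assay bottle."""

    total_volume_ml: float
    liquid_volume_ml: float
    temperature_c: float
    initial_pressure_pa: float
    initial_composition: dict[str, float] = field(
        default_factory=lambda: {"N2": 0.8, "CO2": 0.2}
    )

    def __post_init__(self) -> None:
        if not 0 < self.liquid_volume_ml < self.total_volume_ml:
            raise GasAccountingError(
                "liquid volume must satisfy 0 < liquid < total "
                f"({self.liquid_volume_ml} / {self.total_volume_ml} mL)"
            )
        if self.temperature_c <= 0:
            raise GasAccountingError("temperature must be > 0 degC")
        if self.initial_pressure_pa <= 0:
            raise GasAccountingError("initial pressure must be > 0 Pa")
        unknown = set(self.initial_composition) - set(_GASES)
        if unknown:
            raise GasAccountingError(f"unknown gases in composition: {sorted(unknown)}")
        fractions = list(self.initial_composition.values())
        if any(not 0 <= v <= 1 for v in fractions):
            raise GasAccountingError("mole fractions must lie in [0, 1]")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise GasAccountingError(
                f"initial mole fractions sum to {sum(fractions)}, expected 1"
            )

    @property
    def headspace_volume_ml(self) -> float:
        return self.total_volume_ml - self.liquid_volume_ml

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15


@dataclass(frozen=True)
class GasReading:
    """One measurement of the tracked gas's headspace mole fraction."""

    time_days: float
    mole_fraction: float
    pressure_pa: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mole_fraction <= 1:
            raise GasAccountingError(
                f"mole fraction {self.mole_fraction} outside [0, 1]"
            )
        if self.pressure_pa is not None and self.pressure_pa <= 0:
            raise GasAccountingError("reading pressure must be > 0 Pa")


@dataclass(frozen=True)
class FlushEvent:
    """Headspace replacement: state of the tracked gas just after flushing."""

    time_days: float
    post_flush_fraction: float
    post_flush_pressure_pa: float = ATM_PRESSURE_PA

    def __post_init__(self) -> None:
        if not 0 <= self.post_flush_fraction <= 1:
            raise GasAccountingError("post-flush fraction outside [0, 1]")
        if self.post_flush_pressure_pa <= 0:
            raise GasAccountingError("post-flush pressure must be > 0 Pa")


@dataclass(frozen=True)
class GasCurve:
    """Cumulative gas produced (CH4) or consumed (O2) at STP for one bottle.

    ``cumulative`` is in L at STP; consumption is accumulated as a positive
    quantity. The first point is (time 0, 0).
    """

    times: np.ndarray
    cumulative: np.ndarray
    mode: str  # "methane_production" | "oxygen_consumption"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cumulative, dtype=float)
        if t.shape != c.shape or t.ndim != 1 or t.size == 0:
            raise GasAccountingError("times and cumulative must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise GasAccountingError("curve times must be strictly increasing")
        if self.mode not in ("methane_production", "oxygen_consumption"):
            raise GasAccountingError(f"unknown curve mode {self.mode!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative", c)

    @property
    def final_value(self) -> float:
        return float(self.cumulative[-1])

    @property
    def horizon_days(self) -> float:
        return float(self.times[-1])

    def grams(self, molar_mass: float = O2_MOLAR_MASS) -> np.ndarray:
        """Cumulative amounts as grams of the tracked gas."""
        return self.cumulative / MOLAR_VOLUME_STP_L * molar_mass


@dataclass(frozen=True)
class AggregateCurve:
    """Per-time mean of replicate curves with sample SD (n-1 denominator)."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray | None
    mode: str
    n: int
    flags: tuple[str, ...] = ()


def headspace_moles(spec: BottleSpec, fraction: float, pressure_pa: float) -> float:
    """Moles of the tracked gas in the headspace (ideal gas at incubation T)."""
    if not 0 <= fraction <= 1:
        raise GasAccountingError(f"fraction {fraction} outside [0, 1]")
    if pressure_pa <= 0:
        raise GasAccountingError("pressure must be > 0 Pa")
    volume_m3 = spec.headspace_volume_ml * 1e-6
    return fraction * pressure_pa * volume_m3 / (R_GAS * spec.temperature_k)


def o2_liters_to_grams(liters_stp: float) -> float:
    return liters_stp / MOLAR_VOLUME_STP_L * O2_MOLAR_MASS


def o2_grams_to_liters(grams: float) -> float:
    return grams / O2_MOLAR_MASS * MOLAR_VOLUME_STP_L


def _check_sorted(readings: list[GasReading]) -> None:
    times = [r.time_days for r in readings]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise GasAccountingError("reading times must be strictly increasing")


def _monotonicity_flags(cumulative: np.ndarray) -> tuple[str, ...]:
    running_max = np.maximum.accumulate(cumulative)
    scale = max(float(running_max[-1]), 1e-12)
    worst = float(np.max(running_max - cumulative))
    if worst > MONOTONICITY_TOLERANCE * scale:
        return (
            f"non_monotonic: drop of {worst:.4g} L exceeds "
            f"{MONOTONICITY_TOLERANCE:.0%} of running maximum",
        )
    return ()


def cumulative_methane(
    spec: BottleSpec,
    readings: list[GasReading],
    *,
    assume_constant_pressure: bool = True,
) -> GasCurve:
    """Cumulative CH4 produced (L STP) from headspace CH4 mole fractions.

    Cumulative CH4 at each time is the headspace CH4 mole excess over the
    initial state, times 22.4 L/mol. Readings without a pressure use the
    bottle's initial pressure when ``assume_constant_pressure`` is set;
    otherwise a missing pressure is a configuration error.
    """
    if not readings:
        raise GasAccountingError("no readings")
    _check_sorted(readings)
    n0 = headspace_moles(
        spec, spec.initial_composition.get("CH4", 0.0), spec.initial_pressure_pa
    )
    times, cumulative = [], []
    if readings[0].time_days > 0:
        times.append(0.0)
        cumulative.append(0.0)
    elif readings[0].time_days < 0:
        raise GasAccountingError("reading before time 0")
    for r in readings:
        if r.pressure_pa is not None:
            p = r.pressure_pa
        elif assume_constant_pressure:
            p = spec.initial_pressure_pa
        else:
            raise GasAccountingError(
                f"reading at day {r.time_days} has no pressure and "
                "constant-pressure mode is disabled"
            )
        n = headspace_moles(spec, r.mole_fraction, p)
        times.append(r.time_days)
        cumulative.append((n - n0) * MOLAR_VOLUME_STP_L)
    cum = np.asarray(cumulative)
    return GasCurve(
        times=np.asarray(times),
        cumulative=cum,
        mode="methane_production",
        flags=_monotonicity_flags(cum),
    )


def cumulative_o2_consumed(
    spec: BottleSpec,
    readings: list[GasReading],
    flushes: list[FlushEvent] | None = None,
    *,
    assume_constant_pressure: bool = True,
) -> GasCurve:
    """Cumulative O2 consumed (L STP), segment-wise between flush events.

    Within each inter-flush segment, consumption is the segment-start O2
    moles minus the reading's O2 moles; flushing closes the segment at its
    last reading and restarts accounting from the recorded post-flush state.
    A reading and a flush at the same time are ordered measurement-first.
    """
    if not readings:
        raise GasAccountingError("no readings")
    _check_sorted(readings)
    flushes = sorted(flushes or [], key=lambda fl: fl.time_days)
    if flushes and readings and flushes[0].time_days < 0:
        raise GasAccountingError("flush before time 0")

    # (time, order, payload): readings before flushes at equal times
    events: list[tuple[float, int, object]] = [
        (r.time_days, 0, r) for r in readings
    ] + [(fl.time_days, 1, fl) for fl in flushes]
    events.sort(key=lambda ev: (ev[0], ev[1]))

    seg_pressure = spec.initial_pressure_pa
    seg_start_n = headspace_moles(
        spec, spec.initial_composition.get("O2", 0.0), seg_pressure
    )
    last_n = seg_start_n
    seen_reading_in_segment = True  # initial state counts as the opening anchor
    completed_mol = 0.0
    times, cumulative = [], []
    if readings[0].time_days > 0:
        times.append(0.0)
        cumulative.append(0.0)
    elif readings[0].time_days < 0:
        raise GasAccountingError("reading before time 0")
    last_flush_time = -np.inf
    for t, _, payload in events:
        if isinstance(payload, GasReading):
            r = payload
            if r.time_days < last_flush_time:
                raise GasAccountingError(
                    f"reading at day {r.time_days} precedes flush at day "
                    f"{last_flush_time}"
                )
            if r.pressure_pa is not None:
                p = r.pressure_pa
            elif assume_constant_pressure:
                p = seg_pressure
            else:
                raise GasAccountingError(
                    f"reading at day {r.time_days} has no pressure and "
                    "constant-pressure mode is disabled"
                )
            n = headspace_moles(spec, r.mole_fraction, p)
            times.append(r.time_days)
            cumulative.append(
                (completed_mol + (seg_start_n - n)) * MOLAR_VOLUME_STP_L
            )
            last_n = n
            seen_reading_in_segment = True
        else:
            fl = payload
            if not seen_reading_in_segment:
                raise GasAccountingError(
                    f"flush at day {fl.time_days}: segment has no reading to "
                    "close the O2 balance"
                )
            completed_mol += seg_start_n - last_n
            seg_pressure = fl.post_flush_pressure_pa
            seg_start_n = headspace_moles(spec, fl.post_flush_fraction, seg_pressure)
            last_n = seg_start_n
            last_flush_time = fl.time_days
            seen_reading_in_segment = False
    cum = np.asarray(cumulative)
    return GasCurve(
        times=np.asarray(times),
        cumulative=cum,
        mode="oxygen_consumption",
        flags=_monotonicity_flags(cum),
    )


def _interp_onto(curve: GasCurve, times: np.ndarray, end_hold: bool) -> np.ndarray:
    if not end_hold and (
        times[0] < curve.times[0] - 1e-12 or times[-1] > curve.times[-1] + 1e-12
    ):
        raise GasAccountingError(
            "curve time range "
            f"[{curve.times[0]}, {curve.times[-1]}] does not cover "
            f"[{times[0]}, {times[-1]}]; enable end_hold to extrapolate flat"
        )
    return np.interp(times, curve.times, curve.cumulative)


def blank_correct(
    sample: GasCurve, blanks: list[GasCurve], *, end_hold: bool = False
) -> GasCurve:
    """Subtract the time-wise mean of blank curves from a sample curve.

    Blanks are linearly interpolated onto the sample's time grid. Negative
    corrected values are kept (never clipped) and flagged.
    """
    if not blanks:
        raise GasAccountingError("at least one blank curve required")
    if any(b.mode != sample.mode for b in blanks):
        raise GasAccountingError("blank curves must share the sample's mode")
    blank_mat = np.vstack(
        [_interp_onto(b, sample.times, end_hold) for b in blanks]
    )
    corrected = sample.cumulative - blank_mat.mean(axis=0)
    flags = tuple(sample.flags)
    if np.any(corrected < -1e-12):
        flags += ("negative_after_blank_correction",)
    return GasCurve(
        times=sample.times.copy(), cumulative=corrected, mode=sample.mode, flags=flags
    )


def aggregate_replicates(curves: list[GasCurve]) -> AggregateCurve:
    """Mean curve with per-time sample SD across replicate curves.

    Curves on different grids are resampled by linear interpolation onto the
    first curve's grid restricted to the common time coverage. A single curve
    yields an absent SD with a warning flag.
    """
    if not curves:
        raise GasAccountingError("no curves to aggregate")
    mode = curves[0].mode
    if any(c.mode != mode for c in curves):
        raise GasAccountingError("curves must share a mode")
    start = max(c.times[0] for c in curves)
    end = min(c.times[-1] for c in curves)
    if end <= start:
        raise GasAccountingError("curves have no overlapping time range")
    base = curves[0].times
    grid = base[(base >= start - 1e-12) & (base <= end + 1e-12)]
    values = np.vstack([np.interp(grid, c.times, c.cumulative) for c in curves])
    mean = values.mean(axis=0)
    if len(curves) == 1:
        return AggregateCurve(
            times=grid, mean=mean, sd=None, mode=mode, n=1,
            flags=("single_curve: SD undefined",),
        )
    sd = values.std(axis=0, ddof=1)
    return AggregateCurve(times=grid, mean=mean, sd=sd, mode=mode, n=len(curves))
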
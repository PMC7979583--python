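"""Oral dosing regimens and the clinical-study presets.

Presets mirror the arms of the four ASP8232 studies: the phase-2 ALBUM and
VIDI trials (40 mg once daily, 12 weeks), the renal-impairment/DKD study
part 2 (250 mg loading dose, then 150 mg daily for 27 days), and the
first-in-human single- and multiple-ascending-dose arms.  Doses of 300 mg
and above fall outside the range the model was calibrated on and have no
presets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["Regimen", "build_regimen", "daily_regimen", "REGIMEN_PRESETS"]

#: Calibrated dose range (mg); simulations outside it warrant caution.
DOSE_RANGE_MG = (0.1, 200.0)


@dataclass(frozen=True)
class Regimen:
    """Ordered oral dose events as (time h, dose mg) pairs."""

    events: tuple[tuple[float, float], ...] = ()
    label: str = ""

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be non-decreasing")
        if any(a <= 0 for _, a in self.events):
            raise ValueError("doses must be strictly positive")

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.events]

    @property
    def doses_mg(self) -> list[float]:
        return [a for _, a in self.events]

    @property
    def end_time(self) -> float:
        return self.events[-1][0] if self.events else 0.0


def daily_regimen(dose_mg: float, days: int, label: str = "") -> Regimen:
    """``days`` once-daily doses of ``dose_mg`` starting at t = 0."""
    _dose_range_warning(dose_mg)
    return Regimen(
        tuple((24.0 * k, float(dose_mg)) for k in range(days)),
        label or f"{dose_mg} mg QD x {days} d",
    )


def _dose_range_warning(dose_mg: float) -> None:
    lo, hi = DOSE_RANGE_MG
    if dose_mg and not lo <= dose_mg <= hi:
        warnings.warn(
            f"dose {dose_mg} mg is outside the calibrated range "
            f"[{lo}, {hi}] mg; interpret simulations with caution",
            UserWarning,
            stacklevel=3,
        )


def _loading(day1_mg: float, daily_mg: float, total_days: int, label: str) -> Regimen:
    events = [(0.0, day1_mg)] + [(24.0 * k, daily_mg) for k in range(1, total_days)]
    return Regimen(tuple(events), label)


def _build_presets() -> dict[str, Regimen]:
    presets: dict[str, Regimen] = {}
    # Phase-2 studies: 40 mg once daily for 12 weeks.
    presets["ALBUM"] = daily_regimen(40.0, 84, "ALBUM 40 mg QD x 12 wk")
    presets["VIDI"] = daily_regimen(40.0, 84, "VIDI 40 mg QD x 12 wk")
    # Renal impairment study: single 200 mg (part 1); loading 250 mg then
    # 150 mg QD days 2-28 (part 2).
    presets["0002-part1"] = Regimen(((0.0, 200.0),), "0002 part 1: 200 mg single dose")
    presets["0002-part2"] = _loading(250.0, 150.0, 28, "0002 part 2: 250/150 mg QD x 28 d")
    # First-in-human single-dose arms (within the calibrated range).
    for d in (0.1, 1.0, 3.0, 10.0, 30.0, 100.0):
        presets[f"0001-single-{d:g}"] = Regimen(
            ((0.0, d),), f"0001 single dose {d:g} mg"
        )
    # First-in-human multiple-dose arms with their loading schedules.
    # Low: 0.2 mg day 1, 1 mg loading on day 8, 0.2 mg QD days 9-21.
    low = [(0.0, 0.2), (7 * 24.0, 1.0)] + [(24.0 * k, 0.2) for k in range(8, 21)]
    presets["0001-multiple-low"] = Regimen(tuple(low), "0001 MD low: 0.2 mg QD (1 mg load)")
    # Mid: 200 mg day 1, 600 mg loading day 2, 200 mg QD days 3-14.
    mid = [(0.0, 200.0), (24.0, 600.0)] + [(24.0 * k, 200.0) for k in range(2, 14)]
    presets["0001-multiple-mid"] = Regimen(tuple(mid), "0001 MD mid: 200 mg QD (600 mg load)")
    return presets


REGIMEN_PRESETS = _build_presets()


def build_regimen(spec) -> Regimen:
    """Build a regimen from a preset name or explicit (time, dose) pairs."""
    if isinstance(spec, Regimen):
        return spec
    if isinstance(spec, str):
        try:
            return REGIMEN_PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown regimen preset {spec!r}; available: "
                + ", ".join(sorted(REGIMEN_PRESETS))
            ) from None
    events = tuple((float(t), float(a)) for t, a in spec)
    for _, a in events:
        _dose_range_warning(a)
    return Regimen(events, "custom")
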
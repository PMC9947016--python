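"""Intravenous dosing regimens: timed infusion events for DOX and DEX."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["DoseEvent", "Regimen", "build_regimen"]

_DRUGS = ("DOX", "DEX")


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate intravenous infusion.

    Attributes
    ----------
    drug : {"DOX", "DEX"}
    amount : float
        Dose in mg (absolute, already scaled by body surface area).
    start : float
        Infusion start, h.
    duration : float
        Infusion duration, h; the clinical default is a 15-min (0.25 h)
        infusion.
    """

    drug: str
    amount: float
    start: float
    duration: float = 0.25

    def __post_init__(self) -> None:
        if self.drug not in _DRUGS:
            raise ValueError(f"drug must be one of {_DRUGS}, got {self.drug!r}")
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.start < 0:
            raise ValueError("start must be >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class Regimen:
    """A sequence of infusion events with a simulation horizon.

    Events must be sorted by start time and fit within the horizon.
    Overlapping infusions are legal; their rates add.
    """

    events: tuple[DoseEvent, ...]
    bsa: float = 1.8  # m², body surface area used to scale mg/m² doses
    horizon: float = field(default=0.0)

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if self.bsa <= 0:
            raise ValueError("bsa must be > 0")
        starts = [e.start for e in events]
        if starts != sorted(starts):
            raise ValueError("events must be sorted by start time")
        last_end = max((e.end for e in events), default=0.0)
        if self.horizon == 0.0:
            object.__setattr__(self, "horizon", last_end)
        if self.horizon < last_end:
            raise ValueError("horizon must cover the last infusion")

    def drugs(self) -> set[str]:
        return {e.drug for e in self.events}

    def total_dose(self) -> float:
        """Cumulative dose over all events, mg."""
        return sum(e.amount for e in self.events)

    def shifted(self, offset: float) -> "Regimen":
        """Copy of the regimen with every event delayed by ``offset`` hours."""
        events = tuple(
            DoseEvent(e.drug, e.amount, e.start + offset, e.duration) for e in self.events
        )
        return Regimen(events=events, bsa=self.bsa, horizon=self.horizon + offset)


def build_regimen(
    drug: str,
    dose_per_m2: float,
    bsa: float = 1.8,
    interval_h: float = 504.0,
    n_doses: int = 3,
    duration_h: float = 0.25,
    horizon: float | None = None,
) -> Regimen:
    """Build an evenly spaced multiple-infusion regimen.

    ``n_doses`` infusions of ``dose_per_m2 * bsa`` mg are given at
    ``start = k * interval_h`` for k = 0..n_doses-1. The default interval of
    504 h encodes once-every-three-weeks (Q3W) dosing; 168 h gives weekly
    (Q1W) dosing. The horizon defaults to ``n_doses * interval_h`` so that
    the last cycle is fully observed.
    """
    if dose_per_m2 < 0 or bsa <= 0 or interval_h <= 0 or n_doses < 1 or duration_h <= 0:
        raise ValueError("regimen arguments must be positive (dose may be zero)")
    events = tuple(
        DoseEvent(drug=drug, amount=dose_per_m2 * bsa, start=k * interval_h, duration=duration_h)
        for k in range(n_doses)
    )
    if horizon is None:
        horizon = n_doses * interval_h
    return Regimen(events=events, bsa=bsa, horizon=horizon)
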
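"""Timestamped medication records: weight-normalized infusion steps and boluses."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class MedicationRecord:
    """Per-drug piecewise-constant infusion rates and bolus events.

    ``rates[drug]`` is a time-ordered list of (time_s, rate_mg_per_kg_hr) steps;
    each step holds on the half-open interval [time, next step time). Before the
    first step the rate is 0. ``boluses[drug]`` is a time-ordered list of
    (time_s, dose_mg_per_kg) events. Rates are weight-normalized, so no explicit
    patient weight appears.
    """

    rates: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    boluses: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        for drug, steps in self.rates.items():
            times = [t for t, _ in steps]
            if times != sorted(times):
                raise ValueError(f"rate steps for {drug!r} are not time-ordered")
            for t, r in steps:
                if r < 0:
                    raise ValueError(
                        f"negative infusion rate {r} mg/kg/hr for {drug!r} at t={t} s"
                    )
        for drug, evts in self.boluses.items():
            times = [t for t, _ in evts]
            if times != sorted(times):
                raise ValueError(f"boluses for {drug!r} are not time-ordered")
            for t, d in evts:
                if d < 0:
                    raise ValueError(f"negative bolus dose {d} mg/kg for {drug!r} at t={t} s")

    @property
    def drugs(self) -> list[str]:
        return sorted(set(self.rates) | set(self.boluses))

    def rate_at(self, drug: str, t: float) -> float:
        """Infusion rate of ``drug`` at time ``t`` (half-open step convention)."""
        r = 0.0
        for ts, rate in self.rates.get(drug, []):
            if ts <= t:
                r = rate
            else:
                break
        return r

    def combo_at(self, t: float) -> dict[str, float]:
        """Per-drug rate vector at time ``t`` (zero-rate drugs omitted)."""
        combo = {d: self.rate_at(d, t) for d in self.rates}
        return {d: r for d, r in combo.items() if r > 0}

    def change_times(self) -> list[float]:
        """Times at which any drug's rate actually changes value.

        Consecutive steps recording the same rate are not changes.
        """
        out: set[float] = set()
        for drug, steps in self.rates.items():
            prev = 0.0
            for t, r in steps:
                if r != prev:
                    out.add(t)
                prev = r
        return sorted(out)

    def bolus_times(self) -> list[float]:
        return sorted(t for evts in self.boluses.values() for t, _ in evts)


#: In the synthetic module an infusion regimen has exactly this structure.
InfusionRegimen = MedicationRecord
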
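"""The two comparator strategies and their follow-up schedules.

Current practice: no baseline amyloid-PET; all MCI patients are followed
annually and detected AD patients quarterly.  The PET strategy scans
every MCI patient once at baseline and moves identified amyloid-positive
(AP) patients to quarterly follow-up, so that incident mild AD is caught
one cycle after onset instead of (on average) a year later.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet
from .states import StateSpace, state_space

__all__ = ["Strategy", "current_practice", "pet_strategy", "visits_per_cycle"]


@dataclass(frozen=True)
class Strategy:
    """One arm of the comparison.

    ``schedule_map`` gives the follow-up interval in years per state
    label (states absent from the map get no follow-up visits);
    ``one_time_costs`` is charged at model start (the PET scan).
    """

    name: str
    use_pet: bool
    schedule_map: dict[str, float]
    one_time_costs: float
    intervention_applies: bool

    def interval(self, label: str) -> float | None:
        return self.schedule_map.get(label)


def _base_schedule(params: ParameterSet, ss: StateSpace) -> dict[str, float]:
    sched: dict[str, float] = {
        ss.MCI_AN: params.followup_interval_mci,
        ss.MCI_AP_UNKNOWN: params.followup_interval_mci,
        ss.MCI_AP_KNOWN: params.followup_interval_mci,
        ss.MILD_TREATED: params.followup_interval_ad_detected,
        ss.MOD_TREATED: params.followup_interval_ad_detected,
        ss.SEV_TREATED: params.followup_interval_ad_detected,
    }
    # undetected mild AD keeps the schedule of the MCI state it came from
    for label in ss.tunnel_annual:
        sched[label] = params.followup_interval_mci
    for label in ss.tunnel_quarterly:
        sched[label] = params.followup_interval_ap_detected
    return sched


def current_practice(params: ParameterSet) -> Strategy:
    """Comparator arm: no PET, annual MCI follow-up, no one-time cost."""
    ss = state_space(params.detection_cap_cycles)
    return Strategy(
        name="current_practice",
        use_pet=False,
        schedule_map=_base_schedule(params, ss),
        one_time_costs=0.0,
        intervention_applies=False,
    )


def pet_strategy(params: ParameterSet) -> Strategy:
    """Intervention arm: baseline PET for all, quarterly follow-up once AP is known."""
    ss = state_space(params.detection_cap_cycles)
    sched = _base_schedule(params, ss)
    sched[ss.MCI_AP_KNOWN] = params.followup_interval_ap_detected
    return Strategy(
        name="amyloid_pet",
        use_pet=True,
        schedule_map=sched,
        one_time_costs=params.pet_cost,
        intervention_applies=True,
    )


def visits_per_cycle(label: str, strategy: Strategy, params: ParameterSet) -> float:
    """Expected follow-up visits per cycle in a state (fractional).

    cycle_length / interval for scheduled states; 0 for clinically normal
    and absorbing states.  Fractional visits spread an annual visit evenly
    over its four cycles, the cohort-level expectation.
    """
    interval = strategy.interval(label)
    if interval is None:
        return 0.0
    return params.cycle_length / interval
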
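"""Discounted costs, QALYs, and the incremental cost-effectiveness ratio.

Costs and utilities attach to the clinical severity tier (CN / MCI /
mild / moderate / severe) regardless of detection status — detection
changes only the follow-up visit cost and treatment.  Accrual uses a
half-cycle correction (mean of start- and end-of-cycle occupancy) and
discounting at the cycle midpoint; the one-time PET cost is charged
undiscounted at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace
from .parameters import ParameterSet
from .states import Tier
from .strategies import Strategy, visits_per_cycle

__all__ = [
    "EconResult",
    "CEComparison",
    "discount_factor",
    "accumulate",
    "compare",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def discount_factor(t_years: float, rate: float) -> float:
    """Present-value factor (1 + rate)^(-t), continuous in t."""
    if t_years < 0 or rate < 0:
        raise ValueError("time and rate must be non-negative")
    return float((1.0 + rate) ** (-t_years))


@dataclass(frozen=True)
class EconResult:
    """Discounted totals for one strategy, with the accrual breakdown."""

    strategy_name: str
    total_cost: float
    total_qaly: float
    state_cost: float  # discounted management (medical + non-medical) cost
    visit_cost: float  # discounted follow-up visit cost
    one_time_cost: float  # PET scan at t = 0
    cycle_cost: np.ndarray  # per-cycle discounted cost (excl. one-time)
    cycle_qaly: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {
            "strategy": self.strategy_name,
            "total_cost": self.total_cost,
            "total_qaly": self.total_qaly,
            "state_cost": self.state_cost,
            "visit_cost": self.visit_cost,
            "one_time_cost": self.one_time_cost,
        }


def _tier_annual_cost(params: ParameterSet, tier: Tier) -> float:
    if tier in (Tier.CN, Tier.NONE):
        return 0.0
    return getattr(params, f"medcost_{tier.value}") + getattr(
        params, f"nonmedcost_{tier.value}"
    )


def _tier_utility(params: ParameterSet, tier: Tier) -> float:
    if tier == Tier.NONE:
        return 0.0
    return getattr(params, f"utility_{tier.value}")


def accumulate(
    trace: CohortTrace, params: ParameterSet, strategy: Strategy
) -> EconResult:
    """Turn a cohort trace into discounted cost and QALY totals.

    Per cycle: half-cycle-corrected occupancy x (annual state cost x
    cycle length + visits x visit cost) and x (utility x cycle length),
    discounted at the cycle midpoint.
    """
    ss = trace.space
    if ss.labels != trace.space.labels or trace.occupancy.shape[1] != len(ss):
        raise ValueError("trace and parameter state spaces do not match")
    dt = params.cycle_length
    n_states = len(ss)

    state_cost_rate = np.zeros(n_states)  # USD per cycle per person
    visit_cost_rate = np.zeros(n_states)
    qaly_rate = np.zeros(n_states)  # QALY per cycle per person
    for label in ss:
        i = ss.index[label]
        tier = ss.tier(label)
        state_cost_rate[i] = _tier_annual_cost(params, tier) * dt
        visit_cost_rate[i] = (
            visits_per_cycle(label, strategy, params) * params.followup_cost_per_visit
        )
        qaly_rate[i] = _tier_utility(params, tier) * dt

    # half-cycle correction: effective occupancy is the cycle's mid estimate
    occ = trace.occupancy
    eff = 0.5 * (occ[:-1] + occ[1:])
    mid_t = trace.cycle_times[:-1] + 0.5 * dt
    disc = (1.0 + params.discount_rate) ** (-mid_t)

    cycle_state_cost = disc * (eff @ state_cost_rate)
    cycle_visit_cost = disc * (eff @ visit_cost_rate)
    cycle_qaly = disc * (eff @ qaly_rate)

    state_cost = float(cycle_state_cost.sum())
    visit_cost = float(cycle_visit_cost.sum())
    one_time = float(strategy.one_time_costs)
    return EconResult(
        strategy_name=strategy.name,
        total_cost=state_cost + visit_cost + one_time,
        total_qaly=float(cycle_qaly.sum()),
        state_cost=state_cost,
        visit_cost=visit_cost,
        one_time_cost=one_time,
        cycle_cost=cycle_state_cost + cycle_visit_cost,
        cycle_qaly=cycle_qaly,
    )


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison of intervention vs comparator."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str  # "icer", "dominant", "dominated", or "undefined"

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "label": self.label,
        }


def compare(
    comparator: EconResult, intervention: EconResult, qaly_tol: float = 0.0
) -> CEComparison:
    """Deltas (intervention - comparator) and the ICER or dominance label.

    The ICER is reported only when both deltas share a sign; a strategy
    that costs more for no (or negative) QALY gain is dominated, one that
    saves money without losing QALYs is dominant.  ``qaly_tol`` treats a
    |delta QALY| below it as exactly zero, for comparisons where the two
    arms are analytically identical up to round-off.
    """
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly
    if abs(d_qaly) <= qaly_tol:
        d_qaly = 0.0
    if d_qaly == 0.0 and d_cost == 0.0:
        return CEComparison(d_cost, d_qaly, None, UNDEFINED)
    if d_qaly != 0.0 and (d_cost > 0) == (d_qaly > 0):
        return CEComparison(d_cost, d_qaly, d_cost / d_qaly, "icer")
    if d_cost <= 0.0 and d_qaly >= 0.0:
        return CEComparison(d_cost, d_qaly, None, DOMINANT)
    return CEComparison(d_cost, d_qaly, None, DOMINATED)
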
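"""Cohort engine: per-cycle transition matrices and the cohort trace.

One cycle is 3 months at base settings.  Transition probabilities are
published as marginal annual values; each is converted to a per-cycle
probability under a constant-hazard assumption and the competing
transitions out of a state are composed as: per-cycle death first, then
the surviving mass is split among clinical destinations (renormalised if
their independent per-cycle probabilities overshoot), with the residual
staying in place (tunnel states advance one step instead).

Detection of undetected mild AD is a per-cycle hazard equal to
cycle_length / follow-up interval — an expected-delay match for a
uniformly phased cohort — and is forced at the tunnel cap (3 years after
onset).  Treatment starts at detection and multiplies the annual
worsening probabilities by the treatment relative risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable, annual_to_cycle_probability
from .parameters import ParameterSet
from .states import StateSpace, state_space
from .strategies import Strategy

__all__ = [
    "CohortTrace",
    "initial_distribution",
    "conversion_probability_ap",
    "detection_probability",
    "treated_probability",
    "mortality_probability",
    "build_transition_matrix",
    "run_cohort",
]

_ROW_TOL = 1e-9
_EXTINCTION = 1e-9


def clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def initial_distribution(params: ParameterSet, use_pet: bool) -> np.ndarray:
    """Cycle-0 occupancy: the whole cohort starts as 60-year-old MCI patients.

    Without PET, amyloid status is unknown and the cohort splits by true
    prevalence.  With PET, true positives are identified (sensitivity),
    false negatives stay unknown, and false positives (zero at base case,
    where specificity is 1) are wrongly identified.
    """
    ss = state_space(params.detection_cap_cycles)
    occ = np.zeros(len(ss))
    prev = params.ap_prevalence
    if use_pet:
        occ[ss.index[ss.MCI_AP_KNOWN]] = prev * params.pet_sensitivity
        occ[ss.index[ss.MCI_AP_UNKNOWN]] = prev * (1.0 - params.pet_sensitivity)
        occ[ss.index[ss.MCI_AN]] = (1.0 - prev) * params.pet_specificity
        occ[ss.index[ss.MCI_AP_KNOWN]] += (1.0 - prev) * (1.0 - params.pet_specificity)
    else:
        occ[ss.index[ss.MCI_AP_UNKNOWN]] = prev
        occ[ss.index[ss.MCI_AN]] = 1.0 - prev
    return occ


def conversion_probability_ap(params: ParameterSet, identified: bool = True) -> float:
    """Annual MCI -> mild-AD probability for an amyloid-positive patient.

    The amyloid-negative conversion probability scaled by the relative
    risk of conversion; the virtual intervention effect applies only to
    patients whose positivity has been identified by PET.
    """
    p = params.p_anmci_to_mild * params.rr_ap_conversion
    if identified:
        p *= params.intervention_effect
    return clamp01(p)


def detection_probability(
    label: str, params: ParameterSet, strategy: Strategy
) -> float:
    """Per-cycle probability that undetected mild AD is diagnosed.

    cycle_length / follow-up interval of the schedule the patient carries
    (1.0 when the interval equals the cycle), and forced to 1.0 once the
    tunnel reaches the detection cap regardless of schedule.
    """
    ss = state_space(params.detection_cap_cycles)
    k = ss.tunnel_step(label)  # raises on non-tunnel states
    if k >= ss.n_tunnel:
        return 1.0
    interval = strategy.interval(label)
    if interval is None:
        raise ValueError(f"tunnel state {label} has no follow-up schedule")
    return clamp01(params.cycle_length / interval)


def treated_probability(p: float, treatment_rr: float) -> float:
    """Annual worsening probability under treatment: clamp01(p * RR)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if treatment_rr <= 0:
        raise ValueError("treatment_rr must be > 0")
    return clamp01(p * treatment_rr)


def mortality_probability(
    lt: LifeTable, age: float, label: str, params: ParameterSet
) -> float:
    """Per-cycle death probability in a state at a given age.

    Background mortality comes from the life table at floor(age);
    moderate and severe AD multiply the annual hazard by their excess-
    mortality factor before the cycle conversion:
    q = 1 - (1 - qx)^(multiplier / cycles_per_year).
    """
    ss = state_space(params.detection_cap_cycles)
    if ss.is_absorbing(label):
        return 0.0
    qx = lt.annual_qx(age)
    if label == ss.MOD_TREATED:
        mult = params.excess_mort_moderate
    elif label == ss.SEV_TREATED:
        mult = params.excess_mort_severe
    else:
        mult = 1.0
    if qx >= 1.0:
        return 1.0
    return clamp01(1.0 - (1.0 - qx) ** (mult / params.cycles_per_year))


def _tunnel_entry(params: ParameterSet, strategy: Strategy, mci_label: str) -> str:
    """Which tunnel an MCI state feeds: matches its follow-up interval."""
    ss = state_space(params.detection_cap_cycles)
    interval = strategy.interval(mci_label)
    quarterly = abs(interval - params.followup_interval_ap_detected) < 1e-12
    return ss.tunnel_quarterly[0] if quarterly else ss.tunnel_annual[0]


def build_transition_matrix(
    params: ParameterSet, lt: LifeTable, strategy: Strategy, age: float
) -> np.ndarray:
    """Row-stochastic per-cycle transition matrix at one cohort age."""
    ss = state_space(params.detection_cap_cycles)
    n_cyc = params.cycles_per_year

    def a2c(p_annual: float) -> float:
        return annual_to_cycle_probability(p_annual, n_cyc)

    rr = params.treatment_rr
    outflows: dict[str, dict[str, float]] = {
        ss.CN_AN: {ss.MCI_AN: a2c(params.p_cn_to_mci)},
        ss.CN_AP_UNKNOWN: {ss.MCI_AP_UNKNOWN: a2c(params.p_cn_to_mci)},
        ss.CN_AP_KNOWN: {ss.MCI_AP_KNOWN: a2c(params.p_cn_to_mci)},
        ss.MCI_AN: {
            ss.CN_AN: a2c(params.p_mci_to_cn),
            _tunnel_entry(params, strategy, ss.MCI_AN): a2c(params.p_anmci_to_mild),
            ss.NONAD_EXIT: a2c(params.p_mci_to_nonad),
        },
        ss.MCI_AP_UNKNOWN: {
            ss.CN_AP_UNKNOWN: a2c(params.p_mci_to_cn),
            _tunnel_entry(params, strategy, ss.MCI_AP_UNKNOWN): a2c(
                conversion_probability_ap(params, identified=False)
            ),
            ss.NONAD_EXIT: a2c(params.p_mci_to_nonad),
        },
        ss.MCI_AP_KNOWN: {
            ss.CN_AP_KNOWN: a2c(params.p_mci_to_cn),
            _tunnel_entry(params, strategy, ss.MCI_AP_KNOWN): a2c(
                conversion_probability_ap(params, identified=True)
            ),
            ss.NONAD_EXIT: a2c(params.p_mci_to_nonad),
        },
        ss.MILD_TREATED: {
            ss.MOD_TREATED: a2c(treated_probability(params.p_mild_to_mod, rr)),
            ss.SEV_TREATED: a2c(treated_probability(params.p_mild_to_sev, rr)),
        },
        ss.MOD_TREATED: {
            # improvement is not a worsening transition: no treatment RR
            ss.MILD_TREATED: a2c(params.p_mod_to_mild),
            ss.SEV_TREATED: a2c(treated_probability(params.p_mod_to_sev, rr)),
        },
        ss.SEV_TREATED: {},
    }
    mat = np.zeros((len(ss), len(ss)))
    for label in ss:
        i = ss.index[label]
        if ss.is_absorbing(label):
            mat[i, i] = 1.0
            continue
        q_death = mortality_probability(lt, age, label, params)
        survive = 1.0 - q_death
        mat[i, ss.index[ss.DEATH]] = q_death
        if ss.is_tunnel(label):
            # untreated worsening runs concurrently with detection, but
            # detection is a labelling event, not a clinical transition:
            # it applies only to the mass that is still mild at cycle end,
            # so tier dynamics do not depend on the follow-up schedule
            worsen = {
                ss.MOD_TREATED: a2c(params.p_mild_to_mod),
                ss.SEV_TREATED: a2c(params.p_mild_to_sev),
            }
            w = sum(worsen.values())
            w_scale = 1.0 / w if w > 1.0 else 1.0
            for target, p in worsen.items():
                mat[i, ss.index[target]] += survive * p * w_scale
            still_mild = survive * (1.0 - min(w, 1.0))
            d = detection_probability(label, params, strategy)
            mat[i, ss.index[ss.MILD_TREATED]] += still_mild * d
            nxt = ss.tunnel_next(label)
            undetected = still_mild * (1.0 - d)
            if nxt is None:
                # cap row: detection hazard is forced to 1, nothing remains
                if undetected > _ROW_TOL:
                    raise RuntimeError(f"tunnel cap row {label} leaked mass")
            else:
                mat[i, ss.index[nxt]] += undetected
            continue
        flows = outflows[label]
        total = sum(flows.values())
        scale = 1.0 / total if total > 1.0 else 1.0
        for target, p in flows.items():
            mat[i, ss.index[target]] += survive * p * scale
        mat[i, i] += survive * (1.0 - min(total, 1.0))

    row_sums = mat.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > _ROW_TOL) or np.any(mat < 0):
        bad = ss.labels[int(np.argmax(np.abs(row_sums - 1.0)))]
        raise RuntimeError(f"transition matrix row {bad} is not stochastic")
    return mat


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy of every state, from cycle 0 to extinction.

    ``occupancy[c]`` is the distribution at the *start* of cycle c;
    the last row is the final (absorbed) distribution.
    """

    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    cycle_times: np.ndarray  # years since model start, same length
    space: StateSpace
    strategy_name: str

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state(self, label: str) -> np.ndarray:
        return self.occupancy[:, self.space.index[label]]

    def tier_occupancy(self, tier) -> np.ndarray:
        """Summed occupancy of all states in one clinical tier."""
        cols = [i for i, lab in enumerate(self.space.labels) if self.space.tier(lab) == tier]
        return self.occupancy[:, cols].sum(axis=1)

    def to_frame(self, params: ParameterSet | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.space.labels))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(1, "time_years", self.cycle_times)
        if params is not None:
            df.insert(2, "age_years", params.start_age + self.cycle_times)
        return df


def run_cohort(
    params: ParameterSet, lt: LifeTable, strategy: Strategy
) -> CohortTrace:
    """Iterate the cohort to extinction (or the age cap).

    The matrix is age-dependent and rebuilt whenever the cohort's integer
    age increments.  Any mass still alive at max_age is sent to death.
    """
    ss = state_space(params.detection_cap_cycles)
    if lt.min_age > params.start_age:
        raise ValueError("life table does not cover the start age")
    occ = initial_distribution(params, strategy.use_pet)
    rows = [occ]
    times = [0.0]
    i_death = ss.index[ss.DEATH]
    i_nonad = ss.index[ss.NONAD_EXIT]
    matrices: dict[int, np.ndarray] = {}
    c = 0
    while True:
        t = c * params.cycle_length
        age = params.start_age + t
        living = 1.0 - occ[i_death] - occ[i_nonad]
        if living < _EXTINCTION:
            break
        if age >= params.max_age:
            final = occ.copy()
            alive = final.sum() - final[i_death] - final[i_nonad]
            final[:] = 0.0
            final[i_nonad] = occ[i_nonad]
            final[i_death] = occ[i_death] + alive
            rows.append(final)
            times.append(t + params.cycle_length)
            break
        year = int(np.floor(age))
        if year not in matrices:
            matrices[year] = build_transition_matrix(params, lt, strategy, year)
        occ = occ @ matrices[year]
        c += 1
        rows.append(occ)
        times.append(c * params.cycle_length)
    return CohortTrace(
        occupancy=np.vstack(rows),
        cycle_times=np.asarray(times),
        space=ss,
        strategy_name=strategy.name,
    )
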
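"""Individual-level Monte-Carlo simulator used as an independent oracle
for the cohort trace.

Implements the same model rules as the cohort engine — constant-hazard
annual-to-cycle conversion, death first, hierarchical tunnel composition
— but through its own arithmetic and by sampling individuals, never by
calling the package's matrix builder.  Agreement of state frequencies
with the deterministic trace is a strong end-to-end check on both.
"""

from __future__ import annotations

import math

import numpy as np

from petcea.parameters import ParameterSet
from petcea.states import state_space
from petcea.strategies import Strategy


def _per_cycle(p_annual: float, n: int) -> float:
    if p_annual >= 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (1.0 / n)


def _death_prob(qx: float, mult: float, n: int) -> float:
    if qx >= 1.0:
        return 1.0
    return min(1.0, 1.0 - (1.0 - qx) ** (mult / n))


def _destinations(
    label: str, params: ParameterSet, strategy: Strategy, qx: float
) -> dict[str, float]:
    """Outcome distribution for one individual in ``label`` for one cycle."""
    ss = state_space(params.detection_cap_cycles)
    n = round(1.0 / params.cycle_length)
    rr = params.treatment_rr
    p_ap = min(1.0, params.p_anmci_to_mild * params.rr_ap_conversion)
    p_ap_known = min(1.0, p_ap * params.intervention_effect)

    if ss.is_absorbing(label):
        return {label: 1.0}

    mult = 1.0
    if label == ss.MOD_TREATED:
        mult = params.excess_mort_moderate
    elif label == ss.SEV_TREATED:
        mult = params.excess_mort_severe
    qd = _death_prob(qx, mult, n)
    alive = 1.0 - qd
    out = {ss.DEATH: qd}

    if ss.is_tunnel(label):
        w_mod = _per_cycle(params.p_mild_to_mod, n)
        w_sev = _per_cycle(params.p_mild_to_sev, n)
        w = w_mod + w_sev
        if w > 1.0:
            w_mod, w_sev, w = w_mod / w, w_sev / w, 1.0
        k = ss.tunnel_step(label)
        if k >= ss.n_tunnel:
            d = 1.0
        else:
            d = min(1.0, params.cycle_length / strategy.interval(label))
        mild = alive * (1.0 - w)
        out[ss.MOD_TREATED] = alive * w_mod
        out[ss.SEV_TREATED] = alive * w_sev
        out[ss.MILD_TREATED] = mild * d
        nxt = ss.tunnel_next(label)
        if nxt is not None:
            out[nxt] = mild * (1.0 - d)
        return out

    def quarterly(mci_label: str) -> bool:
        return math.isclose(
            strategy.interval(mci_label), params.followup_interval_ap_detected
        )

    def tunnel1(mci_label: str) -> str:
        return (ss.tunnel_quarterly if quarterly(mci_label) else ss.tunnel_annual)[0]

    flows: dict[str, float]
    if label == ss.CN_AN:
        flows = {ss.MCI_AN: _per_cycle(params.p_cn_to_mci, n)}
    elif label == ss.CN_AP_UNKNOWN:
        flows = {ss.MCI_AP_UNKNOWN: _per_cycle(params.p_cn_to_mci, n)}
    elif label == ss.CN_AP_KNOWN:
        flows = {ss.MCI_AP_KNOWN: _per_cycle(params.p_cn_to_mci, n)}
    elif label == ss.MCI_AN:
        flows = {
            ss.CN_AN: _per_cycle(params.p_mci_to_cn, n),
            tunnel1(label): _per_cycle(params.p_anmci_to_mild, n),
            ss.NONAD_EXIT: _per_cycle(params.p_mci_to_nonad, n),
        }
    elif label == ss.MCI_AP_UNKNOWN:
        flows = {
            ss.CN_AP_UNKNOWN: _per_cycle(params.p_mci_to_cn, n),
            tunnel1(label): _per_cycle(p_ap, n),
            ss.NONAD_EXIT: _per_cycle(params.p_mci_to_nonad, n),
        }
    elif label == ss.MCI_AP_KNOWN:
        flows = {
            ss.CN_AP_KNOWN: _per_cycle(params.p_mci_to_cn, n),
            tunnel1(label): _per_cycle(p_ap_known, n),
            ss.NONAD_EXIT: _per_cycle(params.p_mci_to_nonad, n),
        }
    elif label == ss.MILD_TREATED:
        flows = {
            ss.MOD_TREATED: _per_cycle(min(1.0, params.p_mild_to_mod * rr), n),
            ss.SEV_TREATED: _per_cycle(min(1.0, params.p_mild_to_sev * rr), n),
        }
    elif label == ss.MOD_TREATED:
        flows = {
            ss.MILD_TREATED: _per_cycle(params.p_mod_to_mild, n),
            ss.SEV_TREATED: _per_cycle(min(1.0, params.p_mod_to_sev * rr), n),
        }
    elif label == ss.SEV_TREATED:
        flows = {}
    else:  # pragma: no cover
        raise AssertionError(label)

    total = sum(flows.values())
    scale = 1.0 / total if total > 1.0 else 1.0
    for target, p in flows.items():
        out[target] = out.get(target, 0.0) + alive * p * scale
    out[label] = out.get(label, 0.0) + alive * (1.0 - min(total, 1.0))
    return out


def expected_frequencies(
    params: ParameterSet,
    lt,
    strategy: Strategy,
    record_cycles: tuple[int, ...],
) -> dict[int, np.ndarray]:
    """Deterministic expectation of the simulator: the same independent
    row arithmetic propagated exactly instead of sampled."""
    ss = state_space(params.detection_cap_cycles)
    labels = list(ss.labels)
    idx = ss.index
    occ = np.zeros(len(labels))
    prev = params.ap_prevalence
    if strategy.use_pet:
        occ[idx[ss.MCI_AP_KNOWN]] = prev * params.pet_sensitivity + (1 - prev) * (
            1 - params.pet_specificity
        )
        occ[idx[ss.MCI_AP_UNKNOWN]] = prev * (1 - params.pet_sensitivity)
        occ[idx[ss.MCI_AN]] = (1 - prev) * params.pet_specificity
    else:
        occ[idx[ss.MCI_AP_UNKNOWN]] = prev
        occ[idx[ss.MCI_AN]] = 1 - prev
    out: dict[int, np.ndarray] = {}
    if 0 in record_cycles:
        out[0] = occ.copy()
    for c in range(1, max(record_cycles) + 1):
        age = params.start_age + (c - 1) * params.cycle_length
        qx = lt.annual_qx(int(math.floor(age)))
        new = np.zeros(len(labels))
        for j, label in enumerate(labels):
            if occ[j] == 0.0:
                continue
            for target, p in _destinations(label, params, strategy, qx).items():
                new[idx[target]] += occ[j] * p
        occ = new
        if c in record_cycles:
            out[c] = occ.copy()
    return out


def simulate_frequencies(
    params: ParameterSet,
    lt,
    strategy: Strategy,
    n_patients: int,
    record_cycles: tuple[int, ...],
    seed: int,
) -> dict[int, np.ndarray]:
    """State frequencies of ``n_patients`` simulated individuals at the
    requested cycle starts (cycle c = after c transitions)."""
    rng = np.random.default_rng(seed)
    ss = state_space(params.detection_cap_cycles)
    labels = list(ss.labels)
    idx = ss.index

    counts = np.zeros(len(labels), dtype=np.int64)
    prev = params.ap_prevalence
    if strategy.use_pet:
        probs = np.zeros(len(labels))
        probs[idx[ss.MCI_AP_KNOWN]] = prev * params.pet_sensitivity + (1 - prev) * (
            1 - params.pet_specificity
        )
        probs[idx[ss.MCI_AP_UNKNOWN]] = prev * (1 - params.pet_sensitivity)
        probs[idx[ss.MCI_AN]] = (1 - prev) * params.pet_specificity
    else:
        probs = np.zeros(len(labels))
        probs[idx[ss.MCI_AP_UNKNOWN]] = prev
        probs[idx[ss.MCI_AN]] = 1 - prev
    counts = rng.multinomial(n_patients, probs)

    out: dict[int, np.ndarray] = {}
    if 0 in record_cycles:
        out[0] = counts / n_patients
    last = max(record_cycles)
    for c in range(1, last + 1):
        age = params.start_age + (c - 1) * params.cycle_length
        year = int(math.floor(age))
        qx = lt.annual_qx(year)
        new = np.zeros(len(labels), dtype=np.int64)
        for j, label in enumerate(labels):
            if counts[j] == 0:
                continue
            dest = _destinations(label, params, strategy, qx)
            targets = list(dest)
            p = np.array([dest[t] for t in targets])
            p = p / p.sum()
            draw = rng.multinomial(counts[j], p)
            for t, k in zip(targets, draw):
                new[idx[t]] += k
        counts = new
        if c in record_cycles:
            out[c] = counts / n_patients
    return out
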
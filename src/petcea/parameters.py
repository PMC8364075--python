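"""Model inputs: the base-case parameter set, validation, and config I/O.

The base case describes a cohort of 60-year-old patients diagnosed with
mild cognitive impairment (MCI) in the 2017 Korean health-care setting.
Transition probabilities are annual; the engine converts them to the
3-month cycle internally.  Costs are 2017 USD (1,130 KRW/USD).
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterSet",
    "SensitivityRanges",
    "ValidationError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "default_ranges",
]


class ValidationError(ValueError):
    """A parameter value violates its domain constraint."""


# field name -> (kind, description) used for validation and config round-trips
_PROB = "probability"
_PROP = "proportion"
_MULT = "positive multiplier"
_COST = "non-negative cost"
_TIME = "positive time"

_FIELD_KINDS = {
    "p_cn_to_mci": _PROB,
    "p_mci_to_cn": _PROB,
    "p_anmci_to_mild": _PROB,
    "p_mci_to_nonad": _PROB,
    "p_mild_to_mod": _PROB,
    "p_mild_to_sev": _PROB,
    "p_mod_to_mild": _PROB,
    "p_mod_to_sev": _PROB,
    "excess_mort_moderate": _MULT,
    "excess_mort_severe": _MULT,
    "ap_prevalence": _PROP,
    "rr_ap_conversion": _MULT,
    "pet_sensitivity": _PROP,
    "pet_specificity": _PROP,
    "utility_cn": _PROP,
    "utility_mci": _PROP,
    "utility_mild": _PROP,
    "utility_mod": _PROP,
    "utility_sev": _PROP,
    "medcost_mci": _COST,
    "medcost_mild": _COST,
    "medcost_mod": _COST,
    "medcost_sev": _COST,
    "nonmedcost_mci": _COST,
    "nonmedcost_mild": _COST,
    "nonmedcost_mod": _COST,
    "nonmedcost_sev": _COST,
    "pet_cost": _COST,
    "followup_cost_per_visit": _COST,
    "treatment_rr": _MULT,
    "intervention_effect": _MULT,
    "start_age": _TIME,
    "discount_rate": _COST,  # non-negative rate
    "cycle_length": _TIME,
    "detection_cap_years": _TIME,
    "max_age": _TIME,
    "followup_interval_mci": _TIME,
    "followup_interval_ap_detected": _TIME,
    "followup_interval_ad_detected": _TIME,
}


@dataclass(frozen=True)
class ParameterSet:
    """All model inputs for one analysis.

    Annual transition probabilities of the natural history (clinically
    normal <-> MCI, MCI -> mild AD for amyloid-negative patients, mild/
    moderate/severe AD progression), excess-mortality hazard multipliers
    for moderate and severe AD, amyloid-PET accuracy, per-state utilities
    and annual management costs, and model settings (cycle length,
    discount rate, horizon).
    """

    # natural history, annual probabilities
    p_cn_to_mci: float = 0.0341
    p_mci_to_cn: float = 0.0641
    p_anmci_to_mild: float = 0.0211
    p_mci_to_nonad: float = 0.0017
    p_mild_to_mod: float = 0.3220
    p_mild_to_sev: float = 0.0420
    p_mod_to_mild: float = 0.0430
    p_mod_to_sev: float = 0.3390
    # mortality hazard multipliers relative to the background life table
    excess_mort_moderate: float = 2.57
    excess_mort_severe: float = 7.82
    # amyloid positivity and its consequences
    ap_prevalence: float = 0.3910
    rr_ap_conversion: float = 7.95
    # amyloid-PET operating characteristics (autopsy-confirmed)
    pet_sensitivity: float = 0.92
    pet_specificity: float = 1.0
    # EQ-5D utilities by clinical tier
    utility_cn: float = 0.874
    utility_mci: float = 0.80
    utility_mild: float = 0.43
    utility_mod: float = 0.21
    utility_sev: float = 0.17
    # annual management costs, 2017 USD (clinically normal is 0 by definition)
    medcost_mci: float = 794.0
    medcost_mild: float = 2113.0
    medcost_mod: float = 1478.0
    medcost_sev: float = 1819.0
    nonmedcost_mci: float = 2539.0
    nonmedcost_mild: float = 10956.0
    nonmedcost_mod: float = 11796.0
    nonmedcost_sev: float = 14273.0
    # one-time and per-visit costs
    pet_cost: float = 1041.0
    followup_cost_per_visit: float = 27.0
    # treatment (donepezil) relative risk on worsening transitions of
    # detected AD; virtual intervention multiplier on the identified
    # AP-MCI -> mild-AD transition (1 = no intervention)
    treatment_rr: float = 0.85
    intervention_effect: float = 1.0
    # model settings
    start_age: float = 60.0
    discount_rate: float = 0.05
    cycle_length: float = 0.25
    detection_cap_years: float = 3.0
    max_age: float = 120.0
    # follow-up intervals in years
    followup_interval_mci: float = 1.0
    followup_interval_ap_detected: float = 0.25
    followup_interval_ad_detected: float = 0.25

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, kind in _FIELD_KINDS.items():
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or math.isnan(v):
                raise ValidationError(f"{name}: not a finite number: {v!r}")
            if kind in (_PROB, _PROP) and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: {kind} must lie in [0, 1], got {v}")
            if kind == _MULT and not v > 0.0:
                raise ValidationError(f"{name}: {kind} must be > 0, got {v}")
            if kind == _COST and v < 0.0:
                raise ValidationError(f"{name}: {kind} must be >= 0, got {v}")
            if kind == _TIME and not v > 0.0:
                raise ValidationError(f"{name}: {kind} must be > 0, got {v}")
        if self.max_age <= self.start_age:
            raise ValidationError("max_age: must exceed start_age")
        for name in (
            "followup_interval_mci",
            "followup_interval_ap_detected",
            "followup_interval_ad_detected",
            "detection_cap_years",
        ):
            if not _divides(self.cycle_length, getattr(self, name)):
                raise ValidationError(
                    f"{name}: {getattr(self, name)} is not a whole number of "
                    f"cycles of length {self.cycle_length}"
                )

    @property
    def cycles_per_year(self) -> int:
        n = 1.0 / self.cycle_length
        if not _is_whole(n):
            raise ValidationError("cycle_length must divide one year evenly")
        return round(n)

    @property
    def detection_cap_cycles(self) -> int:
        """Tunnel length K: cycles after mild-AD onset at which detection is forced."""
        return round(self.detection_cap_years / self.cycle_length)

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a validated copy with the given fields changed."""
        unknown = set(changes) - set(_FIELD_KINDS)
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _FIELD_KINDS}


def _divides(step: float, total: float, tol: float = 1e-9) -> bool:
    ratio = total / step
    return abs(ratio - round(ratio)) < tol and round(ratio) >= 1


def _is_whole(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) < tol


def default_parameters() -> ParameterSet:
    """The base case: every input at its published point estimate."""
    return ParameterSet()


def load_parameters(source: str | Path | io.TextIOBase | Mapping | None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a flat YAML mapping.

    ``source`` may be a path, an open text stream, an in-memory mapping, or
    None/empty (the base case).  Keys not listed are left at their default;
    unknown keys are rejected so typos cannot silently revert to defaults.
    """
    if source is None:
        return default_parameters()
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValidationError(f"malformed config: {exc}") from exc
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValidationError("config must be a flat key/value mapping")
    return default_parameters().replace(**doc)


def save_parameters(params: ParameterSet, dest: str | Path | io.TextIOBase) -> None:
    """Write the full parameter set as a flat YAML mapping (round-trips)."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=True)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


@dataclass(frozen=True)
class SensitivityRanges:
    """(low, high) bounds per parameter for one-way sensitivity analysis.

    Keys are ParameterSet field names, plus the joint keys
    ``mgmtcost_{mci,mild,mod,sev}`` which scale the medical and non-medical
    annual cost of one severity tier together (their published range is
    +-50% of the combined management cost).
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __iter__(self):
        return iter(sorted(self.ranges.items()))

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.ranges[name]

    def validate_against(self, base: ParameterSet) -> None:
        for name, (lo, hi) in self.ranges.items():
            b = _base_value(base, name)
            if not lo <= b <= hi:
                raise ValidationError(
                    f"{name}: base value {b} outside sensitivity range ({lo}, {hi})"
                )


_MGMT_TIERS = ("mci", "mild", "mod", "sev")


def _base_value(params: ParameterSet, name: str) -> float:
    if name.startswith("mgmtcost_"):
        tier = name.removeprefix("mgmtcost_")
        return getattr(params, f"medcost_{tier}") + getattr(params, f"nonmedcost_{tier}")
    return getattr(params, name)


def default_ranges(params: ParameterSet | None = None) -> SensitivityRanges:
    """Published one-way sensitivity ranges.

    Literature-derived bounds where they exist; +-50% of the base case for
    cost items (the PET and follow-up cost bounds below are the published
    rounded values of that rule).
    """
    p = params or default_parameters()
    ranges: dict[str, tuple[float, float]] = {
        "ap_prevalence": (0.3617, 0.5556),
        "rr_ap_conversion": (3.53, 15.20),
        "pet_cost": (520.0, 1561.0),
        "followup_cost_per_visit": (14.0, 41.0),
        "treatment_rr": (0.70, 0.93),
        "intervention_effect": (0.95, 1.0),
        "start_age": (60.0, 80.0),
    }
    for tier in _MGMT_TIERS:
        total = getattr(p, f"medcost_{tier}") + getattr(p, f"nonmedcost_{tier}")
        ranges[f"mgmtcost_{tier}"] = (0.5 * total, 1.5 * total)
    sr = SensitivityRanges(ranges)
    sr.validate_against(p)
    return sr
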
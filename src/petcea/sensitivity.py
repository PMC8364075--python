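"""One-way sensitivity analysis: ICER at each parameter's bounds, tornado order."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .economics import CEComparison, accumulate, compare
from .life_tables import LifeTable
from .markov import run_cohort
from .parameters import ParameterSet, SensitivityRanges, ValidationError
from .strategies import current_practice, pet_strategy

__all__ = ["TornadoEntry", "run_icer", "one_way", "tornado_order", "tornado_frame"]


def run_icer(params: ParameterSet, lt: LifeTable) -> CEComparison:
    """Full two-strategy pipeline: PET strategy vs current practice."""
    comp = current_practice(params)
    pet = pet_strategy(params)
    res_comp = accumulate(run_cohort(params, lt, comp), params, comp)
    res_pet = accumulate(run_cohort(params, lt, pet), params, pet)
    return compare(res_comp, res_pet)


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at the low and high bound of one parameter (others at base).

    A bound whose comparison has no finite ICER carries its dominance
    label instead; ``span`` is the absolute difference of the two ICERs
    when both are finite, NaN otherwise.  ``error`` records a bound that
    produced an invalid parameter set.
    """

    parameter: str
    low: float
    high: float
    icer_low: float | str | None
    icer_high: float | str | None
    span: float
    error: str | None = None


def apply_bound(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Set one sensitivity parameter; mgmtcost_* scales its tier's
    medical and non-medical costs jointly, preserving their ratio."""
    if name.startswith("mgmtcost_"):
        tier = name.removeprefix("mgmtcost_")
        med = getattr(params, f"medcost_{tier}")
        nonmed = getattr(params, f"nonmedcost_{tier}")
        base_total = med + nonmed
        if base_total == 0:
            raise ValidationError(f"{name}: base management cost is 0, cannot scale")
        f = value / base_total
        return params.replace(
            **{f"medcost_{tier}": med * f, f"nonmedcost_{tier}": nonmed * f}
        )
    return params.replace(**{name: value})


def _icer_or_label(cmp_result: CEComparison) -> float | str | None:
    return cmp_result.icer if cmp_result.label == "icer" else cmp_result.label


def one_way(
    params: ParameterSet, ranges: SensitivityRanges, lt: LifeTable
) -> list[TornadoEntry]:
    """Rerun the full two-strategy pipeline at each parameter's bounds."""
    entries = []
    for name, (lo, hi) in ranges:
        try:
            icer_lo = _icer_or_label(run_icer(apply_bound(params, name, lo), lt))
            icer_hi = _icer_or_label(run_icer(apply_bound(params, name, hi), lt))
        except (ValidationError, ValueError) as exc:
            entries.append(
                TornadoEntry(name, lo, hi, None, None, math.nan, error=str(exc))
            )
            continue
        if isinstance(icer_lo, float) and isinstance(icer_hi, float):
            span = abs(icer_hi - icer_lo)
        else:
            span = math.nan
        entries.append(TornadoEntry(name, lo, hi, icer_lo, icer_hi, span))
    return entries


def tornado_order(entries: list[TornadoEntry]) -> list[TornadoEntry]:
    """Sort by span descending; non-finite spans (dominance ends, errors)
    last; ties broken by parameter name."""
    def key(e: TornadoEntry):
        finite = isinstance(e.span, float) and math.isfinite(e.span)
        return (not finite, -(e.span if finite else 0.0), e.parameter)

    return sorted(entries, key=key)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "span": e.span,
                "error": e.error,
            }
            for e in entries
        ]
    )
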
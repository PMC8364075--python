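"""Evidence synthesis for model inputs: relative risks from 2x2 counts
and their fixed-effect pooling.

Two model parameters are synthesis-based: the treatment relative risk on
AD worsening transitions (pooled over donepezil trials) and the relative
risk of MCI-to-AD conversion for amyloid-positive vs amyloid-negative
patients.  Both are plain risk ratios pooled under a fixed-effect
(common-effect) assumption, inverse-variance weighted on the log scale
by default, with Mantel-Haenszel as an option; heterogeneity is reported
as Cochran's Q but never acted upon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "StudyEffect",
    "PooledEffect",
    "study_rr",
    "fixed_effect_pool",
    "conversion_rr",
    "read_studies",
]


@dataclass(frozen=True)
class StudyEffect:
    """2x2 event counts for one study (treated/exposed vs control arm)."""

    study: str
    events_treated: float
    n_treated: float
    events_control: float
    n_control: float

    def __post_init__(self) -> None:
        for ev, n, arm in (
            (self.events_treated, self.n_treated, "treated"),
            (self.events_control, self.n_control, "control"),
        ):
            if n <= 0:
                raise ValueError(f"{self.study}: {arm} arm size must be > 0")
            if not 0 <= ev <= n:
                raise ValueError(f"{self.study}: {arm} events must lie in [0, n]")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (
            self.events_treated,
            self.events_control,
            self.n_treated - self.events_treated,
            self.n_control - self.events_control,
        )

    def corrected(self) -> "StudyEffect":
        """Continuity correction: add 0.5 to all four counts."""
        return StudyEffect(
            self.study,
            self.events_treated + 0.5,
            self.n_treated + 0.5,
            self.events_control + 0.5,
            self.n_control + 0.5,
        )


def study_rr(s: StudyEffect) -> tuple[float, float]:
    """Risk ratio of one study and the SE of its log.

    rr = (e_t/n_t) / (e_c/n_c);  se = sqrt(1/e_t - 1/n_t + 1/e_c - 1/n_c).
    Zero cells get the 0.5 continuity correction first.
    """
    if s.has_zero_cell:
        s = s.corrected()
    rr = (s.events_treated / s.n_treated) / (s.events_control / s.n_control)
    se = math.sqrt(
        1.0 / s.events_treated
        - 1.0 / s.n_treated
        + 1.0 / s.events_control
        - 1.0 / s.n_control
    )
    return rr, se


@dataclass(frozen=True)
class PooledEffect:
    """Fixed-effect pooled risk ratio with 95% CI and heterogeneity."""

    rr: float
    ci_low: float
    ci_high: float
    se_log_rr: float
    method: str
    n_studies: int
    weights: tuple[float, ...]  # normalised, sum to 1
    cochran_q: float
    q_df: int
    q_pvalue: float
    corrected_studies: tuple[str, ...]  # studies that needed continuity correction

    def as_dict(self) -> dict:
        return {
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se_log_rr": self.se_log_rr,
            "method": self.method,
            "n_studies": self.n_studies,
            "cochran_q": self.cochran_q,
            "q_df": self.q_df,
            "q_pvalue": self.q_pvalue,
            "corrected_studies": list(self.corrected_studies),
        }


def fixed_effect_pool(
    studies: Sequence[StudyEffect], method: str = "inverse_variance"
) -> PooledEffect:
    """Pool risk ratios under a common-effect assumption.

    ``inverse_variance`` (default): weighted mean of log RRs with weights
    1/se^2; CI = exp(pooled +- 1.96 x pooled SE).  ``mantel_haenszel``:
    the MH summary RR with the same IV standard error for the CI.
    """
    if not studies:
        raise ValueError("at least one study is required")
    if method not in ("inverse_variance", "mantel_haenszel"):
        raise ValueError(f"unknown pooling method: {method}")

    corrected = tuple(s.study for s in studies if s.has_zero_cell)
    per_study = [study_rr(s) for s in studies]
    log_rrs = [math.log(rr) for rr, _ in per_study]
    ivs = [1.0 / se**2 for _, se in per_study]
    w_total = sum(ivs)
    pooled_log_iv = sum(w * lr for w, lr in zip(ivs, log_rrs)) / w_total
    pooled_se = math.sqrt(1.0 / w_total)

    if method == "mantel_haenszel":
        cs = [s.corrected() if s.has_zero_cell else s for s in studies]
        num = sum(s.events_treated * s.n_control / (s.n_treated + s.n_control) for s in cs)
        den = sum(s.events_control * s.n_treated / (s.n_treated + s.n_control) for s in cs)
        pooled_log = math.log(num / den)
    else:
        pooled_log = pooled_log_iv

    q = sum(w * (lr - pooled_log_iv) ** 2 for w, lr in zip(ivs, log_rrs))
    df = len(studies) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else math.nan

    return PooledEffect(
        rr=math.exp(pooled_log),
        ci_low=math.exp(pooled_log - 1.96 * pooled_se),
        ci_high=math.exp(pooled_log + 1.96 * pooled_se),
        se_log_rr=pooled_se,
        method=method,
        n_studies=len(studies),
        weights=tuple(w / w_total for w in ivs),
        cochran_q=q,
        q_df=df,
        q_pvalue=q_p,
        corrected_studies=corrected,
    )


def conversion_rr(
    studies: Iterable[StudyEffect], method: str = "inverse_variance"
) -> PooledEffect:
    """Relative risk of MCI-to-AD conversion, amyloid-positive vs negative.

    The 'treated' arm holds amyloid-positive converters, the 'control'
    arm amyloid-negative; a single study reduces to the simple rate ratio.
    """
    return fixed_effect_pool(list(studies), method=method)


def read_studies(source) -> list[StudyEffect]:
    """Read studies from CSV with columns study,events_t,n_t,events_c,n_c."""
    df = pd.read_csv(source)
    required = {"study", "events_t", "n_t", "events_c", "n_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study CSV missing column(s): {sorted(missing)}")
    return [
        StudyEffect(
            str(r.study),
            float(r.events_t),
            float(r.n_t),
            float(r.events_c),
            float(r.n_c),
        )
        for r in df.itertuples()
    ]
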
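"""The health-state space of the disease-progression model.

Clinical tiers: clinically normal (CN), mild cognitive impairment (MCI),
mild / moderate / severe Alzheimer's disease (AD), plus two absorbing
exits (non-AD dementia and death).  Each CN/MCI state also carries the
patient's amyloid status (positive AP / negative AN) and, for AP,
whether a baseline amyloid-PET has identified it — amyloid status is a
biological trait carried through clinical reversion.

Undetected mild AD is a tunnel: one state per cycle since onset, so that
detection can be forced after a fixed cap (3 years at base settings).
Two parallel tunnels record the follow-up schedule the patient carried
as MCI (annual vs quarterly), which drives the detection hazard.
Moderate and severe AD are detected immediately, hence always treated.
"""

from __future__ import annotations

from enum import Enum
from functools import lru_cache

__all__ = ["Tier", "StateSpace", "state_space"]


class Tier(str, Enum):
    """Clinical severity tier; utilities and management costs attach here."""

    CN = "cn"
    MCI = "mci"
    MILD = "mild"
    MOD = "mod"
    SEV = "sev"
    NONE = "none"  # absorbing exits accrue nothing


class StateSpace:
    """Immutable indexed state list for a given tunnel length K."""

    # fixed (non-tunnel) states
    CN_AN = "CN_AN"
    CN_AP_UNKNOWN = "CN_AP_unknown"
    CN_AP_KNOWN = "CN_AP_known"
    MCI_AN = "MCI_AN"
    MCI_AP_UNKNOWN = "MCI_AP_unknown"
    MCI_AP_KNOWN = "MCI_AP_known"
    MILD_TREATED = "MILD_treated"
    MOD_TREATED = "MOD_treated"
    SEV_TREATED = "SEV_treated"
    NONAD_EXIT = "NONAD_exit"
    DEATH = "DEATH"

    def __init__(self, n_tunnel: int):
        if n_tunnel < 1:
            raise ValueError("tunnel length must be >= 1")
        self.n_tunnel = n_tunnel
        self.tunnel_annual = [f"MILD_undet_annual_{k}" for k in range(1, n_tunnel + 1)]
        self.tunnel_quarterly = [
            f"MILD_undet_quarterly_{k}" for k in range(1, n_tunnel + 1)
        ]
        self.labels: tuple[str, ...] = tuple(
            [
                self.CN_AN,
                self.CN_AP_UNKNOWN,
                self.CN_AP_KNOWN,
                self.MCI_AN,
                self.MCI_AP_UNKNOWN,
                self.MCI_AP_KNOWN,
            ]
            + self.tunnel_annual
            + self.tunnel_quarterly
            + [
                self.MILD_TREATED,
                self.MOD_TREATED,
                self.SEV_TREATED,
                self.NONAD_EXIT,
                self.DEATH,
            ]
        )
        self.index = {label: i for i, label in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    # --- classification helpers -------------------------------------------

    def is_tunnel(self, label: str) -> bool:
        return label.startswith("MILD_undet_")

    def tunnel_step(self, label: str) -> int:
        """1-based cycles-since-onset index k of a tunnel state."""
        if not self.is_tunnel(label):
            raise ValueError(f"{label} is not an undetected-mild tunnel state")
        return int(label.rsplit("_", 1)[1])

    def tunnel_schedule(self, label: str) -> str:
        """'annual' or 'quarterly': the follow-up schedule carried into the tunnel."""
        if not self.is_tunnel(label):
            raise ValueError(f"{label} is not an undetected-mild tunnel state")
        return label.split("_")[2]

    def tunnel_next(self, label: str) -> str | None:
        """Successor tunnel state, or None at the cap."""
        k = self.tunnel_step(label)
        if k >= self.n_tunnel:
            return None
        return f"MILD_undet_{self.tunnel_schedule(label)}_{k + 1}"

    def is_absorbing(self, label: str) -> bool:
        return label in (self.NONAD_EXIT, self.DEATH)

    def tier(self, label: str) -> Tier:
        if label.startswith("CN_"):
            return Tier.CN
        if label.startswith("MCI_"):
            return Tier.MCI
        if self.is_tunnel(label) or label == self.MILD_TREATED:
            return Tier.MILD
        if label == self.MOD_TREATED:
            return Tier.MOD
        if label == self.SEV_TREATED:
            return Tier.SEV
        return Tier.NONE


@lru_cache(maxsize=None)
def state_space(n_tunnel: int) -> StateSpace:
    """Cached state space for a tunnel of ``n_tunnel`` cycles (base 12)."""
    return StateSpace(n_tunnel)
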
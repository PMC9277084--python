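"""Quality-adjusted life-year accrual from state occupancy.

Health-state utilities follow the published base case: 0.74 while
progression-free, 0.58 after progression, 0 when dead.  QALYs are the
occupancy-weighted utility integrated over the cycle grid and discounted
at each cycle's midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psm import StateTrace, discount_factor
from .survival import DAYS_PER_YEAR


@dataclass(frozen=True)
class UtilitySet:
    """Per-state utilities with the ordering 0 <= u_dead <= u_pd <= u_pf <= 1.

    ``mode`` selects the accrual interpretation: ``"constant"`` values each
    state at its utility; ``"linear_decline"`` approximates, at cohort
    level, a utility that falls linearly from u_pf at progression toward
    u_dead at death, by valuing PF person-time at (u_pf+u_pd)/2 and PD
    person-time at (u_pd+u_dead)/2.  The constant mode is the base case:
    it is the interpretation the sensitivity analyses parameterize.
    """

    u_pf: float = 0.74
    u_pd: float = 0.58
    u_dead: float = 0.0
    mode: str = "constant"

    def __post_init__(self):
        if not (0.0 <= self.u_dead <= self.u_pd <= self.u_pf <= 1.0):
            raise ValueError("utilities must satisfy 0 <= u_dead <= u_pd <= u_pf <= 1")
        if self.mode not in ("constant", "linear_decline"):
            raise ValueError(f"unknown utility mode {self.mode!r}")

    def effective(self) -> tuple[float, float]:
        """(PF, PD) person-time utility weights under the selected mode."""
        if self.mode == "constant":
            return self.u_pf, self.u_pd
        return (self.u_pf + self.u_pd) / 2.0, (self.u_pd + self.u_dead) / 2.0


def qaly_quantities(trace: StateTrace, annual_rate: float) -> tuple[float, float]:
    """Discounted person-years in (PF, PD); QALYs are their utility dot."""
    disc = discount_factor(trace.t_mid, annual_rate)
    dt_years = trace.cycle_days / DAYS_PER_YEAR
    q_pf = float(np.sum(trace.pf * dt_years * disc))
    q_pd = float(np.sum(trace.pd * dt_years * disc))
    return q_pf, q_pd


def accrue_qalys(trace: StateTrace, utilities: UtilitySet, annual_rate: float) -> float:
    """Total discounted QALYs for one arm over the model horizon."""
    q_pf, q_pd = qaly_quantities(trace, annual_rate)
    w_pf, w_pd = utilities.effective()
    return w_pf * q_pf + w_pd * q_pd
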
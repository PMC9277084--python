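"""End-to-end model evaluation: config -> curves -> occupancy -> cost/QALY.

This is the glue the sensitivity analyses re-enter with perturbed inputs.
A full evaluation is split into two stages: ``model_quantities`` computes
every expected discounted quantity (administrations, tests, person-years,
deaths) from the survival curves and cycle grid, and
``evaluate_from_quantities`` prices those quantities under a unit-cost and
utility vector.  The second stage is linear, so one-way excursions over
prices/utilities and the whole probabilistic sensitivity analysis reuse a
single set of quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from . import costs as _costs
from .config import StudyConfig
from .outcomes import UtilitySet, qaly_quantities
from .psm import partition_states
from .survival import PiecewiseExpCurve, fit_piecewise_exponential


@dataclass(frozen=True)
class CEResult:
    """Per-arm discounted totals and the incremental comparison."""

    arms: tuple[str, str]  # (intervention, comparator)
    cost: Mapping[str, float]
    qaly: Mapping[str, float]
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    code: str  # "ok" | "dominant" | "dominated" | "undefined"

    def to_dict(self) -> dict:
        i, c = self.arms
        return {
            "intervention": i,
            "comparator": c,
            "cost": dict(self.cost),
            "qaly": dict(self.qaly),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "code": self.code,
        }


def compare(cost1: float, cost0: float, e1: float, e0: float,
            arms: tuple[str, str] = ("intervention", "comparator")) -> CEResult:
    """ICER with explicit dominance coding (never an error)."""
    dc, de = cost1 - cost0, e1 - e0
    if de > 0:
        icer = dc / de
        code = "dominant" if dc <= 0 else "ok"
    elif dc >= 0:
        icer, code = None, "dominated"
    else:
        icer, code = None, "undefined"  # southwest quadrant: cheaper, less effective
    return CEResult(
        arms,
        {arms[0]: cost1, arms[1]: cost0},
        {arms[0]: e1, arms[1]: e0},
        dc,
        de,
        icer,
        code,
    )


def build_curves(
    cfg: StudyConfig, hazard_scales: Optional[Mapping[str, float]] = None
) -> dict[str, PiecewiseExpCurve]:
    """Calibrated per-arm/endpoint curves, optionally hazard-rescaled per arm."""
    hazard_scales = hazard_scales or {}
    curves = {}
    for arm in (cfg.intervention, cfg.comparator):
        scale = hazard_scales.get(arm, 1.0)
        for endpoint in ("OS", "PFS"):
            curve = fit_piecewise_exponential(cfg.build_summary(arm, endpoint))
            if scale != 1.0:
                curve = curve.scale_hazard(scale)
            curves[f"{arm}/{endpoint}"] = curve
    return curves


@dataclass(frozen=True)
class ArmQuantities:
    cost_qty: Mapping[str, Mapping[str, float]]  # parameter -> {category: qty}
    q_pf: float
    q_pd: float


def model_quantities(
    cfg: StudyConfig,
    curves: Mapping[str, PiecewiseExpCurve],
    discount_rate: Optional[float] = None,
) -> dict[str, ArmQuantities]:
    """Stage 1: expected discounted quantities per arm."""
    rate = cfg.discount_rate if discount_rate is None else discount_rate
    grid = cfg.build_grid()
    monitoring = cfg.build_monitoring()
    out = {}
    for arm in (cfg.intervention, cfg.comparator):
        os_curve = curves[f"{arm}/OS"]
        pfs_curve = curves[f"{arm}/PFS"]
        trace = partition_states(os_curve, pfs_curve, grid, cfg.accrual_convention)
        spec = cfg.build_arm_spec(arm)
        cost_qty = _costs.arm_cost_quantities(spec, pfs_curve, trace, grid, rate, monitoring)
        q_pf, q_pd = qaly_quantities(trace, rate)
        out[arm] = ArmQuantities(cost_qty, q_pf, q_pd)
    return out


def _effective_unit_costs(cfg: StudyConfig, unit_costs: Mapping[str, float]) -> dict:
    """In vial mode, per-administration drug costs come from the vial optimizer."""
    out = dict(unit_costs)
    if cfg.acquisition_mode == "vial":
        prices = cfg.build_vial_prices()
        for arm in (cfg.intervention, cfg.comparator):
            for reg in cfg.build_arm_spec(arm).regimens:
                out[f"{reg.drug}_per_admin"] = _costs.per_admin_vial_cost(
                    reg.drug, reg.dose_mg, prices
                )
    return out


def evaluate_from_quantities(
    cfg: StudyConfig,
    quantities: Mapping[str, ArmQuantities],
    unit_costs: Optional[Mapping[str, float]] = None,
    u_pf: Optional[float] = None,
    u_pd: Optional[float] = None,
) -> tuple[CEResult, dict[str, _costs.CostBreakdown]]:
    """Stage 2: price the quantities under a unit-cost/utility vector."""
    uc = _effective_unit_costs(cfg, unit_costs or cfg.base_unit_costs())
    util = UtilitySet(
        u_pf=cfg.utilities.pf.base if u_pf is None else u_pf,
        u_pd=cfg.utilities.pd.base if u_pd is None else u_pd,
        mode=cfg.utilities.mode,
    )
    w_pf, w_pd = util.effective()
    costs, qalys, breakdowns = {}, {}, {}
    for arm, q in quantities.items():
        bd = _costs.price_cost(q.cost_qty, uc)
        breakdowns[arm] = bd
        costs[arm] = bd.total
        qalys[arm] = w_pf * q.q_pf + w_pd * q.q_pd
    i, c = cfg.intervention, cfg.comparator
    return compare(costs[i], costs[c], qalys[i], qalys[c], arms=(i, c)), breakdowns


def evaluate(
    cfg: StudyConfig,
    curves: Optional[Mapping[str, PiecewiseExpCurve]] = None,
    unit_costs: Optional[Mapping[str, float]] = None,
    u_pf: Optional[float] = None,
    u_pd: Optional[float] = None,
    discount_rate: Optional[float] = None,
    hazard_scales: Optional[Mapping[str, float]] = None,
) -> tuple[CEResult, dict[str, _costs.CostBreakdown]]:
    """Full base-case (or perturbed) model run."""
    if curves is None or hazard_scales:
        curves = build_curves(cfg, hazard_scales)
    quantities = model_quantities(cfg, curves, discount_rate)
    return evaluate_from_quantities(cfg, quantities, unit_costs, u_pf, u_pd)
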
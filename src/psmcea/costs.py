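"""Declarative cost accrual for the partitioned survival model.

Every cost component is expressed as ``unit cost x expected discounted
quantity``: drug acquisition and administration follow the dosing calendar
weighted by the probability of still being on treatment (progression-free
survival is the time-on-treatment proxy), monitoring follows the trial's
assessment schedule, adverse-event management is a one-time expected cost
at model entry, progressed-disease visits follow PD occupancy per cycle,
and the terminal (funeral) cost follows the death increments.

Separating quantities from unit costs keeps every total linear in the unit
costs, which is what makes the probabilistic sensitivity analysis a single
matrix product instead of 10,000 model re-runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .psm import ModelGrid, StateTrace, discount_factor
from .survival import PiecewiseExpCurve

CATEGORIES = ("acquisition", "administration", "monitoring", "adverse_events",
              "pd_visits", "terminal")

#: Table-1 style laboratory bundle repeated before every drug administration.
PER_ADMIN_LAB_ITEMS = ("ecg", "hematology", "serum_chemistry", "urinalysis", "coagulation")
#: One-off work-up at model entry (includes the baseline tumour scan).
BASELINE_ITEMS = PER_ADMIN_LAB_ITEMS + (
    "thyroid_function", "pulmonary_function", "hbv_hcv_serology", "radiologic_images",
)
ADMIN_FEE_ITEMS = ("preventive_medication", "infusion_fee", "hospitalization_fee")


@dataclass(frozen=True)
class PriceEntry:
    """One vial presentation: drug, vial size in mg, list price in US$."""

    drug: str
    size_mg: float
    price: float

    def __post_init__(self):
        if self.size_mg <= 0:
            raise ValueError("vial size must be positive")
        if self.price < 0:
            raise ValueError("vial price must be non-negative")


@dataclass(frozen=True)
class Schedule:
    """Administration calendar: either every ``interval_days`` or a repeating
    ``offsets_days`` pattern within ``period_days`` (e.g. weekly x6 then 1
    week off = offsets 0,7,...,35 in a 49-day period)."""

    interval_days: Optional[float] = None
    offsets_days: Optional[Sequence[float]] = None
    period_days: Optional[float] = None

    def dose_days(self, span_days: float) -> np.ndarray:
        """All scheduled dose days in [0, span]."""
        if self.interval_days is not None:
            return np.arange(0.0, span_days + 0.5, float(self.interval_days))
        if self.offsets_days is None or self.period_days is None:
            raise ValueError("schedule needs interval_days or offsets_days+period_days")
        n_periods = int(math.floor(span_days / self.period_days)) + 1
        days = (
            np.arange(n_periods)[:, None] * self.period_days
            + np.asarray(self.offsets_days, dtype=float)[None, :]
        ).ravel()
        return np.sort(days[days <= span_days + 0.5])


@dataclass(frozen=True)
class DosingRegimen:
    """One drug's dosing rule within an arm.

    ``dose_mg`` is the resolved per-administration dose (fixed mg, or
    mg/m2 x body surface area resolved upstream); ``weight`` is the
    fraction of the arm receiving this drug.
    """

    drug: str
    dose_mg: float
    schedule: Schedule
    weight: float = 1.0

    def __post_init__(self):
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")
        if not (0 < self.weight <= 1):
            raise ValueError("regimen weight must be in (0,1]")


@dataclass(frozen=True)
class AEItem:
    """A grade >=3 adverse event: management cost parameter name + incidence."""

    name: str
    incidence: float

    def __post_init__(self):
        if not (0.0 <= self.incidence <= 1.0):
            raise ValueError(f"AE incidence {self.incidence} outside [0,1]")


@dataclass(frozen=True)
class MonitoringRules:
    """Assessment calendar from the trial protocol."""

    thyroid_interval_weeks: Mapping[str, float] = field(
        default_factory=lambda: {"nivolumab": 6.0, "paclitaxel": 3.0, "docetaxel": 9.0}
    )
    imaging_year1_interval_weeks: float = 6.0
    imaging_later_interval_weeks: float = 12.0
    pd_visit_items: Sequence[str] = ("hematology", "serum_chemistry", "hospitalization_fee")

    def imaging_days(self, span_days: float) -> np.ndarray:
        """Tumour scans every 6 weeks in year 1, every 12 weeks thereafter."""
        wk = []
        t = self.imaging_year1_interval_weeks
        while t <= 52.0:
            wk.append(t)
            t += self.imaging_year1_interval_weeks
        t = wk[-1] + self.imaging_later_interval_weeks if wk else self.imaging_later_interval_weeks
        while t * 7.0 <= span_days:
            wk.append(t)
            t += self.imaging_later_interval_weeks
        days = np.asarray(wk) * 7.0
        return days[days <= span_days + 0.5]


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted per-arm cost totals by category."""

    categories: Mapping[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.categories.values()))

    def __getitem__(self, key: str) -> float:
        return self.categories[key]


def vials_for_dose(
    dose_mg: float, prices: Sequence[PriceEntry]
) -> tuple[dict[float, int], float]:
    """Least-cost whole-vial combination covering the dose (no vial sharing).

    Ties are broken toward fewer total vials, then toward larger vials
    first.  Exhaustive over the (tiny) lattice of feasible counts.
    """
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    if not prices:
        raise ValueError("empty price list")
    sizes = sorted({(p.size_mg, p.price) for p in prices}, reverse=True)
    if dose_mg == 0:
        return {s: 0 for s, _ in sizes}, 0.0

    best = None  # (cost, total_vials, neg_counts_largest_first, counts)
    max_counts = [int(math.ceil(dose_mg / s)) for s, _ in sizes]

    def rec(i: int, remaining: float, counts: list[int], cost: float):
        nonlocal best
        if best is not None and cost > best[0]:
            return
        if i == len(sizes) - 1:
            s, pr = sizes[i]
            k = max(0, int(math.ceil(remaining / s))) if remaining > 0 else 0
            cand_counts = counts + [k]
            cand_cost = cost + k * pr
            key = (cand_cost, sum(cand_counts), tuple(-c for c in cand_counts))
            if best is None or key < best[:3] + ():
                best = (cand_cost, sum(cand_counts), tuple(-c for c in cand_counts), cand_counts)
            return
        s, pr = sizes[i]
        for k in range(max_counts[i] + 1):
            rec(i + 1, remaining - k * s, counts + [k], cost + k * pr)

    rec(0, dose_mg, [], 0.0)
    assert best is not None
    counts = {sizes[i][0]: best[3][i] for i in range(len(sizes))}
    return counts, float(best[0])


def per_admin_vial_cost(drug: str, dose_mg: float, prices: Sequence[PriceEntry]) -> float:
    """Vial-optimized list-price cost of one administration of ``drug``."""
    mine = [p for p in prices if p.drug == drug]
    _, cost = vials_for_dose(dose_mg, mine)
    return cost


def dose_day_weights(
    regimen: DosingRegimen, pfs: PiecewiseExpCurve, grid: ModelGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Scheduled dose days over the horizon and S_PFS at each (the expected
    fraction of the cohort still on treatment on that day)."""
    days = regimen.schedule.dose_days(grid.horizon_days)
    return days, pfs.survival_days(days)


def expected_administrations(
    regimen: DosingRegimen, pfs: PiecewiseExpCurve, grid: ModelGrid
) -> np.ndarray:
    """Expected number of administrations falling in each model cycle."""
    days, w = dose_day_weights(regimen, pfs, grid)
    b = grid.boundaries
    idx = np.clip(np.searchsorted(b, days, side="right") - 1, 0, grid.n_cycles - 1)
    out = np.zeros(grid.n_cycles)
    np.add.at(out, idx, w)
    return out


@dataclass(frozen=True)
class ArmSpec:
    """Everything the cost model needs to know about one arm."""

    name: str
    regimens: Sequence[DosingRegimen]
    ae_items: Sequence[AEItem]

    def __post_init__(self):
        total_w = sum(r.weight for r in self.regimens)
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError(f"regimen weights in arm {self.name!r} sum to {total_w}, not 1")


def arm_cost_quantities(
    arm: ArmSpec,
    pfs: PiecewiseExpCurve,
    trace: StateTrace,
    grid: ModelGrid,
    annual_rate: float,
    monitoring: MonitoringRules,
) -> dict[str, dict[str, float]]:
    """Expected discounted quantity per unit-cost parameter for one arm.

    Returns ``{parameter_name: {category: quantity}}`` (one parameter can
    accrue in several categories, e.g. hematology at baseline, before each
    administration, and at PD visits); the arm's cost under any price
    vector is the dot product of quantities and unit costs.
    """
    q: dict[str, dict[str, float]] = {}

    def add(name: str, qty: float, category: str):
        q.setdefault(name, {})
        q[name][category] = q[name].get(category, 0.0) + qty

    # --- drug acquisition + administration-linked events -------------------
    total_admin_disc = 0.0
    for reg in arm.regimens:
        days, w = dose_day_weights(reg, pfs, grid)
        disc = discount_factor(days, annual_rate)
        wd = float(np.sum(w * disc)) * reg.weight
        add(f"{reg.drug}_per_admin", wd, "acquisition")
        total_admin_disc += wd
        # thyroid repeats while on this drug (baseline test handled below)
        interval = monitoring.thyroid_interval_weeks.get(reg.drug)
        if interval:
            t_days = np.arange(interval * 7.0, grid.horizon_days + 0.5, interval * 7.0)
            tw = pfs.survival_days(t_days) * discount_factor(t_days, annual_rate)
            add("thyroid_function", float(np.sum(tw)) * reg.weight, "monitoring")

    for fee in ADMIN_FEE_ITEMS:
        add(fee, total_admin_disc, "administration")
    for item in PER_ADMIN_LAB_ITEMS:
        add(item, total_admin_disc, "monitoring")

    # --- baseline work-up (t=0, undiscounted) ------------------------------
    for item in BASELINE_ITEMS:
        add(item, 1.0, "monitoring")

    # --- tumour assessments until progression or death ---------------------
    im_days = monitoring.imaging_days(grid.horizon_days)
    im_w = pfs.survival_days(im_days) * discount_factor(im_days, annual_rate)
    add("radiologic_images", float(np.sum(im_w)), "monitoring")

    # --- adverse events: one-time expected cost at model entry -------------
    for item in arm.ae_items:
        add(f"ae_{arm.name}_{item.name}", item.incidence, "adverse_events")

    # --- progressed-disease routine visits, per cycle in PD ----------------
    disc_mid = discount_factor(trace.t_mid, annual_rate)
    cycle_frac = trace.cycle_days / grid.cycle_length_days  # pro-rata stub cycle
    pd_qty = float(np.sum(trace.pd * disc_mid * cycle_frac))
    for item in monitoring.pd_visit_items:
        add(item, pd_qty, "pd_visits")

    # --- terminal cost at death --------------------------------------------
    add("funeral", float(np.sum(trace.new_deaths * disc_mid)), "terminal")

    return q


def price_cost(
    quantities: Mapping[str, Mapping[str, float]], unit_costs: Mapping[str, float]
) -> CostBreakdown:
    """Dot quantities with unit costs, aggregated by category."""
    cats = {c: 0.0 for c in CATEGORIES}
    for name, by_cat in quantities.items():
        try:
            unit = unit_costs[name]
        except KeyError:
            raise KeyError(f"no unit cost supplied for parameter {name!r}") from None
        for cat, qty in by_cat.items():
            cats[cat] += qty * unit
    return CostBreakdown(cats)


def total_quantity(quantities: Mapping[str, Mapping[str, float]], name: str) -> float:
    """A parameter's quantity summed over categories (0 if absent)."""
    return float(sum(quantities.get(name, {}).values()))


def ae_expected_cost(items: Sequence[AEItem], unit_costs: Mapping[str, float],
                     arm_name: str) -> float:
    """One-time expected adverse-event management cost at model entry."""
    return sum(it.incidence * unit_costs[f"ae_{arm_name}_{it.name}"] for it in items)


def terminal_and_pd_costs(
    trace: StateTrace,
    funeral_cost: float,
    pd_cycle_cost: float,
    annual_rate: float,
    grid: ModelGrid,
) -> tuple[float, float]:
    """Discounted terminal (funeral) and PD-visit category totals."""
    disc = discount_factor(trace.t_mid, annual_rate)
    frac = trace.cycle_days / grid.cycle_length_days
    terminal = float(np.sum(trace.new_deaths * disc)) * funeral_cost
    pd_cost = float(np.sum(trace.pd * disc * frac)) * pd_cycle_cost
    return terminal, pd_cost
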
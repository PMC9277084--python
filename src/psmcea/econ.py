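"""Incremental cost-effectiveness and sensitivity analyses.

Implements the ICER with dominance coding, the WHO willingness-to-pay
convention (3x GDP per capita), one-way deterministic sensitivity analysis
over every parameter range (tornado), a Monte-Carlo probabilistic
sensitivity analysis with Gamma-distributed costs and Beta-distributed
utilities, the cost-effectiveness acceptability curve via net monetary
benefit, and a bisection solver for the drug-price reduction that brings
the ICER down to a target threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import Range, StudyConfig, seed_streams
from .costs import total_quantity as _costs_total_qty
from .model import CEResult, build_curves, compare, evaluate, evaluate_from_quantities, model_quantities

compute_icer = compare  # the ICER operation is the arm comparison itself


def wtp_threshold(gdp_per_capita: float) -> float:
    """WHO convention: willingness-to-pay of three times GDP per capita."""
    if gdp_per_capita < 0:
        raise ValueError("GDP per capita must be non-negative")
    return 3.0 * gdp_per_capita


class PointMass:
    """Degenerate distribution used for fixed or zero-range parameters."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        return self.value if size is None else np.full(size, self.value)

    def mean(self):
        return self.value

    def std(self):
        return 0.0


def fit_sampling_distribution(param: Range, family: str):
    """Moment-matched sampling distribution for one parameter.

    The mean is anchored at the base-case value and the standard deviation
    at (high - low) / (2 x 1.96), reading the range as a 95% interval.
    Costs use a Gamma fit (shape = mean^2/sd^2, scale = sd^2/mean);
    utilities a Beta fit on [0,1].  Degenerate ranges, and a zero base with
    a Gamma family, collapse to a point mass.
    """
    if not (param.low <= param.base <= param.high):
        raise ValueError("invalid range")
    sd = (param.high - param.low) / (2 * 1.96)
    mean = param.base
    if sd == 0 or family == "fixed":
        return PointMass(mean)
    if family == "gamma":
        if mean == 0:
            warnings.warn("Gamma parameter with base 0: using a point mass at 0",
                          stacklevel=2)
            return PointMass(0.0)
        shape = mean**2 / sd**2
        return stats.gamma(a=shape, scale=sd**2 / mean)
    if family == "beta":
        if not (0 < mean < 1):
            raise ValueError("Beta parameter mean must lie in (0,1)")
        max_var = mean * (1 - mean)
        var = sd**2
        if var >= max_var:
            warnings.warn("Beta variance clipped to keep shapes valid", stacklevel=2)
            var = 0.99 * max_var
        nu = max_var / var - 1.0
        return stats.beta(a=mean * nu, b=(1 - mean) * nu)
    raise ValueError(f"unknown distribution family {family!r}")


# --------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_low: float
    icer_high: float

    @property
    def range(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _icer_or_nan(res: CEResult) -> float:
    return np.nan if res.icer is None else res.icer


def one_way_dsa(cfg: StudyConfig, curves=None) -> list[TornadoEntry]:
    """Two model runs (low/high bound) per parameter, all others at base.

    Parameters swept: every unit-cost row, the two utilities, the discount
    rate over its stated range, and per-arm survival time expressed as a
    multiplicative hazard scale on that arm's OS and PFS curves.
    """
    if curves is None:
        curves = build_curves(cfg)
    base_q = model_quantities(cfg, curves)
    base_costs = cfg.base_unit_costs()
    entries: list[TornadoEntry] = []

    def run_linear(**kw) -> float:
        res, _ = evaluate_from_quantities(cfg, base_q, **kw)
        return _icer_or_nan(res)

    for name, rng_ in cfg.unit_cost_params().items():
        icers = []
        for v in (rng_.low, rng_.high):
            uc = dict(base_costs)
            uc[name] = v
            icers.append(run_linear(unit_costs=uc))
        entries.append(TornadoEntry(name, *icers))

    for uname, key in (("utility_pf", "u_pf"), ("utility_pd", "u_pd")):
        rng_ = cfg.utilities.pf if key == "u_pf" else cfg.utilities.pd
        icers = [run_linear(**{key: v}) for v in (rng_.low, rng_.high)]
        entries.append(TornadoEntry(uname, *icers))

    icers = []
    for rate in (cfg.dsa.discount_low, cfg.dsa.discount_high):
        res, _ = evaluate(cfg, curves=curves, discount_rate=rate)
        icers.append(_icer_or_nan(res))
    entries.append(TornadoEntry("discount_rate", *icers))

    for arm in (cfg.intervention, cfg.comparator):
        icers = []
        for scale in (cfg.dsa.survival_scale_low, cfg.dsa.survival_scale_high):
            res, _ = evaluate(cfg, hazard_scales={arm: scale})
            icers.append(_icer_or_nan(res))
        entries.append(TornadoEntry(f"survival_scale_{arm}", *icers))

    entries.sort(key=lambda e: (np.isnan(e.range), -0.0 if np.isnan(e.range) else -e.range))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "range": [e.range for e in entries],
        }
    )


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------


def run_psa(
    cfg: StudyConfig,
    curves=None,
    n_iter: Optional[int] = None,
    seed=None,
) -> pd.DataFrame:
    """Monte-Carlo PSA: Gamma costs, Beta utilities; survival stays fixed.

    Returns one row per iteration with every drawn parameter, per-arm
    discounted cost and QALYs, and the increments.  Bit-reproducible under
    a fixed seed.
    """
    if curves is None:
        curves = build_curves(cfg)
    n = cfg.psa.iterations if n_iter is None else int(n_iter)
    if n <= 0:
        raise ValueError("iteration count must be positive")
    if seed is None:
        seed = seed_streams(cfg.seed)["psa"]
    rng = np.random.default_rng(seed)

    quantities = model_quantities(cfg, curves)
    specs = cfg.unit_cost_params()
    dists = {name: fit_sampling_distribution(p, p.dist) for name, p in specs.items()}
    dists["utility_pf"] = fit_sampling_distribution(cfg.utilities.pf, "beta")
    dists["utility_pd"] = fit_sampling_distribution(cfg.utilities.pd, "beta")

    draws = {
        name: np.asarray(d.rvs(size=n, random_state=rng), dtype=float)
        for name, d in dists.items()
    }

    out = {"iteration": np.arange(n)}
    out.update(draws)
    names = list(specs)
    mat = np.column_stack([draws[name] for name in names])
    for arm, q in quantities.items():
        qty_vec = np.array([_costs_total_qty(q.cost_qty, name) for name in names])
        out[f"cost_{arm}"] = mat @ qty_vec
        out[f"qaly_{arm}"] = draws["utility_pf"] * q.q_pf + draws["utility_pd"] * q.q_pd
    i, c = cfg.intervention, cfg.comparator
    out["delta_cost"] = out[f"cost_{i}"] - out[f"cost_{c}"]
    out["delta_qaly"] = out[f"qaly_{i}"] - out[f"qaly_{c}"]
    return pd.DataFrame(out)


def ceac(
    samples: pd.DataFrame, wtp_grid: Sequence[float]
) -> pd.DataFrame:
    """P(net monetary benefit > 0) at each willingness-to-pay value."""
    if len(samples) == 0:
        raise ValueError("empty PSA sample")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    de = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    prob = [(de * w - dc > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "probability_cost_effective": prob})


def default_wtp_grid(cfg: StudyConfig, extra: Sequence[float] = ()) -> np.ndarray:
    """$0-$200,000 in $1,000 steps plus the exact thresholds of interest."""
    pts = np.concatenate(
        [
            np.arange(0.0, 200_001.0, 1_000.0),
            [wtp_threshold(cfg.wtp.gdp_per_capita), 37_544.52, 132_029.22],
            np.asarray(list(extra), dtype=float),
        ]
    )
    return np.unique(pts)


# --------------------------------------------------------------------------
# Price-threshold solver
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PriceSolveResult:
    target_wtp: float
    multiplier: float
    reduction_pct: float
    icer_at_solution: Optional[float]
    note: str = ""


def price_threshold(
    cfg: StudyConfig,
    target_wtp: float,
    curves=None,
    tol: float = 1.0,
    max_iter: int = 200,
) -> PriceSolveResult:
    """Bisection on the intervention drug-acquisition price multiplier.

    Scales the per-administration acquisition cost of every drug in the
    intervention arm (for this study: nivolumab only) by m in [0,1] until
    the ICER equals the target within ``tol`` $/QALY.
    """
    if curves is None:
        curves = build_curves(cfg)
    quantities = model_quantities(cfg, curves)
    base_costs = cfg.base_unit_costs()
    drug_params = {f"{reg.drug}_per_admin"
                   for reg in cfg.build_arm_spec(cfg.intervention).regimens}

    def icer_at(m: float) -> Optional[float]:
        uc = dict(base_costs)
        for p in drug_params:
            uc[p] = base_costs[p] * m
        res, _ = evaluate_from_quantities(cfg, quantities, unit_costs=uc)
        return res.icer

    base = icer_at(1.0)
    if base is None:
        raise ValueError("base-case ICER undefined; cannot solve for a price threshold")
    if base <= target_wtp:
        return PriceSolveResult(target_wtp, 1.0, 0.0, base,
                                "base-case ICER already at or below target")
    lo_icer = icer_at(0.0)
    if lo_icer is not None and lo_icer > target_wtp:
        return PriceSolveResult(target_wtp, 0.0, 100.0, lo_icer,
                                "target unreachable even at zero acquisition cost")

    lo, hi = 0.0, 1.0  # icer(lo) <= target < icer(hi)
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        val = icer_at(mid)
        if val is not None and abs(val - target_wtp) < tol:
            return PriceSolveResult(target_wtp, mid, 100.0 * (1.0 - mid), val)
        if val is None or val > target_wtp:
            hi = mid
        else:
            lo = mid
    mid = (lo + hi) / 2.0
    return PriceSolveResult(target_wtp, mid, 100.0 * (1.0 - mid), icer_at(mid),
                            "bisection hit max iterations")
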
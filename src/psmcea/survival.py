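"""Survival-curve reconstruction from published trial summaries.

The trial report prints only medians and a handful of landmark survival
probabilities per arm and endpoint (overall survival, progression-free
survival).  This module turns those summaries into full survival functions
by calibrating a piecewise-exponential curve through every printed anchor,
draws pseudo-individual-patient data (pseudo-IPD) from the calibrated
curves by inverse-CDF sampling with administrative censoring, and
re-estimates survival the way the source analysis does: Kaplan-Meier for
OS and the actuarial life-table method for PFS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

#: Mean Gregorian month, used for every month<->day conversion.
DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


class CalibrationWarning(UserWarning):
    """Non-monotone anchors reconciled by clipping a segment hazard at 0."""


@dataclass(frozen=True)
class SurvivalSummary:
    """Published per-arm survival summary: median plus landmark probabilities.

    Parameters
    ----------
    arm : str
        Treatment arm label, e.g. ``"nivolumab"`` or ``"chemotherapy"``.
    endpoint : str
        ``"OS"`` or ``"PFS"``.
    n : int
        Number of patients in the arm.
    median : float, optional
        Median survival in months (treated as an ``S(t)=0.5`` anchor).
    landmarks : sequence of (time_months, probability)
        Printed landmark survival probabilities.
    """

    arm: str
    endpoint: str
    n: int
    median: Optional[float] = None
    landmarks: Sequence[tuple[float, float]] = field(default_factory=tuple)

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        for t, p in self.landmarks:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"landmark probability {p} outside [0,1]")
            if t <= 0:
                raise ValueError("landmark times must be positive")
        times = [t for t, _ in self.landmarks]
        probs = [p for _, p in self.landmarks]
        order = np.argsort(times)
        if any(np.diff(np.asarray(probs)[order]) > 0):
            raise ValueError("landmark probabilities must be non-increasing in time")

    def anchors(self) -> list[tuple[float, float]]:
        """All (time, survival) anchors: landmarks plus the median as S=0.5."""
        pts = list(self.landmarks)
        if self.median is not None:
            pts.append((self.median, 0.5))
        return sorted(pts)


@dataclass(frozen=True)
class PiecewiseExpCurve:
    """Piecewise-exponential survival function on the month scale.

    ``knots`` start at 0 and are strictly increasing; ``hazards`` holds one
    non-negative rate per month for each segment.  Beyond the last knot the
    last segment's hazard continues (constant-hazard extrapolation), so the
    curve is defined on all of ``[0, inf)``.
    """

    knots: np.ndarray
    hazards: np.ndarray

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        hazards = np.asarray(self.hazards, dtype=float)
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "hazards", hazards)
        if knots[0] != 0 or np.any(np.diff(knots) <= 0):
            raise ValueError("knots must start at 0 and be strictly increasing")
        if len(hazards) != len(knots) - 1 or len(hazards) < 1:
            raise ValueError("need exactly one hazard per segment")
        if np.any(hazards < 0):
            raise ValueError("hazards must be non-negative")
        # cumulative hazard at each knot
        object.__setattr__(
            self, "_cumhaz", np.concatenate([[0.0], np.cumsum(hazards * np.diff(knots))])
        )

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        idx = np.clip(np.searchsorted(self.knots, t, side="right") - 1, 0, len(self.hazards) - 1)
        return self._cumhaz[idx] + self.hazards[idx] * (t - self.knots[idx])

    def survival(self, t):
        """S(t) for t in months (scalar or array)."""
        return np.exp(-self.cumulative_hazard(t))

    def survival_days(self, t_days):
        return self.survival(np.asarray(t_days, dtype=float) / DAYS_PER_MONTH)

    def inverse_survival(self, p):
        """Time t (months) with S(t) = p; ``inf`` where the curve never reaches p."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p must lie in (0, 1]")
        target = -np.log(p)
        idx = np.clip(
            np.searchsorted(self._cumhaz, target, side="right") - 1, 0, len(self.hazards) - 1
        )
        lam = self.hazards[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.knots[idx] + (target - self._cumhaz[idx]) / lam
        t = np.where((lam == 0) & (target > self._cumhaz[idx]), np.inf, t)
        return t if t.ndim else float(t)

    def scale_hazard(self, factor: float) -> "PiecewiseExpCurve":
        """Proportional-hazards rescaling; factor < 1 lengthens survival."""
        if factor <= 0:
            raise ValueError("hazard scale must be positive")
        return PiecewiseExpCurve(self.knots.copy(), self.hazards * factor)


def fit_piecewise_exponential(
    summary: SurvivalSummary,
    knots: Optional[Sequence[float]] = None,
    tol: float = 1e-9,
) -> PiecewiseExpCurve:
    """Calibrate a piecewise-exponential curve through every printed anchor.

    The anchor set is the summary's landmarks plus its median (as an
    ``S=0.5`` point).  On each inter-anchor segment the hazard has the
    closed form ``lambda_i = [ln S(t_{i-1}) - ln S(t_i)] / (t_i - t_{i-1})``,
    which reproduces each anchor exactly.  A non-monotone anchor pair would
    imply a negative hazard; it is clipped at 0 with a
    :class:`CalibrationWarning` (the curve then sits above the offending
    anchor), never silently.

    ``knots``, if given, must contain 0 and every anchor time; extra knots
    subdivide a segment without changing the curve.
    """
    anchors = summary.anchors()
    if not anchors:
        raise ValueError("summary has no anchors (no median and no landmarks)")
    for t, p in anchors:
        if p <= 0:
            raise ValueError(f"anchor probability must be positive, got {p} at t={t}")

    anchor_t = np.array([0.0] + [t for t, _ in anchors])
    anchor_s = np.array([1.0] + [p for _, p in anchors])
    seg_haz = np.log(anchor_s[:-1] / anchor_s[1:]) / np.diff(anchor_t)
    clipped = bool(np.any(seg_haz < 0))
    if clipped:
        bad = anchor_t[1:][seg_haz < 0]
        warnings.warn(
            f"{summary.arm}/{summary.endpoint}: non-monotone anchors at t={bad.tolist()} "
            "months; negative segment hazards clipped at 0",
            CalibrationWarning,
            stacklevel=2,
        )
        seg_haz = np.clip(seg_haz, 0.0, None)

    if knots is None:
        kn = anchor_t
        hz = seg_haz
    else:
        kn = np.asarray(sorted(knots), dtype=float)
        missing = [t for t in anchor_t if not np.any(np.isclose(kn, t))]
        if missing:
            raise ValueError(f"knots must include 0 and every anchor time; missing {missing}")
        # each sub-segment inherits the hazard of the anchor interval containing it
        mids = (kn[:-1] + kn[1:]) / 2
        idx = np.clip(np.searchsorted(anchor_t, mids, side="right") - 1, 0, len(seg_haz) - 1)
        hz = seg_haz[idx]

    curve = PiecewiseExpCurve(kn, hz)
    if not clipped:
        # strict round-trip: every anchor reproduced to within tol
        for t, p in anchors:
            s = float(curve.survival(t))
            if abs(s - p) > tol:
                raise RuntimeError(f"calibration failed at anchor t={t}: S={s} vs {p}")
    return curve


def survival_at(curve: PiecewiseExpCurve, t) -> float:
    """Evaluate S(t) (t in months).  Thin functional wrapper over the curve."""
    return curve.survival(t)


def generate_pseudo_ipd(
    curve: PiecewiseExpCurve,
    n: int,
    cutoff_months: float,
    seed,
    arm: str = "",
    endpoint: str = "",
    method: str = "stratified",
) -> pd.DataFrame:
    """Draw pseudo-individual-patient records from a calibrated curve.

    Event times come from the inverse CDF ``T = S^{-1}(U)``.  With
    ``method="stratified"`` each of the ``n`` uniforms is drawn from its own
    probability stratum (``u_i = (i + U_i)/n``), which is unbiased and pins
    the empirical survival function to the generating curve to within 1/n at
    every time point -- the right behaviour for a reconstruction whose job is
    to reproduce published summaries.  ``method="iid"`` gives plain random
    sampling.  Times past ``cutoff_months`` are administratively censored at
    the cutoff (event=0).

    Returns a DataFrame with columns ``time_days, event, arm, endpoint``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if cutoff_months <= 0:
        raise ValueError("cutoff must be positive")
    rng = np.random.default_rng(seed)
    if method == "stratified":
        u = (np.arange(n) + rng.random(n)) / n
        rng.shuffle(u)
    elif method == "iid":
        u = rng.random(n)
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    # U ~ Uniform(0,1); S is a survival function so T = S^{-1}(U) has law S.
    u = np.clip(u, np.finfo(float).tiny, 1.0)
    t_months = curve.inverse_survival(u)
    event = (t_months <= cutoff_months).astype(int)
    t_months = np.minimum(t_months, cutoff_months)
    return pd.DataFrame(
        {
            "time_days": t_months * DAYS_PER_MONTH,
            "event": event,
            "arm": arm,
            "endpoint": endpoint,
        }
    )


@dataclass(frozen=True)
class StepSurvival:
    """A step survival estimate (Kaplan-Meier or life-table).

    ``times`` are in days; ``survival`` holds the estimate just after each
    time; ``n_risk`` the number at risk entering it.  ``median_days`` is the
    first time the estimate drops to 0.5 or below (KM convention) or the
    linearly interpolated crossing (life-table), ``None`` if never reached.
    """

    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    median_days: Optional[float]

    def survival_at(self, t_days: float) -> float:
        """Right-continuous step lookup; 1 before the first step."""
        idx = np.searchsorted(self.times, t_days + 1e-9) - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def survival_at_months(self, t_months: float) -> float:
        return self.survival_at(t_months * DAYS_PER_MONTH)

    @property
    def median_months(self) -> Optional[float]:
        return None if self.median_days is None else self.median_days / DAYS_PER_MONTH


def km_estimate(ipd: pd.DataFrame) -> StepSurvival:
    """Kaplan-Meier (product-limit) estimate of a pseudo-IPD sample."""
    if len(ipd) == 0:
        raise ValueError("empty pseudo-IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time_days"], event_observed=ipd["event"])
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    if times[0] == 0.0 and surv[0] == 1.0:
        times, surv = times[1:], surv[1:]
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    median = float(times[below[0]]) if len(below) else None
    return StepSurvival(times, surv, at_risk, median)


def life_table_estimate(ipd: pd.DataFrame, interval_width_days: float = 30.0) -> StepSurvival:
    """Actuarial (life-table) estimate with effective denominator ``n - c/2``.

    Within each interval of width ``interval_width_days`` the conditional
    probability of the event is ``d / (n_enter - c/2)`` where ``c`` counts
    records censored in the interval.  The reported survival is the
    interval-end value; the median is interpolated linearly inside the
    interval where the estimate crosses 0.5.
    """
    if len(ipd) == 0:
        raise ValueError("empty pseudo-IPD")
    if interval_width_days <= 0:
        raise ValueError("interval width must be positive")
    t = ipd["time_days"].to_numpy(dtype=float)
    e = ipd["event"].to_numpy(dtype=int)
    w = float(interval_width_days)
    n_int = int(np.ceil((t.max() + 1e-12) / w)) or 1
    # records exactly on a boundary count in the interval they close
    idx = np.clip(np.ceil(t / w - 1e-12).astype(int) - 1, 0, None)
    ends, surv, n_risk = [], [], []
    s_prev, entered = 1.0, float(len(t))
    median = None
    for k in range(n_int):
        d = float(np.sum((idx == k) & (e == 1)))
        c = float(np.sum((idx == k) & (e == 0)))
        n_eff = entered - c / 2.0
        q = d / n_eff if n_eff > 0 else 0.0
        s_k = s_prev * (1.0 - q)
        ends.append((k + 1) * w)
        surv.append(s_k)
        n_risk.append(entered)
        if median is None and s_k <= 0.5 < s_prev:
            median = k * w + w * (s_prev - 0.5) / (s_prev - s_k)
        if median is None and s_k == 0.5 == s_prev:
            median = k * w
        s_prev = s_k
        entered -= d + c
    return StepSurvival(np.asarray(ends), np.asarray(surv), np.asarray(n_risk), median)
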
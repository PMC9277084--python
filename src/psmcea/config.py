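"""Study configuration: schema, base-case values, loading and fixtures.

The whole analysis is driven by one declarative configuration object
mirroring the published parameter table: survival summaries per arm and
endpoint, the cycle grid, dosing regimens and vial prices, every unit-cost
parameter with its base/low/high range and sampling family, adverse-event
items, utilities, discounting, and the sensitivity-analysis settings.

Adverse-event incidences are not published for this comparison; the
shipped profile is a synthetic placeholder patterned on the trial's safety
summary (chemotherapy-dominant haematological toxicity) and is meant to be
replaced with study-specific values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import costs as _costs
from .psm import ModelGrid
from .survival import SurvivalSummary


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Range(_Strict):
    """A base-case value with its deterministic sensitivity range."""

    base: float
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"range must satisfy low <= base <= high, got {self}")
        if self.base < 0:
            raise ValueError("base must be non-negative")
        return self


class ParamSpec(Range):
    """A unit-cost parameter row: range plus sampling family and category."""

    dist: Literal["gamma", "beta", "fixed"] = "gamma"
    category: Literal[
        "acquisition", "administration", "monitoring", "adverse_events", "terminal"
    ] = "monitoring"


class SurvivalSummaryCfg(_Strict):
    median_months: Optional[float] = None
    landmarks: list[tuple[float, float]] = Field(default_factory=list)


class RegimenCfg(_Strict):
    drug: str
    dose_mg: Optional[float] = None
    dose_mg_per_m2: Optional[float] = None
    interval_days: Optional[float] = None
    offsets_days: Optional[list[float]] = None
    period_days: Optional[float] = None
    weight: float = 1.0

    @model_validator(mode="after")
    def _one_dose_rule(self):
        if (self.dose_mg is None) == (self.dose_mg_per_m2 is None):
            raise ValueError(f"regimen {self.drug!r}: give exactly one of dose_mg, dose_mg_per_m2")
        has_interval = self.interval_days is not None
        has_pattern = self.offsets_days is not None and self.period_days is not None
        if has_interval == has_pattern:
            raise ValueError(
                f"regimen {self.drug!r}: give either interval_days or offsets_days+period_days"
            )
        return self


class VialCfg(_Strict):
    drug: str
    size_mg: float
    price: float


class AECfg(_Strict):
    name: str
    cost: Range
    incidence: float = Field(ge=0.0, le=1.0)


class UtilityCfg(_Strict):
    pf: Range = Range(base=0.74, low=0.59, high=0.89)
    pd: Range = Range(base=0.58, low=0.46, high=0.70)
    mode: Literal["constant", "linear_decline"] = "constant"


class GridCfg(_Strict):
    cycle_length_days: float = 60.0
    horizon_months: float = 36.0


class PSACfg(_Strict):
    iterations: int = 10_000


class DSACfg(_Strict):
    survival_scale_low: float = 0.8
    survival_scale_high: float = 1.25
    discount_low: float = 0.0
    discount_high: float = 0.08


class WTPCfg(_Strict):
    gdp_per_capita: float = 12_551.0


class MonitoringCfg(_Strict):
    thyroid_interval_weeks: dict[str, float] = Field(
        default_factory=lambda: {"nivolumab": 6.0, "paclitaxel": 3.0, "docetaxel": 9.0}
    )
    imaging_year1_interval_weeks: float = 6.0
    imaging_later_interval_weeks: float = 12.0
    pd_visit_items: list[str] = Field(
        default_factory=lambda: ["hematology", "serum_chemistry", "hospitalization_fee"]
    )


class StudyConfig(_Strict):
    """Complete declarative description of one cost-effectiveness analysis."""

    arms: dict[str, int]
    intervention: str = "nivolumab"
    comparator: str = "chemotherapy"
    bsa_m2: float = 1.71
    discount_rate: float = Field(default=0.05, ge=0.0)
    accrual_convention: Literal["start", "mid", "end"] = "mid"
    acquisition_mode: Literal["table", "vial"] = "table"
    life_table_interval_days: float = 30.0
    pseudo_ipd_method: Literal["stratified", "iid"] = "stratified"
    seed: int = 2022

    grid: GridCfg = GridCfg()
    survival: dict[str, dict[str, SurvivalSummaryCfg]]
    regimens: dict[str, list[RegimenCfg]]
    vial_prices: list[VialCfg]
    parameters: dict[str, ParamSpec]
    ae: dict[str, list[AECfg]]
    utilities: UtilityCfg = UtilityCfg()
    monitoring: MonitoringCfg = MonitoringCfg()
    psa: PSACfg = PSACfg()
    dsa: DSACfg = DSACfg()
    wtp: WTPCfg = WTPCfg()

    @model_validator(mode="after")
    def _cross_checks(self):
        for arm in (self.intervention, self.comparator):
            if arm not in self.arms:
                raise ValueError(f"arm {arm!r} missing from arms")
            if arm not in self.survival:
                raise ValueError(f"survival summaries missing for arm {arm!r}")
            if arm not in self.regimens:
                raise ValueError(f"regimens missing for arm {arm!r}")
        vial_drugs = {v.drug for v in self.vial_prices}
        for arm, regs in self.regimens.items():
            w = sum(r.weight for r in regs)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"regimen weights for arm {arm!r} sum to {w}, not 1")
            for r in regs:
                if self.acquisition_mode == "table" and f"{r.drug}_per_admin" not in self.parameters:
                    raise ValueError(f"no unit-cost parameter {r.drug}_per_admin for regimen")
                if self.acquisition_mode == "vial" and r.drug not in vial_drugs:
                    raise ValueError(f"no vial prices for drug {r.drug!r}")
        return self

    # ------------------------------------------------------------------ helpers
    def build_grid(self) -> ModelGrid:
        return ModelGrid(self.grid.cycle_length_days, self.grid.horizon_months)

    def build_summary(self, arm: str, endpoint: str) -> SurvivalSummary:
        cfg = self.survival[arm][endpoint]
        return SurvivalSummary(
            arm=arm,
            endpoint=endpoint,
            n=self.arms[arm],
            median=cfg.median_months,
            landmarks=[tuple(lm) for lm in cfg.landmarks],
        )

    def build_arm_spec(self, arm: str) -> _costs.ArmSpec:
        regs = []
        for r in self.regimens[arm]:
            dose = r.dose_mg if r.dose_mg is not None else r.dose_mg_per_m2 * self.bsa_m2
            sched = _costs.Schedule(
                interval_days=r.interval_days,
                offsets_days=r.offsets_days,
                period_days=r.period_days,
            )
            regs.append(_costs.DosingRegimen(r.drug, dose, sched, r.weight))
        ae_items = [_costs.AEItem(a.name, a.incidence) for a in self.ae.get(arm, [])]
        return _costs.ArmSpec(arm, regs, ae_items)

    def build_monitoring(self) -> _costs.MonitoringRules:
        m = self.monitoring
        return _costs.MonitoringRules(
            thyroid_interval_weeks=dict(m.thyroid_interval_weeks),
            imaging_year1_interval_weeks=m.imaging_year1_interval_weeks,
            imaging_later_interval_weeks=m.imaging_later_interval_weeks,
            pd_visit_items=tuple(m.pd_visit_items),
        )

    def build_vial_prices(self) -> list[_costs.PriceEntry]:
        return [_costs.PriceEntry(v.drug, v.size_mg, v.price) for v in self.vial_prices]

    def unit_cost_params(self) -> dict[str, ParamSpec]:
        """All unit-cost parameters, including per-arm AE cost rows (Gamma)."""
        out: dict[str, ParamSpec] = dict(self.parameters)
        for arm, items in self.ae.items():
            for it in items:
                out[f"ae_{arm}_{it.name}"] = ParamSpec(
                    base=it.cost.base, low=it.cost.low, high=it.cost.high,
                    dist="gamma", category="adverse_events",
                )
        return out

    def base_unit_costs(self) -> dict[str, float]:
        return {k: v.base for k, v in self.unit_cost_params().items()}

    # ------------------------------------------------------------------ io
    def dump(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False, width=100)
        )

    @classmethod
    def load(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)


def load_config(path) -> StudyConfig:
    """Load and schema-validate a YAML study configuration."""
    return StudyConfig.load(path)


def seed_streams(master: int) -> dict[str, np.random.SeedSequence]:
    """Deterministic per-purpose random streams derived from the master seed."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(6)
    keys = ["nivolumab/OS", "nivolumab/PFS", "chemotherapy/OS", "chemotherapy/PFS",
            "psa", "misc"]
    return dict(zip(keys, children))


# --------------------------------------------------------------------------
# Base-case configuration mirroring the published parameter table
# --------------------------------------------------------------------------

_PCT20 = lambda v: Range(base=v, low=round(v * 0.8, 4), high=round(v * 1.2, 4))  # noqa: E731


def _p(base, low, high, category="monitoring", dist="gamma"):
    return ParamSpec(base=base, low=low, high=high, dist=dist, category=category)


def _ae(name, base, low, high, incidence):
    return AECfg(name=name, cost=Range(base=base, low=low, high=high), incidence=incidence)


# Synthetic placeholder grade>=3 adverse-event incidence profile (the source
# analysis does not print incidences; these are patterned on the trial's
# published safety summary and clearly NOT trial data).
_AE_NIVO = [
    ("rash", 80.00, 60.00, 100.00, 0.005),
    ("diarrhea", 14_000.00, 8_000.00, 20_000.00, 0.005),
    ("decreased_appetite", 825.00, 150.00, 1_500.00, 0.010),
    ("stomatitis", 2_550.00, 100.00, 5_000.00, 0.005),
    ("nausea", 800.00, 100.00, 1_500.00, 0.005),
    ("arthralgia", 350.00, 100.00, 600.00, 0.005),
    ("neutrophil_count_decreased", 1_575.00, 150.00, 3_000.00, 0.000),
    ("anemia", 5_500.00, 1_000.00, 10_000.00, 0.020),
    ("white_blood_cell_count_decreased", 1_575.00, 150.00, 3_000.00, 0.000),
    ("neutropenia", 1_575.00, 150.00, 3_000.00, 0.000),
    ("peripheral_sensory_neuropathy", 15_000.00, 10_000.00, 20_000.00, 0.005),
    ("febrile_neutropenia", 2_650.00, 300.00, 5_000.00, 0.005),
    ("neuropathy_peripheral", 15_000.00, 10_000.00, 20_000.00, 0.005),
]
_AE_CHEMO = [
    ("rash", 35.00, 20.00, 50.00, 0.010),
    ("diarrhea", 312.50, 25.00, 600.00, 0.020),
    ("decreased_appetite", 825.00, 150.00, 1_500.00, 0.020),
    ("stomatitis", 125.00, 50.00, 200.00, 0.010),
    ("nausea", 350.00, 100.00, 600.00, 0.020),
    ("arthralgia", 0.00, 0.00, 0.00, 0.010),
    ("neutrophil_count_decreased", 1_575.00, 150.00, 3_000.00, 0.280),
    ("anemia", 275.00, 50.00, 500.00, 0.050),
    ("white_blood_cell_count_decreased", 1_575.00, 150.00, 3_000.00, 0.110),
    ("neutropenia", 1_575.00, 150.00, 3_000.00, 0.030),
    ("peripheral_sensory_neuropathy", 25.00, 0.00, 50.00, 0.040),
    ("febrile_neutropenia", 2_650.00, 300.00, 5_000.00, 0.080),
    ("neuropathy_peripheral", 25.00, 0.00, 50.00, 0.020),
]


def default_config(seed: int = 2022) -> StudyConfig:
    """The published base case: trial summaries, Table-1 costs, 60-day cycles."""
    return StudyConfig(
        arms={"nivolumab": 210, "chemotherapy": 209},
        seed=seed,
        survival={
            "nivolumab": {
                "OS": SurvivalSummaryCfg(median_months=10.9, landmarks=[(12, 0.47), (18, 0.31)]),
                "PFS": SurvivalSummaryCfg(median_months=1.7, landmarks=[(6, 0.24), (12, 0.12)]),
            },
            "chemotherapy": {
                "OS": SurvivalSummaryCfg(median_months=8.4, landmarks=[(12, 0.34), (18, 0.21)]),
                "PFS": SurvivalSummaryCfg(median_months=3.4, landmarks=[(6, 0.17), (12, 0.07)]),
            },
        },
        regimens={
            "nivolumab": [RegimenCfg(drug="nivolumab", dose_mg=240.0, interval_days=14.0)],
            "chemotherapy": [
                RegimenCfg(
                    drug="paclitaxel",
                    dose_mg_per_m2=100.0,
                    offsets_days=[0, 7, 14, 21, 28, 35],
                    period_days=49.0,
                    weight=144 / 209,
                ),
                RegimenCfg(drug="docetaxel", dose_mg_per_m2=75.0, interval_days=21.0,
                           weight=65 / 209),
            ],
        },
        vial_prices=[
            VialCfg(drug="nivolumab", size_mg=40, price=718.0),
            VialCfg(drug="nivolumab", size_mg=100, price=1_448.0),
            VialCfg(drug="paclitaxel", size_mg=30, price=77.0),
            VialCfg(drug="docetaxel", size_mg=20, price=142.0),
        ],
        parameters={
            "nivolumab_per_admin": _p(3_614.08, 2_891.26, 4_336.90, "acquisition"),
            "paclitaxel_per_admin": _p(459.60, 367.68, 551.52, "acquisition"),
            "docetaxel_per_admin": _p(997.19, 797.75, 1_196.63, "acquisition"),
            "preventive_medication": _p(93.93, 75.14, 112.72, "administration"),
            "infusion_fee": _p(1.86, 1.49, 2.23, "administration"),
            "hospitalization_fee": _p(39.14, 31.31, 46.97, "administration"),
            "ecg": _p(4.23, 3.38, 5.07),
            "hematology": _p(3.91, 3.13, 4.70),
            "serum_chemistry": _p(28.18, 22.54, 33.81),
            "urinalysis": _p(4.70, 3.76, 5.64),
            "coagulation": _p(10.42, 8.34, 12.50),
            "thyroid_function": _p(23.48, 18.79, 28.18),
            "pulmonary_function": _p(61.05, 48.84, 73.26),
            "hbv_hcv_serology": _p(11.28, 11.28, 19.12),
            "hbv_dna": _p(23.64, 23.64, 62.78),
            "radiologic_images": _p(435.58, 234.82, 919.69),
            "funeral": _p(4_517.85, 3_614.28, 5_421.42, "terminal"),
        },
        ae={
            "nivolumab": [_ae(*row) for row in _AE_NIVO],
            "chemotherapy": [_ae(*row) for row in _AE_CHEMO],
        },
    )


def generate_fixture(seed: int = 2022, outdir=None):
    """Base-case config plus pseudo-IPD bundle for both arms and endpoints.

    Returns ``(config, {arm/endpoint: DataFrame})``; when ``outdir`` is
    given, also writes ``config.yaml`` and ``pseudo_ipd.csv`` there.
    """
    from .survival import fit_piecewise_exponential, generate_pseudo_ipd

    cfg = default_config(seed=seed)
    streams = seed_streams(seed)
    bundle = {}
    for arm in (cfg.intervention, cfg.comparator):
        for endpoint in ("OS", "PFS"):
            summary = cfg.build_summary(arm, endpoint)
            curve = fit_piecewise_exponential(summary)
            bundle[f"{arm}/{endpoint}"] = generate_pseudo_ipd(
                curve,
                n=cfg.arms[arm],
                cutoff_months=cfg.grid.horizon_months,
                seed=streams[f"{arm}/{endpoint}"],
                arm=arm,
                endpoint=endpoint,
                method=cfg.pseudo_ipd_method,
            )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.dump(outdir / "config.yaml")
        import pandas as pd

        pd.concat(bundle.values(), ignore_index=True).to_csv(
            outdir / "pseudo_ipd.csv", index=False
        )
    return cfg, bundle
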
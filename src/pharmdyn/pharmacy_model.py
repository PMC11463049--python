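"""Stock-and-flow model of a sustainable inpatient-pharmacy drug supply chain.

The model tracks five externally meaningful stocks — pharmacy profit (money
units, may go negative), number of pharmacy residents, total expiring
low-consumption medicines on the shelf, cumulative disposed medicines, and
the inventory of high-consumption medicines — plus bookkeeping stocks
(cumulative disposal cost, cumulative low-consumption sales) and internal
smoothing/delay stocks (staff service adaptation, the in-transit pipeline of
high-consumption orders, and the pre-study backlog of unfilled
low-consumption orders).

Functional forms (the source system is documented only at the level of
influence structure and qualitative behaviour, so the algebra below is this
package's own calibrated reconstruction):

* ``response_speed = response_speed_base * workforce_competence**0.5 *
  (1 + 0.25 * pharmacists_in_team)`` — service timeliness raised by staff
  competence and by pharmacists embedded in the prescribing team.  The
  reference calibration normalizes this to 1.
* Staff *adaptation* follows response speed through a first-order smooth
  with time constant ``accuracy_adjust_time``.  While actual service runs
  ahead of what the team is adapted to, an error-cost outflow
  ``ERROR_COST_SCALE * gap**2 / mitigation`` hits profit; the mitigation
  factor grows with competence and team pharmacists, so a raw speed-up is
  costly at first but a competence-backed one is not.
* Expiring stock: inflow ``expiry_inflow_base +
  resident_overprescription_coeff * number_of_residents``; outflows are
  service-driven sales (saturating in stock), inter-pharmacy transfer
  (``transfer_rate_coeff * stock``) and disposal
  (``expiry_fraction * stock / (1 + transfer_rate_coeff)`` — active exchange
  diverts items that would otherwise expire on the shelf).
* High-consumption side: seasonal sinusoidal demand, sales saturating in
  inventory, and an inventory-gap ordering rule feeding a first-order
  material delay of length ``order_delay``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields as dc_fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .sd_engine import (
    ModelDef,
    SimConfig,
    Trajectory,
    VariableDef,
    first_order_smooth,
    material_delay,
    simulate,
)

__all__ = [
    "ParameterSet",
    "ParameterError",
    "reference_parameters",
    "build_pharmacy_model",
    "influence_table",
    "derive_reports",
    "load_parameters",
    "STOCK_NAMES",
]

# ---------------------------------------------------------------------------
# calibration constants (dimensionless unless noted)
# ---------------------------------------------------------------------------
COMPETENCE_EXPONENT = 0.5
PHARMACIST_BOOST = 0.25          # service gain per team pharmacist
REFERENCE_TEAM_FACTOR = 1.5      # 1 + PHARMACIST_BOOST * 2 (reference team of 2)
NORMAL_SERVICE_LEVEL = 1.0       # adaptation level staff start out trained for
ERROR_COST_SCALE = 350.0         # MU/month per unit squared service gap
ERROR_MITIGATION_EXPONENT = 3.0  # competence exponent in error mitigation
LOW_SALES_CAPACITY = 55.0        # packs/month at unit service and full shelves
LOW_SALES_SATURATION = 30.0      # packs; half-saturation of low-consumption sales
INITIAL_SALES_BACKLOG = 60.0     # packs of pre-study unfilled low-consumption orders
BACKLOG_CLEAR_TIME = 0.8         # months
HIGH_SALES_SATURATION = 100.0    # packs; half-saturation of high-consumption sales
DESIRED_INVENTORY_COVER = 2.0    # months of base demand kept as inventory target
ORDER_ADJUSTMENT_GAIN = 1.5      # responsiveness of ordering to inventory gap

#: externally reported stocks (internal smoothing/delay stocks excluded)
STOCK_NAMES = (
    "pharmacy_profit",
    "number_of_residents",
    "total_expiring_medicines",
    "total_disposed_medicines",
    "inventory_high_consumption",
    "cumulative_disposal_cost",
)


class ParameterError(ValueError):
    """One or more parameter values violate their declared valid range."""


# (low, high, low_inclusive, high_inclusive)
_BOUNDS: dict[str, tuple[float, float, bool, bool]] = {
    "initial_profit": (0.0, math.inf, True, False),
    "initial_residents": (0.0, math.inf, True, False),
    "initial_expiring_stock": (0.0, math.inf, True, False),
    "initial_disposed_total": (0.0, math.inf, True, False),
    "initial_inventory_high": (0.0, math.inf, True, False),
    "workforce_competence": (0.0, math.inf, False, False),
    "pharmacists_in_team": (0.0, math.inf, False, False),
    "response_speed_base": (0.0, math.inf, False, False),
    "accuracy_adjust_time": (0.0, math.inf, False, False),
    "avg_price_low": (0.0, math.inf, False, False),
    "profit_margin_low": (0.0, 1.0, True, True),
    "profit_margin_high": (0.0, 1.0, True, True),
    "disposal_unit_cost": (0.0, math.inf, False, False),
    "avg_salary": (0.0, math.inf, False, False),
    "staff_count": (0.0, math.inf, False, False),
    "overhead_cost": (0.0, math.inf, True, False),
    "expiry_inflow_base": (0.0, math.inf, True, False),
    "resident_overprescription_coeff": (0.0, math.inf, True, False),
    "expiry_fraction": (0.0, 1.0, False, True),
    "transfer_rate_coeff": (0.0, 1.0, True, True),
    "monthly_purchase": (0.0, math.inf, False, False),
    "share_high_consumption": (0.0, 1.0, True, True),
    "order_delay": (0.0, math.inf, False, False),
    "demand_high_base": (0.0, math.inf, False, False),
    "demand_seasonal_amplitude": (0.0, 1.0, True, True),
    "demand_period": (0.0, math.inf, False, False),
    # zero intake is a meaningful boundary-test limit, hence inclusive
    "resident_intake_rate": (0.0, math.inf, True, False),
    "residency_duration": (0.0, 1.0e7, False, True),
}

_UNITS: dict[str, str] = {
    "initial_profit": "MU",
    "initial_residents": "persons",
    "initial_expiring_stock": "packs",
    "initial_disposed_total": "packs",
    "initial_inventory_high": "packs",
    "workforce_competence": "index",
    "pharmacists_in_team": "persons",
    "response_speed_base": "index",
    "accuracy_adjust_time": "months",
    "avg_price_low": "MU/pack",
    "profit_margin_low": "fraction",
    "profit_margin_high": "fraction",
    "disposal_unit_cost": "MU/pack",
    "avg_salary": "MU/person/month",
    "staff_count": "persons",
    "overhead_cost": "MU/month",
    "expiry_inflow_base": "packs/month",
    "resident_overprescription_coeff": "packs/month/person",
    "expiry_fraction": "1/month",
    "transfer_rate_coeff": "1/month",
    "monthly_purchase": "packs/month",
    "share_high_consumption": "fraction",
    "order_delay": "months",
    "demand_high_base": "packs/month",
    "demand_seasonal_amplitude": "fraction",
    "demand_period": "months",
    "resident_intake_rate": "persons/month",
    "residency_duration": "months",
}


@dataclass(frozen=True)
class ParameterSet:
    """All model constants and initial stock values, with valid ranges."""

    initial_profit: float
    initial_residents: float
    initial_expiring_stock: float
    initial_disposed_total: float
    initial_inventory_high: float
    workforce_competence: float
    pharmacists_in_team: float
    response_speed_base: float
    accuracy_adjust_time: float
    avg_price_low: float
    profit_margin_low: float
    profit_margin_high: float
    disposal_unit_cost: float
    avg_salary: float
    staff_count: float
    overhead_cost: float
    expiry_inflow_base: float
    resident_overprescription_coeff: float
    expiry_fraction: float
    transfer_rate_coeff: float
    monthly_purchase: float
    share_high_consumption: float
    order_delay: float
    demand_high_base: float
    demand_seasonal_amplitude: float
    demand_period: float
    resident_intake_rate: float
    residency_duration: float

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(cls))

    @classmethod
    def units(cls) -> dict[str, str]:
        return dict(_UNITS)

    @classmethod
    def bounds(cls) -> dict[str, tuple[float, float, bool, bool]]:
        return dict(_BOUNDS)

    def violations(self) -> list[str]:
        """Human-readable list of hard range violations (empty if valid)."""
        out = []
        for name in self.field_names():
            val = getattr(self, name)
            lo, hi, lo_inc, hi_inc = _BOUNDS[name]
            if not isinstance(val, (int, float)) or not math.isfinite(val):
                out.append(f"{name} = {val!r} is not a finite number")
                continue
            ok_lo = val >= lo if lo_inc else val > lo
            ok_hi = val <= hi if hi_inc else val < hi
            if not (ok_lo and ok_hi):
                lob = "[" if lo_inc else "("
                hib = "]" if hi_inc else ")"
                out.append(f"{name} = {val:g} outside {lob}{lo:g}, {hi:g}{hib}")
        return out

    def validate(self) -> "ParameterSet":
        bad = self.violations()
        if bad:
            raise ParameterError("; ".join(bad))
        return self

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.field_names()}

    @classmethod
    def from_dict(cls, d: Mapping[str, float], strict: bool = True) -> "ParameterSet":
        """Build from a flat mapping.  Unknown/missing keys always error;
        range violations raise only when ``strict`` (the default)."""
        names = set(cls.field_names())
        unknown = sorted(set(d) - names)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {unknown}")
        missing = sorted(names - set(d))
        if missing:
            raise ParameterError(f"missing parameter keys: {missing}")
        out = cls(**{k: float(v) for k, v in d.items()})
        return out.validate() if strict else out

    def with_overrides(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs).validate()


def load_parameters(path, strict: bool = True) -> ParameterSet:
    """Read a flat JSON or YAML parameter file (keys = field names)."""
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a flat mapping of parameters")
    return ParameterSet.from_dict(data, strict=strict)


def reference_parameters() -> ParameterSet:
    """The packaged reference calibration (abstract MU/pack units).

    This stand-in emulates the study conditions of a mid-sized inpatient
    pharmacy: a service level normalized to 1, an expiring-stock level that
    starts at its quasi-equilibrium for the initial resident census and then
    climbs as the census grows, and a high-consumption side ordering against
    a two-month inventory cover under seasonal demand.
    """
    return ParameterSet(
        initial_profit=0.0,
        initial_residents=20.0,
        initial_expiring_stock=300.0,
        initial_disposed_total=0.0,
        initial_inventory_high=900.0,
        workforce_competence=1.0,
        pharmacists_in_team=2.0,
        response_speed_base=2.0 / 3.0,
        accuracy_adjust_time=1.5,
        avg_price_low=10.0,
        profit_margin_low=0.25,
        profit_margin_high=0.15,
        disposal_unit_cost=5.0,
        avg_salary=55.0,
        staff_count=6.0,
        overhead_cost=50.0,
        expiry_inflow_base=40.0,
        resident_overprescription_coeff=2.0,
        expiry_fraction=0.06,
        transfer_rate_coeff=0.04,
        monthly_purchase=1000.0,
        share_high_consumption=0.45,
        order_delay=1.5,
        demand_high_base=400.0,
        demand_seasonal_amplitude=0.2,
        demand_period=6.0,
        resident_intake_rate=1.5,
        residency_duration=24.0,
    )


def _response_speed(p: Mapping[str, float]) -> float:
    return (
        p["response_speed_base"]
        * p["workforce_competence"] ** COMPETENCE_EXPONENT
        * (1.0 + PHARMACIST_BOOST * p["pharmacists_in_team"])
    )


def build_pharmacy_model(params: ParameterSet) -> ModelDef:
    """Assemble the validated :class:`ModelDef` for a parameter set."""
    params.validate()
    p = params.to_dict()

    variables: list[VariableDef] = []

    # constants --------------------------------------------------------
    for name in ParameterSet.field_names():
        if name.startswith("initial_"):
            continue  # initial stock values are baked into stock defs
        variables.append(VariableDef(name=name, kind="constant", units=_UNITS[name]))

    # service side -------------------------------------------------------
    variables.append(
        VariableDef(
            name="response_speed",
            kind="auxiliary",
            units="index",
            equation=lambda s, t: (
                s["response_speed_base"]
                * s["workforce_competence"] ** COMPETENCE_EXPONENT
                * (1.0 + PHARMACIST_BOOST * s["pharmacists_in_team"])
            ),
            depends_on=(
                "response_speed_base",
                "workforce_competence",
                "pharmacists_in_team",
            ),
        )
    )
    adapt_stock, adapt_flow = first_order_smooth(
        "response_speed",
        "accuracy_adjust_time",
        name="service_adaptation",
        initial_value=NORMAL_SERVICE_LEVEL,
        units="index",
    )
    variables += [adapt_stock, adapt_flow]
    variables.append(
        VariableDef(
            name="accuracy_gap",
            kind="auxiliary",
            units="index",
            equation=lambda s, t: max(0.0, s["response_speed"] - s["service_adaptation"]),
            depends_on=("response_speed", "service_adaptation"),
        )
    )
    variables.append(
        VariableDef(
            name="error_cost_rate",
            kind="flow",
            units="MU/month",
            equation=lambda s, t: (
                ERROR_COST_SCALE
                * s["accuracy_gap"] ** 2
                * REFERENCE_TEAM_FACTOR
                / (
                    s["workforce_competence"] ** ERROR_MITIGATION_EXPONENT
                    * (1.0 + PHARMACIST_BOOST * s["pharmacists_in_team"])
                )
            ),
            depends_on=("accuracy_gap", "workforce_competence", "pharmacists_in_team"),
        )
    )

    # residents ----------------------------------------------------------
    variables.append(
        VariableDef(
            name="resident_intake",
            kind="flow",
            units="persons/month",
            equation=lambda s, t: s["resident_intake_rate"],
            depends_on=("resident_intake_rate",),
        )
    )
    variables.append(
        VariableDef(
            name="graduation_rate",
            kind="flow",
            units="persons/month",
            equation=lambda s, t: s["number_of_residents"] / s["residency_duration"],
            depends_on=("number_of_residents", "residency_duration"),
        )
    )
    variables.append(
        VariableDef(
            name="number_of_residents",
            kind="stock",
            units="persons",
            initial_value=p["initial_residents"],
            inflows=("resident_intake",),
            outflows=("graduation_rate",),
            non_negative=True,
        )
    )

    # expiring low-consumption medicines --------------------------------
    variables.append(
        VariableDef(
            name="expiring_inflow",
            kind="flow",
            units="packs/month",
            equation=lambda s, t: (
                s["expiry_inflow_base"]
                + s["resident_overprescription_coeff"] * s["number_of_residents"]
            ),
            depends_on=(
                "expiry_inflow_base",
                "resident_overprescription_coeff",
                "number_of_residents",
            ),
        )
    )
    variables.append(
        VariableDef(
            name="sales_low_units",
            kind="flow",
            units="packs/month",
            equation=lambda s, t: (
                LOW_SALES_CAPACITY
                * s["response_speed"]
                * s["total_expiring_medicines"]
                / (s["total_expiring_medicines"] + LOW_SALES_SATURATION)
            ),
            depends_on=("response_speed", "total_expiring_medicines"),
        )
    )
    variables.append(
        VariableDef(
            name="transfer_out",
            kind="flow",
            units="packs/month",
            equation=lambda s, t: s["transfer_rate_coeff"] * s["total_expiring_medicines"],
            depends_on=("transfer_rate_coeff", "total_expiring_medicines"),
        )
    )
    variables.append(
        VariableDef(
            name="disposal_rate",
            kind="flow",
            units="packs/month",
            equation=lambda s, t: (
                s["expiry_fraction"]
                * s["total_expiring_medicines"]
                / (1.0 + s["transfer_rate_coeff"])
            ),
            depends_on=(
                "expiry_fraction",
                "transfer_rate_coeff",
                "total_expiring_medicines",
            ),
        )
    )
    variables.append(
        VariableDef(
            name="total_expiring_medicines",
            kind="stock",
            units="packs",
            initial_value=p["initial_expiring_stock"],
            inflows=("expiring_inflow",),
            outflows=("sales_low_units", "transfer_out", "disposal_rate"),
            non_negative=True,
        )
    )
    variables.append(
        VariableDef(
            name="total_disposed_medicines",
            kind="stock",
            units="packs",
            initial_value=p["initial_disposed_total"],
            inflows=("disposal_rate",),
            non_negative=True,
        )
    )

    # pre-study backlog of unfilled low-consumption orders ---------------
    variables.append(
        VariableDef(
            name="backlog_clearance",
            kind="flow",
            units="packs/month",
            equation=lambda s, t: s["low_sales_backlog"] / BACKLOG_CLEAR_TIME,
            depends_on=("low_sales_backlog",),
        )
    )
    variables.append(
        VariableDef(
            name="low_sales_backlog",
            kind="stock",
            units="packs",
            initial_value=INITIAL_SALES_BACKLOG,
            outflows=("backlog_clearance",),
            non_negative=True,
        )
    )
    variables.append(
        VariableDef(
            name="sales_low_total_units",
            kind="flow",
            units="packs/month",
            equation=lambda s, t: s["sales_low_units"] + s["backlog_clearance"],
            depends_on=("sales_low_units", "backlog_clearance"),
        )
    )
    variables.append(
        VariableDef(
            name="cumulative_sales_low",
            kind="stock",
            units="packs",
            initial_value=0.0,
            inflows=("sales_low_total_units",),
            non_negative=True,
        )
    )

    # high-consumption medicines -----------------------------------------
    variables.append(
        VariableDef(
            name="demand_high",
            kind="auxiliary",
            units="packs/month",
            equation=lambda s, t: s["demand_high_base"]
            * (
                1.0
                + s["demand_seasonal_amplitude"]
                * math.sin(2.0 * math.pi * t / s["demand_period"])
            ),
            depends_on=(
                "demand_high_base",
                "demand_seasonal_amplitude",
                "demand_period",
            ),
        )
    )
    variables.append(
        VariableDef(
            name="selling_high",
            kind="flow",
            units="packs/month",
            equation=lambda s, t: (
                s["demand_high"]
                * s["inventory_high_consumption"]
                / (s["inventory_high_consumption"] + HIGH_SALES_SATURATION)
            ),
            depends_on=("inventory_high_consumption", "demand_high"),
        )
    )
    variables.append(
        VariableDef(
            name="order_rate_high",
            kind="flow",
            units="packs/month",
            equation=lambda s, t: max(
                0.0,
                s["share_high_consumption"]
                * s["monthly_purchase"]
                * (
                    1.0
                    + ORDER_ADJUSTMENT_GAIN
                    * s["response_speed"]
                    * (
                        1.0
                        - s["inventory_high_consumption"]
                        / (DESIRED_INVENTORY_COVER * s["demand_high_base"])
                    )
                ),
            ),
            depends_on=(
                "share_high_consumption",
                "monthly_purchase",
                "response_speed",
                "inventory_high_consumption",
                "demand_high_base",
            ),
        )
    )
    rs0 = _response_speed(p)
    order0 = max(
        0.0,
        p["share_high_consumption"]
        * p["monthly_purchase"]
        * (
            1.0
            + ORDER_ADJUSTMENT_GAIN
            * rs0
            * (
                1.0
                - p["initial_inventory_high"]
                / (DESIRED_INVENTORY_COVER * p["demand_high_base"])
            )
        ),
    )
    transit_stock, arrival_flow = material_delay(
        "order_rate_high",
        "order_delay",
        name="in_transit_high",
        arrival_name="buying_high",
        initial_in_transit=p["order_delay"] * order0,
        units="packs",
    )
    variables += [transit_stock, arrival_flow]
    variables.append(
        VariableDef(
            name="inventory_high_consumption",
            kind="stock",
            units="packs",
            initial_value=p["initial_inventory_high"],
            inflows=("buying_high",),
            outflows=("selling_high",),
            non_negative=True,
        )
    )

    # money ----------------------------------------------------------------
    variables.append(
        VariableDef(
            name="sales_low_before_expiration",
            kind="flow",
            units="MU/month",
            equation=lambda s, t: (
                s["sales_low_total_units"] * s["avg_price_low"] * s["profit_margin_low"]
            ),
            depends_on=("sales_low_total_units", "avg_price_low", "profit_margin_low"),
        )
    )
    variables.append(
        VariableDef(
            name="selling_high_profit",
            kind="flow",
            units="MU/month",
            equation=lambda s, t: (
                s["selling_high"] * s["avg_price_low"] * s["profit_margin_high"]
            ),
            depends_on=("selling_high", "avg_price_low", "profit_margin_high"),
        )
    )
    variables.append(
        VariableDef(
            name="disposal_cost_rate",
            kind="flow",
            units="MU/month",
            equation=lambda s, t: s["disposal_rate"] * s["disposal_unit_cost"],
            depends_on=("disposal_rate", "disposal_unit_cost"),
        )
    )
    variables.append(
        VariableDef(
            name="wage_cost",
            kind="flow",
            units="MU/month",
            equation=lambda s, t: s["avg_salary"] * s["staff_count"],
            depends_on=("avg_salary", "staff_count"),
        )
    )
    variables.append(
        VariableDef(
            name="overhead_cost_rate",
            kind="flow",
            units="MU/month",
            equation=lambda s, t: s["overhead_cost"],
            depends_on=("overhead_cost",),
        )
    )
    variables.append(
        VariableDef(
            name="pharmacy_profit",
            kind="stock",
            units="MU",
            initial_value=p["initial_profit"],
            inflows=("sales_low_before_expiration", "selling_high_profit"),
            outflows=(
                "disposal_cost_rate",
                "wage_cost",
                "overhead_cost_rate",
                "error_cost_rate",
            ),
            non_negative=False,  # the money stock may legitimately go negative
        )
    )
    variables.append(
        VariableDef(
            name="cumulative_disposal_cost",
            kind="stock",
            units="MU",
            initial_value=0.0,
            inflows=("disposal_cost_rate",),
            non_negative=True,
        )
    )

    model = ModelDef(name="pharmacy_supply_chain", variables=variables)
    model.validate()
    return model


def influence_table() -> dict[str, set[str]]:
    """Documented driver set of every flow/auxiliary (structure test input).

    Kept as an explicit literal, independent of :func:`build_pharmacy_model`,
    so the structure-verification test compares two separately maintained
    statements of the model's causal structure.
    """
    return {
        "response_speed": {
            "response_speed_base",
            "workforce_competence",
            "pharmacists_in_team",
        },
        "service_adaptation_change": {
            "response_speed",
            "service_adaptation",
            "accuracy_adjust_time",
        },
        "accuracy_gap": {"response_speed", "service_adaptation"},
        "error_cost_rate": {
            "accuracy_gap",
            "workforce_competence",
            "pharmacists_in_team",
        },
        "resident_intake": {"resident_intake_rate"},
        "graduation_rate": {"number_of_residents", "residency_duration"},
        "expiring_inflow": {
            "expiry_inflow_base",
            "resident_overprescription_coeff",
            "number_of_residents",
        },
        "sales_low_units": {"response_speed", "total_expiring_medicines"},
        "transfer_out": {"transfer_rate_coeff", "total_expiring_medicines"},
        "disposal_rate": {
            "expiry_fraction",
            "transfer_rate_coeff",
            "total_expiring_medicines",
        },
        "backlog_clearance": {"low_sales_backlog"},
        "sales_low_total_units": {"sales_low_units", "backlog_clearance"},
        "demand_high": {
            "demand_high_base",
            "demand_seasonal_amplitude",
            "demand_period",
        },
        "selling_high": {"inventory_high_consumption", "demand_high"},
        "order_rate_high": {
            "share_high_consumption",
            "monthly_purchase",
            "response_speed",
            "inventory_high_consumption",
            "demand_high_base",
        },
        "buying_high": {"in_transit_high", "order_delay"},
        "sales_low_before_expiration": {
            "sales_low_total_units",
            "avg_price_low",
            "profit_margin_low",
        },
        "selling_high_profit": {"selling_high", "avg_price_low", "profit_margin_high"},
        "disposal_cost_rate": {"disposal_rate", "disposal_unit_cost"},
        "wage_cost": {"avg_salary", "staff_count"},
        "overhead_cost_rate": {"overhead_cost"},
    }


def run_reference(config: SimConfig | None = None) -> Trajectory:
    """Simulate the reference calibration (24 months, dt = 0.25 by default)."""
    params = reference_parameters()
    return simulate(build_pharmacy_model(params), params.to_dict(), config or SimConfig())


@dataclass
class ReportTable:
    """Per-time-point derived quantities plus 12-month stock deltas."""

    frame: pd.DataFrame
    stock_deltas: dict[str, dict[str, float]]


def derive_reports(trajectory: Trajectory, params: ParameterSet) -> ReportTable:
    """Derived reporting quantities for a pharmacy-model trajectory.

    Columns: disposal cost rate (recomputed as disposal_rate x unit cost),
    cumulative low-consumption sales, and the net monthly profit change.
    ``stock_deltas`` holds, for each reported stock, the change over months
    0-12 and 12-24 (or the two halves of a non-standard horizon).
    """
    required = ("disposal_rate", "cumulative_sales_low", "pharmacy_profit")
    for name in required:
        if name not in trajectory:
            raise KeyError(f"trajectory lacks required series {name!r}")
    times = trajectory.times
    frame = pd.DataFrame(
        {
            "time_months": times,
            "disposal_cost_rate": trajectory["disposal_rate"]
            * params.disposal_unit_cost,
            "cumulative_sales_low": trajectory["cumulative_sales_low"],
            "net_profit_change": np.gradient(trajectory["pharmacy_profit"], times),
        }
    )
    t0, t_end = float(times[0]), float(times[-1])
    t_mid = 0.5 * (t0 + t_end)
    deltas: dict[str, dict[str, float]] = {}
    for name in STOCK_NAMES:
        if name not in trajectory:
            continue
        deltas[name] = {
            "first_half": trajectory.at(name, t_mid) - trajectory.at(name, t0),
            "second_half": trajectory.at(name, t_end) - trajectory.at(name, t_mid),
        }
    return ReportTable(frame=frame, stock_deltas=deltas)
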
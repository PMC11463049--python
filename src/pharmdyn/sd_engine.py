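"""Generic stock-and-flow system-dynamics integrator.

A model is a flat collection of :class:`VariableDef` objects of four kinds:

``stock``
    An accumulating state variable.  Stocks carry no equation of their own;
    their derivative is the sum of named inflows minus the sum of named
    outflows, integrated by fixed-step forward Euler.
``flow``
    A rate (units per month) computed algebraically each step.
``auxiliary``
    An algebraic intermediate, computed like a flow but not plumbed into any
    stock.
``constant``
    A named parameter supplied at simulation time.

Flows and auxiliaries are evaluated once per step, synchronously, from the
time-``t`` state (all stocks, constants and previously evaluated algebraic
variables), then every stock is advanced by ``dt * (inflows - outflows)``.
Stocks flagged ``non_negative`` floor at zero: when a step would overdraw the
stock, that stock's outflows are scaled down proportionally and the scaled
values are what the trajectory records, so stock accounting stays exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VariableDef",
    "ModelDef",
    "SimConfig",
    "Trajectory",
    "ConservationReport",
    "ModelError",
    "ConfigurationError",
    "NumericError",
    "simulate",
    "first_order_smooth",
    "material_delay",
    "check_conservation",
]

VALID_KINDS = ("stock", "flow", "auxiliary", "constant")

#: signature of an algebraic equation: (state, t) -> value, where ``state``
#: maps variable names (stocks, constants, already-evaluated algebraics) to
#: their current values.
Equation = Callable[[Mapping[str, float], float], float]


class ModelError(ValueError):
    """A model definition violates its structural contract."""


class ConfigurationError(ValueError):
    """Simulation inputs (parameters, run settings) are invalid."""


class NumericError(ArithmeticError):
    """A non-finite value appeared during integration."""


@dataclass(frozen=True)
class VariableDef:
    """Definition of one model variable.

    ``depends_on`` must list exactly the names the equation reads (constants
    included); it is what drives evaluation ordering and the structure
    verification test.
    """

    name: str
    kind: str
    units: str = ""
    equation: Equation | None = None
    depends_on: tuple[str, ...] = ()
    initial_value: float | None = None
    inflows: tuple[str, ...] = ()
    outflows: tuple[str, ...] = ()
    non_negative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ModelError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "stock":
            if self.equation is not None:
                raise ModelError(f"stock {self.name!r} must not carry an equation")
            if self.initial_value is None:
                raise ModelError(f"stock {self.name!r} needs an initial_value")
        elif self.kind == "constant":
            if self.equation is not None:
                raise ModelError(f"constant {self.name!r} must not carry an equation")
        else:
            if self.equation is None:
                raise ModelError(f"{self.kind} {self.name!r} needs an equation")
        object.__setattr__(self, "depends_on", tuple(self.depends_on))
        object.__setattr__(self, "inflows", tuple(self.inflows))
        object.__setattr__(self, "outflows", tuple(self.outflows))


@dataclass
class ModelDef:
    """An ordered collection of variable definitions forming one model."""

    name: str
    variables: list[VariableDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variables = list(self.variables)

    # -- introspection -------------------------------------------------
    def by_name(self) -> dict[str, VariableDef]:
        return {v.name: v for v in self.variables}

    def of_kind(self, *kinds: str) -> list[VariableDef]:
        return [v for v in self.variables if v.kind in kinds]

    @property
    def stocks(self) -> list[VariableDef]:
        return self.of_kind("stock")

    @property
    def constants(self) -> list[VariableDef]:
        return self.of_kind("constant")

    def structure_dump(self) -> list[dict]:
        """JSON-serializable description (name, kind, units, dependencies)."""
        out = []
        for v in self.variables:
            entry = {
                "name": v.name,
                "kind": v.kind,
                "units": v.units,
                "depends_on": sorted(v.depends_on),
            }
            if v.kind == "stock":
                entry["inflows"] = sorted(v.inflows)
                entry["outflows"] = sorted(v.outflows)
                entry["non_negative"] = v.non_negative
            out.append(entry)
        return out

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelError` on any structural violation."""
        names = [v.name for v in self.variables]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ModelError(f"duplicate variable names: {sorted(dupes)}")
        table = self.by_name()
        for v in self.variables:
            for dep in v.depends_on + v.inflows + v.outflows:
                if dep not in table:
                    raise ModelError(f"{v.name!r} references unknown variable {dep!r}")
            for f in v.inflows + v.outflows:
                if table[f].kind not in ("flow", "auxiliary"):
                    raise ModelError(
                        f"stock {v.name!r}: {f!r} is a {table[f].kind}, not a flow"
                    )
        # each flow may drain at most one stock, otherwise non-negativity
        # scaling would be ambiguous
        drained: dict[str, str] = {}
        for s in self.stocks:
            for f in s.outflows:
                if f in drained:
                    raise ModelError(
                        f"flow {f!r} is an outflow of both {drained[f]!r} and {s.name!r}"
                    )
                drained[f] = s.name
        self._evaluation_order()  # raises on algebraic cycles

    def _evaluation_order(self) -> list[VariableDef]:
        """Topological order of flows/auxiliaries (Kahn; deterministic)."""
        algebraic = {v.name: v for v in self.of_kind("flow", "auxiliary")}
        indeg = {
            n: sum(1 for d in v.depends_on if d in algebraic)
            for n, v in algebraic.items()
        }
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            newly = sorted(
                m
                for m, v in algebraic.items()
                if n in v.depends_on and m not in order
            )
            for m in newly:
                indeg[m] -= 1
                if indeg[m] == 0 and m not in ready:
                    ready.append(m)
            ready.sort()
        if len(order) != len(algebraic):
            stuck = sorted(set(algebraic) - set(order))
            raise ModelError(f"cyclic algebraic dependencies among {stuck}")
        return [algebraic[n] for n in order]


@dataclass(frozen=True)
class SimConfig:
    """Fixed-step simulation settings (months)."""

    start_time: float = 0.0
    stop_time: float = 24.0
    dt: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.stop_time <= self.start_time:
            raise ConfigurationError("stop_time must exceed start_time")
        n = (self.stop_time - self.start_time) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"(stop-start)/dt = {n} is not an integer number of steps"
            )

    @property
    def n_steps(self) -> int:
        return int(round((self.stop_time - self.start_time) / self.dt))

    def times(self) -> np.ndarray:
        return self.start_time + self.dt * np.arange(self.n_steps + 1)


@dataclass
class Trajectory:
    """Time grid plus one aligned value series per model variable."""

    times: np.ndarray
    series: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def __contains__(self, name: str) -> bool:
        return name in self.series

    def at(self, name: str, t: float) -> float:
        """Value of ``name`` at the grid point nearest to time ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.series[name][i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_months": self.times})
        for name, vals in self.series.items():
            df[name] = vals
        return df

    def to_csv(self, path) -> None:
        # full precision so identical runs are byte-identical on disk
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def simulate(model: ModelDef, params: Mapping[str, float], config: SimConfig) -> Trajectory:
    """Run ``model`` under ``params`` on the fixed grid of ``config``.

    Deterministic: identical inputs give bitwise-identical trajectories.
    """
    model.validate()
    missing = sorted(c.name for c in model.constants if c.name not in params)
    if missing:
        raise ConfigurationError(f"missing parameter values for: {missing}")

    order = model._evaluation_order()
    stocks = model.stocks
    n = config.n_steps
    times = config.times()

    state: dict[str, float] = {c.name: float(params[c.name]) for c in model.constants}
    for s in stocks:
        state[s.name] = float(s.initial_value)

    record = {v.name: np.empty(n + 1) for v in model.variables}

    for i, t in enumerate(times):
        for v in order:
            state[v.name] = float(v.equation(state, t))
        # floor non-negative stocks by proportionally scaling their outflows
        for s in stocks:
            if not s.non_negative:
                continue
            total_in = sum(state[f] for f in s.inflows)
            total_out = sum(state[f] for f in s.outflows)
            if total_out <= 0.0:
                continue
            headroom = state[s.name] / config.dt + total_in
            if total_out > headroom:
                scale = max(headroom, 0.0) / total_out
                for f in s.outflows:
                    state[f] *= scale
        for name, val in state.items():
            if not math.isfinite(val):
                raise NumericError(
                    f"non-finite value for {name!r} at t={t:g} months"
                )
            record[name][i] = val
        if i < n:
            for s in stocks:
                net = sum(state[f] for f in s.inflows) - sum(
                    state[f] for f in s.outflows
                )
                state[s.name] += config.dt * net

    return Trajectory(times=times, series=record)


def first_order_smooth(
    target_name: str,
    adjust_time: float | str,
    name: str | None = None,
    initial_value: float = 0.0,
    units: str = "",
) -> tuple[VariableDef, VariableDef]:
    """First-order exponential smoothing: dY/dt = (X - Y) / T.

    ``adjust_time`` may be a positive number or the name of a model constant.
    Returns ``(stock, net_flow)`` definitions; the net flow may be negative,
    so the smoothing stock is not flagged non-negative.
    """
    name = name or f"{target_name}_smoothed"
    flow_name = f"{name}_change"
    if isinstance(adjust_time, str):
        deps = (target_name, name, adjust_time)

        def eq(state, t, _x=target_name, _y=name, _tau=adjust_time):
            tau = state[_tau]
            if tau <= 0:
                raise ConfigurationError(f"adjust time {_tau!r} must be > 0")
            return (state[_x] - state[_y]) / tau

    else:
        if adjust_time <= 0:
            raise ConfigurationError("adjust_time must be > 0")
        deps = (target_name, name)

        def eq(state, t, _x=target_name, _y=name, _tau=float(adjust_time)):
            return (state[_x] - state[_y]) / _tau

    stock = VariableDef(
        name=name,
        kind="stock",
        units=units,
        initial_value=initial_value,
        inflows=(flow_name,),
    )
    flow = VariableDef(
        name=flow_name,
        kind="flow",
        units=f"{units}/month" if units else "",
        equation=eq,
        depends_on=deps,
    )
    return stock, flow


def material_delay(
    order_name: str,
    delay_time: float | str,
    name: str = "in_transit",
    arrival_name: str | None = None,
    initial_in_transit: float = 0.0,
    units: str = "",
) -> tuple[VariableDef, VariableDef]:
    """First-order material delay conserving the delayed quantity.

    Orders accumulate in an in-transit stock; the arrival flow drains it at
    rate ``in_transit / delay_time``, so total ordered = total arrived +
    in transit at every instant.
    """
    arrival_name = arrival_name or f"{name}_arrivals"
    if isinstance(delay_time, str):
        deps = (name, delay_time)

        def eq(state, t, _s=name, _tau=delay_time):
            tau = state[_tau]
            if tau <= 0:
                raise ConfigurationError(f"delay time {_tau!r} must be > 0")
            return state[_s] / tau

    else:
        if delay_time <= 0:
            raise ConfigurationError("delay_time must be > 0")
        deps = (name,)

        def eq(state, t, _s=name, _tau=float(delay_time)):
            return state[_s] / _tau

    stock = VariableDef(
        name=name,
        kind="stock",
        units=units,
        initial_value=initial_in_transit,
        inflows=(order_name,),
        outflows=(arrival_name,),
        non_negative=True,
    )
    arrival = VariableDef(
        name=arrival_name,
        kind="flow",
        units=f"{units}/month" if units else "",
        equation=eq,
        depends_on=deps,
    )
    return stock, arrival


@dataclass
class ConservationReport:
    """Outcome of re-integrating every stock from its recorded flows."""

    ok: bool
    failures: list[dict] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def check_conservation(
    trajectory: Trajectory, model: ModelDef, config: SimConfig
) -> ConservationReport:
    """Verify S(t) = S(0) + sum(dt * (inflows - outflows)) for every stock.

    Tolerance accumulates at relative 1e-9 per step, so long runs are not
    penalized for ordinary floating-point drift.
    """
    for s in model.stocks:
        for name in (s.name,) + s.inflows + s.outflows:
            if name not in trajectory.series:
                raise ModelError(f"trajectory lacks series for {name!r}")
    failures = []
    n = len(trajectory.times)
    for s in model.stocks:
        net = np.zeros(n)
        for f in s.inflows:
            net += trajectory[f]
        for f in s.outflows:
            net -= trajectory[f]
        expected = trajectory[s.name][0] + np.concatenate(
            ([0.0], np.cumsum(config.dt * net[:-1]))
        )
        scale = max(1.0, float(np.max(np.abs(expected))))
        tol = 1e-9 * scale * (1 + np.arange(n))
        err = np.abs(trajectory[s.name] - expected)
        bad = np.nonzero(err > tol)[0]
        if bad.size:
            i = int(bad[0])
            failures.append(
                {
                    "stock": s.name,
                    "time": float(trajectory.times[i]),
                    "recorded": float(trajectory[s.name][i]),
                    "expected": float(expected[i]),
                }
            )
    return ConservationReport(ok=not failures, failures=failures)
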
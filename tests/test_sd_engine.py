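"""Forward-Euler integrator, SD primitives and conservation checking."""

import math
import random

import numpy as np
import pytest

from pharmdyn.sd_engine import (
    ConfigurationError,
    ModelDef,
    ModelError,
    NumericError,
    SimConfig,
    Trajectory,
    VariableDef,
    check_conservation,
    first_order_smooth,
    material_delay,
    simulate,
)


def one_stock_model(flow_eq, initial=0.0, non_negative=False, deps=()):
    return ModelDef(
        name="one_stock",
        variables=[
            VariableDef(name="inflow", kind="flow", equation=flow_eq, depends_on=deps),
            VariableDef(
                name="S",
                kind="stock",
                initial_value=initial,
                inflows=("inflow",),
                non_negative=non_negative,
            ),
        ],
    )


def decay_model(rate=0.5, initial=100.0):
    return ModelDef(
        name="decay",
        variables=[
            VariableDef(
                name="loss",
                kind="flow",
                equation=lambda s, t: rate * s["S"],
                depends_on=("S",),
            ),
            VariableDef(
                name="S",
                kind="stock",
                initial_value=initial,
                outflows=("loss",),
                non_negative=True,
            ),
        ],
    )


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------
@pytest.mark.parametrize("dt", [1.0, 0.25, 0.125])
def test_constant_inflow_integrates_exactly(dt):
    model = one_stock_model(lambda s, t: 1.0)
    traj = simulate(model, {}, SimConfig(stop_time=24.0, dt=dt))
    assert traj["S"][-1] == pytest.approx(24.0, abs=1e-12)


def test_exponential_decay_matches_closed_form():
    """Decay run at dt=1/64 stays within 1% of 100*exp(-t/2), scaled by S0.

    Forward Euler's signed relative error grows like rate^2*t*dt/2, so the
    meaningful 1% accuracy statement for this run is in sup norm relative to
    the initial stock; the test also pins the endpoint to the scheme's own
    closed form (1 - rate*dt)^n.
    """
    dt = 1.0 / 64.0
    cfg = SimConfig(stop_time=24.0, dt=dt)
    traj = simulate(decay_model(), {}, cfg)
    exact = 100.0 * np.exp(-0.5 * traj.times)
    assert np.max(np.abs(traj["S"] - exact)) <= 0.01 * 100.0
    scheme_exact = 100.0 * (1.0 - 0.5 * dt) ** cfg.n_steps
    assert traj["S"][-1] == pytest.approx(scheme_exact, rel=1e-10)


def test_random_flow_schedule_equals_cumulative_sum_oracle():
    rng = np.random.default_rng(42)
    cfg = SimConfig(stop_time=24.0, dt=0.25)
    values = rng.normal(0.0, 5.0, size=cfg.n_steps + 1)

    def eq(s, t):
        return values[int(round((t - cfg.start_time) / cfg.dt))]

    model = one_stock_model(eq, initial=3.0)
    traj = simulate(model, {}, cfg)
    expected = 3.0 + np.concatenate(([0.0], np.cumsum(cfg.dt * values[:-1])))
    np.testing.assert_allclose(traj["S"], expected, rtol=0, atol=1e-12)
    assert check_conservation(traj, model, cfg).ok


def test_deterministic_replay_is_bitwise_identical():
    cfg = SimConfig()
    a = simulate(decay_model(), {}, cfg)
    b = simulate(decay_model(), {}, cfg)
    for name in a.series:
        assert np.array_equal(a[name], b[name])


def test_dt_refinement_halves_error():
    exact = 100.0 * math.exp(-0.5 * 24.0)
    errs = []
    for dt in (1.0 / 16.0, 1.0 / 32.0):
        traj = simulate(decay_model(), {}, SimConfig(stop_time=24.0, dt=dt))
        errs.append(abs(traj["S"][-1] - exact))
    ratio = errs[0] / errs[1]
    assert 1.6 <= ratio <= 2.4  # first-order convergence, 20% slack


def test_declaration_order_does_not_change_trajectory():
    def build(order):
        vs = [
            VariableDef(name="a", kind="auxiliary", equation=lambda s, t: 2.0 + t,
                        depends_on=()),
            VariableDef(name="b", kind="flow", equation=lambda s, t: s["a"] * 0.5,
                        depends_on=("a",)),
            VariableDef(name="S", kind="stock", initial_value=1.0, inflows=("b",)),
        ]
        return ModelDef(name="perm", variables=[vs[i] for i in order])

    cfg = SimConfig()
    ref = simulate(build([0, 1, 2]), {}, cfg)
    for order in ([2, 1, 0], [1, 2, 0], [2, 0, 1]):
        other = simulate(build(order), {}, cfg)
        for name in ref.series:
            assert np.array_equal(ref[name], other[name])


def test_missing_parameter_is_reported_by_name():
    model = ModelDef(
        name="needs_k",
        variables=[
            VariableDef(name="k", kind="constant"),
            VariableDef(name="f", kind="flow", equation=lambda s, t: s["k"],
                        depends_on=("k",)),
            VariableDef(name="S", kind="stock", initial_value=0.0, inflows=("f",)),
        ],
    )
    with pytest.raises(ConfigurationError, match="k"):
        simulate(model, {}, SimConfig())


def test_non_finite_value_names_variable_and_time():
    model = one_stock_model(lambda s, t: float("nan") if t >= 1.0 else 0.0)
    with pytest.raises(NumericError, match="inflow"):
        simulate(model, {}, SimConfig())


def test_non_negative_stock_floors_at_zero():
    model = ModelDef(
        name="drain",
        variables=[
            VariableDef(name="out", kind="flow", equation=lambda s, t: 10.0),
            VariableDef(
                name="S",
                kind="stock",
                initial_value=3.0,
                outflows=("out",),
                non_negative=True,
            ),
        ],
    )
    cfg = SimConfig(stop_time=4.0, dt=0.5)
    traj = simulate(model, {}, cfg)
    assert np.all(traj["S"] >= 0.0)
    assert traj["S"][-1] == pytest.approx(0.0, abs=1e-12)
    # scaled outflows keep the stock accounting exact
    assert check_conservation(traj, model, cfg).ok


# ---------------------------------------------------------------------------
# model validation errors
# ---------------------------------------------------------------------------
def test_unknown_dependency_rejected():
    model = one_stock_model(lambda s, t: 1.0, deps=("ghost",))
    with pytest.raises(ModelError, match="ghost"):
        simulate(model, {}, SimConfig())


def test_algebraic_cycle_rejected():
    model = ModelDef(
        name="loop",
        variables=[
            VariableDef(name="a", kind="auxiliary", equation=lambda s, t: s["b"],
                        depends_on=("b",)),
            VariableDef(name="b", kind="auxiliary", equation=lambda s, t: s["a"],
                        depends_on=("a",)),
        ],
    )
    with pytest.raises(ModelError, match="cyclic"):
        model.validate()


def test_flow_draining_two_stocks_rejected():
    model = ModelDef(
        name="shared_outflow",
        variables=[
            VariableDef(name="f", kind="flow", equation=lambda s, t: 1.0),
            VariableDef(name="S1", kind="stock", initial_value=1.0, outflows=("f",)),
            VariableDef(name="S2", kind="stock", initial_value=1.0, outflows=("f",)),
        ],
    )
    with pytest.raises(ModelError, match="outflow of both"):
        model.validate()


def test_bad_sim_grid_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(stop_time=24.0, dt=0.7)
    with pytest.raises(ConfigurationError):
        SimConfig(dt=-0.25)


# ---------------------------------------------------------------------------
# first-order smooth
# ---------------------------------------------------------------------------
def smooth_model(target_value, adjust_time, y0):
    stock, flow = first_order_smooth(
        "x", adjust_time, name="y", initial_value=y0
    )
    return ModelDef(
        name="smooth",
        variables=[
            VariableDef(name="x", kind="auxiliary",
                        equation=lambda s, t: target_value, depends_on=()),
            stock,
            flow,
        ],
    )


def test_smooth_reaches_constant_target():
    traj = simulate(smooth_model(1.0, 1.0, 0.0), {}, SimConfig())
    assert traj["y"][-1] == pytest.approx(1.0, abs=1e-4)


def test_smooth_fixed_point_stays_constant():
    traj = simulate(smooth_model(5.0, 2.0, 5.0), {}, SimConfig())
    np.testing.assert_allclose(traj["y"], 5.0, rtol=0, atol=1e-12)


def test_smooth_step_response_matches_closed_form():
    cfg = SimConfig(stop_time=24.0, dt=1.0 / 64.0)
    traj = simulate(smooth_model(1.0, 2.0, 0.0), {}, cfg)
    expected = 1.0 - math.exp(-1.0)
    assert traj.at("y", 2.0) == pytest.approx(expected, rel=0.02)


def test_smooth_rejects_non_positive_adjust_time():
    with pytest.raises(ConfigurationError):
        first_order_smooth("x", 0.0)
    with pytest.raises(ConfigurationError):
        first_order_smooth("x", -1.0)


# ---------------------------------------------------------------------------
# material delay
# ---------------------------------------------------------------------------
def delay_model(order_eq, delay):
    stock, arrival = material_delay("orders", delay, name="pipeline",
                                    arrival_name="arrivals")
    return ModelDef(
        name="delay",
        variables=[
            VariableDef(name="orders", kind="flow", equation=order_eq, depends_on=()),
            stock,
            arrival,
            VariableDef(name="received", kind="stock", initial_value=0.0,
                        inflows=("arrivals",)),
        ],
    )


def test_delay_zero_orders_zero_arrivals():
    traj = simulate(delay_model(lambda s, t: 0.0, 2.0), {}, SimConfig())
    np.testing.assert_array_equal(traj["arrivals"], 0.0)


def test_delay_constant_orders_reach_steady_state():
    traj = simulate(delay_model(lambda s, t: 3.0, 1.5), {},
                    SimConfig(stop_time=24.0, dt=0.25))
    assert traj["arrivals"][-1] == pytest.approx(3.0, rel=0.01)


def test_delay_conserves_pulse_volume():
    # 2-month pulse of 5/month -> total volume 10
    delay = 1.0
    traj = simulate(
        delay_model(lambda s, t: 5.0 if t < 2.0 else 0.0, delay),
        {},
        SimConfig(stop_time=12.0, dt=0.125),
    )
    volume = 10.0
    # conservation at every step: ordered = arrived + in transit
    ordered = np.concatenate(
        ([0.0], np.cumsum(0.125 * traj["orders"][:-1]))
    )
    np.testing.assert_allclose(
        ordered, traj["received"] + traj["pipeline"], rtol=0, atol=1e-9
    )
    # by t = 10 * delay nearly everything has arrived
    assert traj.at("received", 10.0 * delay) == pytest.approx(volume, rel=0.01)


def test_delay_rejects_non_positive_delay():
    with pytest.raises(ConfigurationError):
        material_delay("orders", 0.0)


# ---------------------------------------------------------------------------
# conservation checking
# ---------------------------------------------------------------------------
def test_conservation_detects_corruption():
    cfg = SimConfig()
    model = decay_model()
    traj = simulate(model, {}, cfg)
    assert check_conservation(traj, model, cfg).ok
    corrupted = Trajectory(
        times=traj.times, series={k: v.copy() for k, v in traj.series.items()}
    )
    corrupted.series["S"][40] += 1.0
    report = check_conservation(corrupted, model, cfg)
    assert not report.ok
    assert report.failures[0]["stock"] == "S"
    assert report.failures[0]["time"] == pytest.approx(traj.times[40])


def test_closed_transfer_system_conserves_total():
    model = ModelDef(
        name="transfer",
        variables=[
            VariableDef(name="move", kind="flow",
                        equation=lambda s, t: 0.3 * s["A"], depends_on=("A",)),
            VariableDef(name="A", kind="stock", initial_value=10.0,
                        outflows=("move",), non_negative=True),
            VariableDef(name="B", kind="stock", initial_value=2.0,
                        inflows=("move",)),
        ],
    )
    traj = simulate(model, {}, SimConfig())
    np.testing.assert_allclose(traj["A"] + traj["B"], 12.0, rtol=1e-12)


def test_conservation_requires_matching_model():
    cfg = SimConfig()
    traj = simulate(decay_model(), {}, cfg)
    other = one_stock_model(lambda s, t: 1.0)
    with pytest.raises(ModelError):
        check_conservation(traj, other, cfg)
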
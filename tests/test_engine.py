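"""Simulation engine: step semantics, closed forms, oracle equivalence,
boundedness, Euler consistency, equilibrium detection."""

import numpy as np
import pytest

import reifnet as rn
import reifnet.model_spec as ms
from reifnet.engine import (
    ScenarioSchedule,
    SimulationConfig,
    Snapshot,
    detect_equilibrium,
    simulate,
    step,
)
from reifnet.errors import EngineError, SpecificationError


def _chain_spec(eta=1.0, weight=1.0):
    """X (held at 1) -> Y with identity aggregation: geometric approach to 1."""
    m = ms.RoleMatrices()
    m.mb = {"X": [], "Y": ["X"]}
    m.mcwv = {"X": [], "Y": [weight]}
    m.mcwa = {"X": [], "Y": [None]}
    m.msv = {"X": 0.0, "Y": eta}
    m.mcfwv = {"Y": {"identity": 1.0}}
    return ms.from_matrices(m, {"X": 1.0, "Y": 0.0})


def _hebb_fixture(h=0.7, mu_init=0.4):
    """pre/post held constant; W governed by hebb with adaptive mu (M) and
    adaptive speed (H), exercising every reification channel in one step."""
    m = ms.RoleMatrices()
    m.mb = {
        "pre": [], "post": [], "M": [], "H": [],
        "W": ["pre", "post"],
    }
    m.mcwv = {"pre": [], "post": [], "M": [], "H": [], "W": [1.0, 1.0]}
    m.mcwa = {"W": [None, None]}
    m.msv = {"pre": 0.0, "post": 0.0, "M": 0.0, "H": 0.0}
    m.msa = {"W": "H"}
    m.mcfwv = {"W": {"hebb": 1.0}}
    m.mcfpa = {"W": {"hebb": {"mu": "M"}}}
    return ms.from_matrices(
        m, {"pre": 0.8, "post": 0.9, "W": 0.2, "M": mu_init, "H": h}
    )


class TestStep:
    def test_worked_update(self):
        """Y(t+dt) = Y + eta*(agg - Y)*dt: 0.2 + 0.5*(0.6-0.2)*0.5 = 0.3."""
        spec = _chain_spec(eta=0.5, weight=0.6)
        out = step(spec, Snapshot(0.0, {"X": 1.0, "Y": 0.2}), dt=0.5)
        assert out["Y"] == pytest.approx(0.3, abs=1e-15)
        assert out.t == 0.5

    def test_zero_speed_is_identity_except_scheduled_inputs(self):
        spec = _chain_spec(eta=0.0)
        sched = ScenarioSchedule("s", 10.0, {"X": [(0.0, 0.0), (0.4, 0.7)]})
        out = step(spec, Snapshot(0.0, {"X": 0.3, "Y": 0.8}), sched, dt=0.5)
        assert out["Y"] == 0.8
        assert out["X"] == pytest.approx(0.7)  # overwritten from the schedule

    def test_reified_hebb_step_matches_hand_formula(self):
        """W' = W + H*[hebb(pre, post, W; mu=M) - W]*dt with everything read at t."""
        spec = _hebb_fixture(h=0.7, mu_init=0.4)
        snap = Snapshot(0.0, {"pre": 0.8, "post": 0.9, "W": 0.2, "M": 0.4, "H": 0.7})
        out = step(spec, snap, dt=0.5)
        hebb_val = 0.8 * 0.9 * (1 - 0.2) + 0.4 * 0.2
        expected = 0.2 + 0.7 * (hebb_val - 0.2) * 0.5
        assert out["W"] == pytest.approx(expected, abs=1e-15)

    def test_missing_state_raises(self):
        spec = _chain_spec()
        with pytest.raises(EngineError, match="missing"):
            step(spec, Snapshot(0.0, {"X": 1.0}))

    def test_synchronous_update_ignores_write_order(self):
        """Jacobi semantics: swapping state declaration order cannot change
        the step, because everything is read at t before anything is written."""
        m = ms.RoleMatrices()
        m.mb = {"A": ["B"], "B": ["A"]}
        m.mcwv = {"A": [1.0], "B": [1.0]}
        m.msv = {"A": 1.0, "B": 1.0}
        m.mcfwv = {"A": {"identity": 1.0}, "B": {"identity": 1.0}}
        fwd = ms.from_matrices(m, {"A": 0.8, "B": 0.1})
        m2 = ms.RoleMatrices()
        m2.mb = {"B": ["A"], "A": ["B"]}
        m2.mcwv = {"B": [1.0], "A": [1.0]}
        m2.msv = {"B": 1.0, "A": 1.0}
        m2.mcfwv = {"B": {"identity": 1.0}, "A": {"identity": 1.0}}
        rev = ms.from_matrices(m2, {"A": 0.8, "B": 0.1})
        s = Snapshot(0.0, {"A": 0.8, "B": 0.1})
        o1, o2 = step(fwd, s, dt=0.25), step(rev, s, dt=0.25)
        assert o1["A"] == o2["A"] and o1["B"] == o2["B"]


class TestSimulate:
    def test_chain_follows_geometric_closed_form(self):
        """With X=1, omega=1, eta=1, identity: Y(k*dt) = 1 - (1-dt)^k."""
        spec = _chain_spec()
        for dt in (0.5, 0.25):
            traj = simulate(spec, config=SimulationConfig(dt=dt, horizon=20.0))
            ks = np.arange(len(traj))
            expected = 1.0 - (1.0 - dt) ** ks
            assert np.max(np.abs(traj.series("Y") - expected)) < 1e-12
        assert traj.final("Y") == pytest.approx(1.0, abs=1e-9)

    def test_length_and_grid(self):
        spec = _chain_spec()
        traj = simulate(spec, config=SimulationConfig(dt=0.5, horizon=10.0))
        assert len(traj) == 21
        assert np.allclose(np.diff(traj.times), 0.5)

    def test_fixed_point_stays_constant(self):
        spec = _chain_spec(eta=0.8, weight=1.0)
        spec = spec.with_initial_values({"X": 1.0, "Y": 1.0})  # agg == Y
        traj = simulate(spec, config=SimulationConfig(dt=0.5, horizon=50.0))
        assert np.all(traj.series("Y") == 1.0)

    def test_child_model_trajectories_bounded(self, happy_offline_run):
        vals = happy_offline_run.values
        assert np.isfinite(vals).all()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert vals.shape == (641, 84)

    def test_deterministic(self, child_spec):
        cfg = SimulationConfig(horizon=30.0)
        a = simulate(child_spec, rn.scenario("happy_offline"), cfg)
        b = simulate(child_spec, rn.scenario("happy_offline"), cfg)
        assert np.array_equal(a.values, b.values)

    def test_requires_horizon_or_schedule(self, child_spec):
        with pytest.raises(SpecificationError):
            simulate(child_spec)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_small_networks_match_straight_line_implementation(
        self, seed, oracle_step
    ):
        """Engine == independently written update equations, to 1e-12/step."""
        spec = ms.random_network(3, 1, 0.8, seed=seed)
        values = {s.id: s.initial_value for s in spec.states}
        snap = Snapshot(0.0, dict(values))
        for k in range(60):
            expected = oracle_step(spec, snap.values, dt=0.5)
            snap = step(spec, snap, dt=0.5)
            for sid, v in expected.items():
                assert snap[sid] == pytest.approx(v, abs=1e-12)

    def test_reified_mu_and_speed_match_oracle(self, oracle_step):
        spec = _hebb_fixture()
        snap = Snapshot(0.0, {s.id: s.initial_value for s in spec.states})
        for _ in range(40):
            expected = oracle_step(spec, snap.values, dt=0.5)
            snap = step(spec, snap, dt=0.5)
            assert snap["W"] == pytest.approx(expected["W"], abs=1e-14)


class TestBoundedness:
    @pytest.mark.parametrize("seed", range(30))
    def test_unclamped_random_networks_stay_in_unit_interval(self, seed):
        """Convex-combination argument: with combination values in [0,1] and
        eta*dt <= 1, no clamping is ever needed."""
        spec = ms.random_network(6, 2, 0.5, seed=100 + seed)
        cfg = SimulationConfig(dt=0.5, horizon=100.0, clamp_mode=False)
        traj = simulate(spec, config=cfg)
        assert traj.values.min() >= -1e-12
        assert traj.values.max() <= 1.0 + 1e-12

    def test_clamp_mode_is_inert_on_well_formed_specs(self):
        spec = ms.random_network(6, 2, 0.5, seed=42)
        on = simulate(spec, config=SimulationConfig(dt=0.5, horizon=100.0))
        off = simulate(
            spec, config=SimulationConfig(dt=0.5, horizon=100.0, clamp_mode=False)
        )
        assert np.array_equal(on.values, off.values)


class TestEulerConsistency:
    def test_halving_dt_halves_the_error(self):
        """First-order integrator: deviation(dt, dt/2) / deviation(dt/2, dt/4)
        approaches 2 on a smooth fixture."""
        m = ms.RoleMatrices()
        m.mb = {"X": [], "Y": ["X"], "Z": ["Y"]}
        m.mcwv = {"X": [], "Y": [0.9], "Z": [0.8]}
        m.msv = {"X": 0.0, "Y": 0.6, "Z": 0.4}
        m.mcfwv = {
            "Y": {"alogistic": 1.0},
            "Z": {"alogistic": 1.0},
        }
        m.mcfpv = {
            "Y": {"alogistic": {"sigma": 3.0, "tau": 0.3}},
            "Z": {"alogistic": {"sigma": 2.0, "tau": 0.2}},
        }
        spec = ms.from_matrices(m, {"X": 1.0, "Y": 0.0, "Z": 0.0})

        def run(dt):
            return simulate(spec, config=SimulationConfig(dt=dt, horizon=20.0))

        t1, t2, t4 = run(0.2), run(0.1), run(0.05)
        d12 = np.abs(t1.values - t2.values[::2]).max()
        d24 = np.abs(t2.values - t4.values[::2]).max()
        assert d12 / d24 == pytest.approx(2.0, abs=0.5)


class TestHebbianGrowth:
    def test_monotone_growth_under_full_coactivation(self):
        """Fire together, wire together: pre=post=1, mu=1, eta>0 gives a
        nondecreasing W trajectory converging to 1."""
        spec = _hebb_fixture(h=0.5, mu_init=1.0)
        spec = spec.with_initial_values({"pre": 1.0, "post": 1.0, "W": 0.05})
        traj = simulate(spec, config=SimulationConfig(dt=0.5, horizon=100.0))
        w = traj.series("W")
        assert np.all(np.diff(w) >= -1e-15)
        assert w[-1] == pytest.approx(1.0, abs=1e-6)


class TestDetectEquilibrium:
    def test_constant_trajectory_settles_immediately(self):
        spec = _chain_spec(eta=0.8)
        spec = spec.with_initial_values({"X": 1.0, "Y": 1.0})
        traj = simulate(spec, config=SimulationConfig(dt=0.5, horizon=30.0))
        assert detect_equilibrium(traj, tol=1e-6, window=10.0) == 0.0

    def test_chain_settles_faster_with_larger_eta(self):
        times = []
        for eta in (0.2, 0.8):
            traj = simulate(
                _chain_spec(eta=eta), config=SimulationConfig(dt=0.5, horizon=200.0)
            )
            t_eq = detect_equilibrium(traj, tol=1e-4, window=10.0)
            assert t_eq is not None
            times.append(t_eq)
        assert times[1] < times[0]

    def test_oscillator_never_settles(self):
        """Two mutually suppressive states wired to a period-4 cycle."""
        m = ms.RoleMatrices()
        m.mb = {"one": [], "A": ["one", "B"], "B": ["A"]}
        m.mcwv = {"one": [], "A": [1.0, -1.0], "B": [1.0]}
        m.msv = {"one": 0.0, "A": 1.0, "B": 1.0}
        m.mcfwv = {"A": {"identity": 1.0}, "B": {"identity": 1.0}}
        spec = ms.from_matrices(m, {"one": 1.0, "A": 1.0, "B": 0.0})
        traj = simulate(spec, config=SimulationConfig(dt=1.0, horizon=100.0))
        assert detect_equilibrium(traj, tol=1e-3, window=10.0) is None

    def test_residuals_at_equilibrium(self, firm_coping_run, child_spec):
        """At a detected equilibrium, |aggimpact - Y| <= tol/eta for every
        state with positive speed."""
        tol = 1e-3
        t_eq = detect_equilibrium(firm_coping_run, tol=tol, window=50.0)
        assert t_eq is not None
        k = int(t_eq / firm_coping_run.dt)
        snap = firm_coping_run.snapshot(min(k + 1, len(firm_coping_run) - 1))
        resolved = ms.resolve(child_spec, snap.values)
        for sid, r in resolved.items():
            if r.speed <= 0 or not r.incoming:
                continue
            impacts = [w * snap[src] for w, src in zip(r.weights, r.incoming)]
            agg = rn.combine(list(r.assignments), impacts, {"w": snap[sid]})
            agg = min(1.0, max(0.0, agg))
            assert abs(agg - snap[sid]) <= tol / r.speed + 1e-9


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path, happy_offline_run):
        path = tmp_path / "traj.csv"
        happy_offline_run.to_csv(path)
        loaded = rn.Trajectory.from_csv(path)
        assert loaded.ids == happy_offline_run.ids
        assert np.allclose(loaded.values, happy_offline_run.values, atol=1e-9)
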
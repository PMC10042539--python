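"""Agent-based model: growth law, transfer lottery, division, trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoqpi.abm import (
    ABMParams,
    AgentState,
    Population,
    apply_transfer,
    baseline_mass,
    divide_and_partition,
    relative_increase,
    run_simulation,
    step_growth,
)
from mitoqpi.errors import InvalidParameterError


def params(**kw):
    defaults = dict(n0=10, m0=1.0, Td=40.0, seed=0)
    defaults.update(kw)
    return ABMParams(**defaults)


class TestStepGrowth:
    def test_euler_update_negative_agent(self):
        p = params(f=0.0, r=1.0, k0=0.1, dt=1.0)
        (out,) = step_growth([AgentState(1.0, 1.0, False)], p)
        assert out.mass == pytest.approx(1.1)

    def test_zero_growth_leaves_masses_unchanged(self):
        p = params(f=0.0, r=1.0, k0=0.0, dt=1.0)
        (out,) = step_growth([AgentState(1.0, 1.0, False)], p)
        assert out.mass == 1.0

    def test_transfer_positive_agent_uses_boosted_rate(self):
        p = params(f=0.0, r=1.15, k0=0.1, dt=1.0)
        (out,) = step_growth([AgentState(1.0, 1.0, True)], p)
        assert out.mass == pytest.approx(1.115)
        assert out.has_transfer

    def test_invalid_dt_rejected(self):
        with pytest.raises(InvalidParameterError):
            params(dt=-1.0)
        with pytest.raises(InvalidParameterError):
            params(dt=0.0)


class TestApplyTransfer:
    def test_zero_fraction_flips_no_one(self, rng):
        p = params(f=0.0)
        pop = Population.uniform(100, 1.0)
        out = apply_transfer(pop, p, rng)
        assert not out.has_transfer.any()

    def test_unit_probability_flips_everyone(self, rng):
        """At f*dt/Td == 1 every transfer-negative agent becomes positive.

        Validated parameters enforce dt << Td, so the boundary is exercised
        through a duck-typed parameter object.
        """
        from types import SimpleNamespace

        p = SimpleNamespace(f=1.0, step=10.0, Td=10.0)
        pop = Population.uniform(50, 1.0)
        out = apply_transfer(pop, p, rng)
        assert out.has_transfer.all()
        too_high = SimpleNamespace(f=1.0, step=11.0, Td=10.0)
        with pytest.raises(InvalidParameterError):
            apply_transfer(pop, too_high, rng)

    def test_binomial_expectation(self):
        """10,000 negatives at f=0.05, dt=Td/100: mean new positives = 5."""
        p = params(n0=10_000, f=0.05, dt=0.4, Td=40.0)
        counts = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pop = Population.uniform(10_000, 1.0)
            out = apply_transfer(pop, p, rng)
            counts.append(out.has_transfer.sum())
        mean = np.mean(counts)
        # Binomial(10000, 5e-4): mean 5, sd of the mean over 200 reps ~ 0.16
        assert mean == pytest.approx(5.0, abs=0.8)

    def test_positive_agents_unchanged(self, rng):
        p = params(f=1.0)
        pop = Population(
            mass=np.ones(4),
            baseline_mass=np.ones(4),
            has_transfer=np.array([True, True, False, False]),
        )
        out = apply_transfer(pop, p, rng)
        assert out.has_transfer[:2].all()


class TestDivideAndPartition:
    def test_halving_rule_and_single_inheritance(self):
        out = divide_and_partition([AgentState(2.2, 1.0, True)])
        assert len(out) == 2
        assert [a.mass for a in out] == [1.1, 1.1]
        assert [a.baseline_mass for a in out] == [1.1, 1.1]
        assert sum(a.has_transfer for a in out) == 1

    def test_below_threshold_no_division(self):
        out = divide_and_partition([AgentState(1.9, 1.0, False)])
        assert len(out) == 1
        assert out[0].mass == 1.9

    def test_one_keeps_one_loses_en_masse(self):
        pop = Population(
            mass=np.full(100, 2.5),
            baseline_mass=np.ones(100),
            has_transfer=np.ones(100, dtype=bool),
        )
        out = divide_and_partition(pop)
        assert len(out) == 200
        assert out.has_transfer.sum() == 100

    @given(
        masses=st.lists(
            st.floats(min_value=0.1, max_value=10.0, allow_nan=False),
            min_size=1,
            max_size=50,
        ),
        flags=st.lists(st.booleans(), min_size=50, max_size=50),
    )
    @settings(max_examples=100, deadline=None)
    def test_mass_conserved_exactly(self, masses, flags):
        """Division conserves total population mass to machine precision."""
        n = len(masses)
        pop = Population(
            mass=np.array(masses),
            baseline_mass=np.ones(n),
            has_transfer=np.array(flags[:n]),
        )
        # halving is exact in binary floating point, so the exact (correctly
        # rounded) sums must agree bit-for-bit
        before = math.fsum(pop.mass)
        out = divide_and_partition(pop)
        assert math.fsum(out.mass) == before


class TestRunSimulation:
    def test_pure_exponential_reaches_8x_after_3_doublings(self):
        p = params(n0=50, f=0.0, r=1.0, d_target=3)
        traj = run_simulation(p)
        ratio = traj.total_mass[-1] / traj.total_mass[0]
        assert ratio == pytest.approx(8.0, rel=0.01)

    def test_neutral_r_gives_zero_increase(self):
        vals = [
            relative_increase(
                run_simulation(params(n0=200, f=0.05, r=1.0, d_target=5, seed=s)), 5
            )
            for s in range(5)
        ]
        assert abs(np.mean(vals)) < 1e-6

    def test_reproducible_for_fixed_seed(self):
        p = params(n0=100, f=0.05, r=1.15, d_target=4, seed=11)
        t1 = run_simulation(p)
        t2 = run_simulation(p)
        np.testing.assert_array_equal(t1.total_mass, t2.total_mass)
        np.testing.assert_array_equal(t1.fraction_positive, t2.fraction_positive)

    def test_monotone_in_r_and_f(self):
        """Average relative increase grows with r and with f."""
        def mean_ri(f, r):
            vals = [
                relative_increase(
                    run_simulation(params(n0=150, f=f, r=r, d_target=5, seed=s)), 5
                )
                for s in range(20)
            ]
            return np.mean(vals)

        by_r = [mean_ri(0.1, r) for r in (1.0, 1.15, 1.4)]
        assert by_r == sorted(by_r)
        by_f = [mean_ri(f, 1.3) for f in (0.0, 0.05, 0.2)]
        assert by_f == sorted(by_f)

    def test_trajectory_mass_strictly_increasing(self):
        traj = run_simulation(params(n0=50, f=0.05, r=1.15, d_target=3))
        assert np.all(np.diff(traj.total_mass) > 0)
        assert np.all((traj.fraction_positive >= 0) & (traj.fraction_positive <= 1))


class TestBaselineAndRelativeIncrease:
    @pytest.mark.parametrize(
        "m0,d,expected", [(1.0, 0, 1.0), (1.0, 1, 2.0), (1.0, 20, 1_048_576.0)]
    )
    def test_baseline_closed_form(self, m0, d, expected):
        assert baseline_mass(m0, d) == pytest.approx(expected)

    def test_negative_doublings_rejected(self):
        with pytest.raises(InvalidParameterError):
            baseline_mass(1.0, -1)

    def test_relative_increase_arithmetic(self):
        traj = run_simulation(params(n0=20, f=0.0, r=1.0, d_target=2))
        # pure exponential: matches baseline, so increase ~ 0%
        assert relative_increase(traj, 2) == pytest.approx(0.0, abs=0.5)
        with pytest.raises(InvalidParameterError):
            relative_increase(traj, 5)

    def test_relative_increase_ratio_examples(self):
        # synthetic trajectory: mass exactly 1.15x the 2-doubling baseline
        p = params(n0=1, f=0.0, r=1.0, d_target=2)
        traj = run_simulation(p)
        traj.total_mass = traj.total_mass * 1.15
        traj.total_mass[0] = traj.total_mass[0] / 1.15  # keep m0 reference
        assert relative_increase(traj, 2) == pytest.approx(15.0, abs=0.6)


def test_agent_state_validates_masses():
    with pytest.raises(InvalidParameterError):
        AgentState(-1.0, 1.0)
    with pytest.raises(InvalidParameterError):
        AgentState(1.0, 0.0)
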
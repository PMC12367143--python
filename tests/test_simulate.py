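"""Stochastic and mean-field simulation engines."""

import numpy as np
import pytest

import aakin.schemes as sch
from aakin.fitting import default_rateset
from aakin.schemes import EnzymeState, RateSet, ReactionScheme, ReactionStep
from aakin.simulate import (AssayConditions, Trajectory, initial_velocity,
                            simulate_ode, simulate_ssa,
                            steady_state_distribution, steady_state_velocity)

ALL_VARIANTS = [sch.CLASS1_MONOMER, sch.CLASS1_TRNA_REQUIRED,
                sch.CLASS2_FLIPFLOP, sch.PP_EXCHANGE, sch.SINGLE_TURNOVER]


def _toy(states, steps, **kw):
    s = ReactionScheme(variant="toy", states=tuple(states), steps=tuple(steps), **kw)
    s.validate()
    return s


def _two_state_switch(k=5.0):
    states = [EnzymeState("A", (frozenset(),)), EnzymeState("B", (frozenset(),))]
    steps = [ReactionStep("flip", "A", "B", "conversion")]
    return _toy(states, steps, start_label="A"), RateSet({"flip": (k, k)})


def _poisson_emitter(k=2.0):
    """E + S -> E + P with S a bath: product is a Poisson process."""
    states = [EnzymeState("E", (frozenset(),))]
    steps = [ReactionStep("cat", "E", "E", "conversion", consumes=sch.AA,
                          releases=sch.AATRNA)]
    scheme = ReactionScheme(variant="toy", states=tuple(states),
                            steps=tuple(steps), start_label="E",
                            product_steps=("cat",))
    scheme.validate()
    return scheme, RateSet({"cat": (k, 0.0)})


def _aa_conditions(**kw):
    base = dict(concentrations={sch.ATP: 5000.0, sch.AA: 500.0,
                                sch.TRNA: 10.0},
                enzyme_conc=0.01, enzyme_copies=100, duration=2.0)
    base.update(kw)
    return AssayConditions(**base)


class TestSSA:
    def test_bitwise_determinism(self, mm_oracle):
        cond = AssayConditions(concentrations={sch.TRNA: 5.0},
                               enzyme_copies=50, duration=5.0)
        a = simulate_ssa(mm_oracle, cond, seed=42)
        b = simulate_ssa(mm_oracle, cond, seed=42)
        assert np.array_equal(a.firings, b.firings)
        assert np.array_equal(a.state_counts, b.state_counts)
        c = simulate_ssa(mm_oracle, cond, seed=43)
        assert not np.array_equal(a.firings, c.firings)

    def test_zero_enzyme_copies_make_no_product(self, mm_oracle):
        cond = AssayConditions(concentrations={sch.TRNA: 5.0},
                               enzyme_copies=0, duration=1.0)
        traj = simulate_ssa(mm_oracle, cond, seed=1)
        assert traj.n_events == 0
        assert np.all(traj.product == 0)

    def test_two_state_switch_splits_evenly(self):
        scheme, rates = _two_state_switch(k=20.0)
        cond = AssayConditions(enzyme_copies=200, duration=50.0)
        traj = simulate_ssa((scheme, rates), cond, seed=7)
        occ = traj.state_occupancy("A")[len(traj.times) // 2:].mean() / 200
        # binomial sd per sample ~ 0.035; time average is tighter
        assert abs(occ - 0.5) < 0.05

    def test_poisson_rate_matches_closed_form(self):
        scheme, rates = _poisson_emitter(k=0.01)  # 0.01 uM^-1 s^-1
        conc = 200.0
        cond = AssayConditions(concentrations={sch.AA: conc},
                               enzyme_copies=50, duration=5.0)
        expected = 0.01 * conc  # per-enzyme product rate, s^-1
        vals = [float(initial_velocity(
            simulate_ssa((scheme, rates), cond, seed=s), "product"))
            for s in range(10)]
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - expected) < 3 * max(se, 1e-3 * expected)

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_enzyme_conservation_every_sample(self, variant):
        scheme = sch.build_scheme(variant)
        rates = default_rateset(scheme)
        cond = _aa_conditions(duration=1.0)
        traj = simulate_ssa((scheme, rates), cond, seed=3,
                            start_state=scheme.start_label)
        assert np.all(traj.total_enzyme == cond.enzyme_copies)
        assert np.all(traj.state_counts >= 0)

    def test_firing_counts_monotone(self, cys_model):
        traj = simulate_ssa(cys_model, _aa_conditions(duration=0.5), seed=9)
        assert np.all(np.diff(traj.firings, axis=0) >= 0)


class TestODE:
    def test_state_fractions_sum_to_one(self, cys_model):
        cond = _aa_conditions(duration=1.0)
        traj = simulate_ode(cys_model, cond)
        assert np.allclose(traj.total_enzyme, cond.enzyme_copies, rtol=1e-6)

    def test_bath_pools_never_change(self, cys_model):
        traj = simulate_ode(cys_model, _aa_conditions(duration=1.0))
        # bath species are not tracked as counts; their pool entries stay 0
        assert np.all(traj.pool_counts == 0.0)

    def test_ssa_ensemble_matches_ode_within_5pct(self, cys_model):
        """Law of large numbers: mean SSA product curve at 1000 copies
        agrees with the mean-field trajectory."""
        cond = _aa_conditions(enzyme_copies=1000, duration=2.0)
        ode = simulate_ode(cys_model, cond)
        acc = np.zeros_like(ode.product)
        reps = 3
        for s in range(reps):
            acc += simulate_ssa(cys_model, cond, seed=100 + s).product
        acc /= reps
        tail = slice(len(acc) // 4, None)  # skip near-zero initial counts
        rel = np.abs(acc[tail] - ode.product[tail]) / np.maximum(ode.product[tail], 1)
        assert rel.max() < 0.05

    def test_oracle_ode_matches_mm_velocity(self, mm_oracle):
        cond = AssayConditions(concentrations={sch.TRNA: 5.0},
                               enzyme_copies=100, duration=10.0)
        traj = simulate_ode(mm_oracle, cond)
        v = float(initial_velocity(traj, "product"))
        assert v == pytest.approx(5.0, rel=0.01)  # kcat S/(Km+S) at S=Km


class TestSteadyState:
    def test_two_state_analytic_occupancy(self):
        scheme, _ = _two_state_switch()
        rates = RateSet({"flip": (3.0, 1.0)})
        pi = steady_state_distribution(scheme, rates, AssayConditions())
        assert pi == pytest.approx([0.25, 0.75], rel=1e-12)

    def test_oracle_velocity_closed_form(self, mm_oracle):
        scheme, rates = mm_oracle
        for s_conc in (1.0, 5.0, 50.0):
            cond = AssayConditions(concentrations={sch.TRNA: s_conc})
            v = steady_state_velocity(scheme, rates, cond, "product")
            assert v == pytest.approx(10.0 * s_conc / (5.0 + s_conc), rel=1e-12)

    def test_pp_exchange_ssa_velocity_matches_flux_oracle(self, cys_model):
        """SSA-measured exchange velocity equals the stationary
        reverse-activation flux of the same chain."""
        scheme = sch.build_pp_exchange_scheme()
        cond = AssayConditions(
            concentrations={sch.ATP: 5000.0, sch.AA: 500.0, sch.PPI: 2000.0},
            enzyme_copies=200, duration=1.0)
        expected = steady_state_velocity(scheme, cys_model.rates, cond,
                                         "pp_exchange")
        vals = [float(initial_velocity(
            simulate_ssa((scheme, cys_model.rates), cond, seed=s),
            "pp_exchange")) for s in range(6)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * max(se, 0.005 * expected)


class TestInitialVelocity:
    def test_no_events_flagged(self):
        t = np.linspace(0, 1, 11)
        traj = Trajectory(times=t, state_counts=np.ones((11, 1)),
                          pool_counts=np.zeros((11, 6)), firings=None,
                          product=np.zeros(11), exchange=np.zeros(11),
                          state_labels=("E",), enzyme_copies=1,
                          conditions=AssayConditions())
        v = initial_velocity(traj, "product")
        assert float(v) == 0.0 and v.low_confidence

    def test_exact_linear_product_recovers_slope(self):
        t = np.linspace(0, 2, 101)
        lam, e0 = 37.0, 10
        traj = Trajectory(times=t, state_counts=np.full((101, 1), e0),
                          pool_counts=np.zeros((101, 6)), firings=None,
                          product=lam * t, exchange=np.zeros(101),
                          state_labels=("E",), enzyme_copies=e0,
                          conditions=AssayConditions())
        assert float(initial_velocity(traj, "product")) == pytest.approx(lam / e0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            initial_velocity(None, "bogus")
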
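"""Integrator correctness against closed forms, observables, trajectory IO."""

import math

import numpy as np
import pytest

import cannakin as ck
from cannakin.errors import (InvalidArgumentError, UndefinedYieldError,
                             UnknownSpeciesError)
from cannakin.synthetic import toy_chain_model, toy_chain_solution


class TestIntegratorOracle:
    @pytest.mark.parametrize("n,k", [(1, 1.0), (3, 1.0), (5, 0.7)])
    def test_bateman_chain_matches_closed_form(self, n, k):
        model = toy_chain_model(n=n, k=k, s0=1.0)
        traj = ck.simulate(model, t_end=5.0, dt_out=0.1, rtol=1e-10, atol=1e-12)
        exact = toy_chain_solution(n=n, k=k, s0=1.0, t=traj.times)
        rel = np.abs(traj.conc - exact) / np.maximum(np.abs(exact), 1e-9)
        mask = exact > 1e-6  # relative error where the closed form is resolvable
        assert rel[mask].max() < 1e-6

    def test_mass_conservation_along_chain(self):
        traj = ck.simulate(toy_chain_model(3, 1.0, 2.5), t_end=8.0, dt_out=0.2)
        totals = traj.conc.sum(axis=0)
        assert np.allclose(totals, 2.5, rtol=1e-8, atol=1e-8)

    def test_tolerance_halving_leaves_endpoint(self, default_model):
        a = ck.simulate(default_model, t_end=8.0, dt_out=0.5, rtol=1e-8, atol=1e-10)
        b = ck.simulate(default_model, t_end=8.0, dt_out=0.5, rtol=5e-9, atol=5e-11)
        fa, fb = a.conc[:, -1], b.conc[:, -1]
        scale = np.maximum(np.abs(fa), 1e-6)
        assert (np.abs(fa - fb) / scale).max() < 1e-3

    def test_no_sources_stays_at_zero(self):
        cfg = ck.ScenarioConfig(glucose_mM=0.0, ha_feed_mM=None)
        traj = ck.simulate(ck.build_default_model(cfg), t_end=5.0, dt_out=0.5)
        assert traj.conc.max() == 0.0

    def test_clamped_species_constant(self, default_traj):
        ha_ex = default_traj.series("ha_ex")
        assert np.all(ha_ex == 1.0)

    def test_invalid_horizon(self, default_model):
        with pytest.raises(InvalidArgumentError):
            ck.simulate(default_model, t_end=-1.0)


class TestObservables:
    def test_depletion_time_exponential_decay(self):
        # single first-order sink: t* = ln(s0/threshold)/k
        traj = ck.simulate(toy_chain_model(1, 1.0, 1.0), t_end=6.0, dt_out=0.05)
        assert ck.depletion_time(traj, "s0", 0.1) == pytest.approx(
            math.log(10.0), abs=1e-3)

    def test_depletion_sentinel_when_never_crossing(self, default_traj):
        assert ck.depletion_time(default_traj, "ha_ex", 0.5) == math.inf

    def test_grid_refinement_stability(self, default_model):
        coarse = ck.simulate(default_model, t_end=25.0, dt_out=0.1)
        fine = ck.simulate(default_model, t_end=25.0, dt_out=0.05)
        assert ck.depletion_time(coarse, "glc_ex", 0.1) == pytest.approx(
            ck.depletion_time(fine, "glc_ex", 0.1), abs=5e-3)

    def test_steady_state_time_clamped_species_is_zero(self, default_traj):
        assert ck.steady_state_time(default_traj, "ha_ex") == 0.0

    def test_steady_state_time_saturating_approach(self):
        # terminal stage of a 1-step chain: s(t)=s0(1-e^(-kt)); the relative
        # rate k*e^(-kt)/(1-e^(-kt)) drops below tol at the closed-form root
        k, tol = 1.0, 0.01
        traj = ck.simulate(toy_chain_model(1, k, 1.0), t_end=12.0, dt_out=0.01)
        expected = math.log(1.0 + k / tol) / k
        assert ck.steady_state_time(traj, "s1", tol) == pytest.approx(
            expected, abs=0.05)

    def test_thca_monotone_nondecreasing(self, default_traj):
        thca = default_traj.series("thca")
        assert np.all(np.diff(thca) >= -1e-12)

    def test_ethanol_diauxic_pattern(self, default_traj):
        """Crabtree overflow: ethanol rises while glucose is abundant and is
        reconsumed after depletion."""
        t = default_traj.times
        etoh = default_traj.series("etoh")
        dep = ck.depletion_time(default_traj, "glc_ex", 0.1)
        early = etoh[(t > 1.0) & (t < dep - 1.0)]
        late = etoh[t > dep + 1.0]
        assert np.all(np.diff(early) > 0)
        assert np.all(np.diff(late) < 0)
        assert etoh[-1] < etoh[np.searchsorted(t, dep)]


class TestUnitsAndYield:
    def test_mass_conversion_examples(self, default_traj):
        assert ck.to_mass_conc(0.0, "thca", default_traj.mw) == 0.0
        assert ck.to_mass_conc(1.0, "glc_ex", default_traj.mw) == pytest.approx(180.16)
        # 0.837 mM THCA at mw 358.48 lands within 0.1% of 300 mg/L
        assert ck.to_mass_conc(0.837, "thca", default_traj.mw) == pytest.approx(
            300.0, rel=1e-3)

    def test_missing_mw_raises(self, default_traj):
        with pytest.raises(UnknownSpeciesError):
            ck.to_mass_conc(1.0, "nonexistent", default_traj.mw)

    def test_yield_zero_product(self):
        cfg = ck.ScenarioConfig(ha_feed_mM=None)  # glucose burns, no THCA
        traj = ck.simulate(ck.build_default_model(cfg), t_end=5.0, dt_out=0.5)
        assert ck.yield_per_substrate(traj, "thca", "glc_ex") == pytest.approx(0.0, abs=1e-12)

    def test_yield_undefined_without_consumption(self):
        cfg = ck.ScenarioConfig(glucose_mM=0.0, ha_feed_mM=None)
        traj = ck.simulate(ck.build_default_model(cfg), t_end=2.0, dt_out=0.5)
        with pytest.raises(UndefinedYieldError):
            ck.yield_per_substrate(traj, "thca", "glc_ex")

    def test_yield_stoichiometric_conversion(self):
        # 1:1 molar conversion implies yield = mw_product / mw_substrate
        model = toy_chain_model(1, 2.0, 1.0)
        model.species[0].mw = 100.0
        model.species[1].mw = 82.0  # e.g. a dehydration product
        traj = ck.simulate(model, t_end=10.0, dt_out=0.5)
        assert ck.yield_per_substrate(traj, "s1", "s0") == pytest.approx(
            82.0 / 100.0, rel=1e-6)


class TestTrajectoryIO:
    def test_csv_round_trip_lossless(self, default_model, tmp_path):
        traj = ck.simulate(default_model, t_end=3.0, dt_out=0.25)
        path = tmp_path / "run.csv"
        ck.write_trajectory_csv(traj, path)
        back = ck.read_trajectory_csv(path)
        assert back.species_ids == traj.species_ids
        assert np.allclose(back.conc, traj.conc, rtol=1e-11, atol=1e-14)
        assert np.allclose(back.times, traj.times, rtol=1e-11, atol=0)
        assert np.allclose(back.ledger.h2o2_produced, traj.ledger.h2o2_produced,
                           rtol=1e-11, atol=1e-14)
        assert back.meta["model_hash"] == traj.meta["model_hash"]
        assert back.mw["thca"] == traj.mw["thca"]
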
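"""Objective contracts, determinism, and parameter recovery."""

import pytest

import cannakin as ck
from cannakin.calibrate import (CalibrationAnchor, FreeParameterSet,
                                apply_free_parameters, calibrate,
                                default_anchor_set,
                                default_free_parameter_set, evaluate_anchor,
                                objective)
from cannakin.errors import InvalidArgumentError
from cannakin.synthetic import PerturbationSpec, perturbed_parameter_set

RECOVERY_NAMES = ["ha_diffusion_k", "thcas_vmax"]


def _truth_anchors(noise_cv: float = 0.0, seed: int = 7) -> list[CalibrationAnchor]:
    """Anchors measured from a run of the shipped (truth) parameter set."""
    traj = ck.simulate(ck.build_default_model(), t_end=40.0, dt_out=0.1)
    if noise_cv > 0.0:
        from cannakin.synthetic import noisy_trajectory
        traj = noisy_trajectory(traj, cv=noise_cv, seed=seed)
    return [
        CalibrationAnchor("conc_at", "thca", target=traj.at("thca", 40.0),
                          time=40.0, tolerance=0.01, weight=2.0),
        CalibrationAnchor("conc_at", "cbga", target=traj.at("cbga", 40.0),
                          time=40.0, tolerance=0.01, weight=1.0),
        CalibrationAnchor("conc_at", "ha_c", target=traj.at("ha_c", 40.0),
                          time=40.0, tolerance=0.01, weight=1.0),
    ]


class TestObjective:
    def test_zero_at_self_consistent_anchors(self):
        fps = default_free_parameter_set(names=RECOVERY_NAMES)
        anchors = _truth_anchors()
        assert objective(fps, anchors) == pytest.approx(0.0, abs=1e-8)

    def test_positive_after_perturbing_one_vmax(self):
        fps = default_free_parameter_set(names=RECOVERY_NAMES)
        bumped = FreeParameterSet(
            values={**fps.values, "thcas_vmax": fps.values["thcas_vmax"] * 2.0},
            bounds=fps.bounds)
        assert objective(bumped, _truth_anchors()) > 1e-4

    def test_upper_bound_anchor_one_sided(self, default_traj):
        below = CalibrationAnchor("conc_at", "ha_c", target=0.3, time=40.0,
                                  tolerance=0.03, kind="upper_bound")
        assert evaluate_anchor(default_traj, below) < 0.3
        fps = default_free_parameter_set(names=[])
        assert objective(fps, [below]) == pytest.approx(0.0, abs=1e-12)

    def test_anchor_validation(self):
        with pytest.raises(InvalidArgumentError):
            CalibrationAnchor("conc_at", "thca", target=1.0, time=40.0,
                              tolerance=0.0)


class TestCalibrate:
    def test_degenerate_all_fixed_returns_fixed_point(self):
        fps = FreeParameterSet(values={}, bounds={})
        res = calibrate(_truth_anchors(), free=fps, objective_ceiling=10.0)
        assert res.parameters.values == {}

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            calibrate([], free=default_free_parameter_set(names=RECOVERY_NAMES))

    def test_deterministic_given_seed(self, tmp_path):
        anchors = _truth_anchors()
        free = default_free_parameter_set(names=["thcas_vmax"], span=2.0)
        runs = []
        for i in range(2):
            res = calibrate(anchors, free=free, seed=11, n_starts=2, maxiter=25,
                            objective_ceiling=100.0)
            path = tmp_path / f"params_{i}.yaml"
            res.parameters.to_yaml(path)
            runs.append(path.read_text())
        assert runs[0] == runs[1]

    def test_recovery_noise_free_within_10_percent(self):
        """Generate anchors from the shipped truth, start the search from a
        perturbed point, and require the identifiable vmax-type factors
        back within 10%."""
        truth = default_free_parameter_set(names=RECOVERY_NAMES, span=4.0)
        start = perturbed_parameter_set(truth, PerturbationSpec(sigma=0.25, seed=3))
        res = calibrate(_truth_anchors(), free=start, seed=1, n_starts=1,
                        maxiter=120, objective_ceiling=1.0)
        for name in RECOVERY_NAMES:
            assert res.parameters.values[name] == pytest.approx(
                truth.values[name], rel=0.10)

    def test_recovery_with_observation_noise_within_15_percent(self):
        truth = default_free_parameter_set(names=RECOVERY_NAMES, span=4.0)
        start = perturbed_parameter_set(truth, PerturbationSpec(sigma=0.2, seed=5))
        res = calibrate(_truth_anchors(noise_cv=0.05, seed=9), free=start,
                        seed=2, n_starts=1, maxiter=120, objective_ceiling=1.0)
        for name in RECOVERY_NAMES:
            assert res.parameters.values[name] == pytest.approx(
                truth.values[name], rel=0.15)


class TestShippedDefaults:
    def test_default_anchor_set_met_by_shipped_parameters(self):
        """The shipped parameter file reproduces the printed anchors without
        re-calibration (objective below the contract bound)."""
        fps = default_free_parameter_set(names=[])
        val = objective(fps, default_anchor_set())
        assert val < 0.01

    def test_apply_free_parameters_is_pure(self):
        params = ck.load_default_params()
        fps = default_free_parameter_set(names=["thcas_vmax"])
        fps.values["thcas_vmax"] *= 3.0
        out = apply_free_parameters(params, fps)
        assert out["reactions"]["thcas"]["vmax"] == pytest.approx(
            params["reactions"]["thcas"]["vmax"] * 3.0)
        # original untouched
        assert params == ck.load_default_params()
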
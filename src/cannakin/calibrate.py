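"""Calibration of the free kinetic parameters against printed anchors.

The underlying study reports model *endpoints* (glucose gone at 20.8 h from
111 mM, THCA at 0.837 mM after 40 h, roughly 0.65 mM excess GPP, an
intracellular hexanoic-acid steady state under 0.3 mM, olivetolic acid
steady within 10 h) but none of its rate constants.  This module owns the
inverse problem: a small set of named free parameters (vmax-type scale
factors, the hexanoic-acid diffusion constant, the glucose-regulation
half-point and the PPP fraction) is fitted by multi-start Nelder-Mead
simplex search, seeded from a Latin-hypercube design in log-parameter
space, so that the default model reproduces the anchors.  Km values are
never fitted; they stay at the literature-plausible defaults recorded in
the parameter file.

The shipped ``data/params_default.yaml`` is the frozen output of this
procedure.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.stats import qmc

from .config import ScenarioConfig
from .errors import CalibrationFailedError, InvalidArgumentError
from .pathway import build_default_model, load_default_params
from .simulate import (depletion_time, simulate, steady_state_time,
                       yield_per_substrate)

__all__ = [
    "CalibrationAnchor",
    "FreeParameterSet",
    "FREE_PARAM_PATHS",
    "default_free_parameter_set",
    "default_anchor_set",
    "apply_free_parameters",
    "evaluate_anchor",
    "objective",
    "calibrate",
    "CalibrationResult",
]

log = logging.getLogger("cannakin")

#: Where each free parameter lives inside the nested parameter dict.
FREE_PARAM_PATHS: dict[str, tuple[str, ...]] = {
    "glc_uptake_vmax": ("reactions", "glc_uptake", "vmax"),
    "glycolysis_vmax": ("reactions", "glycolysis", "vmax"),
    "thmgr_vmax": ("reactions", "thmgr", "vmax"),
    "erg20ww_k": ("reactions", "erg20ww", "k"),
    "erg20_residual_fraction": ("globals", "erg20_residual_fraction"),
    "ols_oac_vmax": ("reactions", "ols_oac", "vmax"),
    "nphb_vmax": ("reactions", "nphb", "vmax"),
    "thcas_vmax": ("reactions", "thcas", "vmax"),
    "aae1_vmax": ("reactions", "aae1", "vmax"),
    "acc1_vmax": ("reactions", "acc1", "vmax"),
    "ha_diffusion_k": ("reactions", "ha_diffusion", "k"),
    "k_rep": ("globals", "k_rep"),
    "f_ppp": ("globals", "f_ppp"),
}

_SPECIAL_BOUNDS = {
    "erg20_residual_fraction": (1e-5, 0.2),
    "f_ppp": (0.01, 0.5),
    "k_rep": (0.5, 50.0),
}


@dataclass
class CalibrationAnchor:
    """One printed observable the default parameter set must reproduce.

    ``observable`` is one of ``depletion_time``, ``conc_at``,
    ``steady_state_time`` or ``yield``; ``kind`` is ``equality`` (squared
    relative residual) or ``upper_bound`` (one-sided hinge penalty).
    """

    observable: str
    species: str
    target: float
    units: str = "mM"
    time: Optional[float] = None        # for conc_at
    threshold: float = 0.1              # for depletion_time
    rel_rate_tol: float = 0.01          # for steady_state_time
    substrate: str = "glc_ex"           # for yield
    tolerance: float = 0.05
    weight: float = 1.0
    kind: str = "equality"

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.weight <= 0:
            raise InvalidArgumentError("anchor tolerance and weight must be > 0")


@dataclass
class FreeParameterSet:
    """Named free parameters with bounds; the calibration search space."""

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            lo, hi = self.bounds[name]
            if not (0 < lo <= hi):
                raise InvalidArgumentError(f"bounds for {name} must be positive")
            if not (lo <= v <= hi):
                raise InvalidArgumentError(
                    f"{name}={v!r} outside declared bounds [{lo}, {hi}]")

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def to_yaml(self, path=None) -> str:
        payload = {
            "values": {k: float(f"{v:.12g}") for k, v in self.values.items()},
            "bounds": {k: [float(lo), float(hi)] for k, (lo, hi) in self.bounds.items()},
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "FreeParameterSet":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(values=dict(d["values"]),
                   bounds={k: (v[0], v[1]) for k, v in d["bounds"].items()})


def _get_path(params: dict, path: tuple[str, ...]) -> float:
    node = params
    for key in path:
        node = node[key]
    return node


def _set_path(params: dict, path: tuple[str, ...], value: float) -> None:
    node = params
    for key in path[:-1]:
        node = node[key]
    node[path[-1]] = float(value)


def default_free_parameter_set(params: Optional[dict] = None,
                               names: Optional[Sequence[str]] = None,
                               span: float = 30.0) -> FreeParameterSet:
    """Free-parameter set centered on the current parameter file.

    Bounds default to a symmetric factor of ``span`` around each current
    value; the residual ERG20 fraction, the PPP fraction and the regulation
    half-point carry their own physically motivated ranges.
    """
    if params is None:
        params = load_default_params()
    if names is None:
        names = list(FREE_PARAM_PATHS)
    values, bounds = {}, {}
    for name in names:
        v = float(_get_path(params, FREE_PARAM_PATHS[name]))
        values[name] = v
        bounds[name] = _SPECIAL_BOUNDS.get(name, (v / span, v * span))
    return FreeParameterSet(values=values, bounds=bounds)


def apply_free_parameters(params: dict, fps: FreeParameterSet) -> dict:
    """Return a deep copy of ``params`` with the free values written in."""
    out = copy.deepcopy(params)
    for name, value in fps.values.items():
        _set_path(out, FREE_PARAM_PATHS[name], value)
    return out


def load_anchors(path) -> list[CalibrationAnchor]:
    """Read an anchor list from a YAML file (list of anchor mappings)."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [CalibrationAnchor(**e) for e in entries]


def default_anchor_set() -> list[CalibrationAnchor]:
    """The shipped endpoint anchors the default parameter file reproduces."""
    import importlib.resources

    ref = importlib.resources.files("cannakin.data").joinpath("anchors_default.yaml")
    return [CalibrationAnchor(**e) for e in yaml.safe_load(ref.read_text())]


def evaluate_anchor(traj, anchor: CalibrationAnchor) -> float:
    if anchor.observable == "depletion_time":
        return depletion_time(traj, anchor.species, anchor.threshold)
    if anchor.observable == "conc_at":
        return traj.at(anchor.species, anchor.time)
    if anchor.observable == "steady_state_time":
        return steady_state_time(traj, anchor.species, anchor.rel_rate_tol)
    if anchor.observable == "yield":
        return yield_per_substrate(traj, anchor.species, anchor.substrate)
    raise InvalidArgumentError(f"unknown observable {anchor.observable!r}")


_FAILURE_PENALTY = 1e6


def objective(fps: FreeParameterSet, anchors: Sequence[CalibrationAnchor],
              config: Optional[ScenarioConfig] = None,
              base_params: Optional[dict] = None,
              rtol: float = 1e-6, atol: float = 1e-9,
              dt_out: float = 0.1) -> float:
    """Weighted sum of squared relative residuals over the anchors.

    Equality anchors contribute ``w*((obs-target)/target)^2``; upper bounds
    contribute a one-sided hinge ``w*max(0,(obs-bound)/bound)^2``.  Exactly
    zero iff every anchor is met exactly.  A failed simulation returns a
    large finite penalty instead of raising, so the simplex can retreat.
    """
    if config is None:
        config = ScenarioConfig()
    if base_params is None:
        base_params = load_default_params()
    params = apply_free_parameters(base_params, fps)
    t_end = max([config.t_end_h] + [a.time for a in anchors if a.time is not None])
    try:
        model = build_default_model(config, params=params)
        traj = simulate(model, t_end=t_end, dt_out=dt_out, rtol=rtol, atol=atol)
    except Exception as exc:  # noqa: BLE001 - any solver failure is a penalty
        log.warning("simulation failed during calibration (%s); penalized", exc)
        return _FAILURE_PENALTY
    total = 0.0
    for a in anchors:
        obs = evaluate_anchor(traj, a)
        if not math.isfinite(obs):
            # sentinel (e.g. never-steady); treat as a full-scale miss
            total += a.weight * 4.0
            continue
        if a.kind == "equality":
            total += a.weight * ((obs - a.target) / a.target) ** 2
        else:
            total += a.weight * max(0.0, (obs - a.target) / a.target) ** 2
    return total


@dataclass
class CalibrationResult:
    parameters: FreeParameterSet
    objective_value: float
    report: pd.DataFrame
    n_evaluations: int = 0
    starts: list = field(default_factory=list)


def _flat_flags(best: FreeParameterSet, anchors, config, base_params,
                best_obj: float, n_grid: int = 3) -> dict[str, bool]:
    """Mark parameters whose objective profile is flat across their bounds."""
    flags = {}
    for name in best.names:
        lo, hi = best.bounds[name]
        probes = np.geomspace(lo, hi, n_grid)
        deltas = []
        for p in probes:
            trial = FreeParameterSet(values={**best.values, name: float(p)},
                                     bounds=best.bounds)
            deltas.append(abs(objective(trial, anchors, config, base_params) - best_obj))
        flags[name] = max(deltas) < 0.01 * max(best_obj, 1e-6) + 1e-9
    return flags


def calibrate(anchors: Sequence[CalibrationAnchor],
              free: Optional[FreeParameterSet] = None,
              config: Optional[ScenarioConfig] = None,
              base_params: Optional[dict] = None,
              seed: int = 0, n_starts: int = 4, maxiter: int = 200,
              objective_ceiling: float = 1.0,
              include_center: bool = True,
              flag_flat: bool = False) -> CalibrationResult:
    """Fit the free parameters to the anchors.

    Derivative-free local search (Nelder-Mead) in log-parameter space,
    multi-started from a seeded Latin-hypercube design over the bounds (the
    current values are included as one start).  Deterministic given the
    seed.  Raises :class:`CalibrationFailedError` if no start converges
    below ``objective_ceiling``.
    """
    if not anchors:
        raise InvalidArgumentError("anchors must be non-empty")
    if free is None:
        free = default_free_parameter_set(base_params)
    if not free.values:  # degenerate: everything fixed
        val = objective(free, anchors, config, base_params)
        report = pd.DataFrame(columns=["parameter", "lower", "upper", "start",
                                       "fitted", "flat"])
        return CalibrationResult(parameters=free, objective_value=val, report=report)

    names = free.names
    lo = np.array([free.bounds[n][0] for n in names])
    hi = np.array([free.bounds[n][1] for n in names])
    log_lo, log_hi = np.log(lo), np.log(hi)

    def to_fps(x: np.ndarray) -> FreeParameterSet:
        vals = np.exp(np.clip(x, log_lo, log_hi))
        vals = np.minimum(np.maximum(vals, lo), hi)  # exp/log round-off
        return FreeParameterSet(values=dict(zip(names, map(float, vals))),
                                bounds=free.bounds)

    evals = {"n": 0}

    def fun(x: np.ndarray) -> float:
        evals["n"] += 1
        penalty = float(np.sum(np.maximum(0.0, x - log_hi) ** 2 +
                               np.maximum(0.0, log_lo - x) ** 2))
        return objective(to_fps(x), anchors, config, base_params) + 10.0 * penalty

    starts = []
    if include_center:
        starts.append(np.log(np.array([free.values[n] for n in names])))
    n_lhs = max(0, n_starts - len(starts))
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        unit = sampler.random(n_lhs)
        starts.extend(log_lo + unit * (log_hi - log_lo))

    best_x, best_val, records = None, math.inf, []
    for i, x0 in enumerate(starts):
        # explicit initial simplex: +-20% parameter steps in log space
        # (the Nelder-Mead default scales with |x| and degenerates for
        # log-values near zero)
        simplex = np.tile(x0, (len(names) + 1, 1))
        for d in range(len(names)):
            simplex[d + 1, d] += 0.2
        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-4,
                                "fatol": 1e-8, "adaptive": True,
                                "initial_simplex": simplex})
        records.append({"start": i, "objective": float(res.fun)})
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
    if best_x is None or best_val > objective_ceiling:
        raise CalibrationFailedError(
            f"no start converged below ceiling {objective_ceiling} "
            f"(best {best_val:.4g})", diagnostics=records)

    best = to_fps(best_x)
    flats = (_flat_flags(best, anchors, config, base_params, best_val)
             if flag_flat else {n: False for n in names})
    report = pd.DataFrame([
        {"parameter": n,
         "lower": free.bounds[n][0], "upper": free.bounds[n][1],
         "start": free.values[n], "fitted": best.values[n],
         "flat": flats[n]}
        for n in names
    ])
    return CalibrationResult(parameters=best, objective_value=best_val,
                             report=report, n_evaluations=evals["n"],
                             starts=records)
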
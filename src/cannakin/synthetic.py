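"""Synthetic-data generators: the test bed for every other module.

Nothing in this package depends on downloads or deposited data; the
generators here produce (a) perturbed kinetic-parameter sets for
parameter-recovery experiments, (b) noisy pseudo-observed trajectories
(multiplicative lognormal noise — concentrations are positive, so additive
Gaussian noise would be the wrong error model), and (c) analytic
first-order toy chains whose closed-form (Bateman cascade) solution is the
independent oracle for the ODE integrator.

Every generator is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import math

import numpy as np

from .calibrate import FreeParameterSet
from .errors import InvalidArgumentError
from .model import PathwayModel, RateLaw, Reaction, Species
from .simulate import Trajectory

__all__ = [
    "PerturbationSpec",
    "perturbed_parameter_set",
    "noisy_trajectory",
    "toy_chain_model",
    "toy_chain_solution",
]

from dataclasses import dataclass, field


@dataclass
class PerturbationSpec:
    """Multiplicative lognormal parameter noise: sigma, seed, and subset."""

    sigma: float = 0.25
    seed: int = 0
    subset: tuple[str, ...] = ()  # empty = perturb every parameter

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidArgumentError(f"sigma must be >= 0, got {self.sigma}")


def perturbed_parameter_set(base: FreeParameterSet,
                            spec: PerturbationSpec) -> FreeParameterSet:
    """Multiply selected parameters by exp(N(0, sigma^2)) draws.

    Draws are taken in a fixed (sorted-name) order from a generator seeded
    with ``spec.seed``, so the output is reproducible.  Results are clipped
    into the declared bounds.
    """
    rng = np.random.default_rng(spec.seed)
    subset = set(spec.subset) if spec.subset else set(base.values)
    values = {}
    for name in sorted(base.values):
        v = base.values[name]
        if name in subset and spec.sigma > 0:
            v *= math.exp(rng.normal(0.0, spec.sigma))
        lo, hi = base.bounds[name]
        values[name] = min(max(v, lo), hi)
    return FreeParameterSet(values=values, bounds=dict(base.bounds))


def noisy_trajectory(traj: Trajectory, cv: float, seed: int = 0) -> Trajectory:
    """Pointwise multiplicative lognormal noise with coefficient of variation cv.

    For a lognormal factor with unit mean and coefficient of variation
    ``cv``, the log-scale parameters are sigma^2 = ln(1+cv^2) and
    mu = -sigma^2/2.  Negative concentrations are impossible by
    construction; cv=0 returns an identical copy.
    """
    if cv < 0:
        raise InvalidArgumentError(f"cv must be >= 0, got {cv}")
    conc = traj.conc.copy()
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = math.log1p(cv * cv)
        sigma = math.sqrt(sigma2)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=conc.shape)
        conc = conc * factors
    meta = dict(traj.meta)
    meta.update({"noise_cv": cv, "noise_seed": seed})
    return Trajectory(times=traj.times.copy(), species_ids=list(traj.species_ids),
                      conc=conc, ledger=traj.ledger, mw=dict(traj.mw), meta=meta)


def toy_chain_model(n: int, k: float, s0: float) -> PathwayModel:
    """Linear irreversible first-order chain S0 -> S1 -> ... -> Sn.

    All stages share the rate constant ``k`` (1/h); S0 starts at ``s0`` mM
    and everything else at zero.  The closed-form solution is the Erlang /
    Bateman cascade implemented in :func:`toy_chain_solution`; together they
    form the integrator's independent oracle.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if k <= 0:
        raise InvalidArgumentError(f"k must be > 0, got {k}")
    species = [Species(id=f"s{i}", name=f"stage {i}", compartment="cytosol",
                       initial_conc=s0 if i == 0 else 0.0, mw=100.0)
               for i in range(n + 1)]
    reactions = [
        Reaction(id=f"step{i}", enzyme=f"E{i}",
                 stoichiometry={f"s{i}": -1, f"s{i+1}": 1},
                 substrates=[f"s{i}"],
                 rate_law=RateLaw(kind="mass_action", k=k),
                 name=f"first-order conversion s{i} -> s{i+1}")
        for i in range(n)
    ]
    return PathwayModel(species=species, reactions=reactions, name=f"toy_chain_{n}")


def toy_chain_solution(n: int, k: float, s0: float, t) -> np.ndarray:
    """Closed-form concentrations of the equal-rate chain at times ``t``.

    Returns an array of shape ``(n+1, len(t))``:
    ``S_i(t) = s0 (kt)^i e^(-kt) / i!`` for the intermediate stages and
    ``S_n(t) = s0 (1 - e^(-kt) sum_(j<n) (kt)^j / j!)`` for the terminal sink.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    kt = k * t
    out = np.zeros((n + 1, t.size))
    decay = np.exp(-kt)
    for i in range(n):
        out[i] = s0 * kt ** i * decay / math.factorial(i)
    partial = sum(kt ** j / math.factorial(j) for j in range(n))
    out[n] = s0 * (1.0 - decay * partial)
    return out


@dataclass
class _FixtureSet:
    """Paths of one generated fixture bundle (see :func:`write_fixtures`)."""

    params: str
    trajectory: str
    toy_chain: str
    files: list[str] = field(default_factory=list)


def write_fixtures(out_dir, seed: int = 0, cv: float = 0.05) -> _FixtureSet:
    """Emit a fixture bundle in the same formats the main pipeline reads.

    Writes a perturbed free-parameter YAML, a noisy 10-h default trajectory
    CSV (+ metadata sidecar), and a toy-chain trajectory CSV.
    """
    import os

    from .calibrate import default_free_parameter_set
    from .pathway import build_default_model
    from .simulate import simulate, write_trajectory_csv

    os.makedirs(out_dir, exist_ok=True)
    fps = perturbed_parameter_set(default_free_parameter_set(),
                                  PerturbationSpec(sigma=0.25, seed=seed))
    p_params = os.path.join(out_dir, "perturbed_params.yaml")
    fps.to_yaml(p_params)

    traj = simulate(build_default_model(), t_end=10.0, dt_out=0.1)
    noisy = noisy_trajectory(traj, cv=cv, seed=seed)
    p_traj = os.path.join(out_dir, "noisy_trajectory.csv")
    write_trajectory_csv(noisy, p_traj)

    chain = toy_chain_model(n=3, k=1.0, s0=1.0)
    p_chain = os.path.join(out_dir, "toy_chain.csv")
    write_trajectory_csv(simulate(chain, t_end=5.0, dt_out=0.05), p_chain)
    return _FixtureSet(params=p_params, trajectory=p_traj, toy_chain=p_chain,
                       files=[p_params, p_traj, p_chain])
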
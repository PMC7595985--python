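"""Deterministic ODE integration of a pathway model and derived observables.

The state vector holds every non-ledger species (clamped boundary species
are carried at constant value) plus six cumulative cofactor counters (ATP
consumed, ATP produced, NADH net, NADPH net, CO2 released, H2O2 produced).
Integration uses a stiff-capable adaptive solver (LSODA) with tight default
tolerances; reported observables (depletion times, steady-state times) are
computed by linear interpolation on the output grid so that refining the
grid does not move them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (InvalidArgumentError, SolverError, StabilityError,
                     UndefinedYieldError, UnknownSpeciesError)
from .model import PathwayModel, validate_model
from .pathway import LedgerTotals

__all__ = [
    "Trajectory",
    "simulate",
    "depletion_time",
    "steady_state_time",
    "to_mass_conc",
    "yield_per_substrate",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

_NEG_TOL = 1e-6  # mM; excursions below -1e-6 abort as a stability error
_GUARD_EPS = 1e-4  # mM; half-point of the co-substrate depletion switch


@dataclass
class Trajectory:
    """Time-resolved result of one simulation.

    ``conc`` is species x time (mM) over the non-ledger species listed in
    ``species_ids``; ``ledger`` holds the six cumulative cofactor series;
    ``mw`` maps species to g/mol for unit conversions; ``meta`` records the
    solver settings and the hash of the model that produced the run.
    """

    times: np.ndarray
    species_ids: list[str]
    conc: np.ndarray
    ledger: LedgerTotals
    mw: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise UnknownSpeciesError(
                f"species {species_id!r} not in trajectory") from None

    def series(self, species_id: str) -> np.ndarray:
        return self.conc[self.index(species_id)]

    def at(self, species_id: str, t: float) -> float:
        """Linearly interpolated concentration at time ``t`` (h)."""
        return float(np.interp(t, self.times, self.series(species_id)))

    def final(self, species_id: str) -> float:
        return float(self.series(species_id)[-1])


def _compile_rhs(model: PathwayModel):
    """Build the ODE right-hand side and the output bookkeeping arrays."""
    dynamic = [sp for sp in model.species if not sp.is_ledger]
    idx = {sp.id: i for i, sp in enumerate(dynamic)}
    n = len(dynamic)
    clamped = np.array([sp.is_clamped for sp in dynamic])
    y0 = np.array([sp.initial_conc for sp in dynamic], dtype=float)

    ledger_ids = [sp.id for sp in model.species if sp.is_ledger]
    lidx = {sid: i for i, sid in enumerate(ledger_ids)}

    n_rx = len(model.reactions)
    # stoichiometry of dynamic species, reactions x species
    S = np.zeros((n_rx, n))
    # ledger counter coefficients, reactions x 6
    L = np.zeros((n_rx, 6))
    rate_specs = []
    for r, rx in enumerate(model.reactions):
        eff = rx.effective_stoichiometry()
        for sid, coef in eff.items():
            if sid in idx:
                S[r, idx[sid]] = coef
        d_atp = eff.get("atp", 0.0)
        L[r, 0] = max(-d_atp, 0.0)            # atp consumed
        L[r, 1] = max(d_atp, 0.0)             # atp produced
        L[r, 2] = eff.get("nadh", 0.0)        # nadh net
        L[r, 3] = eff.get("nadph", 0.0)       # nadph net
        L[r, 4] = eff.get("co2", 0.0)         # co2 released (net)
        L[r, 5] = eff.get("h2o2", 0.0)        # h2o2 produced

        law = rx.rate_law
        sub_idx = tuple(idx[s] for s in rx.substrates)
        reg = None
        if law.regulation is not None:
            rg = law.regulation
            reg = (idx[rg.species], rg.k_half, rg.hill_n, rg.mode)
        rev_idx = ()
        if law.kind == "mass_action" and law.k_rev:
            rev_idx = tuple(idx[sid] for sid, c in rx.stoichiometry.items()
                            if c > 0 and sid in idx)
        # consumed co-substrates absent from the rate law (e.g. the second
        # acetyl-CoA of the HMG-CoA synthase step) get a smooth depletion
        # switch so starved scenarios cannot push a pool negative
        guard_idx = tuple(
            idx[sid] for sid, c in eff.items()
            if c < 0 and sid in idx and idx[sid] not in sub_idx
            and not dynamic[idx[sid]].is_clamped)
        rate_specs.append((law.kind, law, sub_idx, rev_idx, reg, guard_idx))

    S_dyn = S.copy()
    S_dyn[:, clamped] = 0.0  # boundary species stay constant
    ST = S_dyn.T
    LT = L.T

    def rates(y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        v = np.empty(n_rx)
        for r, (kind, law, sub, rev, reg, guard) in enumerate(rate_specs):
            if kind == "michaelis_menten":
                s = yc[sub[0]]
                val = law.vmax * s / (law.km_a + s)
            elif kind == "ordered_bibi":
                a, b = yc[sub[0]], yc[sub[1]]
                val = law.vmax * a * b / (
                    law.ki_a * law.km_b + law.km_b * a + law.km_a * b + a * b)
            elif kind == "mass_action":
                val = law.k
                for i in sub:
                    val *= yc[i]
                if rev:
                    back = law.k_rev
                    for i in rev:
                        back *= yc[i]
                    val -= back
            elif kind == "diffusion":
                val = law.k * (y[sub[0]] - y[sub[1]])
            else:  # zero_order_feed
                val = law.k
            if reg is not None:
                ri, kh, hn, mode = reg
                m = yc[ri] ** hn
                kn = kh ** hn
                val *= m / (kn + m) if mode == "activate" else kn / (kn + m)
            for gi in guard:
                s = yc[gi]
                val *= s / (s + _GUARD_EPS)
            v[r] = val
        return v

    def rhs(t: float, state: np.ndarray) -> np.ndarray:
        v = rates(state[:n])
        return np.concatenate((ST @ v, LT @ v))

    return rhs, rates, y0, [sp.id for sp in dynamic], ledger_ids, lidx, n


def simulate(model: PathwayModel, t_end: float = 40.0, dt_out: float = 0.05,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model from its initial state to ``t_end`` hours.

    Raises :class:`SolverError` on integration failure (carrying the last
    good time) and :class:`StabilityError` if any concentration dips below
    -1e-6 mM.  Reported concentrations are clipped into [0, inf) at 1e-9
    resolution.
    """
    if t_end <= 0:
        raise InvalidArgumentError(f"t_end must be > 0, got {t_end}")
    findings = validate_model(model)
    if findings:
        raise InvalidArgumentError(f"model fails validation: {findings[:3]}")

    rhs, _, y0, species_ids, _, _, n = _compile_rhs(model)
    state0 = np.concatenate((y0, np.zeros(6)))
    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)
    if t_eval[-1] > t_end:
        t_eval = t_eval[:-1]
    if not math.isclose(t_eval[-1], t_end):
        t_eval = np.append(t_eval, t_end)

    sol = solve_ivp(rhs, (0.0, t_end), state0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SolverError(f"integration failed: {sol.message}", last_time=last)

    conc = sol.y[:n]
    worst = conc.min()
    if worst < -_NEG_TOL:
        bad = species_ids[int(np.argwhere(conc == worst)[0][0])]
        raise StabilityError(
            f"negative-concentration excursion {worst:.3e} mM in {bad!r}",
            last_time=float(sol.t[-1]))
    conc = np.clip(conc, 0.0, None)

    ledger = LedgerTotals(**{f: sol.y[n + i] for i, f in enumerate(LedgerTotals.FIELDS)})
    mw = {sp.id: sp.mw for sp in model.species}
    meta = {
        "model_hash": model.content_hash(),
        "solver": method,
        "rtol": rtol,
        "atol": atol,
        "dt_out": dt_out,
        "t_end": t_end,
    }
    return Trajectory(times=sol.t, species_ids=species_ids, conc=conc,
                      ledger=ledger, mw=mw, meta=meta)


def depletion_time(traj: Trajectory, species_id: str,
                   threshold: float = 0.1) -> float:
    """First time the species crosses below ``threshold`` mM.

    Linear interpolation between grid points; ``inf`` if the species never
    crosses.
    """
    if threshold < 0:
        raise InvalidArgumentError(f"threshold must be >= 0, got {threshold}")
    s = traj.series(species_id)
    t = traj.times
    if s[0] < threshold:
        return 0.0
    below = np.nonzero(s < threshold)[0]
    if below.size == 0:
        return math.inf
    j = int(below[0])
    t0, t1, s0, s1 = t[j - 1], t[j], s[j - 1], s[j]
    if s1 == s0:
        return float(t1)
    return float(t0 + (s0 - threshold) * (t1 - t0) / (s0 - s1))


def steady_state_time(traj: Trajectory, species_id: str,
                      rel_rate_tol: float = 0.01) -> float:
    """Earliest time after which |d[s]/dt| / max([s], eps) stays below tol.

    ``rel_rate_tol`` is a fractional rate per hour (default 1 %/h); eps is
    1e-6 mM.  Clamped/constant series return 0; ``inf`` if the criterion is
    never met through the end of the run.
    """
    if rel_rate_tol <= 0:
        raise InvalidArgumentError(f"rel_rate_tol must be > 0, got {rel_rate_tol}")
    s = traj.series(species_id)
    t = traj.times
    eps = 1e-6
    rel = np.abs(np.gradient(s, t)) / np.maximum(s, eps)
    ok = rel < rel_rate_tol
    if not ok[-1]:
        return math.inf
    # last index where criterion fails; steady from the next grid point on
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return 0.0
    return float(t[bad[-1] + 1])


def to_mass_conc(c: float, species_id: str, mw: dict[str, float] | None = None,
                 model: PathwayModel | None = None) -> float:
    """Convert mM to mg/L using the species' molecular weight.

    Provide either a ``mw`` map (e.g. ``traj.mw``) or a model to look it up.
    """
    if mw is None:
        if model is None:
            raise UnknownSpeciesError("need a mw map or a model to convert units")
        mw = {sp.id: sp.mw for sp in model.species}
    if species_id not in mw:
        raise UnknownSpeciesError(f"no molecular weight for {species_id!r}")
    return c * mw[species_id]


def yield_per_substrate(traj: Trajectory, product: str = "thca",
                        substrate: str = "glc_ex") -> float:
    """Mass yield (g product per g substrate consumed) over the whole run."""
    for sid in (product, substrate):
        if sid not in traj.mw:
            raise UnknownSpeciesError(f"no molecular weight for {sid!r}")
    prod_mass = (traj.final(product) - traj.series(product)[0]) * traj.mw[product]
    sub_series = traj.series(substrate)
    consumed = (sub_series[0] - sub_series[-1]) * traj.mw[substrate]
    if consumed <= 0:
        raise UndefinedYieldError(
            f"no {substrate!r} was consumed; yield undefined")
    return prod_mass / consumed


def write_trajectory_csv(traj: Trajectory, path, meta_path=None) -> None:
    """Write ``time_h,<species>...`` CSV plus ledger columns; 12 sig digits.

    A sidecar YAML metadata file is written next to the CSV (or at
    ``meta_path``) carrying solver settings and the model hash.
    """
    import yaml

    header = ["time_h"] + traj.species_ids + [f"ledger_{f}" for f in LedgerTotals.FIELDS]
    cols = [traj.times] + [traj.conc[i] for i in range(len(traj.species_ids))] + \
           [np.asarray(getattr(traj.ledger, f), dtype=float) for f in LedgerTotals.FIELDS]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in zip(*cols):
            fh.write(",".join(f"{x:.12g}" for x in row) + "\n")
    mp = meta_path if meta_path is not None else str(path) + ".meta.yaml"
    with open(mp, "w") as fh:
        yaml.safe_dump({"meta": traj.meta, "mw": traj.mw}, fh, sort_keys=True)


def read_trajectory_csv(path, meta_path=None) -> Trajectory:
    """Inverse of :func:`write_trajectory_csv` (lossless at 12 sig digits)."""
    import yaml

    data = np.genfromtxt(path, delimiter=",", names=True)
    names = list(data.dtype.names)
    times = np.asarray(data["time_h"], dtype=float)
    ledger_fields = [n for n in names if n.startswith("ledger_")]
    species_ids = [n for n in names if n != "time_h" and not n.startswith("ledger_")]
    conc = np.vstack([np.asarray(data[s], dtype=float) for s in species_ids])
    ledger = LedgerTotals(**{f.removeprefix("ledger_"): np.asarray(data[f], dtype=float)
                             for f in ledger_fields})
    mp = meta_path if meta_path is not None else str(path) + ".meta.yaml"
    meta, mw = {}, {}
    try:
        with open(mp) as fh:
            side = yaml.safe_load(fh) or {}
        meta = side.get("meta", {})
        mw = side.get("mw", {})
    except FileNotFoundError:
        pass
    return Trajectory(times=times, species_ids=species_ids, conc=conc,
                      ledger=ledger, mw=mw, meta=meta)
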
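"""Product-sensitivity analysis: THCA response to intermediate boluses.

The question mirrors the bottleneck hunt of the underlying study: which
pathway intermediate, if the cell had more of it, would raise the final
THCA titer most?  Every intermediate starts the batch at 0 mM, so a
relative perturbation is undefined; the perturbation is therefore a t=0
concentration bolus (default 0.05 mM), and the score is the THCA endpoint
gain normalized by the bolus — a dimensionless transfer coefficient:

    score_i = [THCA_i(t_end) - THCA_base(t_end)] / bolus

A score near 1 means the extra material is converted essentially
quantitatively (CBGA behaves this way: its only sink is THCA synthase); a
score near 0 means the intermediate is not limiting or has no path to the
product.  An optional time-integrated variant averages the normalized gain
over the whole output grid instead of taking the endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UnknownSpeciesError
from .model import PathwayModel
from .simulate import Trajectory, simulate

__all__ = [
    "DEFAULT_SENSITIVITY_INPUTS",
    "SensitivityResult",
    "product_sensitivity",
    "sensitivity_oracle",
    "sensitivity_table",
]

#: The seven intermediates from the mevalonate and olivetolic-acid pathways
#: scored by default; a caller-chosen extra input can be appended freely.
DEFAULT_SENSITIVITY_INPUTS: tuple[str, ...] = (
    "accoa_c", "cbga", "oa", "gpp", "ipp", "dmapp", "mva",
)


@dataclass
class SensitivityResult:
    """Scores and descending ranking of one sensitivity analysis."""

    inputs: list[str]
    scores: dict[str, float]
    ranking: list[str]
    settings: dict = field(default_factory=dict)
    baseline: float = 0.0


def _bumped(model: PathwayModel, species_id: str, delta: float) -> PathwayModel:
    m = model.copy()
    sp = m.get_species(species_id)
    if sp.initial_conc + delta < 0:
        raise InvalidArgumentError(
            f"bolus would make {species_id} initial concentration negative")
    sp.initial_conc += delta
    return m


def product_sensitivity(model: PathwayModel,
                        inputs: tuple[str, ...] | list[str] | None = None,
                        output: str = "thca",
                        bolus: float = 0.05,
                        t_end: float = 40.0,
                        time_integrated: bool = False,
                        dt_out: float = 0.1,
                        rtol: float = 1e-8, atol: float = 1e-10,
                        ) -> SensitivityResult:
    """Forward-difference bolus sensitivity of the product for each input."""
    if bolus <= 0:
        raise InvalidArgumentError(f"bolus must be > 0, got {bolus}")
    if inputs is None:
        inputs = DEFAULT_SENSITIVITY_INPUTS
    spmap = model.species_map()
    for sid in list(inputs) + [output]:
        if sid not in spmap:
            raise UnknownSpeciesError(f"species {sid!r} not in model")

    base = simulate(model, t_end=t_end, dt_out=dt_out, rtol=rtol, atol=atol)

    def response(traj: Trajectory) -> float:
        gain = traj.series(output) - base.series(output)
        if time_integrated:
            return float(np.mean(gain)) / bolus
        return float(gain[-1]) / bolus

    scores = {}
    for sid in inputs:
        traj = simulate(_bumped(model, sid, bolus), t_end=t_end, dt_out=dt_out,
                        rtol=rtol, atol=atol)
        scores[sid] = response(traj)
    ranking = sorted(scores, key=lambda s: scores[s], reverse=True)
    return SensitivityResult(
        inputs=list(inputs), scores=scores, ranking=ranking,
        settings={"bolus": bolus, "t_end": t_end, "output": output,
                  "norm": "time_integrated" if time_integrated else "endpoint"},
        baseline=base.final(output))


def sensitivity_oracle(model: PathwayModel, input_species: str,
                       bolus: float = 0.05, t_end: float = 40.0,
                       output: str = "thca",
                       dt_out: float = 0.1,
                       rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Independent finite-difference check of one sensitivity score.

    Central difference of half-width bolus/2.  Because intermediates start
    at 0 mM, a symmetric stencil about the base would need a negative
    initial concentration; in that case the center is shifted to bolus/2 so
    the two evaluations sit at the base and at base+bolus.  The model is
    rebuilt from its serialized form so the check does not share mutable
    state with :func:`product_sensitivity`.
    """
    if bolus <= 0:
        raise InvalidArgumentError(f"bolus must be > 0, got {bolus}")
    fresh = PathwayModel.from_dict(model.to_dict())
    base_init = fresh.get_species(input_species).initial_conc
    half = bolus / 2.0
    lo_delta = -half if base_init >= half else 0.0
    hi_delta = lo_delta + bolus
    lo = simulate(_bumped(fresh, input_species, lo_delta), t_end=t_end,
                  dt_out=dt_out, rtol=rtol, atol=atol)
    hi = simulate(_bumped(fresh, input_species, hi_delta), t_end=t_end,
                  dt_out=dt_out, rtol=rtol, atol=atol)
    return (hi.final(output) - lo.final(output)) / bolus


def sensitivity_table(result: SensitivityResult) -> pd.DataFrame:
    """Ranked TSV-ready table: species, score, rank."""
    return pd.DataFrame([
        {"species": sid, "score": result.scores[sid], "rank": i + 1}
        for i, sid in enumerate(result.ranking)
    ])


def plot_sensitivity(result: SensitivityResult, ax=None):
    """Optional bar-chart rendering (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    table = sensitivity_table(result)
    ax.bar(table["species"], table["score"], color="#3b7a57")
    ax.set_ylabel("THCA gain per mM bolus")
    ax.set_title(f"product sensitivity ({result.settings.get('norm', 'endpoint')})")
    ax.tick_params(axis="x", rotation=45)
    return ax
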
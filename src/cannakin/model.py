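"""Model data structures: species, reactions, variants, and the pathway model.

A :class:`PathwayModel` is the complete in-silico cell: a list of
:class:`Species` (medium, cytosol, mitochondrion, plus bookkeeping "ledger"
species for cofactors), a list of :class:`Reaction` objects each carrying a
:class:`RateLaw`, and the named enzyme variants that have been applied to it.

Ledger species (ATP, NADH, NADPH, CO2, H2O2) record cumulative cofactor
usage.  They appear in reaction stoichiometries but never in a rate-law
denominator: they are integrated for reporting and impose no kinetic
limitation, mirroring a model in which energy supply is tracked but never
caps pathway activity.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from . import ratelaws
from .errors import InvalidArgumentError, UnknownEnzymeError

__all__ = [
    "Species",
    "Regulation",
    "RateLaw",
    "Branch",
    "Reaction",
    "EnzymeVariant",
    "PathwayModel",
    "apply_variant",
    "validate_model",
    "COMPARTMENTS",
    "RATE_LAW_KINDS",
    "LEDGER_COMPARTMENT",
]

COMPARTMENTS = ("medium", "cytosol", "mitochondrion", "ledger")
LEDGER_COMPARTMENT = "ledger"
RATE_LAW_KINDS = (
    "michaelis_menten",
    "ordered_bibi",
    "mass_action",
    "diffusion",
    "zero_order_feed",
)

# substrate-list arity each rate-law kind expects
_ARITY = {
    "michaelis_menten": (1, 1),
    "ordered_bibi": (2, 2),
    "mass_action": (1, 2),
    "diffusion": (2, 2),
    "zero_order_feed": (0, 0),
}


@dataclass
class Species:
    """One chemical species.

    ``initial_conc`` is mM; ``mw`` g/mol.  ``is_clamped`` marks a
    constant-concentration boundary species (e.g. the extracellular
    hexanoic-acid feed held at 1 mM).
    """

    id: str
    name: str
    compartment: str
    initial_conc: float = 0.0
    mw: float = 1.0
    is_clamped: bool = False

    @property
    def is_ledger(self) -> bool:
        return self.compartment == LEDGER_COMPARTMENT


@dataclass
class Regulation:
    """Multiplicative Hill regulation of a reaction's vmax by one species."""

    species: str
    k_half: float
    hill_n: float = 2.0
    mode: str = "repress"  # or "activate"


@dataclass
class RateLaw:
    """Kinetic law of one reaction; fields used depend on ``kind``.

    michaelis_menten: vmax, km_a          (substrates: [s])
    ordered_bibi:     vmax, km_a, km_b, ki_a   (substrates: [a, b])
    mass_action:      k, optionally k_rev (substrates: 1-2; reverse uses
                      the reaction's non-ledger products)
    diffusion:        k                   (substrates: [outside, inside])
    zero_order_feed:  k (mM/h)            (substrates: [])
    """

    kind: str
    vmax: float = 0.0
    km_a: float = 0.0
    km_b: float = 0.0
    ki_a: float = 0.0
    k: float = 0.0
    k_rev: float = 0.0
    regulation: Optional[Regulation] = None


@dataclass
class Branch:
    """One product set of a branched reaction with its molar fraction."""

    label: str
    fraction: float
    products: dict[str, float] = field(default_factory=dict)


@dataclass
class Reaction:
    """One reaction: stoichiometry, ordered substrate list, rate law.

    ``stoichiometry`` holds the shared part (consumption and unbranched
    products, ledger deltas included) as signed coefficients.  Branched
    reactions additionally carry ``branches``; the effective stoichiometry is
    ``stoichiometry + sum(fraction * branch.products)``, which makes the
    branch ratio exact by construction at every instant.
    """

    id: str
    enzyme: str
    stoichiometry: dict[str, float]
    substrates: list[str]
    rate_law: RateLaw
    branches: list[Branch] = field(default_factory=list)
    name: str = ""

    def effective_stoichiometry(self) -> dict[str, float]:
        eff = dict(self.stoichiometry)
        for br in self.branches:
            for sp, coef in br.products.items():
                eff[sp] = eff.get(sp, 0.0) + br.fraction * coef
        return eff


@dataclass
class EnzymeVariant:
    """A named enzyme engineering intervention as a fold-change on vmax."""

    enzyme: str
    label: str
    activity_multiplier: float
    provenance: str = ""


@dataclass
class PathwayModel:
    """The complete in-silico cell."""

    species: list[Species]
    reactions: list[Reaction]
    variants_applied: list[EnzymeVariant] = field(default_factory=list)
    constants: dict[str, float] = field(default_factory=dict)
    name: str = "pathway_model"

    # -- lookups ---------------------------------------------------------
    def species_map(self) -> dict[str, Species]:
        return {sp.id: sp for sp in self.species}

    def get_species(self, species_id: str) -> Species:
        for sp in self.species:
            if sp.id == species_id:
                return sp
        raise UnknownEnzymeError(f"no species with id {species_id!r}")

    def get_reaction(self, reaction_id: str) -> Reaction:
        for rx in self.reactions:
            if rx.id == reaction_id:
                return rx
        raise UnknownEnzymeError(f"no reaction with id {reaction_id!r}")

    def reactions_by_enzyme(self, enzyme: str) -> list[Reaction]:
        return [rx for rx in self.reactions if rx.enzyme == enzyme]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayModel":
        species = [Species(**s) for s in d["species"]]
        reactions = []
        for r in d["reactions"]:
            law = dict(r["rate_law"])
            reg = law.pop("regulation", None)
            rate_law = RateLaw(**law)
            if reg:
                rate_law.regulation = Regulation(**reg)
            reactions.append(
                Reaction(
                    id=r["id"],
                    enzyme=r["enzyme"],
                    stoichiometry=dict(r["stoichiometry"]),
                    substrates=list(r["substrates"]),
                    rate_law=rate_law,
                    branches=[Branch(**b) for b in r.get("branches", [])],
                    name=r.get("name", ""),
                )
            )
        variants = [EnzymeVariant(**v) for v in d.get("variants_applied", [])]
        return cls(
            species=species,
            reactions=reactions,
            variants_applied=variants,
            constants=dict(d.get("constants", {})),
            name=d.get("name", "pathway_model"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PathwayModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Stable hash of the model definition (provenance for outputs).

        Numeric leaves are canonicalized to float first so that an exact
        round trip through a format that widens integers (YAML, SBML)
        hashes identically.
        """
        def norm(obj):
            if isinstance(obj, bool):
                return obj
            if isinstance(obj, (int, float)):
                return float(obj)
            if isinstance(obj, dict):
                return {k: norm(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [norm(v) for v in obj]
            return obj

        blob = json.dumps(norm(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def copy(self) -> "PathwayModel":
        return copy.deepcopy(self)


def apply_variant(model: PathwayModel, variant: EnzymeVariant,
                  in_place: bool = False) -> PathwayModel:
    """Scale the vmax (or mass-action k) of the variant's enzyme.

    Variants compose multiplicatively on the same enzyme and commute across
    distinct enzymes.  A multiplier of 1.0 leaves the kinetics unchanged but
    is still recorded in ``variants_applied``.
    """
    if variant.activity_multiplier <= 0:
        raise InvalidArgumentError(
            f"activity_multiplier must be > 0, got {variant.activity_multiplier!r}")
    target = model if in_place else model.copy()
    hits = target.reactions_by_enzyme(variant.enzyme)
    if not hits:
        raise UnknownEnzymeError(
            f"variant {variant.label!r} targets unknown enzyme {variant.enzyme!r}")
    for rx in hits:
        law = rx.rate_law
        if law.kind in ("michaelis_menten", "ordered_bibi"):
            law.vmax *= variant.activity_multiplier
        else:
            law.k *= variant.activity_multiplier
            law.k_rev *= variant.activity_multiplier
    target.variants_applied.append(variant)
    return target


def _validate_species(sp: Species, findings: list[str]) -> None:
    if sp.compartment not in COMPARTMENTS:
        findings.append(f"species {sp.id}: unknown compartment {sp.compartment!r}")
    if sp.mw <= 0:
        findings.append(f"species {sp.id}: mw must be > 0 (got {sp.mw})")
    if sp.initial_conc < 0:
        findings.append(f"species {sp.id}: negative initial concentration")


def _validate_rate_law(rx: Reaction, findings: list[str]) -> None:
    law = rx.rate_law
    if law.kind not in RATE_LAW_KINDS:
        findings.append(f"reaction {rx.id}: unknown rate-law kind {law.kind!r}")
        return
    lo, hi = _ARITY[law.kind]
    if not (lo <= len(rx.substrates) <= hi):
        findings.append(
            f"reaction {rx.id}: rate law {law.kind} expects between {lo} and "
            f"{hi} ordered substrates, got {len(rx.substrates)}")
    for name in ("vmax", "km_a", "km_b", "ki_a", "k", "k_rev"):
        if getattr(law, name) < 0:
            findings.append(f"reaction {rx.id}: kinetic constant {name} is negative")
    if law.kind == "michaelis_menten" and law.km_a <= 0:
        findings.append(f"reaction {rx.id}: michaelis_menten needs km_a > 0")
    if law.kind == "ordered_bibi":
        for name in ("km_a", "km_b", "ki_a"):
            if getattr(law, name) <= 0:
                findings.append(f"reaction {rx.id}: ordered_bibi needs {name} > 0")
    reg = law.regulation
    if reg is not None:
        if reg.hill_n < 1:
            findings.append(f"reaction {rx.id}: regulation hill_n must be >= 1")
        if reg.k_half <= 0:
            findings.append(f"reaction {rx.id}: regulation k_half must be > 0")
        if reg.mode not in ("repress", "activate"):
            findings.append(f"reaction {rx.id}: regulation mode {reg.mode!r}")


def validate_model(model: PathwayModel) -> list[str]:
    """Structural validation; returns a list of human-readable findings.

    An empty list means every invariant holds: unique species ids, known
    compartments, positive molecular weights, stoichiometries referencing
    known species, branch fractions summing to one, rate-law arities
    matching their ordered substrate lists, and no ledger species appearing
    in any rate law (ledger species record usage, they never limit rates).
    """
    findings: list[str] = []
    ids = [sp.id for sp in model.species]
    seen = set()
    for sid in ids:
        if sid in seen:
            findings.append(f"duplicate species id {sid!r}")
        seen.add(sid)
    spmap = model.species_map()
    for sp in model.species:
        _validate_species(sp, findings)

    rids = set()
    for rx in model.reactions:
        if rx.id in rids:
            findings.append(f"duplicate reaction id {rx.id!r}")
        rids.add(rx.id)
        for sid in rx.effective_stoichiometry():
            if sid not in spmap:
                findings.append(f"reaction {rx.id}: unknown species {sid!r} in stoichiometry")
        if rx.branches:
            total = sum(br.fraction for br in rx.branches)
            if abs(total - 1.0) > 1e-12:
                findings.append(
                    f"reaction {rx.id}: branch fractions sum to {total!r}, not 1")
            for br in rx.branches:
                if br.fraction < 0:
                    findings.append(f"reaction {rx.id}: negative branch fraction {br.label}")
        for sid in rx.substrates:
            if sid not in spmap:
                findings.append(f"reaction {rx.id}: unknown substrate {sid!r}")
            elif spmap[sid].is_ledger:
                findings.append(
                    f"reaction {rx.id}: ledger species {sid!r} used in a rate law")
        reg = rx.rate_law.regulation
        if reg is not None and reg.species in spmap and spmap[reg.species].is_ledger:
            findings.append(
                f"reaction {rx.id}: ledger species {reg.species!r} used as regulator")
        _validate_rate_law(rx, findings)
    return findings


def evaluate_rate(rx: Reaction, conc: dict[str, float]) -> float:
    """Evaluate one reaction's rate (mM/h) at the given concentrations.

    Reference implementation used by validation tests and post-hoc flux
    integration; the ODE right-hand side uses a compiled equivalent.
    """
    law = rx.rate_law
    subs = [max(conc[s], 0.0) for s in rx.substrates]
    if law.kind == "michaelis_menten":
        v = ratelaws.mm_rate(law.vmax, law.km_a, subs[0])
    elif law.kind == "ordered_bibi":
        v = ratelaws.bibi_rate(law.vmax, law.km_a, law.km_b, law.ki_a, subs[0], subs[1])
    elif law.kind == "mass_action":
        prods = tuple(
            max(conc[sid], 0.0)
            for sid, coef in rx.stoichiometry.items()
            if coef > 0 and sid in conc
        ) if law.k_rev else ()
        v = ratelaws.mass_action_rate(law.k, tuple(subs), law.k_rev, prods)
    elif law.kind == "diffusion":
        v = ratelaws.diffusion_rate(law.k, conc[rx.substrates[0]], conc[rx.substrates[1]])
    elif law.kind == "zero_order_feed":
        v = ratelaws.zero_order_rate(law.k)
    else:  # pragma: no cover - guarded by validate_model
        raise InvalidArgumentError(f"unknown rate law kind {law.kind!r}")
    reg = law.regulation
    if reg is not None:
        v *= ratelaws.hill_factor(max(conc[reg.species], 0.0), reg.k_half, reg.hill_n, reg.mode)
    # smooth depletion switch on consumed co-substrates absent from the law
    for sid, coef in rx.effective_stoichiometry().items():
        if coef < 0 and sid in conc and sid not in rx.substrates:
            s = max(conc[sid], 0.0)
            v *= s / (s + 1e-4)
    return v
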
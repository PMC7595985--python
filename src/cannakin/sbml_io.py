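"""SBML Level 3 import/export of pathway models.

Export writes a standards-valid SBML L3 core document: compartments,
species with initial concentrations (clamped feeds flagged as boundary
species), and reactions with explicit kinetic-law math and local
parameters.  Because SBML core has no notion of this package's structured
rate-law kinds (ordered substrate lists, Hill regulation factors, branch
fractions), each element additionally carries a namespaced annotation with
a JSON payload that preserves the exact definition; import prefers that
payload and falls back to recognizing the kinetic-law parameter signature
for documents produced elsewhere.  Unknown kinetic-law forms are rejected
with :class:`UnsupportedRateLawError`.
"""

from __future__ import annotations

import json

import libsbml

from .errors import SBMLReadError, UnsupportedRateLawError
from .model import (Branch, PathwayModel, RateLaw, Reaction, Regulation,
                    Species, validate_model)

__all__ = ["export_sbml", "import_sbml", "sbml_string"]

_NS = "https://cannakin.readthedocs.io/ns/sbml"
_COMPARTMENTS = ("medium", "cytosol", "mitochondrion", "ledger")


def _annotation(payload: dict) -> str:
    body = json.dumps(payload, sort_keys=True).replace("&", "&amp;").replace("<", "&lt;")
    return f'<cannakin:payload xmlns:cannakin="{_NS}">{body}</cannakin:payload>'


def _read_payload(element) -> dict | None:
    node = element.getAnnotation()
    if node is None:
        return None
    for i in range(node.getNumChildren()):
        child = node.getChild(i)
        if child.getName() == "payload":
            text = child.getChild(0).getCharacters() if child.getNumChildren() else ""
            if text:
                return json.loads(text)
    return None


def _kinetic_formula(rx: Reaction) -> str:
    law = rx.rate_law
    subs = rx.substrates
    if law.kind == "michaelis_menten":
        s = subs[0]
        expr = f"vmax * {s} / (km_a + {s})"
    elif law.kind == "ordered_bibi":
        a, b = subs
        expr = (f"vmax * {a} * {b} / "
                f"(ki_a * km_b + km_b * {a} + km_a * {b} + {a} * {b})")
    elif law.kind == "mass_action":
        expr = "k * " + " * ".join(subs)
        if law.k_rev:
            prods = [sid for sid, c in rx.stoichiometry.items() if c > 0]
            expr += " - k_rev * " + " * ".join(prods)
    elif law.kind == "diffusion":
        out_s, in_s = subs
        expr = f"k * ({out_s} - {in_s})"
    else:  # zero_order_feed
        expr = "k"
    reg = law.regulation
    if reg is not None:
        m, kh, n = reg.species, "reg_k", "reg_n"
        if reg.mode == "activate":
            expr = f"({expr}) * {m}^{n} / ({kh}^{n} + {m}^{n})"
        else:
            expr = f"({expr}) * {kh}^{n} / ({kh}^{n} + {m}^{n})"
    return expr


def _local_params(law: RateLaw) -> dict[str, float]:
    out = {}
    if law.kind == "michaelis_menten":
        out = {"vmax": law.vmax, "km_a": law.km_a}
    elif law.kind == "ordered_bibi":
        out = {"vmax": law.vmax, "km_a": law.km_a, "km_b": law.km_b,
               "ki_a": law.ki_a}
    else:
        out = {"k": law.k}
        if law.k_rev:
            out["k_rev"] = law.k_rev
    if law.regulation is not None:
        out["reg_k"] = law.regulation.k_half
        out["reg_n"] = law.regulation.hill_n
    return out


def sbml_string(model: PathwayModel) -> str:
    """Serialize the model to an SBML L3V2 core document string."""
    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel()
    m.setId(model.name or "pathway_model")
    m.setAnnotation(_annotation({
        "constants": model.constants,
        "variants_applied": [
            {"enzyme": v.enzyme, "label": v.label,
             "activity_multiplier": v.activity_multiplier,
             "provenance": v.provenance}
            for v in model.variants_applied],
    }))

    used = {sp.compartment for sp in model.species}
    for comp in _COMPARTMENTS:
        if comp not in used:
            continue
        c = m.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        c.setSize(1.0)
        c.setSpatialDimensions(3)

    for sp in model.species:
        s = m.createSpecies()
        s.setId(sp.id)
        s.setName(sp.name)
        s.setCompartment(sp.compartment)
        s.setInitialConcentration(sp.initial_conc)
        s.setBoundaryCondition(bool(sp.is_clamped))
        s.setConstant(bool(sp.is_clamped))
        s.setHasOnlySubstanceUnits(False)
        s.setAnnotation(_annotation({"mw": sp.mw, "is_clamped": sp.is_clamped}))

    for rx in model.reactions:
        r = m.createReaction()
        r.setId(rx.id)
        if rx.name:
            r.setName(rx.name)
        r.setReversible(rx.rate_law.kind in ("mass_action", "diffusion")
                        and (rx.rate_law.k_rev > 0 or rx.rate_law.kind == "diffusion"))
        eff = rx.effective_stoichiometry()
        for sid in sorted(eff):
            coef = eff[sid]
            if coef == 0:
                continue
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        if rx.rate_law.regulation is not None:
            mod = r.createModifier()
            mod.setSpecies(rx.rate_law.regulation.species)
        kl = r.createKineticLaw()
        math_ast = libsbml.parseL3Formula(_kinetic_formula(rx))
        if math_ast is None:  # pragma: no cover - formulas are well-formed
            raise SBMLReadError(f"could not build kinetic law for {rx.id}")
        kl.setMath(math_ast)
        for pname, pval in _local_params(rx.rate_law).items():
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(float(pval))
        payload = {
            "enzyme": rx.enzyme,
            "stoichiometry": {k: float(v) for k, v in rx.stoichiometry.items()},
            "substrates": rx.substrates,
            "rate_law": {
                "kind": rx.rate_law.kind, "vmax": rx.rate_law.vmax,
                "km_a": rx.rate_law.km_a, "km_b": rx.rate_law.km_b,
                "ki_a": rx.rate_law.ki_a, "k": rx.rate_law.k,
                "k_rev": rx.rate_law.k_rev,
                "regulation": (
                    {"species": rx.rate_law.regulation.species,
                     "k_half": rx.rate_law.regulation.k_half,
                     "hill_n": rx.rate_law.regulation.hill_n,
                     "mode": rx.rate_law.regulation.mode}
                    if rx.rate_law.regulation else None),
            },
            "branches": [{"label": b.label, "fraction": float(b.fraction),
                          "products": {k: float(v) for k, v in b.products.items()}}
                         for b in rx.branches],
        }
        r.setAnnotation(_annotation(payload))

    return libsbml.writeSBMLToString(doc)


def export_sbml(model: PathwayModel, path) -> str:
    """Write the model as SBML L3 to ``path``; returns the path."""
    text = sbml_string(model)
    with open(path, "w") as fh:
        fh.write(text)
    return str(path)


def _law_from_locals(kl, substrates: list[str]) -> RateLaw:
    """Fallback reconstruction from local-parameter signatures."""
    names = {kl.getLocalParameter(i).getId(): kl.getLocalParameter(i).getValue()
             for i in range(kl.getNumLocalParameters())}
    if {"vmax", "km_a", "km_b", "ki_a"} <= set(names):
        return RateLaw(kind="ordered_bibi", vmax=names["vmax"],
                       km_a=names["km_a"], km_b=names["km_b"], ki_a=names["ki_a"])
    if {"vmax", "km_a"} <= set(names):
        return RateLaw(kind="michaelis_menten", vmax=names["vmax"],
                       km_a=names["km_a"])
    if "k" in names and len(substrates) == 2 and "k_rev" not in names:
        return RateLaw(kind="mass_action", k=names["k"])
    if "k" in names:
        return RateLaw(kind="mass_action", k=names["k"],
                       k_rev=names.get("k_rev", 0.0))
    raise UnsupportedRateLawError(
        f"unrecognized kinetic-law parameterization: {sorted(names)}")


def import_sbml(path) -> PathwayModel:
    """Read an SBML L3 document back into a :class:`PathwayModel`.

    Documents written by :func:`export_sbml` round-trip exactly (including
    branch structure and regulation, via the embedded payloads).  Foreign
    documents are accepted when their kinetic laws match one of the modeled
    forms; anything else raises :class:`UnsupportedRateLawError`.
    """
    reader = libsbml.SBMLReader()
    doc = reader.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())]
        raise SBMLReadError(f"SBML parse errors: {msgs[:3]}")
    doc.checkConsistency()
    fatal = [doc.getError(i).getMessage() for i in range(doc.getNumErrors())
             if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
    if fatal:
        raise SBMLReadError(f"SBML consistency errors: {fatal[:3]}")
    sm = doc.getModel()
    if sm is None:
        raise SBMLReadError("document contains no model")

    species = []
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        payload = _read_payload(s) or {}
        species.append(Species(
            id=s.getId(), name=s.getName() or s.getId(),
            compartment=s.getCompartment(),
            initial_conc=s.getInitialConcentration()
            if s.isSetInitialConcentration() else 0.0,
            mw=float(payload.get("mw", 1.0)),
            is_clamped=bool(payload.get("is_clamped", s.getBoundaryCondition())),
        ))

    reactions = []
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        payload = _read_payload(r)
        if payload is not None:
            law_d = dict(payload["rate_law"])
            reg = law_d.pop("regulation", None)
            law = RateLaw(**law_d)
            if reg:
                law.regulation = Regulation(**reg)
            reactions.append(Reaction(
                id=r.getId(), enzyme=payload["enzyme"],
                stoichiometry={k: float(v)
                               for k, v in payload["stoichiometry"].items()},
                substrates=list(payload["substrates"]),
                rate_law=law,
                branches=[Branch(label=b["label"], fraction=b["fraction"],
                                 products={k: float(v)
                                           for k, v in b["products"].items()})
                          for b in payload["branches"]],
                name=r.getName() or "",
            ))
            continue
        # foreign document: reconstruct from SBML structure alone
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        kl = r.getKineticLaw()
        if kl is None:
            raise UnsupportedRateLawError(f"reaction {r.getId()} has no kinetic law")
        substrates = [sid for sid, c in stoich.items() if c < 0]
        law = _law_from_locals(kl, substrates)
        n_sub = 2 if law.kind in ("ordered_bibi",) else min(len(substrates), 2)
        reactions.append(Reaction(
            id=r.getId(), enzyme=r.getName() or r.getId(),
            stoichiometry=stoich, substrates=substrates[:max(n_sub, 1)],
            rate_law=law, name=r.getName() or ""))

    mpayload = _read_payload(sm) or {}
    from .model import EnzymeVariant
    model = PathwayModel(
        species=species, reactions=reactions,
        variants_applied=[EnzymeVariant(**v)
                          for v in mpayload.get("variants_applied", [])],
        constants={k: float(v) for k, v in mpayload.get("constants", {}).items()},
        name=sm.getId() or "pathway_model")
    findings = validate_model(model)
    if findings:
        raise SBMLReadError(f"imported model fails validation: {findings[:3]}")
    return model
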
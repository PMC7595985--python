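"""The concrete THCA-production roster: species, reactions, and audits.

This module encodes the engineered *S. cerevisiae* cell the package
simulates:

* a glucose batch in the medium, taken up by facilitated transport and
  catabolized by a lumped glycolysis, with a pentose-phosphate black box
  skimming a fixed fraction of the flux into NADPH;
* the Crabtree overflow — pyruvate decarboxylase feeding a glucose-activated
  ADH1 that parks carbon in an isolated ethanol pool, and a
  glucose-repressed ADH2 that feeds it back to acetaldehyde after the
  diauxic shift;
* the engineered cytosolic acetyl-CoA supply: an acylating acetaldehyde
  dehydrogenase (ADA, replacing the native ALD/ACS bypass) plus an ATP
  citrate lyase shuttle from the mitochondrial pool; the glyoxylate-cycle
  drains (CIT2, MLS1) are deleted and therefore absent;
* the GPP-optimized mevalonate chain ERG10 -> ERG13 -> tHMGR -> ERG12 ->
  ERG8 -> MVD1 -> IDI1 -> ERG20(F96W-N127W), with a small residual
  farnesyl-forming activity so FPP still accumulates;
* the olivetolic-acid branch: diffusive hexanoic-acid uptake, AAE1
  activation to hexanoyl-CoA, ACC1 malonyl-CoA supply, and the fused
  OLS/OAC reaction with its fixed 95:5 olivetol:olivetolic-acid product
  split (the lactone by-products HTAL/PDAL default to zero);
* the cannabinoid steps: the CBGA-specific NphB variant (ordered bi-bi on
  GPP + olivetolic acid) and THCAS, which releases one H2O2 per THCA.

Cofactors (ATP, NADH, NADPH, CO2, H2O2) are ledger species: their usage is
integrated for reporting, but they never appear in a rate law and impose no
constraint — energy supply is a model *output*, not a brake.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import pandas as pd
import yaml

from .config import ScenarioConfig
from .errors import ContractError, UnknownSpeciesError
from .model import (Branch, EnzymeVariant, PathwayModel, RateLaw, Reaction,
                    Regulation, Species, apply_variant, validate_model)
from .variants import get_variant

__all__ = [
    "LedgerTotals",
    "build_default_model",
    "load_default_params",
    "cofactor_ledger",
    "stoichiometric_cost",
    "reaction_table",
    "LEDGER_SPECIES",
]

LEDGER_SPECIES = ("atp", "nadh", "nadph", "co2", "h2o2")

#: (id, name, compartment, mw g/mol).  Initial concentrations are set by the
#: scenario; every intracellular intermediate starts at zero.
_SPECIES_TABLE = [
    ("glc_ex", "Glucose (medium)", "medium", 180.16),
    ("ha_ex", "Hexanoic acid (medium)", "medium", 116.16),
    ("glc_in", "Glucose (cytosol)", "cytosol", 180.16),
    ("pyr", "Pyruvate", "cytosol", 88.06),
    ("acald", "Acetaldehyde", "cytosol", 44.05),
    ("etoh", "Ethanol (Crabtree pool)", "cytosol", 46.07),
    ("accoa_c", "Acetyl-CoA (cytosol)", "cytosol", 809.57),
    ("accoa_m", "Acetyl-CoA (mitochondrion)", "mitochondrion", 809.57),
    ("acacoa", "Acetoacetyl-CoA", "cytosol", 851.65),
    ("hmgcoa", "HMG-CoA", "cytosol", 911.66),
    ("mva", "Mevalonate", "cytosol", 148.16),
    ("mvap", "Mevalonate 5-phosphate", "cytosol", 228.14),
    ("mvapp", "Mevalonate 5-diphosphate", "cytosol", 308.12),
    ("ipp", "Isopentenyl diphosphate", "cytosol", 246.07),
    ("dmapp", "Dimethylallyl diphosphate", "cytosol", 246.07),
    ("gpp", "Geranyl diphosphate", "cytosol", 314.21),
    ("fpp", "Farnesyl diphosphate", "cytosol", 382.33),
    ("ha_c", "Hexanoic acid (cytosol)", "cytosol", 116.16),
    ("hcoa", "Hexanoyl-CoA", "cytosol", 865.68),
    ("malcoa", "Malonyl-CoA", "cytosol", 853.58),
    ("olivetol", "Olivetol", "cytosol", 180.25),
    ("oa", "Olivetolic acid", "cytosol", 224.25),
    ("htal", "Hexanoyl triacetic acid lactone", "cytosol", 250.29),
    ("pdal", "Pentyl diacetic acid lactone", "cytosol", 196.24),
    ("cbga", "Cannabigerolic acid", "cytosol", 360.49),
    ("goa", "2-O-geranyl olivetolic acid", "cytosol", 360.49),
    ("thca", "Tetrahydrocannabinolic acid", "cytosol", 358.48),
    ("atp", "ATP ledger", "ledger", 507.18),
    ("nadh", "NADH ledger", "ledger", 665.40),
    ("nadph", "NADPH ledger", "ledger", 745.40),
    ("co2", "CO2 ledger", "ledger", 44.01),
    ("h2o2", "H2O2 ledger", "ledger", 34.01),
]

#: Reporting-only toxicity constants; never used in any rate expression.
REPORTING_CONSTANTS = {
    "thc_ec50_mg_per_l": 360.0,        # EC50 of THC on yeast, direct incubation
    "ha_ec50_mM": 1.2,                 # hexanoic-acid cytotoxicity EC50
    "thca_experimental_ceiling_mg_per_l": 280.0,  # highest titer seen in vivo
    "ha_safe_feed_mM": 1.0,            # growth unaffected up to this feed
}


def load_default_params() -> dict:
    """Load the shipped calibrated parameter file into a nested dict."""
    ref = importlib.resources.files("cannakin.data").joinpath("params_default.yaml")
    return yaml.safe_load(ref.read_text())


def _mm(params: dict, rid: str, regulation: Regulation | None = None,
        vmax_scale: float = 1.0) -> RateLaw:
    p = params["reactions"][rid]
    return RateLaw(kind="michaelis_menten", vmax=p["vmax"] * vmax_scale,
                   km_a=p["km_a"], regulation=regulation)


def build_default_model(config: Optional[ScenarioConfig] = None,
                        params: Optional[dict] = None) -> PathwayModel:
    """Assemble the full roster model for one scenario.

    Parameters default to the shipped calibrated file.  The returned model
    has the scenario's enzyme variants already applied and passes
    :func:`validate_model` (an AssertionError here would mean a programming
    error in the roster itself).
    """
    if config is None:
        config = ScenarioConfig()
    if params is None:
        params = load_default_params()
        if config.params_path:
            with open(config.params_path) as fh:
                params = yaml.safe_load(fh)

    g = params["globals"]
    f_ppp = float(g["f_ppp"])
    reg_act = Regulation(species="glc_ex", k_half=g["k_rep"], hill_n=g["hill_n"],
                         mode="activate")
    reg_rep = Regulation(species="glc_ex", k_half=g["k_rep"], hill_n=g["hill_n"],
                         mode="repress")

    species = []
    for sid, name, comp, mw in _SPECIES_TABLE:
        init = 0.0
        clamped = False
        if sid == "glc_ex":
            init = config.glucose_mM
        elif sid == "ha_ex":
            init = config.ha_feed_mM if config.ha_feed_mM is not None else 0.0
            clamped = config.ha_feed_mM is not None
        species.append(Species(id=sid, name=name, compartment=comp,
                               initial_conc=init, mw=mw, is_clamped=clamped))

    P = params["reactions"]
    bf_ols = params["branch_fractions"]["ols_oac"]
    bf_nphb = params["branch_fractions"]["nphb"]

    reactions = [
        Reaction("r01_glc_uptake", "HXT", {"glc_ex": -1, "glc_in": 1},
                 ["glc_ex"], _mm(params, "glc_uptake"),
                 name="facilitated glucose uptake"),
        Reaction("r02_glycolysis", "glycolysis",
                 {"glc_in": -1, "pyr": 2, "atp": 2, "nadh": 2},
                 ["glc_in"], _mm(params, "glycolysis", vmax_scale=1.0 - f_ppp),
                 name="lumped glycolysis to pyruvate"),
        Reaction("r03_ppp", "PPP",
                 {"glc_in": -1, "nadph": 2},
                 ["glc_in"], _mm(params, "glycolysis", vmax_scale=f_ppp),
                 name="pentose-phosphate black box (NADPH supply)"),
        Reaction("r04_pdc", "PDC1", {"pyr": -1, "acald": 1, "co2": 1},
                 ["pyr"], _mm(params, "pdc"),
                 name="pyruvate decarboxylase"),
        Reaction("r05_adh1", "ADH1", {"acald": -1, "etoh": 1, "nadh": -1},
                 ["acald"], _mm(params, "adh1", regulation=reg_act),
                 name="Crabtree overflow to ethanol (glucose-activated)"),
        Reaction("r06_adh2", "ADH2", {"etoh": -1, "acald": 1, "nadh": 1},
                 ["etoh"], _mm(params, "adh2", regulation=reg_rep),
                 name="ethanol reconsumption after diauxic shift (glucose-repressed)"),
        Reaction("r07_ada", "ADA", {"acald": -1, "accoa_c": 1, "nadh": 1},
                 ["acald"], _mm(params, "ada"),
                 name="acylating acetaldehyde dehydrogenase (PDH-bypass replacement)"),
        Reaction("r08_pdh", "PDH", {"pyr": -1, "accoa_m": 1, "nadh": 1, "co2": 1},
                 ["pyr"], _mm(params, "pdh"),
                 name="pyruvate dehydrogenase (mitochondrial)"),
        Reaction("r09_tca", "TCA", {"accoa_m": -1, "co2": 2, "nadh": 4, "atp": 1},
                 ["accoa_m"], _mm(params, "tca"),
                 name="lumped citric-acid cycle (FADH2 counted as NADH)"),
        Reaction("r10_acl", "ACL", {"accoa_m": -1, "accoa_c": 1, "atp": -1},
                 ["accoa_m"], _mm(params, "acl"),
                 name="ATP citrate lyase shuttle to the cytosolic pool"),
        Reaction("r11_erg10", "ERG10", {"accoa_c": -2, "acacoa": 1},
                 ["accoa_c"], _mm(params, "erg10"),
                 name="thiolase: 2 acetyl-CoA -> acetoacetyl-CoA"),
        Reaction("r12_erg13", "ERG13", {"acacoa": -1, "accoa_c": -1, "hmgcoa": 1},
                 ["acacoa"], _mm(params, "erg13"),
                 name="HMG-CoA synthase"),
        Reaction("r13_thmgr", "tHMGR", {"hmgcoa": -1, "mva": 1, "nadph": -2},
                 ["hmgcoa"], _mm(params, "thmgr"),
                 name="HMG-CoA reductase (rate-limiting)"),
        Reaction("r14_erg12", "ERG12", {"mva": -1, "mvap": 1, "atp": -1},
                 ["mva"], _mm(params, "erg12"),
                 name="mevalonate kinase"),
        Reaction("r15_erg8", "ERG8", {"mvap": -1, "mvapp": 1, "atp": -1},
                 ["mvap"], _mm(params, "erg8"),
                 name="phosphomevalonate kinase"),
        Reaction("r16_mvd1", "MVD1", {"mvapp": -1, "ipp": 1, "atp": -1, "co2": 1},
                 ["mvapp"], _mm(params, "mvd1"),
                 name="mevalonate diphosphate decarboxylase"),
        Reaction("r17_idi1", "IDI1", {"ipp": -1, "dmapp": 1},
                 ["ipp"],
                 RateLaw(kind="mass_action", k=P["idi1"]["k"],
                         k_rev=P["idi1"]["k_rev"]),
                 name="IPP <-> DMAPP isomerase (reversible)"),
        Reaction("r18_erg20ww", "ERG20ww", {"ipp": -1, "dmapp": -1, "gpp": 1},
                 ["ipp", "dmapp"],
                 RateLaw(kind="mass_action", k=P["erg20ww"]["k"]),
                 name="ERG20 F96W-N127W: IPP + DMAPP -> GPP"),
        Reaction("r19_erg20res", "ERG20res", {"gpp": -1, "ipp": -1, "fpp": 1},
                 ["gpp", "ipp"],
                 RateLaw(kind="mass_action",
                         k=P["erg20ww"]["k"] * g["erg20_residual_fraction"]),
                 name="residual geranyltransferase activity: GPP + IPP -> FPP"),
        Reaction("r20_ha_diffusion", "passive", {"ha_ex": -1, "ha_c": 1},
                 ["ha_ex", "ha_c"],
                 RateLaw(kind="diffusion", k=P["ha_diffusion"]["k"]),
                 name="hexanoic-acid membrane diffusion"),
        Reaction("r21_aae1", "AAE1", {"ha_c": -1, "hcoa": 1, "atp": -2},
                 ["ha_c"], _mm(params, "aae1"),
                 name="acyl-activating enzyme (ATP -> AMP, 2 ATP-equivalents)"),
        Reaction("r22_acc1", "ACC1", {"accoa_c": -1, "malcoa": 1, "atp": -1, "co2": -1},
                 ["accoa_c"], _mm(params, "acc1"),
                 name="acetyl-CoA carboxylase"),
        Reaction("r23_ols_oac", "OLS_OAC", {"hcoa": -1, "malcoa": -3},
                 ["hcoa", "malcoa"],
                 RateLaw(kind="ordered_bibi", vmax=P["ols_oac"]["vmax"],
                         km_a=P["ols_oac"]["km_a"], km_b=P["ols_oac"]["km_b"],
                         ki_a=P["ols_oac"]["ki_a"]),
                 branches=[
                     Branch("olivetol", bf_ols["olivetol"], {"olivetol": 1, "co2": 4}),
                     Branch("oa", bf_ols["oa"], {"oa": 1, "co2": 3}),
                     Branch("htal", bf_ols["htal"], {"htal": 1, "co2": 3}),
                     Branch("pdal", bf_ols["pdal"], {"pdal": 1, "co2": 3}),
                 ],
                 name="fused olivetol synthase / olivetolic acid cyclase"),
        Reaction("r24_nphb", "NphB", {"gpp": -1, "oa": -1},
                 ["gpp", "oa"],
                 RateLaw(kind="ordered_bibi", vmax=P["nphb"]["vmax"],
                         km_a=P["nphb"]["km_a"], km_b=P["nphb"]["km_b"],
                         ki_a=P["nphb"]["ki_a"]),
                 branches=[
                     Branch("cbga", bf_nphb["cbga"], {"cbga": 1}),
                     Branch("goa", bf_nphb["goa"], {"goa": 1}),
                 ],
                 name="NphB Y288A/G286S prenyltransferase: GPP + OA -> CBGA"),
        Reaction("r25_thcas", "THCAS", {"cbga": -1, "thca": 1, "h2o2": 1},
                 ["cbga"], _mm(params, "thcas"),
                 name="THCA synthase (equimolar H2O2 co-product)"),
    ]

    model = PathwayModel(species=species, reactions=reactions,
                         constants=dict(REPORTING_CONSTANTS),
                         name="thca_yeast")
    for label in config.variants:
        apply_variant(model, get_variant(label), in_place=True)

    findings = validate_model(model)
    if findings:  # pragma: no cover - roster is valid by construction
        raise AssertionError(f"default roster failed validation: {findings}")
    return model


@dataclass
class LedgerTotals:
    """Cumulative cofactor usage (mM-equivalents of cytosol).

    Fields may hold scalars (totals) or arrays (time series along a
    trajectory grid).  ATP is split into consumed and produced streams;
    NAD(P)H are net (production minus consumption).
    """

    atp_consumed: object = 0.0
    atp_produced: object = 0.0
    nadh_net: object = 0.0
    nadph_net: object = 0.0
    co2_released: object = 0.0
    h2o2_produced: object = 0.0

    FIELDS = ("atp_consumed", "atp_produced", "nadh_net", "nadph_net",
              "co2_released", "h2o2_produced")


def cofactor_ledger(traj, model: Optional[PathwayModel] = None) -> LedgerTotals:
    """Final cumulative cofactor totals of a trajectory.

    If ``model`` is supplied, the trajectory must have been produced from it
    (checked via the model hash recorded in the trajectory metadata).
    """
    if getattr(traj, "ledger", None) is None:
        raise ContractError("trajectory carries no cofactor ledger")
    if model is not None:
        recorded = traj.meta.get("model_hash")
        if recorded is not None and recorded != model.content_hash():
            raise ContractError(
                "trajectory was not produced from the supplied model "
                f"(hash {recorded} != {model.content_hash()})")
    return LedgerTotals(**{f: float(getattr(traj.ledger, f)[-1])
                           for f in LedgerTotals.FIELDS})


#: Per-unit cofactor costs along the unbranched path, derived by summing the
#: roster reactions (two IPP-equivalents per GPP; hexanoyl-CoA counted as one
#: acyl-CoA unit in the C2 budget).  Positive = consumed per mol of target;
#: negative = released.
_COST_TABLE = {
    "gpp": {"accoa_c": 6.0, "atp": 6.0, "nadph": 4.0, "co2": -2.0},
    "oa": {"hcoa": 1.0, "malcoa": 3.0, "accoa_c": 4.0, "atp": 5.0,
           "nadph": 0.0, "co2": 0.0},
}


def stoichiometric_cost(target: str) -> dict[str, float]:
    """Closed-form cofactor cost per mol of ``target``, no branching losses.

    Supported targets: ``gpp``, ``oa``, ``cbga``, ``thca``.  CBGA and THCA
    are the sums of the GPP and olivetolic-acid paths (the prenylation and
    oxidocyclization steps consume no tracked cofactor; THCAS releases one
    H2O2 per THCA).
    """
    target = target.lower()
    if target in _COST_TABLE:
        return dict(_COST_TABLE[target])
    if target in ("cbga", "thca"):
        total: dict[str, float] = {}
        for part in ("gpp", "oa"):
            for k, v in _COST_TABLE[part].items():
                if k in ("hcoa", "malcoa"):
                    continue  # intermediate pools, already expanded into the sums
                total[k] = total.get(k, 0.0) + v
        if target == "thca":
            total["h2o2"] = -1.0
        return total
    raise UnknownSpeciesError(
        f"unsupported cost target {target!r}; supported: gpp, oa, cbga, thca")


def reaction_table(model: PathwayModel) -> pd.DataFrame:
    """Human-readable reaction roster (id, enzyme, equation, law, parameters)."""
    rows = []
    for rx in model.reactions:
        eff = rx.effective_stoichiometry()
        lhs = " + ".join(f"{-c:g} {s}" for s, c in eff.items() if c < 0)
        rhs = " + ".join(f"{c:g} {s}" for s, c in eff.items() if c > 0)
        law = rx.rate_law
        pars = {k: getattr(law, k) for k in ("vmax", "km_a", "km_b", "ki_a", "k", "k_rev")
                if getattr(law, k)}
        rows.append({
            "id": rx.id,
            "enzyme": rx.enzyme,
            "equation": f"{lhs} -> {rhs}" if rhs else f"{lhs} ->",
            "rate_law": law.kind,
            "parameters": "; ".join(f"{k}={v:.6g}" for k, v in pars.items()),
        })
    return pd.DataFrame(rows)
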
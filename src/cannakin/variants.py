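"""Registry of literature-reported enzyme engineering variants.

Each entry is a fold-change on the target enzyme's limiting rate, with the
study it was reported in.  The default model applies the subset listed in
:data:`DEFAULT_VARIANT_LABELS`; the remaining entries are available for
scenario exploration (``--variant`` on the CLI, or ``apply_variant`` from
code).
"""

from __future__ import annotations

from .errors import UnknownEnzymeError
from .model import EnzymeVariant

__all__ = ["VARIANT_REGISTRY", "DEFAULT_VARIANT_LABELS", "get_variant"]

VARIANT_REGISTRY: dict[str, EnzymeVariant] = {
    v.label: v
    for v in [
        EnzymeVariant(
            enzyme="tHMGR", label="tHMGR_truncation", activity_multiplier=11.0,
            provenance="N-terminally truncated Hevea brasiliensis HMGR; 11-fold "
                       "activity vs the membrane-bound enzyme (Harker et al.)"),
        EnzymeVariant(
            enzyme="IDI1", label="IDI1_overexpression", activity_multiplier=2.0,
            provenance="IDI1 overexpression raising isomerase capacity; improved "
                       "geraniol titers (Zhao et al.)"),
        EnzymeVariant(
            enzyme="ACC1", label="ACC1_overexpression", activity_multiplier=2.0,
            provenance="ACC1 overexpression; 2-fold malonyl-CoA improvement "
                       "(Runguphan & Keasling)"),
        EnzymeVariant(
            enzyme="ACC1", label="ACC1_S659A_S1157A", activity_multiplier=3.0,
            provenance="Phosphosite mutant escaping SNF1 inactivation; 3-fold "
                       "overall activity (Lian et al.)"),
        EnzymeVariant(
            enzyme="OLS_OAC", label="OAC_Y27F", activity_multiplier=1.62,
            provenance="OAC Y27F, 162% relative activity vs wild type "
                       "(Yang et al.)"),
        EnzymeVariant(
            enzyme="THCAS", label="THCAS_N89Q_N499Q", activity_multiplier=2.0,
            provenance="Glycosylation-site variant, 2-fold activity (Zirpel et al.)"),
        EnzymeVariant(
            enzyme="THCAS", label="THCAS_H494C_R532C", activity_multiplier=1.7,
            provenance="Added disulfide bond, 1.7-fold activity (Zirpel et al.)"),
        EnzymeVariant(
            enzyme="NphB", label="NphB_x10", activity_multiplier=10.0,
            provenance="Hypothetical further 10-fold NphB improvement; used for "
                       "sensitivity-shift scenarios"),
    ]
}

# Variants baked into the shipped default model.  ERG20 F96W-N127W and NphB
# Y288A/G286S are not multipliers here: the roster's GPP-forming ERG20 and
# CBGA-specific NphB reactions *are* those mutants (their calibrated
# kinetics describe the mutant, and the wild-type forms are not modeled).
DEFAULT_VARIANT_LABELS: tuple[str, ...] = (
    "tHMGR_truncation",
    "IDI1_overexpression",
    "ACC1_S659A_S1157A",
    "OAC_Y27F",
    "THCAS_N89Q_N499Q",
    "THCAS_H494C_R532C",
)


def get_variant(label: str) -> EnzymeVariant:
    try:
        return VARIANT_REGISTRY[label]
    except KeyError:
        raise UnknownEnzymeError(
            f"unknown variant {label!r}; known: {sorted(VARIANT_REGISTRY)}") from None
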
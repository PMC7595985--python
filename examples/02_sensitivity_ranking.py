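"""Rank pathway intermediates by their leverage on the final THCA titer.

Each intermediate gets a 0.05 mM bolus at t=0; the score is the THCA
endpoint gain per mM of bolus (a transfer coefficient: 1 means the extra
material is converted quantitatively, 0 means it does not help).  The run
also shows how the picture shifts if the prenyltransferase were engineered
10x faster: the olivetolic-acid score moves closer to CBGA's — the supply
side becomes the whole story — while a GPP bolus helps even less, because
a faster NphB holds a smaller standing pool of olivetolic acid for it to
pair with.
"""

import cannakin as ck
from cannakin.sensitivity import product_sensitivity, sensitivity_table

model = ck.build_default_model()
result = product_sensitivity(model, bolus=0.05, t_end=40.0)

print("baseline THCA(40 h) = %.4f mM" % result.baseline)
print(sensitivity_table(result).to_string(index=False,
                                          float_format=lambda v: f"{v:.4f}"))

faster = ck.apply_variant(model, ck.get_variant("NphB_x10"))
shifted = product_sensitivity(faster, bolus=0.05, t_end=40.0)
print("\nwith a 10x faster NphB:")
for sid in ("cbga", "oa", "gpp"):
    print(f"  {sid:5s}: {result.scores[sid]:.4f} -> {shifted.scores[sid]:.4f} "
          f"(relative to CBGA: {result.scores[sid]/result.scores['cbga']:.4f}"
          f" -> {shifted.scores[sid]/shifted.scores['cbga']:.4f})")
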
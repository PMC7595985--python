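# Default kinetic parameter set for the THCA pathway model.
#
# Units: vmax mM/h, km/ki mM, first-order k 1/h, bimolecular k 1/(mM*h).
# vmax values are BASE (wild-type-equivalent) rates; the enzyme variants
# listed in the default scenario multiply them at model-build time
# (e.g. tHMGR x11, THCAS x2 x1.7).
#
# No kinetic constant of the underlying study is published; every value
# below is a calibration output of cannakin.calibration against the printed
# model endpoints (glucose depletion 20.8 h from 111 mM, THCA 0.837 mM and
# GPP ~0.65 mM at 40 h, intracellular hexanoic acid <= 0.3 mM under a 1 mM
# clamped feed, olivetolic acid steady within 10 h).  Km values are fixed
# at literature-plausible mid-range magnitudes (BRENDA/SABIO-RK-style
# single-digit mM for transport and central carbon, sub-mM for the
# dedicated biosynthetic enzymes) and were not fitted.
schema: cannakin-params-v1
globals:
  f_ppp: 0.1                 # fraction of glucose catabolism routed through the PPP black box
  k_rep: 5.0                 # mM glucose; shared half-point of ADH1 activation / ADH2 repression
  hill_n: 2.0
  erg20_residual_fraction: 0.003425   # residual GPP+IPP->FPP activity of ERG20ww, as a fraction of its GPP-forming k
reactions:
  glc_uptake: {vmax: 5.669, km_a: 1.0}
  glycolysis: {vmax: 50.0, km_a: 0.5}    # total glucose catabolism capacity, split (1-f_ppp):f_ppp with the PPP
  pdc: {vmax: 20.0, km_a: 2.0}
  adh1: {vmax: 16.0, km_a: 1.0}
  adh2: {vmax: 2.7, km_a: 5.0}
  ada: {vmax: 2.5, km_a: 0.5}
  pdh: {vmax: 2.0, km_a: 0.5}
  tca: {vmax: 2.0, km_a: 0.3}
  acl: {vmax: 1.0, km_a: 0.3}
  erg10: {vmax: 0.15, km_a: 0.3}
  erg13: {vmax: 0.3, km_a: 0.1}
  thmgr: {vmax: 0.012513, km_a: 0.05}
  erg12: {vmax: 1.0, km_a: 0.05}
  erg8: {vmax: 1.0, km_a: 0.05}
  mvd1: {vmax: 1.0, km_a: 0.05}
  idi1: {k: 20.0, k_rev: 10.0}
  erg20ww: {k: 2000.0}
  ha_diffusion: {k: 0.724034}
  aae1: {vmax: 1.2, km_a: 0.3}
  acc1: {vmax: 0.573615, km_a: 0.5}
  ols_oac: {vmax: 0.93, km_a: 0.1, km_b: 0.05, ki_a: 0.05}
  nphb: {vmax: 0.10853, km_a: 0.02, km_b: 0.15, ki_a: 0.01}
  thcas: {vmax: 0.021015, km_a: 0.2}
branch_fractions:
  ols_oac: {olivetol: 0.95, oa: 0.05, htal: 0.0, pdal: 0.0}
  nphb: {cbga: 1.0, goa: 0.0}
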
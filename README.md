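# cannakin

Kinetic whole-cell modeling of heterologous tetrahydrocannabinolic acid
(THCA) biosynthesis in engineered *Saccharomyces cerevisiae*.

Recombinant cannabinoid production in yeast is limited less by missing
enzymes than by precursor logistics: cytosolic acetyl-CoA, malonyl-CoA and
hexanoyl-CoA supply on the polyketide side, and geranyl diphosphate (GPP)
supply from the mevalonate pathway on the prenyl side. `cannakin` is an
ordinary-differential-equation model of one engineered cell plus its
medium, built for metabolic engineers and modelers who want to ask
"which intervention moves the titer?" before building a strain. It covers:

- glucose uptake and a lumped glycolysis, with a pentose-phosphate black
  box skimming a fixed fraction of the flux into NADPH;
- the Crabtree effect: a glucose-activated ADH1 parks overflow carbon in an
  isolated ethanol pool, and a glucose-repressed ADH2 feeds it back after
  the diauxic shift;
- an engineered cytosolic acetyl-CoA supply (acylating acetaldehyde
  dehydrogenase replacing the PDH bypass, plus an ATP-citrate-lyase shuttle;
  glyoxylate-cycle drains deleted);
- the GPP-optimized mevalonate chain (ERG10 → ERG13 → truncated HMG-CoA
  reductase → ERG12 → ERG8 → MVD1 → IDI1 → ERG20 F96W-N127W, with a small
  residual FPP-forming activity);
- the olivetolic-acid branch: diffusive hexanoic-acid uptake, AAE1
  activation, ACC1 malonyl-CoA supply, and a fused OLS/OAC reaction with a
  fixed 95:5 olivetol : olivetolic-acid product split;
- the cannabinoid steps: the CBGA-specific NphB prenyltransferase variant
  (ordered bi-bi on GPP + olivetolic acid) and THCA synthase, which
  releases one H₂O₂ per THCA.

Cofactors (ATP, NADH, NADPH, CO₂, H₂O₂) are tracked as a cumulative ledger
but never limit any rate: energy demand is a model output, not a brake.

## Rate laws

Single-substrate steps use irreversible Michaelis–Menten kinetics,
*v* = *V*<sub>max</sub>·*S*/(*K*<sub>m</sub> + *S*). The two condensations
where neither substrate is in excess use the irreversible ordered bi-bi
form

*v* = *V*<sub>max</sub>·*A*·*B* / (*K*<sub>iA</sub>*K*<sub>mB</sub> +
*K*<sub>mB</sub>*A* + *K*<sub>mA</sub>*B* + *A·B*).

Prenyl couplings are mass action, the IPP ⇌ DMAPP isomerization is
reversible mass action, hexanoic-acid uptake is passive diffusion
*k*(*S*<sub>out</sub> − *S*<sub>in</sub>), and the glucose switching of
ADH1/ADH2 is a multiplicative Hill factor (*n* = 2) on *V*<sub>max</sub>.
Units are mM, hours, and mM·h⁻¹ throughout. The shipped default parameter
set (`src/cannakin/data/params_default.yaml`) was calibrated with the
package's own multi-start Nelder–Mead machinery; see `docs/methods.md`.

## Worked example

```python
import cannakin as ck

model = ck.build_default_model()          # 111 mM glucose, 1 mM HA feed
traj  = ck.simulate(model, t_end=40.0)

thca = traj.final("thca")
print(f"THCA(40 h) = {thca:.4f} mM = "
      f"{ck.to_mass_conc(thca, 'thca', traj.mw):.1f} mg/L")
print(f"glucose depleted at {ck.depletion_time(traj, 'glc_ex', 0.1):.1f} h")
print(f"yield {ck.yield_per_substrate(traj):.4f} g THCA / g glucose")
```

prints

```
THCA(40 h) = 0.8370 mM = 300.0 mg/L
glucose depleted at 20.8 h
yield 0.0150 g THCA / g glucose
```

— the 40-hour batch converts a 20 g/L glucose charge into a ~300 mg/L THCA
titer (0.015 g per g glucose), with glucose exhausted at 20.8 h and the
ethanol formed by Crabtree overflow reconsumed afterwards. The
`examples/` directory holds one short script per capability: the default
batch, the bolus sensitivity ranking (CBGA first, olivetolic acid a close
second), a parameter-recovery experiment, an SBML round trip, and a
leave-one-out scan of the engineered enzyme variants. A thin CLI mirrors
the library: `cannakin simulate`, `cannakin sensitivity`,
`cannakin calibrate`, `cannakin export-sbml`, `cannakin make-fixtures`.

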
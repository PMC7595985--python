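# Calibration anchors: the printed model endpoints the shipped default
# parameter set reproduces.  Fields mirror cannakin.calibrate.CalibrationAnchor.
- observable: depletion_time
  species: glc_ex
  target: 20.8          # h; 111 mM glucose completely metabolized
  units: h
  threshold: 0.1        # mM cutoff for "completely"
  tolerance: 0.5
  weight: 2.0
- observable: conc_at
  species: thca
  target: 0.837         # mM at 40 h (~299.8 mg/L)
  time: 40.0
  tolerance: 0.004
  weight: 4.0
- observable: conc_at
  species: gpp
  target: 0.65          # mM accumulated excess at 40 h ("about")
  time: 40.0
  tolerance: 0.065
  weight: 1.0
- observable: conc_at
  species: ha_c
  target: 0.3           # mM; intracellular steady state stays below this
  time: 40.0
  tolerance: 0.03
  weight: 1.0
  kind: upper_bound
- observable: steady_state_time
  species: oa
  target: 10.0          # h; olivetolic acid steady (<1%/h) by then
  units: h
  rel_rate_tol: 0.01
  tolerance: 1.0
  weight: 1.0
  kind: upper_bound
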
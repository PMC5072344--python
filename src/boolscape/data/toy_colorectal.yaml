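# Marker roles, input condition and driver-mutation profile for the
# colorectal-like toy model (toy_colorectal.bnet).
markers:
  cyclinD: CyclinD
  cyclinE: CyclinE
  cyclinA: CyclinA
  cyclinB: CyclinB
  caspase: Casp3
  ecadherin: Ecadherin
  mmp: MMP
  rho: Rho
inputs:
  "on": [EGF, ECM, Wnt]
  "off": [DNAdam]
mutations:
  - {node: APC, value: 0, label: APC}
  - {node: KRAS, value: 1, label: KRAS}
  - {node: PTEN, value: 0, label: PTEN}
  - {node: TP53, value: 0, label: TP53}
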
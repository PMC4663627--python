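# Measurement-buffer ionic compositions as explicit species (no pH
# speciation model; counter-ions from the weighed salts are listed).
ps_0.1x:
  description: 0.1x phosphate solution (240 uM NaH2PO4 + 760 uM Na2HPO4, pH 7.4)
  temperature_K: 298.15
  relative_permittivity: 78.5
  species:
    - {name: "Na+", concentration_M: 1.76e-3, charge: 1}
    - {name: "H2PO4-", concentration_M: 2.4e-4, charge: -1}
    - {name: "HPO4-2", concentration_M: 7.6e-4, charge: -2}
pbs_1x:
  description: 1x PBS (138 mM NaCl, 2.7 mM KCl, 8 mM Na2HPO4, 1.5 mM KH2PO4)
  temperature_K: 298.15
  relative_permittivity: 78.5
  species:
    - {name: "Na+", concentration_M: 0.154, charge: 1}
    - {name: "K+", concentration_M: 4.2e-3, charge: 1}
    - {name: "Cl-", concentration_M: 0.1407, charge: -1}
    - {name: "HPO4-2", concentration_M: 8.0e-3, charge: -2}
    - {name: "H2PO4-", concentration_M: 1.5e-3, charge: -1}
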
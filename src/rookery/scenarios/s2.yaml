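format: rookery-scenario-v1
name: S2
description: >-
  Cabo Verde stepping-stone model (reconstruction of the top-ranked
  gene-flow model): USA/Mexico is ancestral and founds Cabo Verde, which acts
  as the central stepping stone, founding Brazil westwards and the
  Mediterranean eastwards and remaining the source of recent migrants
  towards both sides of the basin (admixture pulses).
sites: 674
generation_time_years: 50
kappa: 2.0
mutation_rate: {kind: uniform, low: 1.0e-07, high: 1.0e-03}
demes:
  - {name: HgI, size: {kind: uniform_int, low: 100, high: 500}, samples: 0}
  - {name: HgII, size: {kind: uniform_int, low: 100, high: 500}, samples: 0}
  - {name: Brazil, size: {kind: uniform_int, low: 100, high: 500}, samples: 100}
  - {name: CaboVerde, size: {kind: uniform_int, low: 100, high: 500}, samples: 100}
  - {name: USAMexico, size: {kind: uniform_int, low: 100, high: 500}, samples: 100}
  - {name: Mediterranean, size: {kind: uniform_int, low: 100, high: 500}, samples: 100}
events:
  - {kind: admixture, deme: Brazil, source: CaboVerde, fraction: {kind: uniform, low: 0.05, high: 0.5}, time: {kind: uniform_int, low: 40, high: 59}}
  - {kind: admixture, deme: USAMexico, source: CaboVerde, fraction: {kind: uniform, low: 0.05, high: 0.5}, time: {kind: uniform_int, low: 60, high: 79}}
  - {kind: split, deme: Mediterranean, source: CaboVerde, time: {kind: uniform_int, low: 80, high: 100}}
  - {kind: split, deme: Brazil, source: CaboVerde, time: {kind: uniform_int, low: 4000, high: 5999}}
  - {kind: split, deme: CaboVerde, source: USAMexico, time: {kind: uniform_int, low: 6000, high: 8999}}
  - {kind: split, deme: USAMexico, source: HgI, time: {kind: uniform_int, low: 9000, high: 10000}}
  - {kind: split, deme: HgII, source: HgI, time: {kind: fixed, value: 50000}}
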
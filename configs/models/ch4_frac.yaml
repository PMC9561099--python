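# Methane molar fraction, mol CH4 / (mol CH4 + mol CO2).
response: ch4_frac
fixed: [byr.flk.sex, ryr.lot.group.round]
random:
  animal: {group_by: [animal], covariance: pedigree}
  wgpe: {group_by: [animal, round], covariance: identity}
  agpe: {group_by: [animal, ryr], covariance: identity}
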
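# Methane yield, g CH4 per kg dry matter intake.
response: ch4_dmi
fixed: [byr.flk.sex, ryr.lot.group.round]
random:
  animal: {group_by: [animal], covariance: pedigree}
  wgpe: {group_by: [animal, round], covariance: identity}
  agpe: {group_by: [animal, ryr], covariance: identity}
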
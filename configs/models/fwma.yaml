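# Mixed-age fleece weight, kg.
response: fleece_kg
fixed: [rflk.ryr.mob.ageclass, aod, brr]
random:
  animal: {group_by: [animal], covariance: pedigree}
  pe: {group_by: [animal], covariance: identity}
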
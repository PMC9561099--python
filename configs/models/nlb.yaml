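# Number of lambs born (0-3).
response: nlb
fixed: [rflk.ryr.mob.ageclass]
random:
  animal: {group_by: [animal], covariance: pedigree}
  pe: {group_by: [animal], covariance: identity}
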
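# Pregnancy-scan litter size (0-3).
response: pregsc
fixed: [rflk.ryr.mob.ageclass]
random:
  animal: {group_by: [animal], covariance: pedigree}
  pe: {group_by: [animal], covariance: identity}
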
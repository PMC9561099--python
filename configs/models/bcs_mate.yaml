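# Mating body condition score (1-5 in half units).
response: bcs_mate
fixed: [rflk.ryr.mob.ageclass, nlb_prev, brr]
random:
  animal: {group_by: [animal], covariance: pedigree}
  pe: {group_by: [animal], covariance: identity}
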
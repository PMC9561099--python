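# Mating live weight of adult ewes, repeated records at ages 2-6.
response: lw_mate_kg
fixed: [rflk.ryr.mob.ageclass, nlb_prev, aod, brr]
random:
  animal: {group_by: [animal], covariance: pedigree}
  pe: {group_by: [animal], covariance: identity}
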
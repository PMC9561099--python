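# Litter survival to weaning: lambs weaned / lambs born, undefined (NA)
# for ewes that did not lamb; litter size fitted as a fixed factor.
response: lsw
fixed: [rflk.ryr.mob.ageclass, nlb]
random:
  animal: {group_by: [animal], covariance: pedigree}
  pe: {group_by: [animal], covariance: identity}
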
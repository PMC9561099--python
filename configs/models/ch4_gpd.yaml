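# Gross methane emissions, g CH4/day: repeatability animal model with
# within-round (wgpe) and across-round (agpe, by recording year) PE terms.
response: ch4_gpd
fixed: [byr.flk.sex, ryr.lot.group.round, brr]
covariates: [bdev]
random:
  animal: {group_by: [animal], covariance: pedigree}
  wgpe: {group_by: [animal, round], covariance: identity}
  agpe: {group_by: [animal, ryr], covariance: identity}
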
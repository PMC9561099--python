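# First Nematodirus egg count on the log_e(x + 50) scale.
response: nem_log
fixed: [byr.flk.sex]
random:
  animal: {group_by: [animal], covariance: pedigree}
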
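# First faecal egg count on the log_e(x + 50) scale; single record per
# animal, so no permanent-environment term.
response: fec_log
fixed: [byr.flk.sex]
random:
  animal: {group_by: [animal], covariance: pedigree}
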
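# Published standardization constants for the two instrument totals that are
# z-scored instead of unit-scaled.  Overridable via PipelineConfig.
moca_total: {mean: 23.25, sd: 4.82}
phq9_total: {mean: 5.79, sd: 5.8}
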
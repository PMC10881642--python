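# Demo pipeline configuration: synthetic reference cohort, all analyses.
# Group sizes, DaT z-score distributions and demographics follow the
# packaged defaults (HC 23, DLB-DaT(+) 86, DLB-DaT(-) 22, AD 49, PD 33, MSA 19).
input:
  synthetic: {}
analyses: [regional, connectivity, expression]
seed: 0
outdir: fdgpattern_out
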
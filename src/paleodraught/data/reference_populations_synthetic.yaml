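# SYNTHETIC stand-in reference values, for illustration and testing only.
#
# The published comparator herds (lifetime draught oxen from the Carpathians,
# Romanian young bulls fattened for meat, and the semi-feral Chillingham
# herd) report their modified pathological index means in figures, not as
# printed numbers, so no authoritative values can be transcribed here. The
# values below are invented placeholders that preserve only the qualitative
# ordering those studies show (fattened bulls lowest, unworked semi-feral
# herd low, lifetime draught oxen highest, and posterior above anterior for
# worked herds). They are excluded from any quantitative acceptance check.
populations:
  - name: "draught oxen (synthetic stand-in)"
    draught: true
    mean_mpi_anterior: 0.32
    mean_mpi_posterior: 0.41
    provenance: "illustrative synthetic values; not digitised from any source"
  - name: "fattened young bulls (synthetic stand-in)"
    draught: false
    mean_mpi_anterior: 0.05
    mean_mpi_posterior: 0.04
    provenance: "illustrative synthetic values; not digitised from any source"
  - name: "semi-feral herd (synthetic stand-in)"
    draught: false
    mean_mpi_anterior: 0.10
    mean_mpi_posterior: 0.08
    provenance: "illustrative synthetic values; not digitised from any source"
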
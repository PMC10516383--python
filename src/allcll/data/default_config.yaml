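# Default configuration. Every tunable of the workflow appears here;
# values may be overridden by a user YAML passed with --config.
reconstruction:
  min_clip: 10          # minimum soft-clip length harvested as junction evidence (nt)
  min_mapq: 20
  window: 5             # single-linkage breakpoint clustering window (nt)
  min_support: 3        # reads per junction cluster
  min_overlap: 20       # V-side / J-side consensus join overlap (nt)
  max_mismatch_rate: 0.05
annotation:
  match: 1
  mismatch: -2
  gap_open: -7          # affine gap: length-k gap scores -(6 + k)
  gap_extend: -1
  min_v_identity: 60.0
  min_j_identity: 60.0
  min_j_span: 20
  d_min_length: 5
  d_min_identity: 80.0
light_chain:
  min_codon_support: 10 # reads across the position-110 codon
cna:
  del_threshold: -0.2
  gain_threshold: 0.15
  min_targets: 3
  uniformity_threshold: 0.5   # IQR of backbone log2 ratios
  min_mapq: 20
variants:
  min_base_q: 20
  min_mapq: 20
  min_depth: 100
  min_alt_reads: 5
  vaf_cutoff: 0.02            # below: filtered out
  high_confidence_vaf: 0.03   # at/above: pass; between: low-confidence
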
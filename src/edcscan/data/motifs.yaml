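# Conserved EDC protein sequence motifs.
#
# Lowercase 'x' marks a wildcard position (matches any residue and never
# counts as a mismatch).  Matching is case-insensitive on the subject.
# max_mismatches is the default budget for discovery scans; exact checks
# should pass max_mismatches=0 explicitly.
- name: sedc_n_terminal
  consensus: MSYxxxxQQCKQPCQPPP
  anchor: n_terminal
  max_mismatches: 2
- name: sedc_internal_mcsr
  consensus: MCSRxxxxxCH
  anchor: internal
  max_mismatches: 2
- name: sedc_c_terminal
  consensus: QQxKQPSQWPxQxxK
  anchor: c_terminal
  max_mismatches: 2
# The beta-keratin "core box" has no published consensus string; this entry
# is a placeholder that users can fill in via their own catalogue file.
- name: beta_keratin_core_box
  consensus: null
  anchor: internal
  max_mismatches: 0
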
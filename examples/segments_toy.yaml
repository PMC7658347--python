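# Segment definitions for the synthetic two-spoke assembly written by
# `tuscmorph make-synthetic` (defaults: 3 helices x 20 residues per block).
# Chains: A = spoke-1 GRIP1+GRIP2, B = spoke-1 gamma-body,
#         C = spoke-2 GRIP1+GRIP2, D = spoke-2 gamma-body.
atom_subset: CA_ONLY
anchor: [Spc97-GRIP1, Spc97-GRIP2, gamma-Spc97]
segments:
  - name: Spc97-GRIP1
    query: [[A, 1, 60]]
  - name: Spc97-GRIP2
    query: [[A, 61, 120]]
  - name: gamma-Spc97
    query: [[B, 1, 60]]
  - name: Spc98-GRIP1
    query: [[C, 1, 60]]
  - name: Spc98-GRIP2
    query: [[C, 61, 120]]
  - name: gamma-Spc98
    query: [[D, 1, 60]]
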
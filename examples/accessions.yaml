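# Segment definitions for comparing the C. albicans gamma-TuSC model
# (PDB-7ANZ, query) against spokes 1-2 of the S. cerevisiae gamma-TuSC
# oligomer in the closed state (PDB 5FLZ, reference).
#
# IMPORTANT — USER-EDITABLE BOUNDARIES.  The GRIP1/GRIP2 domain boundaries
# below are placeholders: the original analysis does not publish boundary
# residue numbers, so they MUST be reviewed and adjusted against the
# deposited entries before use.  Chain ids follow the deposited files
# (7ANZ: A = Spc97, B = Spc98, C/D = gamma-tubulins; 5FLZ spokes 1-2:
# verify chain mapping in the header).  Fetch the files yourself, e.g.
#   https://files.rcsb.org/download/7ANZ.cif
#   https://files.rcsb.org/download/5FLZ.cif
# and place them under data/accessions/.
atom_subset: CA_ONLY
anchor: [Spc97-GRIP1, Spc97-GRIP2, gamma-Spc97]
segments:
  - name: Spc97-GRIP1
    query:     [[A, 92, 560]]    # EDIT ME: Spc97 GRIP1 domain boundaries
    reference: [[A, 55, 560]]    # EDIT ME: 5FLZ spoke-1 Spc97 GRIP1
  - name: Spc97-GRIP2
    query:     [[A, 561, 871]]   # EDIT ME
    reference: [[A, 561, 822]]   # EDIT ME
  - name: gamma-Spc97
    query:     [[C, 1, 465]]     # EDIT ME
    reference: [[C, 1, 455]]     # EDIT ME
  - name: Spc98-GRIP1
    query:     [[B, 150, 625]]   # EDIT ME
    reference: [[B, 178, 625]]   # EDIT ME
  - name: Spc98-GRIP2
    query:     [[B, 626, 846]]   # EDIT ME
    reference: [[B, 626, 846]]   # EDIT ME
  - name: gamma-Spc98
    query:     [[D, 1, 465]]     # EDIT ME
    reference: [[D, 1, 455]]     # EDIT ME
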
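provenance: >
  Packaged GABA_B receptor segment library. Residue ranges use author
  numbering of the deposited heterodimer structures (active 7EB2, inactive
  7C7S). Chain ids are placeholders; remap them per structure with
  SegmentLibrary.with_chain_roles.
segments:
  GB1_LBupper:
    subunit_role: GB1
    chain_id: A
    residue_ranges: [[222, 235], [247, 260]]
    atom_mode: CA_ONLY
  GB1_LBlower:
    subunit_role: GB1
    chain_id: A
    residue_ranges: [[347, 358], [368, 382]]
    atom_mode: CA_ONLY
  GB1_TM4:
    subunit_role: GB1
    chain_id: A
    residue_ranges: [[711, 731]]
    atom_mode: CA_ONLY
  GB2_TM4:
    subunit_role: GB2
    chain_id: B
    residue_ranges: [[598, 618]]
    atom_mode: CA_ONLY
  GB1_TM5:
    subunit_role: GB1
    chain_id: A
    residue_ranges: [[769, 789]]
    atom_mode: CA_ONLY
  GB2_TM5:
    subunit_role: GB2
    chain_id: B
    residue_ranges: [[655, 675]]
    atom_mode: CA_ONLY
  GB1_TM6:
    subunit_role: GB1
    chain_id: A
    residue_ranges: [[805, 825]]
    atom_mode: CA_ONLY
  GB2_TM6:
    subunit_role: GB2
    chain_id: B
    residue_ranges: [[692, 712]]
    atom_mode: CA_ONLY
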
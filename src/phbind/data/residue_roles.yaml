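# Residue-name -> particle-role map. Edit or extend and pass to
# load_role_map()/read_structure(). Unlisted amino acids are covered by
# the built-in standard set; any unknown residue maps to "other" with a
# logged warning.
roles:
  POPC: "lipid:POPC"
  POPE: "lipid:POPE"
  POPS: "lipid:POPS"
  POP2: "lipid:PIP2"
  PIP2: "lipid:PIP2"
  POP3: "lipid:PIP3"
  PIP3: "lipid:PIP3"
  W: solvent
  WF: solvent
  SOL: solvent
  HOH: solvent
  TIP3: solvent
  NA: other
  CL: other
  ION: other
# Head-group phosphate bead/atom names for PIP lipids; in addition any
# particle of a PIP lipid whose name starts with "P" is flagged.
pip_phosphate_names: [PO4, P1, P2, P3, P4, P5, P]
# Particle names treated as backbone for proteins.
backbone_names: [BB, CA]
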
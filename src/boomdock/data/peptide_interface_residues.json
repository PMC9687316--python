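{
  "comment": "BBM residues at the interface of each peptide-BBM docked complex (reported lists), with the docked pose id and the BBM fragment whose DNA-binding range applies.",
  "entries": [
    {"peptide": "P1", "pose": "dock16", "site": "frag1",
     "residues": ["ILE210", "TYR211", "LEU246", "GLY247", "TYR249", "LYS251", "GLU253", "LYS254", "ARG257", "ALA258", "LEU261", "ALA262", "PHE275"]},
    {"peptide": "P2", "pose": "dock89", "site": "frag1",
     "residues": ["ARG216", "TYR223", "ASP250", "LYS251", "GLU252", "GLU253", "LYS254", "ARG257", "PHE275", "PRO276"]},
    {"peptide": "P2", "pose": "dock10", "site": "frag1",
     "residues": ["ALA225", "TYR245", "LEU246", "GLY247", "GLY248", "TYR249", "GLU253", "LYS254", "ARG257", "ALA258", "TYR259", "LEU261"]},
    {"peptide": "P3", "pose": "dock49", "site": "frag2",
     "residues": ["VAL316", "THR317", "TRP325", "GLN326", "ALA327", "ARG328", "GLN346", "GLU347", "ALA350", "GLU351", "TYR353", "ASP354"]},
    {"peptide": "P4", "pose": "dock96", "site": "frag1",
     "residues": ["ARG222", "GLY248", "TYR249", "ASP250", "LYS251", "LYS254", "ALA255", "ARG257"]},
    {"peptide": "P5", "pose": "dock57", "site": "frag1",
     "residues": ["TYR249", "ASP250", "LYS251", "GLU253", "LYS254", "ARG257", "ALA258", "LEU261"]},
    {"peptide": "P6", "pose": "dock2", "site": "frag1",
     "residues": ["TYR249", "ASP250", "LYS251", "LYS254", "ARG257", "ALA258", "LEU261", "LEU264", "LYS265", "GLY268"]},
    {"peptide": "P7", "pose": "dock30", "site": "frag2",
     "residues": ["THR317", "TRP325", "GLU351", "ASP354", "VAL316", "GLN346", "TYR353", "ARG328", "ALA349", "ILE358", "ALA350", "ALA357"]}
  ]
}
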
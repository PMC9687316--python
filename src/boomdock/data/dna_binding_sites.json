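{
  "comment": "DNA-binding residue ranges of the two BBM fragments (AP2/ERF domains), author numbering, inclusive.",
  "frag1": [210, 276],
  "frag2": [312, 370]
}
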
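{
  "name": "contact-based linear binding-affinity model (interfacial contacts + non-interacting surface composition)",
  "version": "1.0",
  "temperature_K": 298.15,
  "contact_weights": {
    "cc": -0.09459,
    "ca": -0.10007,
    "cp": 0.0,
    "pp": 0.19577,
    "pa": -0.22671,
    "aa": 0.0
  },
  "nis_weights": {
    "apolar": 0.18681,
    "charged": 0.1381
  },
  "intercept": -15.9433,
  "classes": {
    "charged": ["D", "E", "K", "R"],
    "polar": ["C", "H", "N", "Q", "S", "T", "W", "Y"],
    "apolar": ["A", "F", "G", "I", "L", "M", "P", "V"]
  },
  "nis_rel_sasa_threshold": 0.05,
  "max_asa": {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0
  }
}
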
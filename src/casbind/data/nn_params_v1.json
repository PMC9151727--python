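{
 "dna_dna": {
  "d-:dA|dA:dT": 2.0,
  "d-:dA|dC:dG": 2.0,
  "d-:dA|dG:dC": 2.0,
  "d-:dA|dT:dA": 2.0,
  "d-:dC|dA:dT": 2.0,
  "d-:dC|dC:dG": 2.0,
  "d-:dC|dG:dC": 2.0,
  "d-:dC|dT:dA": 2.0,
  "d-:dG|dA:dT": 2.0,
  "d-:dG|dC:dG": 2.0,
  "d-:dG|dG:dC": 2.0,
  "d-:dG|dT:dA": 2.0,
  "d-:dT|dA:dT": 2.0,
  "d-:dT|dC:dG": 2.0,
  "d-:dT|dG:dC": 2.0,
  "d-:dT|dT:dA": 2.0,
  "dA:d-|dA:dT": 2.0,
  "dA:d-|dC:dG": 2.0,
  "dA:d-|dG:dC": 2.0,
  "dA:d-|dT:dA": 2.0,
  "dA:dT|d-:dA": 2.0,
  "dA:dT|d-:dC": 2.0,
  "dA:dT|d-:dG": 2.0,
  "dA:dT|d-:dT": 2.0,
  "dA:dT|dA:d-": 2.0,
  "dA:dT|dA:dT": -1.0,
  "dA:dT|dC:d-": 2.0,
  "dA:dT|dC:dG": -1.44,
  "dA:dT|dG:d-": 2.0,
  "dA:dT|dG:dC": -1.28,
  "dA:dT|dT:d-": 2.0,
  "dA:dT|dT:dA": -0.88,
  "dC:d-|dA:dT": 2.0,
  "dC:d-|dC:dG": 2.0,
  "dC:d-|dG:dC": 2.0,
  "dC:d-|dT:dA": 2.0,
  "dC:dG|d-:dA": 2.0,
  "dC:dG|d-:dC": 2.0,
  "dC:dG|d-:dG": 2.0,
  "dC:dG|d-:dT": 2.0,
  "dC:dG|dA:d-": 2.0,
  "dC:dG|dA:dT": -1.45,
  "dC:dG|dC:d-": 2.0,
  "dC:dG|dC:dG": -1.84,
  "dC:dG|dG:d-": 2.0,
  "dC:dG|dG:dC": -2.17,
  "dC:dG|dT:d-": 2.0,
  "dC:dG|dT:dA": -1.28,
  "dG:d-|dA:dT": 2.0,
  "dG:d-|dC:dG": 2.0,
  "dG:d-|dG:dC": 2.0,
  "dG:d-|dT:dA": 2.0,
  "dG:dC|d-:dA": 2.0,
  "dG:dC|d-:dC": 2.0,
  "dG:dC|d-:dG": 2.0,
  "dG:dC|d-:dT": 2.0,
  "dG:dC|dA:d-": 2.0,
  "dG:dC|dA:dT": -1.3,
  "dG:dC|dC:d-": 2.0,
  "dG:dC|dC:dG": -2.24,
  "dG:dC|dG:d-": 2.0,
  "dG:dC|dG:dC": -1.84,
  "dG:dC|dT:d-": 2.0,
  "dG:dC|dT:dA": -1.44,
  "dT:d-|dA:dT": 2.0,
  "dT:d-|dC:dG": 2.0,
  "dT:d-|dG:dC": 2.0,
  "dT:d-|dT:dA": 2.0,
  "dT:dA|d-:dA": 2.0,
  "dT:dA|d-:dC": 2.0,
  "dT:dA|d-:dG": 2.0,
  "dT:dA|d-:dT": 2.0,
  "dT:dA|dA:d-": 2.0,
  "dT:dA|dA:dT": -0.58,
  "dT:dA|dC:d-": 2.0,
  "dT:dA|dC:dG": -1.3,
  "dT:dA|dG:d-": 2.0,
  "dT:dA|dG:dC": -1.45,
  "dT:dA|dT:d-": 2.0,
  "dT:dA|dT:dA": -1.0
 },
 "pam_factor": {
  "NGG": 1.0
 },
 "rna_dna": {
  "rA:dT|rA:dT": -1.0,
  "rA:dT|rC:dG": -2.1,
  "rA:dT|rG:dC": -1.8,
  "rA:dT|rU:dA": -0.9,
  "rC:dG|rA:dT": -0.9,
  "rC:dG|rC:dG": -2.1,
  "rC:dG|rG:dC": -1.7,
  "rC:dG|rU:dA": -0.9,
  "rG:dC|rA:dT": -1.3,
  "rG:dC|rC:dG": -2.7,
  "rG:dC|rG:dC": -2.9,
  "rG:dC|rU:dA": -1.1,
  "rU:dA|rA:dT": -0.6,
  "rU:dA|rC:dG": -1.5,
  "rU:dA|rG:dC": -1.6,
  "rU:dA|rU:dA": -0.2
 },
 "rna_rna": {
  "r-:rA|rA:rU": 1.9,
  "r-:rA|rC:rG": 1.9,
  "r-:rA|rG:rC": 1.9,
  "r-:rA|rU:rA": 1.9,
  "r-:rC|rA:rU": 1.9,
  "r-:rC|rC:rG": 1.9,
  "r-:rC|rG:rC": 1.9,
  "r-:rC|rU:rA": 1.9,
  "r-:rG|rA:rU": 1.9,
  "r-:rG|rC:rG": 1.9,
  "r-:rG|rG:rC": 1.9,
  "r-:rG|rU:rA": 1.9,
  "r-:rU|rA:rU": 1.9,
  "r-:rU|rC:rG": 1.9,
  "r-:rU|rG:rC": 1.9,
  "r-:rU|rU:rA": 1.9,
  "rA:r-|rA:rU": 1.9,
  "rA:r-|rC:rG": 1.9,
  "rA:r-|rG:rC": 1.9,
  "rA:r-|rU:rA": 1.9,
  "rA:rU|r-:rA": 1.9,
  "rA:rU|r-:rC": 1.9,
  "rA:rU|r-:rG": 1.9,
  "rA:rU|r-:rU": 1.9,
  "rA:rU|rA:r-": 1.9,
  "rA:rU|rA:rU": -0.93,
  "rA:rU|rC:r-": 1.9,
  "rA:rU|rC:rG": -2.24,
  "rA:rU|rG:r-": 1.9,
  "rA:rU|rG:rC": -2.08,
  "rA:rU|rU:r-": 1.9,
  "rA:rU|rU:rA": -1.1,
  "rC:r-|rA:rU": 1.9,
  "rC:r-|rC:rG": 1.9,
  "rC:r-|rG:rC": 1.9,
  "rC:r-|rU:rA": 1.9,
  "rC:rG|r-:rA": 1.9,
  "rC:rG|r-:rC": 1.9,
  "rC:rG|r-:rG": 1.9,
  "rC:rG|r-:rU": 1.9,
  "rC:rG|rA:r-": 1.9,
  "rC:rG|rA:rU": -2.11,
  "rC:rG|rC:r-": 1.9,
  "rC:rG|rC:rG": -3.26,
  "rC:rG|rG:r-": 1.9,
  "rC:rG|rG:rC": -2.36,
  "rC:rG|rU:r-": 1.9,
  "rC:rG|rU:rA": -2.08,
  "rG:r-|rA:rU": 1.9,
  "rG:r-|rC:rG": 1.9,
  "rG:r-|rG:rC": 1.9,
  "rG:r-|rU:rA": 1.9,
  "rG:rC|r-:rA": 1.9,
  "rG:rC|r-:rC": 1.9,
  "rG:rC|r-:rG": 1.9,
  "rG:rC|r-:rU": 1.9,
  "rG:rC|rA:r-": 1.9,
  "rG:rC|rA:rU": -2.35,
  "rG:rC|rC:r-": 1.9,
  "rG:rC|rC:rG": -3.42,
  "rG:rC|rG:r-": 1.9,
  "rG:rC|rG:rC": -3.26,
  "rG:rC|rU:r-": 1.9,
  "rG:rC|rU:rA": -2.24,
  "rU:r-|rA:rU": 1.9,
  "rU:r-|rC:rG": 1.9,
  "rU:r-|rG:rC": 1.9,
  "rU:r-|rU:rA": 1.9,
  "rU:rA|r-:rA": 1.9,
  "rU:rA|r-:rC": 1.9,
  "rU:rA|r-:rG": 1.9,
  "rU:rA|r-:rU": 1.9,
  "rU:rA|rA:r-": 1.9,
  "rU:rA|rA:rU": -1.33,
  "rU:rA|rC:r-": 1.9,
  "rU:rA|rC:rG": -2.35,
  "rU:rA|rG:r-": 1.9,
  "rU:rA|rG:rC": -2.11,
  "rU:rA|rU:r-": 1.9,
  "rU:rA|rU:rA": -0.93
 },
 "rt": 0.61633,
 "version": "casbind-nn-1",
 "weights": [
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0
 ],
 "weights_version": "uniform-1.0"
}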
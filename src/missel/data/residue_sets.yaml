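# Bundled residue-set definitions for the NOTCH1/NOTCH2 EGF11-12 analyses.
# Protein coordinates (UniProt numbering of the receptor).
notch1_interface:
  provenance: "Ligand-binding interface residues of NOTCH1 EGF11-12 (structural mapping of the NOTCH1-Jagged1 interface)"
  residues: [413, 415, 418, 420, 421, 422, 423, 424, 425, 435, 436, 444, 447,
             448, 450, 451, 452, 454, 466, 467, 468, 469, 470, 471, 475, 477,
             478, 479, 480]
notch2_interface:
  provenance: "Ligand-binding interface residues of NOTCH2 EGF11-12 (NOTCH2-Jagged1 complex)"
  residues: [418, 421, 424, 425, 426, 428, 429, 439, 440, 452, 454, 456, 470,
             472, 473, 481]
notch1_calcium:
  provenance: "Calcium-binding residues of NOTCH1 EGF11-12 (MetalPDB, structure 2VJ3)"
  residues: [412, 413, 415, 431, 432, 435, 452, 453, 455, 469, 470]
notch2_calcium:
  provenance: "Calcium-binding residues of NOTCH2 EGF11-12 (MetalPDB, structure 5MWB)"
  residues: [415, 416, 418, 435, 436, 439, 456, 457, 459, 473, 474]
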
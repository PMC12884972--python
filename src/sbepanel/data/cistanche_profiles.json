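{
  "comment": "Reference-orientation alleles per assay. The two pharmacopeial species carry full composite profiles observed on authenticated genomic DNA; the six adulterants carry their designed diagnostic alleles.",
  "profiles": {
    "C. deserticola": {
      "Cd-1": "A",
      "Cd-2": "A",
      "CdITS-1": "T",
      "CdITS-2": "C",
      "Ct-1": "G",
      "Ct-2": "G",
      "Csi-1": "A",
      "Csi-2": "A",
      "Csa-1": "G",
      "Csa-2": "T"
    },
    "C. tubulosa": {
      "CdITS-1": "C",
      "Ct-1": "A",
      "Ct-2": "A",
      "Csi-1": "A",
      "Csi-2": "A",
      "Csa-1": "G",
      "Csa-2": "T",
      "CroITS": "C",
      "CriITS": "G"
    },
    "C. salsa": {
      "Csa-1": "A",
      "Csa-2": "C"
    },
    "C. sinensis": {
      "Csi-1": "G",
      "Csi-2": "C"
    },
    "C. phelypaea": {
      "CpITS": "T"
    },
    "C. ambigua": {
      "CaITS": "C"
    },
    "C. rosea": {
      "CroITS": "T"
    },
    "C. ridgewayana": {
      "CriITS": "A"
    }
  },
  "rules": {
    "C. deserticola": {
      "CdITS-2": "C",
      "Cd-2": "A",
      "Cd-1": "A",
      "CdITS-1": "T"
    },
    "C. tubulosa": {
      "Ct-1": "A",
      "Ct-2": "A"
    },
    "C. salsa": {
      "Csa-1": "A",
      "Csa-2": "C"
    },
    "C. sinensis": {
      "Csi-1": "G",
      "Csi-2": "C"
    },
    "C. phelypaea": {
      "CpITS": "T"
    },
    "C. ambigua": {
      "CaITS": "C"
    },
    "C. rosea": {
      "CroITS": "T"
    },
    "C. ridgewayana": {
      "CriITS": "A"
    }
  }
}
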
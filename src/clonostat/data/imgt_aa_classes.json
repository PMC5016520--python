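{
  "_note": "IMGT classes of the 20 common amino acids, transcribed from the published IMGT definitions (Pommie et al., J Mol Recognit 2004). Editable: correct memberships here without code changes. The 'physicochemical' scheme is shipped as the identity over the 20 amino acids (each residue its own class) pending curation of the combined scheme; edit to group residues if a combined definition is preferred. The 'AA' scheme is always the identity and is not listed here.",
  "hydropathy": {
    "hydrophobic": "ACFILMVW",
    "neutral": "GHPSTY",
    "hydrophilic": "DEKNQR"
  },
  "volume": {
    "very_small": "AGS",
    "small": "CDNPT",
    "medium": "EHQV",
    "large": "IKLMR",
    "very_large": "FWY"
  },
  "chemical": {
    "aliphatic": "AGILPV",
    "aromatic": "FWY",
    "sulfur": "CM",
    "hydroxyl": "ST",
    "basic": "HKR",
    "acidic": "DE",
    "amide": "NQ"
  },
  "charge": {
    "positive": "HKR",
    "negative": "DE",
    "uncharged": "ACFGILMNPQSTVWY"
  },
  "hydrogen": {
    "donor": "KRW",
    "acceptor": "DE",
    "donor_and_acceptor": "HNQSTY",
    "none": "ACFGILMPV"
  },
  "polarity": {
    "polar": "DEHKNQRSTY",
    "nonpolar": "ACFGILMPVW"
  },
  "physicochemical": {
    "A": "A", "C": "C", "D": "D", "E": "E", "F": "F",
    "G": "G", "H": "H", "I": "I", "K": "K", "L": "L",
    "M": "M", "N": "N", "P": "P", "Q": "Q", "R": "R",
    "S": "S", "T": "T", "V": "V", "W": "W", "Y": "Y"
  }
}
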
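"""Numeric lookup tables shared by the scoring modules.

Contents:

* the Fickett (1982) TESTCODE position/content probability tables, as bundled
  by CPAT-style coding-potential scorers;
* a GC3-biased codon-usage table used by the simulator to write realistic
  open reading frames (grass genomes favour G/C in the wobble position);
* RNA/RNA dinucleotide stacking free energies for the hybridization scorer.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Fickett TESTCODE tables (Fickett, NAR 1982).  A position or content value is
# mapped to the probability at the first threshold it meets or exceeds.
# ---------------------------------------------------------------------------

FICKETT_POSITION_THRESHOLDS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

FICKETT_POSITION_PROBABILITIES = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}

FICKETT_POSITION_WEIGHTS = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

FICKETT_CONTENT_THRESHOLDS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]

FICKETT_CONTENT_PROBABILITIES = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}

FICKETT_CONTENT_WEIGHTS = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


# ---------------------------------------------------------------------------
# Codon usage for the simulator.  Relative weights within each amino acid;
# GC-ending codons are preferred, as in wheat and other Poaceae.
# ---------------------------------------------------------------------------

CODON_USAGE = {
    # Ala
    "GCC": 0.40, "GCG": 0.30, "GCT": 0.20, "GCA": 0.10,
    # Arg
    "CGC": 0.30, "CGG": 0.25, "AGG": 0.20, "CGT": 0.10, "AGA": 0.08, "CGA": 0.07,
    # Asn
    "AAC": 0.70, "AAT": 0.30,
    # Asp
    "GAC": 0.65, "GAT": 0.35,
    # Cys
    "TGC": 0.70, "TGT": 0.30,
    # Gln
    "CAG": 0.70, "CAA": 0.30,
    # Glu
    "GAG": 0.70, "GAA": 0.30,
    # Gly
    "GGC": 0.40, "GGG": 0.25, "GGT": 0.20, "GGA": 0.15,
    # His
    "CAC": 0.65, "CAT": 0.35,
    # Ile
    "ATC": 0.55, "ATT": 0.30, "ATA": 0.15,
    # Leu
    "CTC": 0.30, "CTG": 0.30, "CTT": 0.15, "TTG": 0.10, "CTA": 0.08, "TTA": 0.07,
    # Lys
    "AAG": 0.75, "AAA": 0.25,
    # Met
    "ATG": 1.00,
    # Phe
    "TTC": 0.65, "TTT": 0.35,
    # Pro
    "CCG": 0.35, "CCC": 0.30, "CCT": 0.20, "CCA": 0.15,
    # Ser
    "AGC": 0.30, "TCC": 0.25, "TCG": 0.20, "TCT": 0.10, "AGT": 0.08, "TCA": 0.07,
    # Thr
    "ACC": 0.40, "ACG": 0.25, "ACT": 0.20, "ACA": 0.15,
    # Trp
    "TGG": 1.00,
    # Tyr
    "TAC": 0.65, "TAT": 0.35,
    # Val
    "GTC": 0.35, "GTG": 0.35, "GTT": 0.20, "GTA": 0.10,
}

STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# RNA/RNA nearest-neighbor stacking free energies, kcal/mol at 37 degC.
#
# Watson-Crick stacks are the ten unique parameters of Xia et al.,
# Biochemistry 37:14719 (1998).  A stack "XY/WZ" is the duplex
#     5'-X Y-3'
#     3'-W Z-5'
# i.e. X pairs W and Y pairs Z.  Stacks involving a G:U wobble pair are
# approximated as 0.55x the mean of the Watson-Crick stacks obtained by
# substituting the wobble with either of its canonical neighbours (a smooth
# stand-in for the Mathews et al. 1999 wobble parameters; see docs/methods.md).
# ---------------------------------------------------------------------------

WC_STACKS_RNA = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}

WOBBLE_SCALE = 0.55
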
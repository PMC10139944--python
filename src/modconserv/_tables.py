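"""Shared amino-acid tables: alphabets, physicochemical groupings, background frequencies.

The BLOSUM62 substitution matrix itself is taken from Biopython
(``Bio.Align.substitution_matrices``); this module holds the small derived
tables the scoring and statistics code needs everywhere.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard amino acids in canonical alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Symbols treated as gaps for gap-fraction and gap-penalty purposes:
#: the alignment gap character plus the ambiguous codes X, B, Z.
GAP_SYMBOLS: frozenset[str] = frozenset("XBZ-")

#: Full residue alphabet accepted in alignment rows.
ALIGNMENT_ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS) | GAP_SYMBOLS

#: Stereochemical groups: residues within one group are interchangeable for
#: the stereochemically sensitive entropy score.
STEREO_GROUPS: tuple[tuple[str, ...], ...] = (
    ("V", "L", "I", "M"),
    ("F", "W", "Y"),
    ("S", "T"),
    ("N", "Q"),
    ("H", "K", "R"),
    ("D", "E"),
    ("A", "G"),
    ("P",),
    ("C",),
)

STEREO_GROUP_OF: dict[str, int] = {
    aa: gi for gi, group in enumerate(STEREO_GROUPS) for aa in group
}

#: Chemical classes used to stratify the chemical-similarity window average.
CHEMICAL_CLASSES: dict[str, tuple[str, ...]] = {
    "aliphatic": ("G", "A", "V", "L", "I", "M", "P"),
    "aromatic": ("F", "Y", "W"),
    "polar_uncharged": ("S", "T", "C", "N", "Q"),
    "acidic": ("E", "D"),
    "basic": ("K", "R", "H"),
}

CHEMICAL_CLASS_OF: dict[str, str] = {
    aa: cls for cls, members in CHEMICAL_CLASSES.items() for aa in members
}

#: Modification types retained for analysis; rarer noncanonical events are dropped.
MODIFICATION_TYPES: frozenset[str] = frozenset(
    {
        "phosphorylation",
        "ubiquitylation",
        "monoacetylation",
        "N-glycosylation",
        "succinylation",
    }
)

# BLOSUM62 amino-acid background frequencies (the marginal distribution the
# matrix was built against), as popularized by the divergence-based
# conservation-scoring literature.  Indexed here in AMINO_ACIDS order and
# renormalized so the vector sums to exactly 1.
_BLOSUM62_BACKGROUND_RAW: dict[str, float] = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}

_bg = np.array([_BLOSUM62_BACKGROUND_RAW[aa] for aa in AMINO_ACIDS], dtype=float)
BLOSUM62_BACKGROUND: np.ndarray = _bg / _bg.sum()
BLOSUM62_BACKGROUND.setflags(write=False)
del _bg


def load_substitution_matrix(name: str = "BLOSUM62"):
    """Load a named substitution matrix (e.g. BLOSUM62, PAM30) from Biopython."""
    return substitution_matrices.load(name)


def substitution_lookup(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Return the matrix as a plain symmetric dict keyed by residue pairs."""
    mat = load_substitution_matrix(name)
    alpha = mat.alphabet
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(alpha):
        for j, b in enumerate(alpha):
            out[(a, b)] = float(mat[i, j])
    return out
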
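"""Sequence alphabet helpers shared across modules.

Sequences are aligned COI barcode fragments over the IUPAC DNA alphabet
plus the gap character ``-``.  For distance work every site that is not an
unambiguous A/C/G/T in *both* members of a pair is deleted pairwise, so the
numeric encoding collapses gaps, N and all partial ambiguity codes into a
single "missing" state.
"""

from __future__ import annotations

import numpy as np

#: full legal alphabet for aligned barcode sequences
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: unambiguous bases
BASES = "ACGT"

#: ambiguity codes (anything that is not a plain base or a gap)
AMBIGUITY = set("RYSWKMBDHVN")

#: numeric code used for every non-ACGT character
MISSING = 4

_CODE_TABLE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_TABLE[ord(_b)] = _i

#: IUPAC ambiguity code -> set of compatible bases (used by haplotype collapsing)
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: transition partner of each base (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: transversion alternatives of each base
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def encode(sequence: str) -> np.ndarray:
    """Encode an aligned sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def encode_matrix(sequences: list[str]) -> np.ndarray:
    """Stack encoded sequences into an ``(n, L)`` uint8 matrix."""
    if not sequences:
        return np.empty((0, 0), dtype=np.uint8)
    return np.vstack([encode(s) for s in sequences])


def informative_length(sequence: str) -> int:
    """Number of non-gap, non-N characters (the 'informative' fragment length).

    Partial ambiguity codes (R, Y, ...) still represent a sequenced position
    and count toward length; they are only excluded from composition and
    distance computation.
    """
    return sum(1 for c in sequence if c not in "-N")


def is_purine_pyrimidine_code(codes: np.ndarray) -> np.ndarray:
    """Boolean array: True where the encoded base is a purine (A or G)."""
    return (codes == 0) | (codes == 2)
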
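"""The 20-residue alphabet and the row order of the residue adjacency matrix.

Rows of the adjacency matrix are ordered alphabetically by *full* amino-acid
name (Alanine, Arginine, ..., Valine), which places Alanine in row 1 and
Tyrosine in row 19.  Note this differs from ordering by one-letter code
(which would put Tyrosine last but one before Valine only by accident of
the alphabet); the full-name order is the fixed convention throughout.
"""

from __future__ import annotations

#: Residues ordered alphabetically by full amino-acid name.
RESIDUE_ORDER: tuple[str, ...] = tuple("ARNDCEQGHILKMFPSTWYV")

FULL_NAMES: dict[str, str] = {
    "A": "Alanine",
    "R": "Arginine",
    "N": "Asparagine",
    "D": "Aspartic acid",
    "C": "Cysteine",
    "E": "Glutamic acid",
    "Q": "Glutamine",
    "G": "Glycine",
    "H": "Histidine",
    "I": "Isoleucine",
    "L": "Leucine",
    "K": "Lysine",
    "M": "Methionine",
    "F": "Phenylalanine",
    "P": "Proline",
    "S": "Serine",
    "T": "Threonine",
    "W": "Tryptophan",
    "Y": "Tyrosine",
    "V": "Valine",
}

#: Standard one-letter codes.
STANDARD_RESIDUES: frozenset[str] = frozenset(RESIDUE_ORDER)

#: Accepted but non-standard codes (ambiguity codes and the rare
#: selenocysteine / pyrrolysine letters).  They occupy sequence positions
#: but contribute to no adjacency-matrix row.
NONSTANDARD_RESIDUES: frozenset[str] = frozenset("XBZUO")

_ROW_INDEX = {res: i for i, res in enumerate(RESIDUE_ORDER)}


def row_index(residue: str) -> int:
    """Zero-based adjacency-matrix row of a standard residue code."""
    try:
        return _ROW_INDEX[residue]
    except KeyError:
        raise ValueError(f"not a standard residue code: {residue!r}") from None


def in_alphabet_order(residues) -> tuple[str, ...]:
    """Sort a collection of standard residue codes into row order."""
    rs = tuple(residues)
    for r in rs:
        row_index(r)
    if len(set(rs)) != len(rs):
        raise ValueError("duplicate residue codes")
    return tuple(sorted(rs, key=row_index))
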
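"""Di/tri-peptide ligand enumeration and peptide-to-SMILES construction.

Short peptides (2-3 residues) cross the intestinal barrier far more readily
than longer ones, so the candidate peptides selected by the occurrence scan
are decomposed into their short bioactive constituents before target
prediction and ADMET profiling. Those constituents are then rendered as
SMILES strings for the cheminformatics tools.

SMILES are assembled by concatenating per-residue template blocks N-to-C:
a free (neutral) N-terminal amine, amide backbone links, and a C-terminal
carboxylic acid. Proline's backbone nitrogen is part of its pyrrolidine
ring, so its block opens the ring on the nitrogen (``N1[C@@H](CCC1)C(=O)``)
and works unchanged at the N-terminus and internally. Every chiral
alpha-carbon is written with a single consistent L-configuration tag;
glycine has no stereocentre. Assembly is pure string concatenation, so the
module needs no chemistry toolkit at run time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ValidationError
from .fragment_library import FragmentLibrary
from .survey_io import validate_sequence


@dataclass(frozen=True)
class ResidueTemplate:
    """SMILES building block for one amino acid.

    ``side_chain`` is the substituent on the alpha-carbon (empty for
    glycine). Ring-bond numbers inside a side chain close within the block,
    so blocks can be concatenated freely.
    """

    code: str
    side_chain: str
    is_proline_like: bool = False
    stereo_tag: str = "L"  # "L" or "achiral"


#: Templates for the 20 standard residues (neutral side chains).
RESIDUE_TEMPLATES: dict[str, ResidueTemplate] = {
    "A": ResidueTemplate("A", "C"),
    "R": ResidueTemplate("R", "CCCNC(=N)N"),
    "N": ResidueTemplate("N", "CC(N)=O"),
    "D": ResidueTemplate("D", "CC(O)=O"),
    "C": ResidueTemplate("C", "CS"),
    "E": ResidueTemplate("E", "CCC(O)=O"),
    "Q": ResidueTemplate("Q", "CCC(N)=O"),
    "G": ResidueTemplate("G", "", stereo_tag="achiral"),
    "H": ResidueTemplate("H", "Cc1c[nH]cn1"),
    "I": ResidueTemplate("I", "[C@@H](CC)C"),
    "L": ResidueTemplate("L", "CC(C)C"),
    "K": ResidueTemplate("K", "CCCCN"),
    "M": ResidueTemplate("M", "CCSC"),
    "F": ResidueTemplate("F", "Cc1ccccc1"),
    "P": ResidueTemplate("P", "CCC", is_proline_like=True),
    "S": ResidueTemplate("S", "CO"),
    "T": ResidueTemplate("T", "[C@H](O)C"),
    "W": ResidueTemplate("W", "Cc1c[nH]c2c1cccc2"),
    "Y": ResidueTemplate("Y", "Cc1ccc(O)cc1"),
    "V": ResidueTemplate("V", "C(C)C"),
}


def residue_block(code: str) -> str:
    """The ``N...C(=O)`` SMILES block for one residue."""
    try:
        tpl = RESIDUE_TEMPLATES[code]
    except KeyError:
        raise ValidationError(f"no residue template for {code!r}") from None
    if tpl.is_proline_like:
        # Backbone N opens the pyrrolidine ring; the side chain closes it.
        return f"N1[C@@H]({tpl.side_chain}1)C(=O)"
    if tpl.stereo_tag == "achiral":
        return "NCC(=O)"
    return f"N[C@@H]({tpl.side_chain})C(=O)"


def peptide_to_smiles(sequence: str) -> str:
    """SMILES for a linear peptide, written N-terminus to C-terminus.

    The N-terminal amine is free (non-zwitterionic) and the C-terminus is a
    carboxylic acid. Output is deterministic: the same sequence always gives
    the same string.
    """
    seq = validate_sequence(sequence)
    return "".join(residue_block(code) for code in seq) + "O"


def enumerate_bioactive_fragments(
    parent: str, library: FragmentLibrary, max_len: int = 3
) -> frozenset[str]:
    """Distinct library fragments of length <= max_len occurring in ``parent``.

    This is the candidate ligand set forwarded to target prediction and
    ADMET profiling.
    """
    seq = validate_sequence(parent)
    if max_len < 2:
        raise ValidationError(f"max_len must be >= 2, got {max_len}")
    found = set()
    for frag in library.fragments:
        if len(frag) <= max_len and frag in seq:
            found.add(frag)
    return frozenset(found)


def fragments_to_smiles(fragments: Iterable[str]) -> dict[str, str]:
    """SMILES for each fragment, keyed by sequence (sorted, deterministic)."""
    return {
        frag: peptide_to_smiles(frag)
        for frag in sorted(set(fragments), key=lambda f: (len(f), f))
    }
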
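"""Structure parsing, canonicalization and monoisotopic-mass computation.

Every other stage of the workflow talks about metabolites through this
module: structures are held as RDKit molecules, identity is a stereo-blind
canonical SMILES key, and masses are neutral monoisotopic masses computed
from a fixed isotope table covering the elements that occur in metabolomes.
"""

from __future__ import annotations

import warnings
from typing import Dict

from rdkit import Chem, RDLogger
from rdkit.Chem import Mol

# RDKit's parse diagnostics go through our own exceptions instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "StructureParseError",
    "UnsupportedElementError",
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "parse_structure",
    "canonical_key",
    "molecular_formula",
    "formula_string",
    "monoisotopic_mass",
    "neutralize_charges",
    "heavy_atom_count",
]


class StructureParseError(ValueError):
    """A line-notation string could not be parsed into a valid structure."""


class UnsupportedElementError(ValueError):
    """The molecule contains an element outside the supported mass table."""


#: Monoisotopic (most abundant isotope) masses in Da, IUPAC values.
#: Restricted to elements with appreciable metabolome coverage; anything
#: else is rejected loudly rather than silently mis-weighed.
MONOISOTOPIC_MASSES: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "F": 18.9984032,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "Se": 73.9224766,
    "I": 126.904468,
}

#: Mass of a proton in Da (for adduct arithmetic downstream).
PROTON_MASS = 1.007276466


def parse_structure(smiles: str) -> Mol:
    """Parse a SMILES string into a sanitized molecule.

    Aromaticity is perceived and implicit hydrogens assigned by the
    sanitization pass. Multi-fragment (dot-separated) inputs are allowed.

    Raises
    ------
    StructureParseError
        If the string is empty or not valid SMILES; the message names the
        offending input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureParseError("empty structure string")
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        raise StructureParseError(f"unparsable structure string: {smiles!r}")
    return mol


def canonical_key(mol: Mol, strip_stereo: bool = True) -> str:
    """Stable canonical identity string for a structure.

    With ``strip_stereo`` (the default) the key identifies the constitution
    only: two stereoisomers collapse to one key, which is the convention
    used for deduplicating derivatives and for mass matching. The key is an
    internal identity; it is never meant to be compared across software
    versions.
    """
    work = Chem.Mol(mol)
    if strip_stereo:
        Chem.RemoveStereochemistry(work)
    for atom in work.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(work, canonical=True)


def molecular_formula(mol: Mol) -> Dict[str, int]:
    """Element → count map, including implicit and explicit hydrogens."""
    counts: Dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        nh = atom.GetTotalNumHs()
        if nh:
            counts["H"] = counts.get("H", 0) + nh
    return counts


def formula_string(mol: Mol) -> str:
    """Hill-order molecular formula (C first, H second, rest alphabetical)."""
    counts = molecular_formula(mol)
    parts = []
    for sym in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
        if sym in counts:
            n = counts[sym]
            parts.append(sym + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(mol: Mol) -> float:
    """Neutral monoisotopic mass in Da.

    Sums the most-abundant-isotope mass over every atom, including implicit
    hydrogens. The molecule is treated as the neutral species; charged
    inputs should be passed through :func:`neutralize_charges` first.
    """
    if mol.GetNumAtoms() == 0:
        raise ValueError("cannot compute the mass of an empty molecule")
    total = 0.0
    for sym, count in molecular_formula(mol).items():
        try:
            total += MONOISOTOPIC_MASSES[sym] * count
        except KeyError:
            raise UnsupportedElementError(
                f"element {sym!r} is outside the supported mass table "
                f"({sorted(MONOISOTOPIC_MASSES)})"
            ) from None
    return total


def neutralize_charges(mol: Mol) -> Mol:
    """Normalize protonation state to the neutral species where achievable.

    Protonates −1 oxyanions (and other deprotonated heteroatoms) and
    deprotonates +1 protonated amines. Permanent charges — e.g. quaternary
    nitrogen with no proton to remove — are left untouched with a warning.
    Idempotent: applying twice equals applying once.
    """
    # +1 atoms that carry a proton and -1 atoms not balancing an adjacent
    # cation (avoids breaking ylides / nitro groups written charge-separated).
    pattern = Chem.MolFromSmarts(
        "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
    )
    work = Chem.Mol(mol)
    matches = [idx for (idx,) in work.GetSubstructMatches(pattern)]
    for idx in matches:
        atom = work.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        n_h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(n_h - charge)
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(work)
    net = sum(a.GetFormalCharge() for a in work.GetAtoms())
    if net != 0:
        warnings.warn(
            f"structure retains a permanent net charge of {net:+d} after "
            "neutralization",
            stacklevel=2,
        )
    return work


def heavy_atom_count(mol: Mol) -> int:
    """Number of non-hydrogen atoms."""
    return mol.GetNumHeavyAtoms()
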
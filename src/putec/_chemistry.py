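"""Heavy-atom donor/acceptor chemistry for proteins and nucleic acids.

Deposited cryo-EM models carry no hydrogens, so hydrogen bonds are
identified from heavy-atom donor/acceptor pairs with a distance cutoff
and, where an acceptor antecedent exists, an angular criterion.  The
tables below cover protein backbone and side chains plus RNA/DNA bases,
riboses and phosphates.
"""

from __future__ import annotations

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

RNA_RESIDUES = {"A", "C", "G", "U", "I"}
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DU", "DI"}
NA_RESIDUES = RNA_RESIDUES | DNA_RESIDUES


def base_code(residue_name: str) -> str | None:
    """One-letter base code of an RNA/DNA residue name, else None."""
    rn = residue_name.strip().upper()
    if rn in RNA_RESIDUES:
        return rn
    if rn in DNA_RESIDUES:
        return rn[1]
    return None


# --- hydrogen bonding -------------------------------------------------------
# donors: heavy atoms carrying a polar hydrogen; acceptors: lone-pair
# bearers.  Acceptor antecedents serve the donor-acceptor-antecedent
# angle check (>= 90 degrees).

PROTEIN_DONORS = {
    "*": {"N"},  # backbone amide (except proline, handled by caller cheaply)
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}

PROTEIN_ACCEPTORS = {
    "*": {"O": "C", "OXT": "C"},  # atom -> antecedent
    "ASN": {"OD1": "CG"},
    "ASP": {"OD1": "CG", "OD2": "CG"},
    "GLN": {"OE1": "CD"},
    "GLU": {"OE1": "CD", "OE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "MET": {"SD": "CG"},
}

# sugar-phosphate moiety, shared by all nucleotides
NA_BACKBONE_DONORS = {"O2'"}
NA_BACKBONE_ACCEPTORS = {
    "OP1": "P", "OP2": "P", "O1P": "P", "O2P": "P",
    "O5'": "P", "O3'": "C3'", "O4'": "C4'", "O2'": "C2'",
}

BASE_DONORS = {
    "A": {"N6"},
    "G": {"N1", "N2"},
    "C": {"N4"},
    "U": {"N3"},
    "T": {"N3"},
}

BASE_ACCEPTORS = {
    "A": {"N1": "C6", "N3": "C2", "N7": "C5"},
    "G": {"O6": "C6", "N3": "C2", "N7": "C5"},
    "C": {"O2": "C2", "N3": "C2"},
    "U": {"O2": "C2", "O4": "C4"},
    "T": {"O2": "C2", "O4": "C4"},
}

#: base atoms on the Watson-Crick edge, used to call canonical pairs
WC_EDGE_ATOMS = {
    "A": {"N1", "N6"},
    "G": {"N1", "N2", "O6"},
    "C": {"N3", "N4", "O2"},
    "U": {"N3", "O2", "O4"},
    "T": {"N3", "O2", "O4"},
}


def donor_atoms(residue_name: str) -> set[str]:
    rn = residue_name.strip().upper()
    if rn in PROTEIN_RESIDUES:
        out = set() if rn == "PRO" else set(PROTEIN_DONORS["*"])
        out |= PROTEIN_DONORS.get(rn, set())
        return out
    code = base_code(rn)
    if code is not None:
        out = set(BASE_DONORS.get(code, set()))
        if rn in RNA_RESIDUES:
            out |= NA_BACKBONE_DONORS
        return out
    return set()


def acceptor_atoms(residue_name: str) -> dict[str, str | None]:
    """Map acceptor atom name -> antecedent atom name (or None)."""
    rn = residue_name.strip().upper()
    if rn in PROTEIN_RESIDUES:
        out: dict[str, str | None] = dict(PROTEIN_ACCEPTORS["*"])
        out.update(PROTEIN_ACCEPTORS.get(rn, {}))
        return out
    code = base_code(rn)
    if code is not None:
        out = dict(NA_BACKBONE_ACCEPTORS)
        if rn in DNA_RESIDUES:
            out.pop("O2'", None)
        out.update(BASE_ACCEPTORS.get(code, {}))
        return out
    return {}


# --- charged groups and aromatic rings --------------------------------------

#: positively charged nitrogen atoms (guanidinium, ammonium, imidazolium)
CATION_ATOMS = {
    "ARG": {"NE", "NH1", "NH2", "CZ"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}

#: negatively charged oxygens: carboxylates and phosphates
ANION_ATOMS_PROTEIN = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
PHOSPHATE_OXYGENS = {"OP1", "OP2", "O1P", "O2P", "OP3", "O3P"}

#: aromatic ring definitions: residue -> list of ring atom-name tuples
AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"), ("CG", "CD1", "CD2", "NE1", "CE2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

PURINE_RING6 = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_RING5 = ("C4", "C5", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def ring_definitions(residue_name: str) -> list[tuple[str, ...]]:
    rn = residue_name.strip().upper()
    if rn in AROMATIC_RINGS:
        return list(AROMATIC_RINGS[rn])
    code = base_code(rn)
    if code in ("A", "G"):
        return [PURINE_RING6, PURINE_RING5]
    if code in ("C", "U", "T"):
        return [PYRIMIDINE_RING]
    return []
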
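"""Chemical perception shared by all detectors.

Computed once per system: hydrogen-bond donors/acceptors, apolar atoms,
aromatic rings, charged groups, halogen-bond donors and metals. Standard
amino-acid (and, in nucleic mode, nucleotide) functional groups come from
name lookup tables; ligand and special-residue chemistry comes from formal
charges / valence (SDF-derived where available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .system import METAL_ELEMENTS

# per-residue acceptor atom names; backbone O / OXT accept for all residues
PROTEIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "HID": {"NE2"}, "HIE": {"ND1"},
    "MET": {"SD"}, "CYS": {"SG"},
}

AROMATIC_RING_ATOMS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HID": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIE": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

NUCLEIC_RING_ATOMS = {
    "purine": [("N9", "C8", "N7", "C5", "C4"),
               ("N1", "C2", "N3", "C4", "C5", "C6")],
    "pyrimidine": [("N1", "C2", "N3", "C4", "C5", "C6")],
}
PURINES = {"A", "G", "DA", "DG", "RA", "RG"}
PYRIMIDINES = {"U", "T", "C", "DT", "DC", "DU", "RU", "RC"}

POSITIVE_GROUPS = {
    "ARG": ("CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
}
NEGATIVE_GROUPS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class Ring:
    atom_ids: tuple
    residue: object
    owner: str  # "ligand" or "receptor"


@dataclass
class ChargedGroup:
    atom_ids: tuple
    residue: object
    owner: str
    sign: int


@dataclass
class Perception:
    """Per-system chemistry tables keyed by atom id."""

    donors: dict = field(default_factory=dict)      # heavy id -> [H ids]
    acceptors: set = field(default_factory=set)
    apolar: set = field(default_factory=set)
    rings: list = field(default_factory=list)
    pos_groups: list = field(default_factory=list)
    neg_groups: list = field(default_factory=list)
    halogen_donors: list = field(default_factory=list)  # (C id, X id)
    metals: list = field(default_factory=list)
    water_oxygens: dict = field(default_factory=dict)   # ResidueKey -> O id

    def polar_ids(self, component_filter=None, atoms=None):
        """Heavy atoms able to hydrogen-bond (donor or acceptor)."""
        ids = set(self.donors) | self.acceptors
        if component_filter is None:
            return ids
        return {i for i in ids
                if atoms[i].residue.component in component_filter}


RECEPTOR_COMPONENTS = ("protein", "nucleic", "special")


def perceive(system) -> Perception:
    atoms = system.atoms
    p = Perception()
    p.water_oxygens = system.water_oxygen_ids()

    for a in atoms:
        if a.is_hydrogen:
            continue
        el = a.element.upper()
        comp = a.residue.component
        h_ids = [j for j in a.bonded_ids if atoms[j].is_hydrogen]

        # donors: any N/O/S carrying an explicit hydrogen
        if el in ("N", "O", "S") and h_ids:
            p.donors[a.atom_id] = h_ids

        # acceptors
        if comp == "protein":
            if el == "O" and a.name in ("O", "OXT"):
                p.acceptors.add(a.atom_id)
            elif a.name in PROTEIN_ACCEPTORS.get(a.residue.resname, ()):
                # ring N only accepts when unprotonated
                if not (el == "N" and h_ids):
                    p.acceptors.add(a.atom_id)
        elif comp == "nucleic":
            if el == "O" or (el == "N" and not h_ids):
                p.acceptors.add(a.atom_id)
        elif comp in ("ligand", "special", "water"):
            if el == "O" and a.formal_charge <= 0:
                p.acceptors.add(a.atom_id)
            elif el == "N" and not h_ids and a.formal_charge <= 0 \
                    and len(a.bonded_ids) <= 3:
                p.acceptors.add(a.atom_id)
            elif el == "S" and not h_ids and len(a.bonded_ids) <= 2:
                p.acceptors.add(a.atom_id)

        # apolar: C or S bonded exclusively to C/H
        if el in ("C", "S") and comp in ("ligand",) + RECEPTOR_COMPONENTS:
            if all(atoms[j].element.upper() in ("C", "H")
                   for j in a.bonded_ids):
                p.apolar.add(a.atom_id)

        # halogen-bond donors: ligand C-X with X in Cl/Br/I
        if comp == "ligand" and el in ("CL", "BR", "I"):
            carbons = [j for j in a.bonded_ids
                       if atoms[j].element.upper() == "C"]
            if len(carbons) == 1:
                p.halogen_donors.append((carbons[0], a.atom_id))

        # metals: ions or metal atoms inside special residues
        if el in METAL_ELEMENTS and comp in ("ion", "special"):
            p.metals.append(a.atom_id)

    _perceive_rings(system, p)
    _perceive_charges(system, p)
    return p


def _perceive_rings(system, p):
    atoms = system.atoms
    for ring in system.ligand_rings:
        p.rings.append(Ring(tuple(sorted(ring)),
                            atoms[ring[0]].residue, "ligand"))
    by_res = {}
    for a in atoms:
        by_res.setdefault(a.residue, {})[a.name] = a.atom_id
    for res, names in by_res.items():
        ringsets = None
        if res.component == "protein":
            ringsets = AROMATIC_RING_ATOMS.get(res.resname)
        elif res.component == "nucleic" and system.nucleic_mode:
            if res.resname in PURINES:
                ringsets = NUCLEIC_RING_ATOMS["purine"]
            elif res.resname in PYRIMIDINES:
                ringsets = NUCLEIC_RING_ATOMS["pyrimidine"]
        if not ringsets:
            continue
        for rs in ringsets:
            if all(n in names for n in rs):
                p.rings.append(Ring(tuple(sorted(names[n] for n in rs)),
                                    res, "receptor"))


def _perceive_charges(system, p):
    atoms = system.atoms
    by_res = {}
    for a in atoms:
        by_res.setdefault(a.residue, {})[a.name] = a

    for res, names in by_res.items():
        if res.component == "protein":
            grp = POSITIVE_GROUPS.get(res.resname)
            if grp and all(n in names for n in grp):
                p.pos_groups.append(ChargedGroup(
                    tuple(names[n].atom_id for n in grp), res, "receptor", 1))
            if res.resname in ("HIS", "HIP"):
                nd, ne = names.get("ND1"), names.get("NE2")
                if nd and ne:
                    nd_h = any(atoms[j].is_hydrogen for j in nd.bonded_ids)
                    ne_h = any(atoms[j].is_hydrogen for j in ne.bonded_ids)
                    if nd_h and ne_h:  # doubly protonated imidazolium
                        p.pos_groups.append(ChargedGroup(
                            (nd.atom_id, ne.atom_id), res, "receptor", 1))
            grp = NEGATIVE_GROUPS.get(res.resname)
            if grp and all(n in names for n in grp):
                p.neg_groups.append(ChargedGroup(
                    tuple(names[n].atom_id for n in grp), res, "receptor", -1))
        elif res.component in ("ligand", "special"):
            _ligand_charges(system, res, list(names.values()), p)


def _ligand_charges(system, res, res_atoms, p):
    """Formal-charge / pattern-based groups for ligand-like residues."""
    atoms = system.atoms
    owner = "ligand" if res.component == "ligand" else "receptor"
    seen_neg = set()
    for a in res_atoms:
        if a.is_hydrogen:
            continue
        el = a.element.upper()
        if el == "N" and (a.formal_charge > 0 or len(a.bonded_ids) == 4):
            p.pos_groups.append(ChargedGroup((a.atom_id,), res, owner, 1))
        if el in ("C", "S", "P"):
            term_o = [j for j in a.bonded_ids
                      if atoms[j].element.upper() == "O"
                      and len(atoms[j].bonded_ids) == 1]
            charged = any(atoms[j].formal_charge < 0 for j in term_o)
            if len(term_o) >= 2 and charged:
                ids = tuple(sorted(term_o))
                if ids not in seen_neg:
                    seen_neg.add(ids)
                    p.neg_groups.append(ChargedGroup(ids, res, owner, -1))
    for a in res_atoms:
        if not a.is_hydrogen and a.formal_charge < 0 \
                and not any(a.atom_id in g for g in seen_neg):
            p.neg_groups.append(ChargedGroup((a.atom_id,), res, owner, -1))
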
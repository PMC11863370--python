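"""Loading topology/trajectory/ligand files into a uniform in-memory model.

The on-disk formats (PDB topology, DCD/XTC trajectory, SDF V2000 ligand) are
read through MDAnalysis and RDKit; this module flattens them into plain
dataclasses (`AtomRecord`, `MolecularSystem`) that the detectors operate on,
classifies every residue into one of the six components
(protein / nucleic / ligand / water / ion / special), and can remap residue
numbers onto a reference structure by per-chain sequence alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

COMPONENTS = ("protein", "nucleic", "ligand", "water", "ion", "special")

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}
ION_ELEMENTS = {"NA", "K", "CL", "MG", "CA", "ZN", "FE", "MN", "CU", "NI",
                "CO", "CD", "BR", "I", "LI", "RB", "CS", "F"}
METAL_ELEMENTS = {"FE", "ZN", "MG", "MN", "CU", "NI", "CO", "CA", "CD", "NA", "K"}
NUCLEIC_RESNAMES = {"A", "U", "G", "C", "T", "DA", "DT", "DG", "DC", "DU",
                    "RA", "RU", "RG", "RC"}

# single-bond covalent radii (Å) for the distance-based fallback perception
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20, "B": 0.84,
}
BOND_TOLERANCE = 0.4  # Å added on top of the radii sum

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HID": "H", "HIE": "H", "HIP": "H", "CYX": "C", "MSE": "M",
}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue: chain + 3-letter name + number + component."""

    chain: str
    resname: str
    resid: int
    component: str = "protein"

    def __post_init__(self):
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")

    def label(self) -> str:
        return f"{self.resname}{self.resid}{self.chain}"

    def identity(self) -> tuple:
        """(chain, resname, resid) — what interaction keys carry."""
        return (self.chain, self.resname, self.resid)


@dataclass
class AtomRecord:
    """One atom of the topology with its bonded environment."""

    atom_id: int
    name: str
    element: str
    residue: ResidueKey
    formal_charge: int = 0
    is_hydrogen: bool = False
    bonded_ids: list = field(default_factory=list)


@dataclass
class MolecularSystem:
    """Topology + per-frame coordinates + component labels.

    ``frames`` is an (F, N, 3) array in Å. Ligand aromatic rings (lists of
    atom ids) are stored on the system because they come from the SDF bond
    orders (or the geometric fallback), not from residue templates.
    """

    atoms: list
    frames: np.ndarray
    ligand_atom_ids: list
    water_residues: list = field(default_factory=list)
    special_residues: list = field(default_factory=list)
    nucleic_mode: bool = False
    ligand_rings: list = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom "
                f"count {len(self.atoms)}")
        if not self.ligand_atom_ids:
            raise ValueError("ligand_atom_ids must be non-empty")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self, frame: int) -> np.ndarray:
        return self.frames[frame]

    # ------------------------------------------------------------------ #
    # selections

    def residues(self) -> list:
        seen, out = set(), []
        for a in self.atoms:
            if a.residue not in seen:
                seen.add(a.residue)
                out.append(a.residue)
        return out

    def atoms_of(self, residue: ResidueKey) -> list:
        return [a for a in self.atoms if a.residue == residue]

    def atom_ids_of(self, residue: ResidueKey) -> list:
        return [a.atom_id for a in self.atoms if a.residue == residue]

    def select_component(self, *components: str) -> list:
        return [a for a in self.atoms if a.residue.component in components]

    def backbone_ids(self) -> list:
        """Protein backbone heavy atoms (N, CA, C) used for fitting."""
        return [a.atom_id for a in self.atoms
                if a.residue.component == "protein"
                and a.name in ("N", "CA", "C")]

    def ligand_heavy_ids(self) -> list:
        return [i for i in self.ligand_atom_ids
                if not self.atoms[i].is_hydrogen]

    def water_oxygen_ids(self) -> dict:
        """Map water ResidueKey -> id of its O atom."""
        out = {}
        for a in self.atoms:
            if a.residue.component == "water" and a.element == "O":
                out.setdefault(a.residue, a.atom_id)
        return out


# ---------------------------------------------------------------------- #
# component classification


def classify_components(resnames_by_residue, special_resnames=(),
                        nucleic_flag=False, ligand_resname=None,
                        atom_info=None):
    """Assign one component label per residue.

    Parameters
    ----------
    resnames_by_residue : list of (chain, resname, resid)
    special_resnames : iterable of resnames to treat as special ligands
    atom_info : optional dict (chain, resname, resid) -> list of
        (name, element) used for the backbone / monoatomic-ion checks.

    Returns dict (chain, resname, resid) -> component.
    """
    special = {s.upper() for s in special_resnames}
    overlap = special & WATER_RESNAMES
    if overlap:
        raise ValueError(
            f"resname(s) {sorted(overlap)} are both water and special")
    labels = {}
    for key in resnames_by_residue:
        chain, resname, resid = key
        rn = resname.upper()
        names = atom_info.get(key, []) if atom_info else []
        atom_names = {n for n, _ in names}
        if rn in WATER_RESNAMES:
            labels[key] = "water"
        elif rn in special:
            labels[key] = "special"
        elif ligand_resname is not None and rn == ligand_resname.upper():
            labels[key] = "ligand"
        elif len(names) == 1 and names[0][1].upper() in ION_ELEMENTS:
            labels[key] = "ion"
        elif nucleic_flag and rn in NUCLEIC_RESNAMES:
            labels[key] = "nucleic"
        elif {"N", "CA", "C"} <= atom_names:
            labels[key] = "protein"
        else:
            labels[key] = "ligand" if ligand_resname is None else "special"
    return labels


# ---------------------------------------------------------------------- #
# bond perception


def perceive_bonds(elements, coords, exclude_ids=frozenset()):
    """Distance-heuristic covalent bonds: d <= r1 + r2 + 0.4 Å.

    H–H pairs and atoms in ``exclude_ids`` (e.g. metals, ions) never bond.
    Returns a symmetric adjacency as list-of-lists.
    """
    n = len(elements)
    bonded = [[] for _ in range(n)]
    if n == 0:
        return bonded
    from scipy.spatial import cKDTree
    radii = np.array([COVALENT_RADII.get(e.upper(), 0.77) for e in elements])
    tree = cKDTree(coords)
    rmax = 2 * radii.max() + BOND_TOLERANCE
    for i, j in tree.query_pairs(rmax):
        if i in exclude_ids or j in exclude_ids:
            continue
        ei, ej = elements[i].upper(), elements[j].upper()
        if ei == "H" and ej == "H":
            continue
        cutoff = radii[i] + radii[j] + BOND_TOLERANCE
        if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
            bonded[i].append(j)
            bonded[j].append(i)
    return [sorted(b) for b in bonded]


def _fallback_ligand_perception(system):
    """Ligand formal charges and aromatic rings without an SDF.

    Charges: tetravalent N -> +1; terminal O pairs on a C/S/P centre -> the
    group is treated as anionic (one O gets -1). Rings: 5/6-membered cycles
    of C/N/O/S with out-of-plane RMS < 0.15 Å count as aromatic carriers.
    """
    atoms = system.atoms
    lig = set(system.ligand_atom_ids)
    for i in lig:
        a = atoms[i]
        if a.is_hydrogen:
            continue
        if a.element.upper() == "N" and len(a.bonded_ids) == 4:
            a.formal_charge = 1
        if a.element.upper() in ("C", "S", "P"):
            term_o = [j for j in a.bonded_ids
                      if atoms[j].element.upper() == "O"
                      and len(atoms[j].bonded_ids) == 1]
            if len(term_o) >= 2:
                atoms[term_o[0]].formal_charge = -1
    # ring perception on the ligand heavy-atom graph
    import networkx as nx
    g = nx.Graph()
    heavy = [i for i in lig if not atoms[i].is_hydrogen]
    g.add_nodes_from(heavy)
    for i in heavy:
        for j in atoms[i].bonded_ids:
            if j in lig and not atoms[j].is_hydrogen:
                g.add_edge(i, j)
    rings = []
    for cyc in nx.cycle_basis(g):
        if len(cyc) not in (5, 6):
            continue
        if any(atoms[i].element.upper() not in ("C", "N", "O", "S")
               for i in cyc):
            continue
        pts = system.frames[0][cyc]
        cen = pts.mean(axis=0)
        _, s, vh = np.linalg.svd(pts - cen)
        oop = (pts - cen) @ vh[2]
        if np.sqrt((oop ** 2).mean()) < 0.15:
            rings.append(sorted(cyc))
    system.ligand_rings = rings


# ---------------------------------------------------------------------- #
# loading


def _chain_of(atom) -> str:
    try:
        cid = atom.chainID
        if cid and cid.strip():
            return cid.strip()
    except Exception:
        pass
    try:
        return atom.segid.strip() or "A"
    except Exception:
        return "A"


def load_system(topology_path, trajectory_path, ligand_sdf=None,
                special_resnames=(), nucleic_flag=False,
                ligand_resname=None):
    """Read a PDB topology + DCD/XTC trajectory (+ optional SDF ligand).

    The SDF, when given, supplies ligand bond orders, formal charges and
    aromatic rings; its heavy atoms must match the topology's ligand residue
    in count and element order. Without an SDF the ligand chemistry is
    perceived from topology geometry (and a warning is logged).
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path), str(trajectory_path))
        if u.atoms.n_atoms == 0:
            raise ValueError("empty topology")
        try:
            elements = [e.capitalize() for e in u.atoms.elements]
        except Exception:
            from MDAnalysis.topology.guessers import guess_types
            elements = [e.capitalize() for e in guess_types(u.atoms.names)]
        frames = np.stack([u.trajectory.ts.positions.copy().astype(float)
                           for _ in u.trajectory])

    n = u.atoms.n_atoms
    if frames.shape[1] != n:  # MDAnalysis raises earlier, but keep the contract
        raise ValueError(
            f"trajectory atom count {frames.shape[1]} != topology {n}")

    residue_order, atom_info = [], {}
    raw_keys = []
    for a in u.atoms:
        key = (_chain_of(a), a.resname.strip().upper(), int(a.resid))
        raw_keys.append(key)
        if key not in atom_info:
            atom_info[key] = []
            residue_order.append(key)
        atom_info[key].append((a.name.strip(), elements[a.index]))

    labels = classify_components(residue_order, special_resnames,
                                 nucleic_flag, ligand_resname, atom_info)
    if ligand_resname is None:
        lig_res = [k for k, v in labels.items() if v == "ligand"]
        if len(lig_res) == 0:
            raise ValueError("no ligand residue found in topology")
        if len({k[1] for k in lig_res}) > 1:
            raise ValueError(
                f"ambiguous ligand residues {sorted(set(k[1] for k in lig_res))}; "
                "pass ligand_resname")

    reskeys = {k: ResidueKey(k[0], k[1], k[2], labels[k])
               for k in residue_order}
    atoms = []
    for idx, a in enumerate(u.atoms):
        el = elements[idx]
        atoms.append(AtomRecord(
            atom_id=idx, name=a.name.strip(), element=el,
            residue=reskeys[raw_keys[idx]],
            is_hydrogen=(el.upper() == "H")))

    # bond perception on frame 0 (metals/ions never bond covalently here)
    exclude = {i for i, a in enumerate(atoms)
               if a.residue.component == "ion"
               or (a.element.upper() in METAL_ELEMENTS
                   and a.residue.component == "special")}
    bonded = perceive_bonds([a.element for a in atoms], frames[0], exclude)
    for a, b in zip(atoms, bonded):
        a.bonded_ids = b

    ligand_atom_ids = [a.atom_id for a in atoms
                       if a.residue.component == "ligand"]
    system = MolecularSystem(
        atoms=atoms, frames=frames, ligand_atom_ids=ligand_atom_ids,
        water_residues=[r for r in reskeys.values() if r.component == "water"],
        special_residues=[r for r in reskeys.values()
                          if r.component == "special"],
        nucleic_mode=nucleic_flag)

    if ligand_sdf is not None:
        _apply_sdf(system, ligand_sdf)
    else:
        log.warning("no ligand SDF supplied; perceiving ligand bonds and "
                    "formal charges from topology geometry")
        _fallback_ligand_perception(system)
    return system


def _apply_sdf(system, sdf_path):
    """Overlay SDF bond orders / charges / aromaticity onto the topology.

    SDF heavy atoms are matched 1:1, in order, to the topology ligand's
    heavy atoms; an element mismatch is a hard error naming the first
    offending atom.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(sdf_path), removeHs=False,
                                  sanitize=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ValueError(f"could not parse SDF {sdf_path}")
    sdf_heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    top_heavy = [system.atoms[i] for i in system.ligand_atom_ids
                 if not system.atoms[i].is_hydrogen]
    if len(sdf_heavy) != len(top_heavy):
        raise ValueError(
            f"SDF heavy-atom count {len(sdf_heavy)} != topology ligand "
            f"heavy-atom count {len(top_heavy)}")
    for sa, ta in zip(sdf_heavy, top_heavy):
        if sa.GetSymbol().upper() != ta.element.upper():
            raise ValueError(
                f"SDF/topology ligand element mismatch at atom "
                f"{ta.name} (id {ta.atom_id}): topology {ta.element}, "
                f"SDF {sa.GetSymbol()}")
    sdf2top = {sa.GetIdx(): ta.atom_id
               for sa, ta in zip(sdf_heavy, top_heavy)}
    for sa, ta in zip(sdf_heavy, top_heavy):
        ta.formal_charge = sa.GetFormalCharge()
    # heavy-atom bonds from the SDF replace the geometric guess
    lig_heavy_ids = {ta.atom_id for ta in top_heavy}
    for i in lig_heavy_ids:
        a = system.atoms[i]
        a.bonded_ids = [j for j in a.bonded_ids if j not in lig_heavy_ids]
    for bond in mol.GetBonds():
        bi, ei = bond.GetBeginAtom(), bond.GetEndAtom()
        if bi.GetAtomicNum() == 1 or ei.GetAtomicNum() == 1:
            continue
        i, j = sdf2top[bi.GetIdx()], sdf2top[ei.GetIdx()]
        system.atoms[i].bonded_ids.append(j)
        system.atoms[j].bonded_ids.append(i)
    for i in lig_heavy_ids:
        system.atoms[i].bonded_ids = sorted(set(system.atoms[i].bonded_ids))
    ri = mol.GetRingInfo()
    rings = []
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(sorted(sdf2top[i] for i in ring))
    system.ligand_rings = rings


# ---------------------------------------------------------------------- #
# residue renumbering against a reference


@dataclass
class RenumberResult:
    """Outcome of mapping residue numbers onto a reference structure."""

    mapping: dict          # (chain, resid) -> new resid
    unmapped: list         # [(chain, resid, resname), ...]
    chain_pairs: dict      # system chain -> (reference chain, identity)


def _protein_chain_sequences(residues):
    chains = {}
    for r in residues:
        if r.component != "protein":
            continue
        chains.setdefault(r.chain, []).append(r)
    for c in chains:
        chains[c].sort(key=lambda r: r.resid)
    return chains


def renumber_to_reference(system, reference_pdb, identity_floor=0.5):
    """Per-chain global alignment of one-letter sequences; aligned positions
    inherit the reference residue number.

    Scoring: match +1, mismatch −1, gap −2. A chain pair below the identity
    floor (matches / shorter chain length) is rejected; if no pair passes,
    raises ``ValueError("no alignable chain")``.
    """
    import MDAnalysis as mda
    from Bio import Align

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = mda.Universe(str(reference_pdb))
    ref_chains = {}
    for res in ref.residues:
        rn = res.resname.strip().upper()
        if rn not in THREE_TO_ONE:
            continue
        chain = _chain_of(res.atoms[0])
        ref_chains.setdefault(chain, []).append(
            (int(res.resid), THREE_TO_ONE[rn]))
    for c in ref_chains:
        ref_chains[c].sort()

    sys_chains = _protein_chain_sequences(system.residues())
    if not sys_chains or not ref_chains:
        raise ValueError("no alignable chain")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2

    mapping, unmapped, chain_pairs = {}, [], {}
    for chain, residues in sys_chains.items():
        seq = "".join(THREE_TO_ONE.get(r.resname, "X") for r in residues)
        best = None
        for rchain, rres in ref_chains.items():
            rseq = "".join(s for _, s in rres)
            aln = aligner.align(seq, rseq)[0]
            pairs = []
            for (s0, s1), (r0, r1) in zip(*aln.aligned):
                pairs.extend(zip(range(s0, s1), range(r0, r1)))
            matches = sum(seq[i] == rseq[j] for i, j in pairs)
            identity = matches / min(len(seq), len(rseq))
            if best is None or identity > best[0]:
                best = (identity, rchain, rres, pairs)
        identity, rchain, rres, pairs = best
        if identity < identity_floor:
            unmapped.extend((chain, r.resid, r.resname) for r in residues)
            continue
        chain_pairs[chain] = (rchain, identity)
        mapped_pos = {i: j for i, j in pairs}
        for i, r in enumerate(residues):
            if i in mapped_pos:
                mapping[(chain, r.resid)] = rres[mapped_pos[i]][0]
            else:
                unmapped.append((chain, r.resid, r.resname))
    if not chain_pairs:
        raise ValueError("no alignable chain")
    if unmapped:
        log.info("renumbering left %d residue(s) unmapped: %s",
                 len(unmapped), unmapped)
    return RenumberResult(mapping=mapping, unmapped=unmapped,
                          chain_pairs=chain_pairs)


def apply_renumbering(system, result) -> "MolecularSystem":
    """Return the same system with protein resids replaced per the mapping."""
    new_keys = {}
    for a in system.atoms:
        r = a.residue
        if r in new_keys:
            a.residue = new_keys[r]
            continue
        if r.component == "protein" and (r.chain, r.resid) in result.mapping:
            nk = ResidueKey(r.chain, r.resname,
                            result.mapping[(r.chain, r.resid)], r.component)
        else:
            nk = r
        new_keys[r] = nk
        a.residue = nk
    system.water_residues = [new_keys.get(r, r) for r in system.water_residues]
    system.special_residues = [new_keys.get(r, r)
                               for r in system.special_residues]
    return system


# ---------------------------------------------------------------------- #
# PDB writing


def write_frame_pdb(system, frame, path, atom_ids=None):
    """Write one frame (optionally a subset of atoms) as a PDB file."""
    ids = range(system.n_atoms) if atom_ids is None else atom_ids
    coords = system.frames[frame]
    lines = []
    serial = 0
    for i in ids:
        a = system.atoms[i]
        serial += 1
        rec = ("ATOM  " if a.residue.component in ("protein", "nucleic")
               else "HETATM")
        x, y, z = coords[i]
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{rec}{serial:5d} {name[:4]:<4s} {a.residue.resname:<3s} "
            f"{a.residue.chain[:1]:1s}{a.residue.resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element.upper():>2s}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
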
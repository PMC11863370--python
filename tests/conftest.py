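"""Shared fixtures: hand-built in-memory systems and generated toy systems."""

from __future__ import annotations

import numpy as np
import pytest

from trajfp.fixtures import (ScheduleEntry, SyntheticSystemSpec, WaterPlan,
                             generate_system)
from trajfp.system import (AtomRecord, MolecularSystem, ResidueKey,
                           perceive_bonds)


def build_system(atom_specs, frames=None, nucleic_mode=False,
                 ligand_rings=()):
    """Hand-build a MolecularSystem.

    atom_specs: list of (name, element, chain, resname, resid, component,
    position[, formal_charge]). Bonds are perceived from the first frame by
    the covalent-radius heuristic.
    """
    atoms = []
    positions = []
    for i, spec in enumerate(atom_specs):
        name, el, chain, resname, resid, comp, pos = spec[:7]
        charge = spec[7] if len(spec) > 7 else 0
        atoms.append(AtomRecord(
            atom_id=i, name=name, element=el,
            residue=ResidueKey(chain, resname, resid, comp),
            formal_charge=charge, is_hydrogen=(el.upper() == "H")))
        positions.append(pos)
    positions = np.asarray(positions, float)
    if frames is None:
        frames = positions[None, :, :]
    exclude = {i for i, a in enumerate(atoms) if a.residue.component == "ion"
               or (a.residue.component == "special"
                   and a.element.upper() in ("FE", "ZN", "MG", "MN", "CU"))}
    bonded = perceive_bonds([a.element for a in atoms], positions, exclude)
    for a, b in zip(atoms, bonded):
        a.bonded_ids = b
    lig = [a.atom_id for a in atoms if a.residue.component == "ligand"]
    return MolecularSystem(
        atoms=atoms, frames=np.asarray(frames, float), ligand_atom_ids=lig,
        water_residues=sorted({a.residue for a in atoms
                               if a.residue.component == "water"}),
        special_residues=sorted({a.residue for a in atoms
                                 if a.residue.component == "special"}),
        nucleic_mode=nucleic_mode, ligand_rings=list(ligand_rings))


FULL_SCHEDULE = [
    ("hydrophobic", range(10)),
    ("hbond_donor", range(0, 5)),
    ("hbond_acceptor", range(2, 10)),
    ("water_bridge", range(0, 6)),
    ("salt_bridge", range(0, 10, 2)),
    ("pi_stacking", range(5, 10)),
    ("pi_cation", range(0, 4)),
    ("halogen", range(3, 8)),
    ("metal", range(0, 9)),
]


def full_spec(seed=1, n_frames=10, schedule=FULL_SCHEDULE, waters=None):
    if waters is None:
        waters = [WaterPlan((9.0, 9.0, 6.0), frozenset(range(n_frames))),
                  WaterPlan((-10.0, -7.0, -7.0),
                            frozenset(range(n_frames * 3 // 5))),
                  WaterPlan(None)]
    return SyntheticSystemSpec(
        n_frames=n_frames,
        schedule=[ScheduleEntry(it, frozenset(fr)) for it, fr in schedule],
        waters=waters, seed=seed)


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    """One generated all-interaction toy system shared by the session."""
    out = tmp_path_factory.mktemp("toy")
    paths, truth = generate_system(full_spec(seed=1), out)
    return paths, truth


@pytest.fixture(scope="session")
def toy_system(toy_paths):
    from trajfp.system import load_system
    paths, truth = toy_paths
    system = load_system(paths["topology"], paths["trajectory"],
                         paths["ligand_sdf"])
    return system, truth


def randomized_frames(base_system, n_random, seed):
    """Frames with every probe displaced randomly along/around its base
    position and waters scattered near the ligand: geometry crosses every
    threshold region while frame-0 topology (bond perception) stays clean.
    """
    rng = np.random.default_rng(seed)
    x0 = base_system.frames[0]
    by_res = {}
    for a in base_system.atoms:
        by_res.setdefault(a.residue, []).append(a.atom_id)
    frames = [x0]
    lig_ids = base_system.ligand_atom_ids
    lig_cen = x0[lig_ids].mean(axis=0)
    for _ in range(n_random):
        x = x0.copy()
        for res, ids in by_res.items():
            if res.component == "ligand":
                continue
            cen = x0[ids].mean(axis=0)
            u = cen - lig_cen
            u = u / max(np.linalg.norm(u), 1e-9)
            shift = rng.uniform(-2.5, 3.0) * u + rng.normal(0, 0.3, 3)
            x[ids] = x0[ids] + shift
        # small rigid wobble of the ligand
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec(rng.normal(0, 0.05, 3)).as_matrix()
        x[lig_ids] = (x0[lig_ids] - lig_cen) @ rot.T + lig_cen \
            + rng.normal(0, 0.3, 3)
        frames.append(x)
    return np.stack(frames)

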
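"""Per-frame geometric detection of ligand–receptor noncovalent interactions.

Every detector follows the functional-group + distance + angle paradigm:
candidate atoms come from :mod:`trajfp.perception`, geometry is evaluated on
one frame's coordinates, and each hit becomes an :class:`InteractionRecord`.
Records are identified trajectory-wide by their :class:`InteractionKey`
(interaction type, ligand moiety atoms, receptor residue); the identity of a
bridging water is deliberately *not* part of the key, so one water bridge
can be mediated by several different waters across the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .geometry import angle_deg, fold_angle_90, ring_descriptor
from .perception import RECEPTOR_COMPONENTS, perceive

ITYPES = ("hydrophobic", "hbond_donor", "hbond_acceptor", "water_bridge",
          "salt_bridge", "pi_stacking", "pi_cation", "halogen", "metal")


class InteractionKey(NamedTuple):
    """Trajectory-wide identity of one interaction."""

    itype: str
    ligand_atom_ids: tuple
    residue: tuple  # (chain, resname, resid)

    def label(self) -> str:
        c, rn, ri = self.residue
        return f"{self.itype}:{'+'.join(map(str, self.ligand_atom_ids))}" \
               f":{rn}{ri}{c}"


@dataclass
class InteractionRecord:
    """One detected interaction occurrence in one frame."""

    frame: int
    itype: str
    ligand_atom_ids: tuple
    receptor_residue: object
    receptor_atom_ids: tuple = ()
    water_residue: object = None
    geometry: dict = field(default_factory=dict)
    flags: tuple = ()

    def __post_init__(self):
        if self.itype not in ITYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}")
        if not self.ligand_atom_ids and "no_ligand" not in self.flags:
            raise ValueError("ligand_atom_ids must be non-empty")
        self.ligand_atom_ids = tuple(sorted(self.ligand_atom_ids))
        self.receptor_atom_ids = tuple(sorted(self.receptor_atom_ids))

    def key(self) -> Optional[InteractionKey]:
        if not self.ligand_atom_ids:
            return None
        return InteractionKey(self.itype, self.ligand_atom_ids,
                              self.receptor_residue.identity())


def _dist(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def _receptor_atoms(system):
    return [a for a in system.atoms
            if a.residue.component in RECEPTOR_COMPONENTS]


# --------------------------------------------------------------------- #
# detectors


def detect_hydrophobic(frame, system, perception, config):
    """Apolar-C/S ligand atom near an apolar-C/S receptor atom.

    One record per (ligand atom, receptor residue), keeping the closest pair.
    """
    x = system.frames[frame]
    lig = [i for i in perception.apolar
           if system.atoms[i].residue.component == "ligand"]
    rec = [i for i in perception.apolar
           if system.atoms[i].residue.component in RECEPTOR_COMPONENTS]
    best = {}
    if lig and rec:
        from scipy.spatial.distance import cdist
        d = cdist(x[lig], x[rec])
        for li, ri in zip(*np.nonzero(d <= config.hydrophobic_dist_max)):
            i, j = lig[li], rec[ri]
            res = system.atoms[j].residue
            cur = best.get((i, res))
            if cur is None or d[li, ri] < cur[0]:
                best[(i, res)] = (float(d[li, ri]), j)
    out = []
    for (i, res), (dist, j) in best.items():
        out.append(InteractionRecord(
            frame=frame, itype="hydrophobic", ligand_atom_ids=(i,),
            receptor_residue=res, receptor_atom_ids=(j,),
            geometry={"dist": dist}))
    return out


def _hbond_pairs(frame, system, perception, config, donors, acceptors):
    """Shared donor/acceptor geometry: heavy distance + best D-H···A angle."""
    x = system.frames[frame]
    out = []
    for d_id, h_ids in donors:
        for a_id in acceptors:
            dist = _dist(x[d_id], x[a_id])
            if dist > config.hbond_dist_max:
                continue
            ang = max(angle_deg(x[d_id], x[h], x[a_id]) for h in h_ids)
            if ang >= config.hbond_don_angle_min:
                out.append((d_id, a_id, dist, ang))
    return out


def detect_hbonds(frame, system, perception, config):
    """Ligand–receptor hydrogen bonds; type is ligand-relative.

    ``hbond_donor`` when the ligand supplies the donor, ``hbond_acceptor``
    when it supplies the acceptor. Donors without an explicit hydrogen were
    never entered into the donor table (perception logs them implicitly by
    omission); MD topologies carry explicit hydrogens.
    """
    atoms = system.atoms
    lig_donors = [(i, hs) for i, hs in perception.donors.items()
                  if atoms[i].residue.component == "ligand"]
    rec_donors = [(i, hs) for i, hs in perception.donors.items()
                  if atoms[i].residue.component in RECEPTOR_COMPONENTS]
    lig_acc = [i for i in perception.acceptors
               if atoms[i].residue.component == "ligand"]
    rec_acc = [i for i in perception.acceptors
               if atoms[i].residue.component in RECEPTOR_COMPONENTS]
    out = []
    for d, a, dist, ang in _hbond_pairs(frame, system, perception, config,
                                        lig_donors, rec_acc):
        out.append(InteractionRecord(
            frame=frame, itype="hbond_donor", ligand_atom_ids=(d,),
            receptor_residue=atoms[a].residue, receptor_atom_ids=(a,),
            geometry={"dist": dist, "don_angle": ang}))
    for d, a, dist, ang in _hbond_pairs(frame, system, perception, config,
                                        rec_donors, lig_acc):
        out.append(InteractionRecord(
            frame=frame, itype="hbond_acceptor", ligand_atom_ids=(a,),
            receptor_residue=atoms[d].residue, receptor_atom_ids=(d,),
            geometry={"dist": dist, "don_angle": ang}))
    return out


def _leg_is_hbond(x, partner_id, partner_hs, w_o, w_hs, config):
    """A water-bridge leg: heavy distance window + a donor angle from
    whichever side carries the hydrogen."""
    dist = _dist(x[partner_id], x[w_o])
    if not (config.wb_dist_min <= dist <= config.wb_dist_max):
        return None
    angles = []
    for h in partner_hs:  # partner donates to water
        angles.append(angle_deg(x[partner_id], x[h], x[w_o]))
    for h in w_hs:        # water donates to partner
        angles.append(angle_deg(x[w_o], x[h], x[partner_id]))
    if angles and max(angles) >= config.hbond_don_angle_min:
        return dist
    return None


def detect_water_bridges(frame, system, perception, config):
    """Ligand–water–receptor double hydrogen bridges (one record per water)."""
    atoms = system.atoms
    x = system.frames[frame]
    lig_polar = sorted(perception.polar_ids(("ligand",), atoms))
    rec_polar = sorted(perception.polar_ids(RECEPTOR_COMPONENTS, atoms))
    out = []
    for wres, w_o in perception.water_oxygens.items():
        w_hs = [j for j in atoms[w_o].bonded_ids if atoms[j].is_hydrogen]
        for li in lig_polar:
            li_hs = perception.donors.get(li, [])
            d1 = _leg_is_hbond(x, li, li_hs, w_o, w_hs, config)
            if d1 is None:
                continue
            for ri in rec_polar:
                ri_hs = perception.donors.get(ri, [])
                d2 = _leg_is_hbond(x, ri, ri_hs, w_o, w_hs, config)
                if d2 is None:
                    continue
                omega = angle_deg(x[li], x[w_o], x[ri])
                if config.wb_omega_min <= omega <= config.wb_omega_max:
                    out.append(InteractionRecord(
                        frame=frame, itype="water_bridge",
                        ligand_atom_ids=(li,),
                        receptor_residue=atoms[ri].residue,
                        receptor_atom_ids=(ri,), water_residue=wres,
                        geometry={"dist_lig": d1, "dist_rec": d2,
                                  "omega": omega}))
    return out


def _centroid(x, ids):
    return x[list(ids)].mean(axis=0)


def detect_salt_bridges(frame, system, perception, config):
    """Oppositely charged group centroids within the salt-bridge cutoff."""
    x = system.frames[frame]
    out = []
    for pg in perception.pos_groups:
        for ng in perception.neg_groups:
            if pg.owner == ng.owner:
                continue  # need one ligand-side and one receptor-side group
            dist = _dist(_centroid(x, pg.atom_ids), _centroid(x, ng.atom_ids))
            if dist > config.saltbridge_dist_max:
                continue
            lig_grp, rec_grp = (pg, ng) if pg.owner == "ligand" else (ng, pg)
            out.append(InteractionRecord(
                frame=frame, itype="salt_bridge",
                ligand_atom_ids=lig_grp.atom_ids,
                receptor_residue=rec_grp.residue,
                receptor_atom_ids=rec_grp.atom_ids,
                geometry={"dist": dist}))
    return out


def _ring_geom(x, ring):
    return ring_descriptor(x[list(ring.atom_ids)], ring.atom_ids)


def _offset(c1, n1, c2, n2):
    """In-plane centroid offset: min over the two rings of the projection
    of the centroid-centroid vector onto each ring plane."""
    v = c2 - c1
    off1 = np.linalg.norm(v - np.dot(v, n1) * n1)
    off2 = np.linalg.norm(v - np.dot(v, n2) * n2)
    return float(min(off1, off2))


def detect_pi_stacking(frame, system, perception, config):
    """Parallel or T-shaped aromatic ring stacking."""
    x = system.frames[frame]
    lig_rings = [r for r in perception.rings if r.owner == "ligand"]
    rec_rings = [r for r in perception.rings if r.owner == "receptor"]
    out = []
    for lr in lig_rings:
        gl = _ring_geom(x, lr)
        for rr in rec_rings:
            gr = _ring_geom(x, rr)
            dist = _dist(gl.centroid, gr.centroid)
            if dist > config.pistack_dist_max:
                continue
            angle = fold_angle_90(np.degrees(np.arccos(np.clip(
                np.dot(gl.normal, gr.normal), -1.0, 1.0))))
            if angle <= config.pistack_parallel_max:
                style = "parallel"
            elif config.pistack_tshape_min <= angle <= config.pistack_tshape_max:
                style = "tshaped"
            else:
                continue
            off = _offset(gl.centroid, gl.normal, gr.centroid, gr.normal)
            if off > config.pistack_offset_max:
                continue
            out.append(InteractionRecord(
                frame=frame, itype="pi_stacking",
                ligand_atom_ids=lr.atom_ids, receptor_residue=rr.residue,
                receptor_atom_ids=rr.atom_ids,
                geometry={"dist": dist, "angle": angle, "offset": off,
                          "style": style}))
    return out


def detect_pi_cation(frame, system, perception, config):
    """Charged-group centroid over an aromatic ring (either direction)."""
    x = system.frames[frame]
    out = []
    pairs = []
    for ring in perception.rings:
        for grp in perception.pos_groups:
            if ring.owner == grp.owner:
                continue
            pairs.append((ring, grp))
    for ring, grp in pairs:
        g = _ring_geom(x, ring)
        cen = _centroid(x, grp.atom_ids)
        dist = _dist(g.centroid, cen)
        if dist > config.pication_dist_max:
            continue
        v = cen - g.centroid
        off = float(np.linalg.norm(v - np.dot(v, g.normal) * g.normal))
        if off > config.pistack_offset_max:
            continue
        lig_ids = ring.atom_ids if ring.owner == "ligand" else grp.atom_ids
        rec = grp.residue if ring.owner == "ligand" else ring.residue
        rec_ids = grp.atom_ids if ring.owner == "ligand" else ring.atom_ids
        out.append(InteractionRecord(
            frame=frame, itype="pi_cation", ligand_atom_ids=lig_ids,
            receptor_residue=rec, receptor_atom_ids=rec_ids,
            geometry={"dist": dist, "offset": off}))
    return out


def detect_halogen(frame, system, perception, config):
    """Ligand C–X (Cl/Br/I) σ-hole bond to a receptor O/N/S acceptor."""
    atoms = system.atoms
    x = system.frames[frame]
    rec_y = [a.atom_id for a in _receptor_atoms(system)
             if a.element.upper() in ("O", "N", "S")]
    out = []
    for c_id, x_id in perception.halogen_donors:
        for y in rec_y:
            dist = _dist(x[x_id], x[y])
            if dist > config.halogen_dist_max:
                continue
            don = angle_deg(x[c_id], x[x_id], x[y])
            if abs(don - config.halogen_don_angle) > config.halogen_don_tol:
                continue
            neighbors = [j for j in atoms[y].bonded_ids
                         if not atoms[j].is_hydrogen]
            if not neighbors:
                continue
            accs = [angle_deg(x[j], x[y], x[x_id]) for j in neighbors]
            ok = [a for a in accs
                  if abs(a - config.halogen_acc_angle) <= config.halogen_acc_tol]
            if not ok:
                continue
            out.append(InteractionRecord(
                frame=frame, itype="halogen", ligand_atom_ids=(x_id,),
                receptor_residue=atoms[y].residue, receptor_atom_ids=(y,),
                geometry={"dist": dist, "don_angle": don,
                          "acc_angle": ok[0]}))
    return out


def detect_metal(frame, system, perception, config):
    """Metal coordination to ligand / receptor / water O, N or S.

    Only ligand-coordinating records carry a key; water and receptor
    coordination are reported flagged (``water_coordination`` /
    ``receptor_coordination``) and stay out of the fingerprint layer.
    """
    atoms = system.atoms
    x = system.frames[frame]
    out = []
    for m in perception.metals:
        mres = atoms[m].residue
        for a in atoms:
            if a.is_hydrogen or a.atom_id == m:
                continue
            if a.element.upper() not in ("O", "N", "S"):
                continue
            comp = a.residue.component
            if comp not in ("ligand", "water") + RECEPTOR_COMPONENTS:
                continue
            if a.residue == mres:
                continue
            dist = _dist(x[m], x[a.atom_id])
            if dist > config.metal_dist_max:
                continue
            if comp == "ligand":
                out.append(InteractionRecord(
                    frame=frame, itype="metal",
                    ligand_atom_ids=(a.atom_id,), receptor_residue=mres,
                    receptor_atom_ids=(m,), geometry={"dist": dist}))
            elif comp == "water":
                out.append(InteractionRecord(
                    frame=frame, itype="metal", ligand_atom_ids=(),
                    receptor_residue=mres, receptor_atom_ids=(m,),
                    water_residue=a.residue, geometry={"dist": dist},
                    flags=("no_ligand", "water_coordination")))
            else:
                out.append(InteractionRecord(
                    frame=frame, itype="metal", ligand_atom_ids=(),
                    receptor_residue=mres,
                    receptor_atom_ids=(m, a.atom_id),
                    geometry={"dist": dist},
                    flags=("no_ligand", "receptor_coordination")))
    return out


ALL_DETECTORS = (detect_hydrophobic, detect_hbonds, detect_water_bridges,
                 detect_salt_bridges, detect_pi_stacking, detect_pi_cation,
                 detect_halogen, detect_metal)


# --------------------------------------------------------------------- #
# the trajectory sweep and its table


class InteractionTable:
    """All records over all frames, deterministically ordered."""

    def __init__(self, records, n_frames):
        self.n_frames = int(n_frames)
        self.records = sorted(records, key=self._sort_key)

    @staticmethod
    def _sort_key(r):
        wid = r.water_residue.identity() if r.water_residue else ("", "", -1)
        return (r.frame, r.itype, r.ligand_atom_ids,
                r.receptor_residue.identity(), wid)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keyed_records(self):
        return [r for r in self.records if r.key() is not None]

    def keys(self):
        seen, out = set(), []
        for r in self.keyed_records():
            k = r.key()
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def frames_of(self, key) -> set:
        return {r.frame for r in self.keyed_records() if r.key() == key}

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for r in self.records:
            geom = {k: v for k, v in r.geometry.items()
                    if isinstance(v, (int, float))}
            rows.append({
                "frame": r.frame, "itype": r.itype,
                "ligand_atoms": "+".join(map(str, r.ligand_atom_ids)),
                "residue": r.receptor_residue.label(),
                "water_resid": (r.water_residue.resid
                                if r.water_residue else ""),
                "flags": "|".join(r.flags),
                **{f"geom_{k}": round(v, 4) for k, v in sorted(geom.items())},
            })
        cols = ["frame", "itype", "ligand_atoms", "residue", "water_resid",
                "flags"]
        df = pd.DataFrame(rows)
        if df.empty:
            return pd.DataFrame(columns=cols)
        extra = [c for c in df.columns if c not in cols]
        return df[cols + sorted(extra)]


def sweep_trajectory(system, config=None, perception=None) -> InteractionTable:
    """Run every detector on every frame and collect the table."""
    from .config import DetectionConfig
    if system.n_frames == 0:
        raise ValueError("trajectory has zero frames")
    config = config or DetectionConfig()
    perception = perception or perceive(system)
    records = []
    for f in range(system.n_frames):
        for det in ALL_DETECTORS:
            records.extend(det(f, system, perception, config))
    return InteractionTable(records, system.n_frames)
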
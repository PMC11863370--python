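"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's geometry helpers: plain Python
loops, elementary vector algebra (Newell plane normals instead of SVD,
scipy's rotation fitting instead of the package's Kabsch), and a
from-definition DBSCAN. They enumerate every candidate pair and apply the
same thresholds, so any disagreement with the package points at a geometry
or bookkeeping bug, not at a modelling choice.
"""

from __future__ import annotations

import math

import numpy as np

RECEPTOR = ("protein", "nucleic", "special")


def _norm(v):
    return math.sqrt(float(v[0] ** 2 + v[1] ** 2 + v[2] ** 2))


def _dist(a, b):
    return _norm([a[0] - b[0], a[1] - b[1], a[2] - b[2]])


def _angle(a, b, c):
    v1 = [a[i] - b[i] for i in range(3)]
    v2 = [c[i] - b[i] for i in range(3)]
    dot = sum(v1[i] * v2[i] for i in range(3))
    cosv = max(-1.0, min(1.0, dot / (_norm(v1) * _norm(v2))))
    return math.degrees(math.acos(cosv))


def _newell_normal(pts):
    """Plane normal by Newell's method (sum of edge cross products)."""
    n = [0.0, 0.0, 0.0]
    m = len(pts)
    for i in range(m):
        p, q = pts[i], pts[(i + 1) % m]
        n[0] += (p[1] - q[1]) * (p[2] + q[2])
        n[1] += (p[2] - q[2]) * (p[0] + q[0])
        n[2] += (p[0] - q[0]) * (p[1] + q[1])
    length = _norm(n)
    return [c / length for c in n]


def _centroid(x, ids):
    pts = [x[i] for i in ids]
    return [sum(p[k] for p in pts) / len(pts) for k in range(3)]


# --------------------------------------------------------------------- #
# record comparison form


def record_set(records):
    """Canonical comparable form of detector output."""
    out = set()
    for r in records:
        wid = r.water_residue.identity() if r.water_residue else None
        out.add((r.itype, r.ligand_atom_ids, r.receptor_residue.identity(),
                 wid, r.flags))
    return out


# --------------------------------------------------------------------- #
# brute-force detectors


def oracle_hydrophobic(frame, system, p, c):
    x = system.frames[frame]
    hits = {}
    for i in sorted(p.apolar):
        if system.atoms[i].residue.component != "ligand":
            continue
        for j in sorted(p.apolar):
            if system.atoms[j].residue.component not in RECEPTOR:
                continue
            d = _dist(x[i], x[j])
            if d <= c.hydrophobic_dist_max:
                key = (i, system.atoms[j].residue)
                if key not in hits or d < hits[key]:
                    hits[key] = d
    return {("hydrophobic", (i,), res.identity(), None, ())
            for (i, res) in hits}


def oracle_hbonds(frame, system, p, c):
    x = system.frames[frame]
    atoms = system.atoms
    out = set()
    for d_id, h_ids in p.donors.items():
        for a_id in p.acceptors:
            dc, ac = atoms[d_id].residue.component, \
                atoms[a_id].residue.component
            if dc == "ligand" and ac in RECEPTOR:
                itype, lig = "hbond_donor", d_id
                res = atoms[a_id].residue
            elif dc in RECEPTOR and ac == "ligand":
                itype, lig = "hbond_acceptor", a_id
                res = atoms[d_id].residue
            else:
                continue
            if _dist(x[d_id], x[a_id]) > c.hbond_dist_max:
                continue
            if any(_angle(x[d_id], x[h], x[a_id]) >= c.hbond_don_angle_min
                   for h in h_ids):
                out.add((itype, (lig,), res.identity(), None, ()))
    return out


def _oracle_leg(x, partner, partner_hs, wo, w_hs, c):
    d = _dist(x[partner], x[wo])
    if not c.wb_dist_min <= d <= c.wb_dist_max:
        return False
    for h in partner_hs:
        if _angle(x[partner], x[h], x[wo]) >= c.hbond_don_angle_min:
            return True
    for h in w_hs:
        if _angle(x[wo], x[h], x[partner]) >= c.hbond_don_angle_min:
            return True
    return False


def oracle_water_bridges(frame, system, p, c):
    x = system.frames[frame]
    atoms = system.atoms
    polar = set(p.donors) | p.acceptors
    out = set()
    for wres, wo in p.water_oxygens.items():
        w_hs = [j for j in atoms[wo].bonded_ids if atoms[j].is_hydrogen]
        for li in polar:
            if atoms[li].residue.component != "ligand":
                continue
            if not _oracle_leg(x, li, p.donors.get(li, []), wo, w_hs, c):
                continue
            for ri in polar:
                if atoms[ri].residue.component not in RECEPTOR:
                    continue
                if not _oracle_leg(x, ri, p.donors.get(ri, []), wo, w_hs, c):
                    continue
                omega = _angle(x[li], x[wo], x[ri])
                if c.wb_omega_min <= omega <= c.wb_omega_max:
                    out.add(("water_bridge", (li,),
                             atoms[ri].residue.identity(),
                             wres.identity(), ()))
    return out


def oracle_salt_bridges(frame, system, p, c):
    x = system.frames[frame]
    out = set()
    for pg in p.pos_groups:
        for ng in p.neg_groups:
            if pg.owner == ng.owner:
                continue
            d = _dist(_centroid(x, pg.atom_ids), _centroid(x, ng.atom_ids))
            if d > c.saltbridge_dist_max:
                continue
            lig, rec = (pg, ng) if pg.owner == "ligand" else (ng, pg)
            out.add(("salt_bridge", tuple(sorted(lig.atom_ids)),
                     rec.residue.identity(), None, ()))
    return out


def oracle_pi_stacking(frame, system, p, c):
    x = system.frames[frame]
    out = set()
    for lr in p.rings:
        if lr.owner != "ligand":
            continue
        cl = _centroid(x, lr.atom_ids)
        nl = _newell_normal([x[i] for i in lr.atom_ids])
        for rr in p.rings:
            if rr.owner != "receptor":
                continue
            cr = _centroid(x, rr.atom_ids)
            nr = _newell_normal([x[i] for i in rr.atom_ids])
            if _dist(cl, cr) > c.pistack_dist_max:
                continue
            cosv = abs(sum(nl[k] * nr[k] for k in range(3)))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosv))))
            parallel = ang <= c.pistack_parallel_max
            tshape = c.pistack_tshape_min <= ang <= c.pistack_tshape_max
            if not (parallel or tshape):
                continue
            v = [cr[k] - cl[k] for k in range(3)]
            offs = []
            for nn in (nl, nr):
                proj = sum(v[k] * nn[k] for k in range(3))
                offs.append(_norm([v[k] - proj * nn[k] for k in range(3)]))
            if min(offs) > c.pistack_offset_max:
                continue
            out.add(("pi_stacking", tuple(sorted(lr.atom_ids)),
                     rr.residue.identity(), None, ()))
    return out


def oracle_pi_cation(frame, system, p, c):
    x = system.frames[frame]
    out = set()
    for ring in p.rings:
        for grp in p.pos_groups:
            if ring.owner == grp.owner:
                continue
            cr = _centroid(x, ring.atom_ids)
            nn = _newell_normal([x[i] for i in ring.atom_ids])
            cg = _centroid(x, grp.atom_ids)
            if _dist(cr, cg) > c.pication_dist_max:
                continue
            v = [cg[k] - cr[k] for k in range(3)]
            proj = sum(v[k] * nn[k] for k in range(3))
            off = _norm([v[k] - proj * nn[k] for k in range(3)])
            if off > c.pistack_offset_max:
                continue
            lig = ring.atom_ids if ring.owner == "ligand" else grp.atom_ids
            res = grp.residue if ring.owner == "ligand" else ring.residue
            out.add(("pi_cation", tuple(sorted(lig)), res.identity(),
                     None, ()))
    return out


def oracle_halogen(frame, system, p, c):
    x = system.frames[frame]
    atoms = system.atoms
    out = set()
    for c_id, x_id in p.halogen_donors:
        for a in atoms:
            if a.is_hydrogen or a.residue.component not in RECEPTOR:
                continue
            if a.element.upper() not in ("O", "N", "S"):
                continue
            y = a.atom_id
            if _dist(x[x_id], x[y]) > c.halogen_dist_max:
                continue
            don = _angle(x[c_id], x[x_id], x[y])
            if abs(don - c.halogen_don_angle) > c.halogen_don_tol:
                continue
            ok = False
            for j in atoms[y].bonded_ids:
                if atoms[j].is_hydrogen:
                    continue
                acc = _angle(x[j], x[y], x[x_id])
                if abs(acc - c.halogen_acc_angle) <= c.halogen_acc_tol:
                    ok = True
            if ok:
                out.add(("halogen", (x_id,), a.residue.identity(), None, ()))
    return out


def oracle_metal(frame, system, p, c):
    x = system.frames[frame]
    atoms = system.atoms
    out = set()
    for m in p.metals:
        mres = atoms[m].residue
        for a in atoms:
            if a.is_hydrogen or a.atom_id == m or a.residue == mres:
                continue
            if a.element.upper() not in ("O", "N", "S"):
                continue
            comp = a.residue.component
            if comp not in ("ligand", "water") + RECEPTOR:
                continue
            if _dist(x[m], x[a.atom_id]) > c.metal_dist_max:
                continue
            if comp == "ligand":
                out.add(("metal", (a.atom_id,), mres.identity(), None, ()))
            elif comp == "water":
                out.add(("metal", (), mres.identity(),
                         a.residue.identity(),
                         ("no_ligand", "water_coordination")))
            else:
                out.add(("metal", (), mres.identity(), None,
                         ("no_ligand", "receptor_coordination")))
    return out


ORACLES = {
    "hydrophobic": oracle_hydrophobic,
    "hbond": oracle_hbonds,
    "water_bridge": oracle_water_bridges,
    "salt_bridge": oracle_salt_bridges,
    "pi_stacking": oracle_pi_stacking,
    "pi_cation": oracle_pi_cation,
    "halogen": oracle_halogen,
    "metal": oracle_metal,
}


# --------------------------------------------------------------------- #
# from-definition DBSCAN


def dbscan_oracle(points, eps, min_samples):
    """Textbook DBSCAN: core = >= min_samples neighbours (incl. self)
    within eps; clusters grow by BFS from unvisited cores in index order;
    border points take the label of the first cluster reaching them."""
    pts = np.asarray(points, float)
    n = len(pts)
    neigh = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if _dist(pts[i], pts[j]) <= eps:
                neigh[i].add(j)
    core = [len(neigh[i]) >= min_samples for i in range(n)]
    labels = [-1] * n
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            q = queue.pop(0)
            if not core[q]:
                continue
            for j in sorted(neigh[q]):
                if labels[j] == -1:
                    labels[j] = cluster
                    queue.append(j)
        cluster += 1
    return labels


# --------------------------------------------------------------------- #
# rigid fitting via scipy (independent of the package's Kabsch)


def scipy_fit_rmsd(mobile, reference):
    from scipy.spatial.transform import Rotation
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    mc, rc = mob - mob.mean(axis=0), ref - ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(rc, mc)
    aligned = rot.apply(mc)
    return float(np.sqrt(((aligned - rc) ** 2).sum(axis=1).mean()))


def scipy_rmsd_after_fit(mobile, reference, fit_mobile, fit_reference):
    from scipy.spatial.transform import Rotation
    fm = np.asarray(fit_mobile, float)
    fr = np.asarray(fit_reference, float)
    cm, cr = fm.mean(axis=0), fr.mean(axis=0)
    rot, _ = Rotation.align_vectors(fr - cr, fm - cm)
    aligned = rot.apply(np.asarray(mobile, float) - cm) + cr
    diff = aligned - np.asarray(reference, float)
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def representative_oracle(frames, system):
    """Exhaustive pairwise ligand-RMSD matrix; earliest argmin of the mean."""
    frames = sorted(frames)
    if len(frames) == 1:
        return frames[0]
    lig = system.ligand_heavy_ids()
    bb = system.backbone_ids()
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = system.frames[frames[i]], system.frames[frames[j]]
            # the after-fit pair RMSD is symmetric in the two frames
            r = scipy_rmsd_after_fit(xj[lig], xi[lig], xj[bb], xi[bb])
            mat[i, j] = mat[j, i] = r
    means = mat.sum(axis=1) / (n - 1)
    return frames[int(np.argmin(means))]
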
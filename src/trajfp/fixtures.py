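"""Synthetic toy systems with scripted, known-truth interaction schedules.

The generator builds a small rigid "receptor" around a fixed multivalent
ligand: one probe residue per interaction type, each sitting on its own
axis pointing away from the ligand moiety it targets. In frames where an
interaction is scheduled the probe sits at a geometry satisfying the
detector's thresholds with >= 10 % margin; in all other frames it is
translated outward along its axis far enough to violate them with >= 10 %
margin. Waters follow per-water plans: pinned to a hydration site (with a
small clipped jitter) in their occupied frames, teleporting across a remote
shell otherwise (so they are never "stable" there). Geometry is scripted,
not simulated — there is no force field and no dynamics; the point is exact
ground truth for every analysis stage.

Emitted files are the same formats the analyzer consumes: PDB topology,
DCD trajectory, SDF V2000 ligand. Everything is deterministic given the
spec seed (waters and ligand jitter draw from separate RNG streams so that
editing one part of a spec does not change another's randomness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ITYPE_ORDER = ("hydrophobic", "hbond_donor", "hbond_acceptor",
               "water_bridge", "salt_bridge", "pi_stacking", "pi_cation",
               "halogen", "metal")

OUT_SHIFT = 3.0          # Å translation along the probe axis when "out"
BRIDGE_WATER_RESID = 501
PLAN_WATER_RESID0 = 601


# --------------------------------------------------------------------- #
# spec


@dataclass(frozen=True)
class ScheduleEntry:
    """One scripted interaction: which detector fires in which frames."""

    itype: str
    frames: frozenset

    def __post_init__(self):
        if self.itype not in ITYPE_ORDER:
            raise ValueError(f"unknown itype {self.itype!r}")
        object.__setattr__(self, "frames", frozenset(int(f)
                                                     for f in self.frames))


@dataclass(frozen=True)
class WaterPlan:
    """One water: pinned at ``site`` in its occupied frames, diffusive
    elsewhere. ``site=None`` means always diffusive."""

    site: tuple
    occupied_frames: frozenset = frozenset()
    sigma: float = 0.1

    def __post_init__(self):
        object.__setattr__(self, "occupied_frames",
                           frozenset(int(f) for f in self.occupied_frames))
        if self.site is not None:
            object.__setattr__(self, "site", tuple(float(v)
                                                   for v in self.site))


@dataclass
class SyntheticSystemSpec:
    n_frames: int = 10
    schedule: list = field(default_factory=list)
    waters: list = field(default_factory=list)
    ligand_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        seen = set()
        for e in self.schedule:
            if e.itype in seen:
                raise ValueError(
                    f"duplicate schedule entry for {e.itype}; each probe "
                    "exists once")
            seen.add(e.itype)
            bad = [f for f in e.frames
                   if f < 0 or f >= self.n_frames]
            if bad:
                raise ValueError(f"scheduled frames {bad} outside "
                                 f"[0, {self.n_frames})")
        for w in self.waters:
            bad = [f for f in w.occupied_frames if f >= self.n_frames]
            if bad:
                raise ValueError(f"water frames {bad} out of range")

    @classmethod
    def from_dict(cls, d):
        """Build a spec from a plain config mapping (e.g. parsed YAML).

        Keys: ``n_frames`` (int), ``seed`` (int), ``ligand_jitter`` (float),
        ``schedule`` (list of {itype, frames}), ``waters`` (list of
        {site: [x,y,z], frames: [...], sigma}). ``frames`` may be a list of
        ints or a string like ``"0-4,7"``.
        """
        def parse_frames(v):
            if isinstance(v, str):
                out = set()
                for part in v.split(","):
                    part = part.strip()
                    if "-" in part:
                        a, b = part.split("-")
                        out.update(range(int(a), int(b) + 1))
                    elif part:
                        out.add(int(part))
                return frozenset(out)
            return frozenset(int(f) for f in v)

        schedule = [ScheduleEntry(e["itype"], parse_frames(e["frames"]))
                    for e in d.get("schedule", [])]
        waters = [WaterPlan(tuple(w["site"]) if w.get("site") else None,
                            parse_frames(w.get("frames", [])),
                            float(w.get("sigma", 0.1)))
                  for w in d.get("waters", [])]
        return cls(n_frames=int(d.get("n_frames", 10)), schedule=schedule,
                   waters=waters,
                   ligand_jitter=float(d.get("ligand_jitter", 0.05)),
                   seed=int(d.get("seed", 0)))


# --------------------------------------------------------------------- #
# ligand template (all coordinates in Å)

_R = 1.39
_U = {i: (math.cos(math.radians(60 * i)), math.sin(math.radians(60 * i)), 0.0)
      for i in range(6)}


def _v(*a):
    return np.array(a, dtype=float)


def _ax(i):
    return _v(*_U[i])


# benzene scaffold; every position substituted so ring apolar carbons are
# exactly C1/C3/C5
_C = {n: _R * _ax(i) for n, i in
      (("C1", 0), ("C2", 1), ("C3", 2), ("C4", 3), ("C5", 4), ("C6", 5))}

LIGAND_HEAVY = [
    # (name, element, position, formal_charge)
    ("C1", "C", _C["C1"], 0),
    ("C2", "C", _C["C2"], 0),
    ("C3", "C", _C["C3"], 0),
    ("C4", "C", _C["C4"], 0),
    ("C5", "C", _C["C5"], 0),
    ("C6", "C", _C["C6"], 0),
    ("C7", "C", _C["C1"] + 1.50 * _ax(0), 0),          # methyl (hydrophobic)
    ("CL1", "Cl", _C["C2"] + 1.75 * _ax(1), 0),        # halogen donor
    ("C9", "C", _C["C3"] + 1.50 * _ax(2), 0),
    ("N1", "N", _C["C3"] + 2.97 * _ax(2), 1),          # ammonium (salt bridge)
    ("O1", "O", _C["C4"] + 1.36 * _ax(3), 0),          # hydroxyl (H donor)
    ("C8", "C", _C["C5"] + 1.50 * _ax(4), 0),
    ("O2", "O", _C["C5"] + 2.73 * _ax(4), 0),          # carbonyl (acceptor)
    ("O3", "O", _C["C6"] + 1.36 * _ax(5), 0),          # hydroxyl (water bridge)
]

_P = {n: p for n, _, p, _ in LIGAND_HEAVY}

LIGAND_H = [
    ("H71", _P["C7"] + 1.09 * _v(0.33, 0.94, 0.0)),
    ("H72", _P["C7"] + 1.09 * _v(0.33, -0.47, 0.82)),
    ("H73", _P["C7"] + 1.09 * _v(0.33, -0.47, -0.82)),
    ("H91", _P["C9"] + 1.09 * _v(0.0, 0.0, 1.0)),
    ("H92", _P["C9"] + 1.09 * _v(0.0, 0.0, -1.0)),
    # ammonium hydrogens point out of plane so they never aim at the
    # carboxylate probe (donor angle stays < 90 deg)
    ("HN1", _P["N1"] + 1.01 * _v(0.0, 0.0, 1.0)),
    ("HN2", _P["N1"] + 1.01 * _v(0.0, 0.0, -1.0)),
    ("HO1", _P["O1"] + 0.96 * _v(-1.0, 0.0, 0.0)),
    ("HO3", _P["O3"] + 0.96 * _v(0.0, 0.0, 1.0)),
]

# SDF bond list over heavy-atom names: (a, b, order) with 12 = aromatic
LIGAND_BONDS = [
    ("C1", "C2", 12), ("C2", "C3", 12), ("C3", "C4", 12),
    ("C4", "C5", 12), ("C5", "C6", 12), ("C6", "C1", 12),
    ("C1", "C7", 1), ("C2", "CL1", 1), ("C3", "C9", 1), ("C9", "N1", 1),
    ("C4", "O1", 1), ("C5", "C8", 1), ("C8", "O2", 2), ("C6", "O3", 1),
]

RING_NAMES = ("C1", "C2", "C3", "C4", "C5", "C6")


# --------------------------------------------------------------------- #
# probe residues


def _perp(u):
    u = np.asarray(u, float)
    ref = _v(0, 0, 1) if abs(u[2]) < 0.9 else _v(1, 0, 0)
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


def _backbone(ca, u, p):
    """Minimal N-H, CA, C=O backbone fanning out along +u."""
    ca = np.asarray(ca, float)
    n = ca + 1.46 * (0.5 * u + 0.866 * p)
    return [("N", "N", n), ("H", "H", n + 1.01 * u), ("CA", "C", ca),
            ("C", "C", ca + 1.52 * (0.5 * u - 0.866 * p)),
            ("O", "O", ca + 1.52 * (0.5 * u - 0.866 * p) + 1.23 * u)]


def _probe_hydrophobic():
    u, p = _ax(0), _v(0, 1, 0)
    cd1 = _P["C7"] + 3.4 * u
    cg = cd1 + 1.53 * u
    cd2 = cg + 1.53 * _v(0.33, 0.94, 0)
    cb = cg + 1.53 * _v(0.33, -0.94, 0)
    ca = cb + 1.53 * _v(0.707, -0.707, 0)
    atoms = [("CD1", "C", cd1), ("CG", "C", cg), ("CD2", "C", cd2),
             ("CB", "C", cb)] + _backbone(ca, u, p)
    return "LEU", atoms, u


def _probe_hbond_donor():
    u, p = -_ax(0), _v(0, -1, 0)
    od1 = _P["O1"] + 2.9 * u                       # ligand O1-H ... OD1
    cg = od1 + 1.23 * u
    nd2 = cg + 1.33 * _v(-0.5, 0.866, 0)
    cb = cg + 1.53 * _v(-0.5, -0.866, 0)
    ca = cb + 1.53 * _v(-0.94, 0.33, 0)
    atoms = [("OD1", "O", od1), ("CG", "C", cg), ("ND2", "N", nd2),
             ("HD21", "H", nd2 + 1.01 * _v(-0.5, 0.866, 0)),
             ("HD22", "H", nd2 + 1.01 * _v(0, 0, 1.0)),
             ("CB", "C", cb)] + _backbone(ca, u, p)
    return "ASN", atoms, u


def _probe_hbond_acceptor():
    u = _ax(4)                                     # NE2-H ... O2 (ligand)
    p = _v(-0.866, 0.5, 0)
    ne2 = _P["O2"] + 2.9 * u
    cd = ne2 + 1.33 * (0.5 * u + 0.866 * p)
    oe1 = cd + 1.23 * _v(-0.707, 0.707, 0)
    cg = cd + 1.53 * _v(0, -1.0, 0)
    cb = cg + 1.53 * _v(-0.5, -0.866, 0)
    ca = cb + 1.53 * _v(-0.5, -0.866, 0)
    atoms = [("NE2", "N", ne2),
             ("HE21", "H", ne2 + 1.01 * (-u)),
             ("HE22", "H", ne2 + 1.01 * _v(0, 0, 1.0)),
             ("CD", "C", cd), ("OE1", "O", oe1), ("CG", "C", cg),
             ("CB", "C", cb)] + _backbone(ca, u, p)
    return "GLN", atoms, u


_WB_D1 = _v(0.5, -0.866, 0.0)                      # ligand O3 -> water
_WB_V = _v(0.25, -0.433, 0.866)                    # water -> receptor OG
WB_WATER_SITE = _P["O3"] + 3.2 * _WB_D1


def _probe_water_bridge_receptor():
    """The SER side of the ligand-water-receptor bridge (always in place;
    the scheduling degree of freedom is the water)."""
    og = WB_WATER_SITE + 3.2 * _WB_V
    u_out = _v(0.433, -0.75, 0.5)
    p = _perp(u_out)
    cb = og + 1.43 * u_out
    ca = cb + 1.53 * u_out
    # HG sideways (perpendicular to both the water leg and the CB chain)
    hg = og + 0.96 * _v(-0.866, -0.5, 0.0)
    atoms = [("OG", "O", og), ("HG", "H", hg),
             ("CB", "C", cb)] + _backbone(ca, u_out, p)
    return "SER", atoms, u_out


def _probe_salt_bridge():
    u = _ax(2)
    p = _v(0.866, 0.5, 0)                          # in-plane perpendicular
    mid = _P["N1"] + 4.0 * u
    od1, od2 = mid + 1.1 * p, mid - 1.1 * p
    cg = mid + 0.75 * u
    cb = cg + 1.53 * u
    ca = cb + 1.53 * u
    atoms = [("OD1", "O", od1), ("OD2", "O", od2), ("CG", "C", cg),
             ("CB", "C", cb)] + _backbone(ca, u, p)
    return "ASP", atoms, u


def _probe_pi_stacking():
    u, p = _v(0, 0, 1.0), _v(1.0, 0, 0)
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    ring = [(n, "C", _v(_R * math.cos(math.radians(30 + 60 * i)),
                        _R * math.sin(math.radians(30 + 60 * i)), 4.7))
            for i, n in enumerate(names)]
    climb = _v(0.537, 0.31, 0.78)
    cb = ring[0][2] + 1.53 * climb
    ca = cb + 1.53 * climb
    atoms = ring + [("CB", "C", cb)] + _backbone(ca, u, p)
    return "PHE", atoms, u


def _probe_pi_cation():
    u, p = _v(0, 0, -1.0), _v(1.0, 0, 0)
    nz = _v(0, 0, -4.5)
    ce = nz + 1.48 * u
    cd = ce + 1.53 * u
    cg = cd + 1.53 * _v(0.33, 0, -0.94)
    cb = cg + 1.53 * _v(0.33, 0, -0.94)
    ca = cb + 1.53 * _v(0.33, 0, -0.94)
    atoms = [("NZ", "N", nz),
             ("HZ1", "H", nz + 1.01 * _v(0.94, 0, 0.34)),
             ("HZ2", "H", nz + 1.01 * _v(-0.47, 0.814, 0.34)),
             ("HZ3", "H", nz + 1.01 * _v(-0.47, -0.814, 0.34)),
             ("CE", "C", ce), ("CD", "C", cd), ("CG", "C", cg),
             ("CB", "C", cb)] + _backbone(ca, u, p)
    return "LYS", atoms, u


def _probe_halogen():
    # C2-Cl ... O=C at 170 deg / 120 deg; the acceptor is the GLY backbone O
    u2p = _v(0.342, 0.940, 0.0)                    # Cl->O direction
    q = _v(-0.940, 0.342, 0.0)
    y = _P["CL1"] + 3.3 * u2p
    m = 0.5 * u2p + 0.866 * q
    c = y + 1.23 * m
    ca = c + 1.52 * u2p
    n = ca + 1.46 * q
    atoms = [("O", "O", y), ("C", "C", c), ("CA", "C", ca),
             ("N", "N", n), ("H", "H", n + 1.01 * _v(0, 1.0, 0))]
    return "GLY", atoms, u2p


FE_SITE = _P["O2"] + 2.2 * _v(0, 0, 1.0)

PROBE_BUILDERS = {
    "hydrophobic": _probe_hydrophobic,
    "hbond_donor": _probe_hbond_donor,
    "hbond_acceptor": _probe_hbond_acceptor,
    "salt_bridge": _probe_salt_bridge,
    "pi_stacking": _probe_pi_stacking,
    "pi_cation": _probe_pi_cation,
    "halogen": _probe_halogen,
}
PROBE_RESIDS = {"hydrophobic": 1, "hbond_donor": 2, "hbond_acceptor": 3,
                "water_bridge": 4, "salt_bridge": 5, "pi_stacking": 6,
                "pi_cation": 7, "halogen": 8}
PROBE_RESNAMES = {"hydrophobic": "LEU", "hbond_donor": "ASN",
                  "hbond_acceptor": "GLN", "water_bridge": "SER",
                  "salt_bridge": "ASP", "pi_stacking": "PHE",
                  "pi_cation": "LYS", "halogen": "GLY"}


# --------------------------------------------------------------------- #
# assembling the system


@dataclass
class GroundTruth:
    """Construction-time truth tables for a generated system."""

    n_frames: int
    expected_keys: dict          # InteractionKey -> frozenset(frames)
    expected_waters: list        # [(site, frames_covered, coverage_pct)]
    atom_index: dict             # (residue label or "LIG") name -> atom id

    def expected_occurrence_pct(self):
        return {k: 100.0 * len(fr) / self.n_frames
                for k, fr in self.expected_keys.items()}


def _atom_rows(spec):
    """Static atom table: (name, element, resname, chain, resid, base_pos,
    group) where group tags which scheduling block moves the atom."""
    rows = []
    for itype in ITYPE_ORDER:
        if itype in ("water_bridge", "metal"):
            continue
        resname, atoms, u = PROBE_BUILDERS[itype]()
        for name, el, pos in atoms:
            rows.append([name, el, resname, "A", PROBE_RESIDS[itype],
                         np.asarray(pos, float), itype, np.asarray(u, float)])
    # SER side of the water bridge: static
    resname, atoms, _ = _probe_water_bridge_receptor()
    for name, el, pos in atoms:
        rows.append([name, el, resname, "A", PROBE_RESIDS["water_bridge"],
                     np.asarray(pos, float), None, None])
    # ligand
    for name, el, pos, chg in LIGAND_HEAVY:
        rows.append([name, el, "LIG", "L", 100, np.asarray(pos, float),
                     "ligand", None])
    for name, pos in LIGAND_H:
        rows.append([name, "H", "LIG", "L", 100, np.asarray(pos, float),
                     "ligand", None])
    # metal ion
    rows.append(["FE", "Fe", "FE", "I", 200, FE_SITE.copy(), "metal",
                 _v(0, 0, 1.0)])
    # bridge water
    for name, el, off in (("O", "O", _v(0, 0, 0)),
                          ("H1", "H", 0.96 * (-_WB_D1)),
                          ("H2", "H", 0.96 * _WB_V)):
        rows.append([name, el, "HOH", "W", BRIDGE_WATER_RESID,
                     WB_WATER_SITE + off, "bridge_water", None])
    return rows


def _water_rows(spec):
    rows = []
    for i, plan in enumerate(spec.waters):
        resid = PLAN_WATER_RESID0 + i
        for name, el, off in (("O", "O", _v(0, 0, 0)),
                              ("H1", "H", _v(0.76, 0.59, 0)),
                              ("H2", "H", _v(-0.76, 0.59, 0))):
            rows.append([name, el, "HOH", "W", resid, off, f"plan_{i}", None])
    return rows


def _clipped_jitter(rng, sigma, cap=0.35):
    j = rng.normal(0.0, sigma, 3)
    n = np.linalg.norm(j)
    return j if n <= cap else j * (cap / n)


def _remote_point(rng, prev):
    while True:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos = d * rng.uniform(18.0, 25.0)
        if prev is None or np.linalg.norm(pos - prev) >= 1.5:
            return pos


def build_frames(spec):
    """Per-frame coordinates + atom table + ground truth (no file I/O)."""
    rows = _atom_rows(spec) + _water_rows(spec)
    F = spec.n_frames
    n = len(rows)
    scheduled = {e.itype: e.frames for e in spec.schedule}

    ss = np.random.SeedSequence([int(spec.seed) % (2 ** 31), 77])
    lig_ss, wat_ss = ss.spawn(2)
    rng_lig = np.random.default_rng(lig_ss)
    rng_wat = np.random.default_rng(wat_ss)

    coords = np.zeros((F, n, 3))
    lig_shift = np.stack([_clipped_jitter(rng_lig, spec.ligand_jitter,
                                          cap=0.12)
                          if spec.ligand_jitter > 0 else np.zeros(3)
                          for _ in range(F)])

    # plan-water trajectories (separate stream drawn in plan order)
    plan_tracks = {}
    for i, plan in enumerate(spec.waters):
        track = np.zeros((F, 3))
        prev = None
        for f in range(F):
            if plan.site is not None and f in plan.occupied_frames:
                track[f] = np.asarray(plan.site) + \
                    _clipped_jitter(rng_wat, plan.sigma)
            else:
                track[f] = _remote_point(rng_wat, prev)
            prev = track[f]
        plan_tracks[f"plan_{i}"] = track

    wb_frames = scheduled.get("water_bridge", frozenset())
    wb_track = np.zeros((F, 3))
    prev = None
    for f in range(F):
        if f in wb_frames:
            wb_track[f] = np.zeros(3)   # offset from the bridge site
        else:
            wb_track[f] = _remote_point(rng_wat, prev) - WB_WATER_SITE
        prev = wb_track[f] + WB_WATER_SITE

    for f in range(F):
        for j, row in enumerate(rows):
            name, el, resname, chain, resid, base, group, axis = row
            pos = base.copy()
            if group == "ligand":
                pos += lig_shift[f]
            elif group == "bridge_water":
                pos += wb_track[f]
            elif group == "metal" or group in scheduled or \
                    (group is not None and group.startswith("plan_")):
                if group is not None and group.startswith("plan_"):
                    pos = plan_tracks[group][f] + base  # base = intra-water offset
                elif f not in scheduled.get(group, frozenset()):
                    pos += OUT_SHIFT * axis
            elif group is not None and axis is not None:
                if f not in scheduled.get(group, frozenset()):
                    pos += OUT_SHIFT * axis
            coords[f, j] = pos

    truth = _ground_truth(spec, rows)
    return rows, coords, truth


def _ground_truth(spec, rows):
    from .detection import InteractionKey

    index = {}
    for j, row in enumerate(rows):
        name, _, resname, chain, resid, *_ = row
        index[(chain, resid, name)] = j

    def lig(name):
        return index[("L", 100, name)]

    ring_ids = tuple(sorted(lig(n) for n in RING_NAMES))
    moiety = {
        "hydrophobic": (lig("C7"),),
        "hbond_donor": (lig("O1"),),
        "hbond_acceptor": (lig("O2"),),
        "water_bridge": (lig("O3"),),
        "salt_bridge": (lig("N1"),),
        "pi_stacking": ring_ids,
        "pi_cation": ring_ids,
        "halogen": (lig("CL1"),),
        "metal": (lig("O2"),),
    }
    residue = {it: ("A", PROBE_RESNAMES[it], PROBE_RESIDS[it])
               for it in PROBE_RESNAMES}
    residue["metal"] = ("I", "FE", 200)

    expected_keys = {}
    for e in spec.schedule:
        key = InteractionKey(e.itype, moiety[e.itype], residue[e.itype])
        expected_keys[key] = e.frames

    expected_waters = []
    for plan in spec.waters:
        if plan.site is None:
            continue
        covered = {f for f in range(1, spec.n_frames)
                   if f in plan.occupied_frames
                   and (f - 1) in plan.occupied_frames}
        if len(covered) >= 2:   # DBSCAN min_samples default
            expected_waters.append(
                (np.asarray(plan.site, float), frozenset(covered),
                 100.0 * len(covered) / spec.n_frames))
    wb = frozenset(
        f for f in range(1, spec.n_frames)
        if {f, f - 1} <= set(
            next((e.frames for e in spec.schedule
                  if e.itype == "water_bridge"), frozenset())))
    if len(wb) >= 2:
        expected_waters.append((WB_WATER_SITE.copy(), wb,
                                100.0 * len(wb) / spec.n_frames))

    atom_index = {f"{r}:{n}": index[(c, r, n)]
                  for (c, r, n) in index for _ in [0]}
    return GroundTruth(n_frames=spec.n_frames, expected_keys=expected_keys,
                       expected_waters=expected_waters,
                       atom_index=atom_index)


def scripted_mode_sequence(spec, threshold_pct=40.0):
    """Expected mode id per frame, derived from the schedule alone.

    Mirrors the mode-enumeration rules: keys qualify at frequency >=
    threshold; frames group by identical qualifying-key sets; modes rank by
    occurrence (ties -> earliest first frame) and are numbered by rank.
    """
    F = spec.n_frames
    qualifying = [e for e in spec.schedule
                  if 100.0 * len(e.frames) / F >= threshold_pct]
    fps = [frozenset(e.itype for e in qualifying if f in e.frames)
           for f in range(F)]
    groups = {}
    for f, fp in enumerate(fps):
        groups.setdefault(fp, []).append(f)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    label = {fp: i for i, (fp, _) in enumerate(ordered)}
    return [label[fp] for fp in fps]


# --------------------------------------------------------------------- #
# file writers


def _write_pdb(rows, coords0, path):
    lines = []
    for serial, (row, pos) in enumerate(zip(rows, coords0), start=1):
        name, el, resname, chain, resid, *_ = row
        rec = "ATOM  " if chain == "A" else "HETATM"
        pname = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"{rec}{serial:5d} {pname[:4]:<4s} {resname:<3s} {chain}"
            f"{resid:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {el.upper():>2s}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_ligand_sdf(path):
    """Ligand as SDF V2000 (aromatic ring, formal charge, bond orders);
    heavy atoms in the same order as the PDB ligand residue."""
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401  (registers writers)
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    idx = {}
    for name, el, pos, chg in LIGAND_HEAVY:
        a = Chem.Atom(el)
        a.SetFormalCharge(chg)
        idx[name] = mol.AddAtom(a)
    order = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
             12: Chem.BondType.AROMATIC}
    for a, b, o in LIGAND_BONDS:
        mol.AddBond(idx[a], idx[b], order[o])
    conf = Chem.Conformer(mol.GetNumAtoms())
    for name, el, pos, chg in LIGAND_HEAVY:
        conf.SetAtomPosition(idx[name], Point3D(*pos))
    mol.AddConformer(conf)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    with Chem.SDWriter(str(path)) as w:
        w.write(m)
    return path


def _write_dcd(rows, coords, pdb_path, dcd_path):
    import warnings
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path))
        with mda.coordinates.DCD.DCDWriter(str(dcd_path),
                                           n_atoms=len(rows)) as w:
            for f in range(coords.shape[0]):
                u.atoms.positions = coords[f]
                w.write(u.atoms)


def generate_system(spec, out_dir):
    """Emit topology.pdb + traj.dcd + ligand.sdf and return
    (paths dict, GroundTruth)."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, coords, truth = build_frames(spec)
    _validate_margins(spec, rows, coords)
    pdb = out / "topology.pdb"
    dcd = out / "traj.dcd"
    sdf = out / "ligand.sdf"
    _write_pdb(rows, coords[0], pdb)
    _write_dcd(rows, coords, pdb, dcd)
    write_ligand_sdf(sdf)
    return {"topology": str(pdb), "trajectory": str(dcd),
            "ligand_sdf": str(sdf)}, truth


# primary distance criterion per probe: (ligand atom, probe atom, max/min)
_MARGIN_CHECKS = {
    "hydrophobic": ("C7", "CD1", 4.0),
    "hbond_donor": ("O1", "OD1", 4.1),
    "hbond_acceptor": ("O2", "NE2", 4.1),
    "salt_bridge": ("N1", None, 5.5),       # vs OD1/OD2 centroid
    "pi_stacking": (None, None, 5.5),       # ring-centroid distance
    "pi_cation": (None, "NZ", 6.0),
    "halogen": ("CL1", "O", 4.0),
    "metal": ("O2", "FE", 3.0),
    "water_bridge": ("O3", "O", None),      # leg window handled inline
}


def _validate_margins(spec, rows, coords):
    """Construction-time check: scheduled frames satisfy the primary
    distance criterion with >= 10 % margin, unscheduled frames violate it
    with >= 10 % margin."""
    index = {}
    for j, row in enumerate(rows):
        name, _, resname, chain, resid, *_ = row
        index[(chain, resid, name)] = j

    def pos(f, chain, resid, name):
        return coords[f, index[(chain, resid, name)]]

    ring_ids = [index[("L", 100, n)] for n in RING_NAMES]
    for e in spec.schedule:
        lig_name, probe_name, cutoff = _MARGIN_CHECKS[e.itype]
        for f in range(spec.n_frames):
            if e.itype == "water_bridge":
                d = np.linalg.norm(pos(f, "L", 100, "O3") -
                                   pos(f, "W", BRIDGE_WATER_RESID, "O"))
                lo, hi = 2.5, 4.1
                ok = lo * 1.1 <= d <= hi * 0.9 if f in e.frames \
                    else not (lo * 0.9 <= d <= hi * 1.1)
            else:
                if e.itype == "pi_stacking":
                    a = coords[f, ring_ids].mean(axis=0)
                    phe = [index[("A", PROBE_RESIDS["pi_stacking"], n)]
                           for n in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
                    b = coords[f, phe].mean(axis=0)
                elif e.itype == "pi_cation":
                    a = coords[f, ring_ids].mean(axis=0)
                    b = pos(f, "A", PROBE_RESIDS["pi_cation"], "NZ")
                elif e.itype == "salt_bridge":
                    a = pos(f, "L", 100, "N1")
                    r = PROBE_RESIDS["salt_bridge"]
                    b = 0.5 * (pos(f, "A", r, "OD1") + pos(f, "A", r, "OD2"))
                elif e.itype == "metal":
                    a = pos(f, "L", 100, lig_name)
                    b = pos(f, "I", 200, "FE")
                else:
                    a = pos(f, "L", 100, lig_name)
                    b = pos(f, "A", PROBE_RESIDS[e.itype], probe_name)
                d = np.linalg.norm(a - b)
                ok = d <= cutoff * 0.9 if f in e.frames else d >= cutoff * 1.1
            if not ok:
                raise ValueError(
                    f"schedule for {e.itype} is geometrically inconsistent "
                    f"at frame {f} (distance {d:.2f})")
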
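"""Vector, ring-plane and rigid-superposition primitives.

Angles between ring normals are always folded into [0°, 90°] because plane
normals carry an arbitrary sign; no downstream test may depend on normal
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def angle_deg(a, b, c) -> float:
    """Angle at vertex ``b`` of the triangle a-b-c, in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate angle (coincident points)")
    cosv = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


def fold_angle_90(angle: float) -> float:
    """Fold an angle to [0°, 90°] (plane normals are sign-ambiguous)."""
    a = abs(angle) % 180.0
    return 180.0 - a if a > 90.0 else a


def vector_angle_deg(v1, v2) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length vector")
    cosv = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


@dataclass
class RingDescriptor:
    """Plane fit of a ring: centroid, unit normal, out-of-plane RMS (Å)."""

    atom_ids: tuple
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float


def ring_descriptor(coords, atom_ids=None) -> RingDescriptor:
    """Centroid + least-squares plane normal of >= 3 atoms.

    The normal is the singular vector of the smallest principal axis;
    collinear input is rejected.
    """
    pts = np.asarray(coords, float)
    if pts.shape[0] < 3:
        raise ValueError("ring needs at least 3 atoms")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vh = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("collinear atoms do not define a plane")
    normal = vh[2] / np.linalg.norm(vh[2])
    oop = centered @ normal
    return RingDescriptor(
        atom_ids=tuple(atom_ids) if atom_ids is not None else
        tuple(range(pts.shape[0])),
        centroid=centroid, normal=normal,
        planarity_rms=float(np.sqrt((oop ** 2).mean())))


@dataclass
class SuperpositionResult:
    """Least-squares rigid fit: x_aligned = x @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose(mobile_coords, reference_coords) -> SuperpositionResult:
    """Kabsch least-squares rigid fit of ``mobile`` onto ``reference``.

    Uses the SVD of the cross-covariance with the determinant sign fix so
    the rotation is always proper (det = +1). Requires >= 3 non-collinear
    points in the reference.
    """
    mob = np.asarray(mobile_coords, float)
    ref = np.asarray(reference_coords, float)
    if mob.shape != ref.shape:
        raise ValueError("point counts differ")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 points")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    mc, rc = mob - cm, ref - cr
    _, s, _ = np.linalg.svd(rc)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) reference geometry")
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    aligned = mob @ rot.T + trans
    rmsd = float(np.sqrt(((aligned - ref) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_after_fit(mobile, reference, fit_mobile, fit_reference) -> float:
    """RMSD of ``mobile`` vs ``reference`` after fitting on a different
    atom selection (the usual ligand-after-backbone-fit metric)."""
    fit = superpose(fit_mobile, fit_reference)
    aligned = fit.apply(mobile)
    return float(np.sqrt(((aligned - np.asarray(reference, float)) ** 2)
                         .sum(axis=1).mean()))


def rmsd_series(system, analysis_ids, fit_ids=None):
    """Per-frame heavy-atom RMSD of a selection vs frame 0.

    Each frame is first rigid-fitted on ``fit_ids`` (protein backbone by
    default); the RMSD is then measured over the heavy atoms of
    ``analysis_ids``. Frame 0 is 0 by construction.
    """
    if fit_ids is None:
        fit_ids = system.backbone_ids()
    for i in list(analysis_ids) + list(fit_ids):
        if i < 0 or i >= system.n_atoms:
            raise ValueError(f"selection names absent atom id {i}")
    analysis_ids = [i for i in analysis_ids
                    if not system.atoms[i].is_hydrogen]
    if len(analysis_ids) == 0:
        raise ValueError("empty analysis selection")
    if len(fit_ids) == 0:
        raise ValueError("empty fit selection")
    ref = system.frames[0]
    out = np.empty(system.n_frames)
    for f in range(system.n_frames):
        cur = system.frames[f]
        out[f] = rmsd_after_fit(cur[analysis_ids], ref[analysis_ids],
                                cur[fit_ids], ref[fit_ids])
    return out
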
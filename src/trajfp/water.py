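"""Stable-water tracing, density clustering, occurrence tiers and
water-bridge attribution.

A water is *stable* across a frame transition when its oxygen moves strictly
less than ``displacement_max`` (default 1 Å) between the two consecutive
frames; each such transition contributes the oxygen position at the later
frame to a pooled point set. DBSCAN (eps default 1 Å, min_samples 2) on the
pool yields hydration sites; every cluster is then filed into each of the
five coverage tiers (25/50/75/90/99 % of frames) whose threshold it meets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import WaterConfig
from .perception import RECEPTOR_COMPONENTS

log = logging.getLogger(__name__)


@dataclass
class WaterEntry:
    """One low-displacement observation: water O position at frame f,
    having moved < displacement_max since frame f-1."""

    frame: int
    water_residue: object
    coord: np.ndarray


@dataclass
class StableWaterPool:
    entries: list = field(default_factory=list)
    n_frames: int = 0

    def coords(self) -> np.ndarray:
        if not self.entries:
            return np.empty((0, 3))
        return np.stack([e.coord for e in self.entries])


@dataclass
class WaterCluster:
    cluster_id: int
    entries: list
    frames_covered: set = None
    coverage_pct: float = 0.0
    tiers: tuple = ()
    representative: WaterEntry = None
    nearby_residues: list = field(default_factory=list)

    def centroid(self) -> np.ndarray:
        return np.stack([e.coord for e in self.entries]).mean(axis=0)


def trace_stable_waters(system, displacement_max=1.0) -> StableWaterPool:
    """Collect water O positions that moved < displacement_max (strict)
    between consecutive frames. F frames give F-1 opportunities per water."""
    if system.n_frames < 2:
        raise ValueError("need at least 2 frames to trace water movement")
    oxygens = system.water_oxygen_ids()
    pool = StableWaterPool(n_frames=system.n_frames)
    if not oxygens:
        log.warning("system contains no waters; stable-water pool is empty")
        return pool
    items = sorted(oxygens.items(), key=lambda kv: kv[0])
    ids = [i for _, i in items]
    residues = [r for r, _ in items]
    prev = system.frames[0][ids]
    for f in range(1, system.n_frames):
        cur = system.frames[f][ids]
        disp = np.linalg.norm(cur - prev, axis=1)
        for w in np.nonzero(disp < displacement_max)[0]:
            pool.entries.append(WaterEntry(frame=f, water_residue=residues[w],
                                           coord=cur[w].copy()))
        prev = cur
    return pool


def cluster_stable_waters(pool, eps=1.0, min_samples=2):
    """DBSCAN over pooled 3-D positions; noise is discarded.

    Cluster ids are assigned in order of each cluster's first pool entry.
    """
    if not pool.entries:
        return []
    from sklearn.cluster import DBSCAN
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        pool.coords())
    clusters = {}
    for entry, lab in zip(pool.entries, labels):
        if lab == -1:
            continue
        clusters.setdefault(lab, []).append(entry)
    ordered = sorted(clusters.values(),
                     key=lambda es: min(pool.entries.index(e) for e in es))
    return [WaterCluster(cluster_id=i, entries=es)
            for i, es in enumerate(ordered)]


def coverage_tiers(clusters, n_frames, tiers=(25.0, 50.0, 75.0, 90.0, 99.0)):
    """Coverage percentages and tier membership; returns (clusters, groups).

    A cluster enters every tier whose threshold (<=, inclusive) it reaches,
    so membership is monotone. All five groups are always present, possibly
    empty.
    """
    groups = {t: [] for t in tiers}
    for c in clusters:
        c.frames_covered = {e.frame for e in c.entries}
        c.coverage_pct = 100.0 * len(c.frames_covered) / n_frames
        c.tiers = tuple(t for t in tiers if c.coverage_pct >= t)
        for t in c.tiers:
            groups[t].append(c)
    return clusters, groups


def cluster_representatives(cluster, system, contact_cutoff=3.5):
    """Member closest to the cluster centroid (tie: lowest entry index) and
    the receptor residues with a heavy atom within the contact cutoff of it,
    measured at the representative's frame."""
    cen = cluster.centroid()
    dists = [float(np.linalg.norm(e.coord - cen)) for e in cluster.entries]
    best = int(np.argmin(dists))  # argmin keeps the earliest on ties
    rep = cluster.entries[best]
    x = system.frames[rep.frame]
    nearby = []
    for a in system.atoms:
        if a.is_hydrogen or a.residue.component not in RECEPTOR_COMPONENTS:
            continue
        if np.linalg.norm(x[a.atom_id] - rep.coord) <= contact_cutoff:
            if a.residue not in nearby:
                nearby.append(a.residue)
    cluster.representative = rep
    cluster.nearby_residues = sorted(nearby)
    return rep, cluster.nearby_residues


def analyze_waters(system, config: WaterConfig = None):
    """Full stable-water stage: trace, cluster, tier, representatives."""
    config = config or WaterConfig()
    pool = trace_stable_waters(system, config.displacement_max)
    clusters = cluster_stable_waters(pool, config.eps, config.min_samples)
    clusters, groups = coverage_tiers(clusters, system.n_frames, config.tiers)
    for c in clusters:
        cluster_representatives(c, system, config.contact_cutoff)
    return pool, clusters, groups


def waterbridge_summary(table):
    """Per water-bridge key: which waters mediate it, how often, and the
    fractions (a water counts once per frame it mediates the bridge)."""
    per_key = {}
    for r in table.keyed_records():
        if r.itype != "water_bridge":
            continue
        k = r.key()
        per_key.setdefault(k, set()).add((r.frame, r.water_residue))
    out = {}
    for k, frame_waters in per_key.items():
        counts = {}
        for _, w in frame_waters:
            counts[w] = counts.get(w, 0) + 1
        total = sum(counts.values())
        out[k] = {"counts": counts,
                  "fractions": {w: c / total for w, c in counts.items()}}
    return out
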
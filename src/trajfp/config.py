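"""Geometric cutoffs for interaction detection.

All detectors read their thresholds from a single :class:`DetectionConfig`
instance so that every tolerance can be tightened or relaxed per system
(e.g. flavin cofactors stacking against RNA bases may need a looser
π-stacking distance). Distances are in Å, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class DetectionConfig:
    """Default geometric criteria for noncovalent interaction detection.

    The defaults follow the widely used functional-group + distance + angle
    paradigm of structure-based interaction profiling.
    """

    #: max apolar C/S – apolar C/S distance for a hydrophobic contact
    hydrophobic_dist_max: float = 4.0
    #: max heavy donor–acceptor distance for a hydrogen bond
    hbond_dist_max: float = 4.1
    #: min D–H···A angle at the hydrogen
    hbond_don_angle_min: float = 100.0
    #: water-bridge leg heavy-atom distance window
    wb_dist_min: float = 2.5
    wb_dist_max: float = 4.1
    #: allowed ligand-heavy – water-O – receptor-heavy angle window
    wb_omega_min: float = 75.0
    wb_omega_max: float = 140.0
    #: max distance between oppositely charged group centroids
    saltbridge_dist_max: float = 5.5
    #: max ring-centroid distance for π-stacking
    pistack_dist_max: float = 5.5
    #: max interplanar angle for parallel stacking
    pistack_parallel_max: float = 30.0
    #: interplanar angle window for T-shaped stacking
    pistack_tshape_min: float = 60.0
    pistack_tshape_max: float = 90.0
    #: max in-plane centroid offset for stacking (and π-cation)
    pistack_offset_max: float = 2.0
    #: max cation-centroid – ring-centroid distance for π-cation
    pication_dist_max: float = 6.0
    #: max halogen-donor X – acceptor Y distance
    halogen_dist_max: float = 4.0
    #: ideal C–X···Y angle and tolerance
    halogen_don_angle: float = 165.0
    halogen_don_tol: float = 30.0
    #: ideal Yneighbor–Y···X angle and tolerance
    halogen_acc_angle: float = 120.0
    halogen_acc_tol: float = 30.0
    #: max metal – O/N/S coordination distance
    metal_dist_max: float = 3.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise TypeError(f"{f.name} must be numeric, got {v!r}")
            if f.name.endswith(("dist_max", "dist_min")) and v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v}")
        for name in ("hbond_don_angle_min", "wb_omega_min", "wb_omega_max",
                     "pistack_parallel_max", "pistack_tshape_min",
                     "pistack_tshape_max", "halogen_don_angle",
                     "halogen_acc_angle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180], got {v}")
        if self.wb_dist_min >= self.wb_dist_max:
            raise ValueError("wb_dist_min must be < wb_dist_max")


@dataclass
class WaterConfig:
    """Parameters of the stable-water tracing / clustering stage."""

    #: strict upper bound on O displacement between consecutive frames
    displacement_max: float = 1.0
    #: DBSCAN neighbourhood radius on pooled O positions
    eps: float = 1.0
    #: DBSCAN core-point demand (the weakest; the tiers do the filtering)
    min_samples: int = 2
    #: trajectory-coverage tiers (percent) for the output groups
    tiers: tuple = (25.0, 50.0, 75.0, 90.0, 99.0)
    #: heavy-atom cutoff for residues "near" a cluster representative
    contact_cutoff: float = 3.5

    def __post_init__(self) -> None:
        if self.displacement_max <= 0 or self.eps <= 0:
            raise ValueError("displacement_max and eps must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
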
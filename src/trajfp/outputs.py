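"""Barcodes, point clouds, 2D highlight maps and the end-to-end pipeline.

The pipeline strings together: load -> (renumber) -> detection sweep ->
occurrence table -> fingerprints -> binding modes + representatives ->
transition graph -> RMSD series -> barcodes -> point cloud -> stable-water
analysis -> exports, and writes a manifest listing every artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DetectionConfig, WaterConfig
from .detection import sweep_trajectory
from .geometry import superpose, rmsd_series
from .modes import (assign_representatives, build_fingerprints,
                    enumerate_modes, modes_dataframe, occurrence_table,
                    transition_graph)
from .system import load_system, renumber_to_reference, apply_renumbering, \
    write_frame_pdb
from .water import analyze_waters, waterbridge_summary

log = logging.getLogger(__name__)

#: interaction-type color code used in barcodes / point clouds / 2D maps
ITYPE_COLORS = {
    "hydrophobic": "yellow",
    "hbond_acceptor": "red",
    "hbond_donor": "green",
    "metal": "orange",
    "pi_stacking": "darkblue",
    "water_bridge": "cyan",
    "salt_bridge": "magenta",
    "pi_cation": "purple",
    "halogen": "teal",
}


# --------------------------------------------------------------------- #
# barcodes


def barcode_matrix(table, keys=None, n_frames=None, grouped=False):
    """Binary presence/absence matrix, rows = keys, columns = frames.

    With ``grouped=True`` all keys sharing (ligand moiety, itype) are OR-ed
    into one row. Returns (matrix uint8, row labels).
    """
    F = table.n_frames if n_frames is None else int(n_frames)
    keys = table.keys() if keys is None else list(keys)
    frames_by_key = {k: table.frames_of(k) for k in keys}
    if grouped:
        groups = {}
        for k in keys:
            groups.setdefault((k.itype, k.ligand_atom_ids), set()) \
                .update(frames_by_key[k])
        labels = [f"{it}:{'+'.join(map(str, lids))}"
                  for it, lids in groups]
        rows = list(groups.values())
    else:
        labels = [k.label() for k in keys]
        rows = [frames_by_key[k] for k in keys]
    mat = np.zeros((len(rows), F), dtype=np.uint8)
    for i, frames in enumerate(rows):
        for f in frames:
            mat[i, f] = 1
    return mat, labels


# --------------------------------------------------------------------- #
# point cloud


def point_cloud(table, system) -> pd.DataFrame:
    """One point per interaction occurrence, at the (fitted) ligand-moiety
    centroid of that frame.

    All frames are superposed on frame 0 via the protein backbone first, so
    the cloud lives in a common reference; single-atom moieties sit on the
    atom itself.
    """
    bb = system.backbone_ids()
    fits = {}
    ref = system.frames[0]
    for f in range(system.n_frames):
        if f == 0 or not bb:
            fits[f] = None
        else:
            fits[f] = superpose(system.frames[f][bb], ref[bb])
    rows = []
    for r in table.keyed_records():
        x = system.frames[r.frame]
        pos = x[list(r.ligand_atom_ids)].mean(axis=0)
        fit = fits[r.frame]
        if fit is not None:
            pos = fit.apply(pos[None, :])[0]
        rows.append({"x": pos[0], "y": pos[1], "z": pos[2],
                     "itype": r.itype, "frame": r.frame,
                     "key": r.key().label(),
                     "color": ITYPE_COLORS[r.itype]})
    return pd.DataFrame(rows, columns=["x", "y", "z", "itype", "frame",
                                       "key", "color"])


# --------------------------------------------------------------------- #
# 2D highlight map


def highlight_map(modes, system):
    """Per binding mode: ligand atom id -> set of interaction colors.

    Only atoms appearing in the mode's key set are highlighted; an atom in
    several keys carries several colors.
    """
    lig = set(system.ligand_atom_ids)
    out = {}
    for m in modes:
        amap = {}
        for k in m.key_set:
            for i in k.ligand_atom_ids:
                if i not in lig:
                    raise ValueError(
                        f"mode {m.mode_id} references unknown ligand atom {i}")
                amap.setdefault(i, set()).add(ITYPE_COLORS[k.itype])
        out[m.mode_id] = amap
    return out


# --------------------------------------------------------------------- #
# graph exports


def write_dot(graph, path):
    lines = ["digraph binding_modes {"]
    for n, d in sorted(graph.nodes(data=True)):
        lines.append(
            f'  "{n}" [label="mode {n}\\n{d["occurrence_pct"]:.1f}%"];')
    for a, b, d in sorted(graph.edges(data=True)):
        lines.append(
            f'  "{a}" -> "{b}" [label="occ {d["occurrence"]:.3f}\\n'
            f'p {d["probability"]:.3f}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------- #
# pipeline


@dataclass
class PipelineOptions:
    topology: str
    trajectory: str
    ligand_sdf: str = None
    reference_pdb: str = None
    nucleic: bool = False
    special_resnames: tuple = ()
    ligand_resname: str = None
    threshold_pct: float = 40.0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    water: WaterConfig = field(default_factory=WaterConfig)
    out_dir: str = "trajfp_out"
    top_modes: int = 10
    seed: int = 0
    plots: bool = False


def run_pipeline(opts: PipelineOptions) -> dict:
    """Execute the full analysis; returns the manifest (also written to
    ``manifest.json``). Each stage failure aborts with the stage name."""
    out = Path(opts.out_dir)
    for p in (opts.topology, opts.trajectory, opts.ligand_sdf,
              opts.reference_pdb):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"artifacts": {}, "stages": []}

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") \
                from exc
        manifest["stages"].append(name)
        return result

    def register(name, path):
        manifest["artifacts"][name] = str(path)
        return path

    system = stage("load", lambda: load_system(
        opts.topology, opts.trajectory, opts.ligand_sdf,
        opts.special_resnames, opts.nucleic, opts.ligand_resname))

    if opts.reference_pdb:
        def _renumber():
            res = renumber_to_reference(system, opts.reference_pdb)
            apply_renumbering(system, res)
            return res
        renum = stage("renumber", _renumber)
        pd.DataFrame(
            [{"chain": c, "old_resid": o, "new_resid": n}
             for (c, o), n in sorted(renum.mapping.items())]
        ).to_csv(register("renumbering", out / "renumbering.csv"),
                 index=False)

    table = stage("sweep", lambda: sweep_trajectory(system, opts.detection))
    table.to_dataframe().to_csv(
        register("interactions", out / "interactions.csv"), index=False)

    occ = stage("occurrences", lambda: occurrence_table(table))
    occ.drop(columns=["key"]).to_csv(
        register("occurrences", out / "occurrences.csv"), index=False)

    fps = stage("fingerprints",
                lambda: build_fingerprints(table, occ, opts.threshold_pct))
    modes, seq = stage("modes", lambda: enumerate_modes(fps))
    stage("representatives", lambda: assign_representatives(modes, system))
    modes_dataframe(modes).to_csv(
        register("modes", out / "binding_modes.csv"), index=False)
    pd.DataFrame({"frame": range(len(seq)), "mode_id": seq}).to_csv(
        register("mode_sequence", out / "mode_sequence.csv"), index=False)

    rep_dir = out / "representatives"
    rep_dir.mkdir(exist_ok=True)
    for m in modes[:opts.top_modes]:
        write_frame_pdb(system, m.representative_frame,
                        rep_dir / f"mode_{m.mode_id}.pdb")
    register("representatives_dir", rep_dir)

    hmap = stage("highlight_map",
                 lambda: highlight_map(modes[:opts.top_modes], system))
    with open(register("highlight_map", out / "highlight_map.json"),
              "w") as fh:
        json.dump({str(mid): {str(a): sorted(cols)
                              for a, cols in amap.items()}
                   for mid, amap in hmap.items()}, fh, indent=1)

    graph = stage("transition_graph",
                  lambda: transition_graph(seq) if len(seq) >= 2 else None)
    if graph is not None:
        import networkx as nx
        nx.write_graphml(graph, register("graphml",
                                         out / "transition_graph.graphml"))
        write_dot(graph, register("dot", out / "transition_graph.dot"))

    def _rmsd():
        lig = system.ligand_heavy_ids()
        bb = system.backbone_ids()
        fit = bb if bb else lig
        return pd.DataFrame({
            "frame": range(system.n_frames),
            "backbone_rmsd": (rmsd_series(system, bb, bb) if bb
                              else np.zeros(system.n_frames)),
            "ligand_rmsd": rmsd_series(system, lig, fit),
        })
    rmsd_df = stage("rmsd", _rmsd)
    rmsd_df.to_csv(register("rmsd", out / "rmsd.csv"), index=False)

    mat, labels = stage("barcodes", lambda: barcode_matrix(table))
    pd.DataFrame(mat, index=labels,
                 columns=[f"f{f}" for f in range(table.n_frames)]) \
        .to_csv(register("barcodes", out / "barcodes.csv"))
    gmat, glabels = barcode_matrix(table, grouped=True)
    pd.DataFrame(gmat, index=glabels,
                 columns=[f"f{f}" for f in range(table.n_frames)]) \
        .to_csv(register("barcodes_grouped", out / "barcodes_grouped.csv"))

    cloud = stage("point_cloud", lambda: point_cloud(table, system))
    cloud_json = {"points": cloud.round(4).to_dict(orient="records"),
                  "colors": ITYPE_COLORS}
    with open(register("point_cloud", out / "point_cloud.json"), "w") as fh:
        json.dump(cloud_json, fh, indent=1)

    def _waters():
        if system.n_frames < 2 or not system.water_residues:
            return None, [], {t: [] for t in opts.water.tiers}
        return analyze_waters(system, opts.water)
    pool, clusters, groups = stage("water_analysis", _waters)

    water_dir = out / "stable_waters"
    water_dir.mkdir(exist_ok=True)
    rows = []
    for c in clusters:
        rows.append({
            "cluster_id": c.cluster_id, "n_entries": len(c.entries),
            "coverage_pct": round(c.coverage_pct, 3),
            "tiers": "+".join(f"{t:g}" for t in c.tiers),
            "rep_x": round(float(c.representative.coord[0]), 3),
            "rep_y": round(float(c.representative.coord[1]), 3),
            "rep_z": round(float(c.representative.coord[2]), 3),
            "nearby_residues": ";".join(r.label()
                                        for r in c.nearby_residues)})
    pd.DataFrame(rows, columns=["cluster_id", "n_entries", "coverage_pct",
                                "tiers", "rep_x", "rep_y", "rep_z",
                                "nearby_residues"]) \
        .to_csv(register("water_clusters", water_dir / "clusters.csv"),
                index=False)
    for t, cs in groups.items():
        tdir = water_dir / f"tier_{t:g}pct"
        tdir.mkdir(exist_ok=True)
        for c in cs:
            _write_water_pdb(c, tdir / f"cluster_{c.cluster_id}.pdb")
    register("water_tiers_dir", water_dir)

    wb = stage("waterbridge_summary", lambda: waterbridge_summary(table))
    wb_rows = []
    for k, d in wb.items():
        for w, c in sorted(d["counts"].items()):
            wb_rows.append({"bridge": k.label(), "water_resid": w.resid,
                            "count": c,
                            "fraction": round(d["fractions"][w], 6)})
    pd.DataFrame(wb_rows, columns=["bridge", "water_resid", "count",
                                   "fraction"]) \
        .to_csv(register("waterbridge_summary",
                         out / "waterbridge_summary.csv"), index=False)

    if opts.plots:
        stage("plots", lambda: _plot_barcode(mat, labels, out))
        register("barcode_png", out / "barcodes.png")

    config_log = {"detection": asdict(opts.detection),
                  "water": {**asdict(opts.water),
                            "tiers": list(opts.water.tiers)},
                  "threshold_pct": opts.threshold_pct,
                  "seed": opts.seed}
    with open(register("config", out / "config.json"), "w") as fh:
        json.dump(config_log, fh, indent=1)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    manifest["artifacts"]["manifest"] = str(out / "manifest.json")
    return manifest


def _write_water_pdb(cluster, path):
    rep = cluster.representative
    x, y, z = rep.coord
    lines = [
        f"HETATM{1:5d}  O   HOH W{rep.water_residue.resid % 10000:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
        f"{cluster.coverage_pct / 100.0:6.2f}           O",
        "END"]
    Path(path).write_text("\n".join(lines) + "\n")


def _plot_barcode(mat, labels, out):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(labels))))
    ax.imshow(1 - mat, cmap="gray", aspect="auto", interpolation="none")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_xlabel("frame")
    fig.tight_layout()
    fig.savefig(out / "barcodes.png", dpi=150)
    plt.close(fig)
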
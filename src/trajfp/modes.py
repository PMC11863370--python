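"""Occurrence statistics, frame fingerprints, binding modes and the
Markov transition graph.

A *binding mode* is a recurring frame fingerprint: the set of
threshold-passing interaction keys present in a frame. Frames with no
qualifying interaction form the (perfectly valid) empty mode, so the modes
always partition the trajectory. Transitions between consecutive frames,
including self-loops, are counted into a directed graph whose edges carry

* ``count``       – raw number of transitions,
* ``occurrence``  – count / F (transitions per trajectory frame),
* ``probability`` – count / occurrence_count(source mode).

With F frames there are F − 1 transitions, so edge occurrences sum to
(F − 1)/F, and the outgoing probabilities of every mode sum to 1 except for
the mode of the final frame, where one visit has no outgoing transition and
the sum is 1 − 1/occurrence_count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import rmsd_after_fit


def occurrence_table(table, n_frames=None) -> pd.DataFrame:
    """Per-key frame counts and frequencies (% of trajectory).

    Multiple records of one key within one frame (e.g. two waters mediating
    the same bridge) count once for that frame.
    """
    F = table.n_frames if n_frames is None else int(n_frames)
    if F < 1:
        raise ValueError("need at least one frame")
    frames_by_key = {}
    for r in table.keyed_records():
        if r.frame >= F or r.frame < 0:
            raise ValueError(f"record frame {r.frame} outside [0, {F})")
        frames_by_key.setdefault(r.key(), set()).add(r.frame)
    rows = [{"key": k, "itype": k.itype,
             "ligand_atoms": "+".join(map(str, k.ligand_atom_ids)),
             "residue": f"{k.residue[1]}{k.residue[2]}{k.residue[0]}",
             "count": len(frames), "frequency_pct": 100.0 * len(frames) / F}
            for k, frames in frames_by_key.items()]
    df = pd.DataFrame(rows, columns=["key", "itype", "ligand_atoms",
                                     "residue", "count", "frequency_pct"])
    if not df.empty:
        df = df.sort_values(["frequency_pct", "itype", "ligand_atoms",
                             "residue"], ascending=[False, True, True, True],
                            ignore_index=True)
    return df


def build_fingerprints(table, occurrences, threshold_pct=40.0):
    """Per-frame sets of qualifying keys (frequency >= threshold, inclusive).

    Returns a list of frozensets, one per frame; frames with no qualifying
    key yield the empty fingerprint.
    """
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold_pct must lie in [0, 100]")
    qualifying = set(
        occurrences.loc[occurrences["frequency_pct"] >= threshold_pct, "key"])
    per_frame = [set() for _ in range(table.n_frames)]
    for r in table.keyed_records():
        k = r.key()
        if k in qualifying:
            per_frame[r.frame].add(k)
    return [frozenset(s) for s in per_frame]


@dataclass
class BindingMode:
    """A recurring fingerprint with its frames and statistics."""

    mode_id: int
    key_set: frozenset
    frames: list
    occurrence_count: int = 0
    occurrence_pct: float = 0.0
    representative_frame: int = None

    def __post_init__(self):
        self.frames = sorted(self.frames)
        self.occurrence_count = len(self.frames)


def enumerate_modes(fingerprints):
    """Group frames by identical fingerprint; rank by occurrence.

    Ties are broken by earliest first frame. Returns (modes, mode_sequence)
    where mode_sequence[f] is the mode_id of frame f. The 2D-depiction set
    is the top 10 by rank.
    """
    F = len(fingerprints)
    groups = {}
    for f, fp in enumerate(fingerprints):
        groups.setdefault(fp, []).append(f)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    modes = []
    for rank, (fp, frames) in enumerate(ordered):
        m = BindingMode(mode_id=rank, key_set=fp, frames=frames)
        m.occurrence_pct = 100.0 * m.occurrence_count / F
        modes.append(m)
    seq = np.empty(F, dtype=int)
    for m in modes:
        for f in m.frames:
            seq[f] = m.mode_id
    return modes, seq.tolist()


def representative_frame(mode_frames, system) -> int:
    """The frame minimizing mean ligand heavy-atom RMSD to the mode's other
    frames, each pair compared after a protein-backbone fit.

    Ties go to the lowest frame index; a single-frame mode returns its frame.
    """
    frames = sorted(mode_frames)
    if not frames:
        raise ValueError("mode has no frames")
    if len(frames) == 1:
        return frames[0]
    lig = system.ligand_heavy_ids()
    bb = system.backbone_ids()
    n = len(frames)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = system.frames[frames[i]], system.frames[frames[j]]
            if bb:
                r = rmsd_after_fit(xj[lig], xi[lig], xj[bb], xi[bb])
            else:
                r = float(np.sqrt(((xj[lig] - xi[lig]) ** 2)
                                  .sum(axis=1).mean()))
            d[i, j] = d[j, i] = r
    mean = d.sum(axis=1) / (n - 1)
    return frames[int(np.argmin(mean))]  # argmin takes the first minimum


def assign_representatives(modes, system):
    for m in modes:
        m.representative_frame = representative_frame(m.frames, system)
    return modes


def transition_graph(mode_sequence, n_frames=None):
    """Directed multigraph-free transition counts over consecutive frames.

    Node attributes: ``occurrence_count``, ``occurrence_pct``.
    Edge attributes: ``count``, ``occurrence`` (= count/F),
    ``probability`` (= count / source occurrence_count). Self-loops included.
    """
    import networkx as nx
    seq = list(mode_sequence)
    F = len(seq) if n_frames is None else int(n_frames)
    if len(seq) != F:
        raise ValueError("mode_sequence length != F")
    if F < 2:
        raise ValueError("need at least 2 frames for transitions")
    occ = {}
    for m in seq:
        occ[m] = occ.get(m, 0) + 1
    counts = {}
    for a, b in zip(seq[:-1], seq[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    g = nx.DiGraph()
    for m, c in occ.items():
        g.add_node(m, occurrence_count=c, occurrence_pct=100.0 * c / F)
    for (a, b), c in counts.items():
        g.add_edge(a, b, count=c, occurrence=c / F, probability=c / occ[a])
    return g


def modes_dataframe(modes) -> pd.DataFrame:
    rows = [{"mode_id": m.mode_id,
             "key_set": ";".join(sorted(k.label() for k in m.key_set)),
             "occurrence_count": m.occurrence_count,
             "occurrence_pct": m.occurrence_pct,
             "representative_frame": m.representative_frame}
            for m in modes]
    return pd.DataFrame(rows, columns=["mode_id", "key_set",
                                       "occurrence_count", "occurrence_pct",
                                       "representative_frame"])
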
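# trajfp

Geometric protein/nucleic-acid–ligand interaction fingerprints, binding-mode
transition graphs and stable-water analysis for molecular-dynamics
trajectories.

## What it does

MD simulations of a receptor–ligand complex produce thousands of frames; the
question that matters is *how* the ligand is bound and how that changes over
time. `trajfp` answers it with the classical functional-group + distance +
angle paradigm of interaction profiling:

1. **Per-frame detection.** Nine noncovalent interaction types are detected
   geometrically in every frame: hydrophobic contacts, hydrogen bonds
   (ligand as donor or acceptor), water bridges (ligand–water–receptor double
   hydrogen bonds), salt bridges, π-stacking (parallel and T-shaped),
   π-cation, halogen bonds and metal coordination. Each occurrence is keyed
   by (interaction type, ligand moiety atoms, receptor residue); the identity
   of a bridging water is *not* part of the key, so one bridge can be
   mediated by different waters over time.
2. **Occurrence statistics and fingerprints.** Every key's frequency is
   `100 · (frames present) / F`. Keys at or above the occurrence threshold
   (default 40 %) enter the per-frame fingerprint; frames with identical
   fingerprints form a **binding mode**. Modes partition the trajectory,
   are ranked by occurrence, and each gets a representative frame: the one
   with the lowest mean ligand heavy-atom RMSD (after protein-backbone
   superposition) to the mode's other frames. The top 10 modes form the
   depiction set.
3. **Transition graph.** Consecutive-frame mode transitions (self-loops
   included) build a directed Markov-chain graph. An edge from mode *a* to
   *b* carries `count`, `occurrence = count / F` and
   `probability = count / occurrence_count(a)`.
4. **Barcodes and point clouds.** Each key gets a binary presence strip over
   frames (row sums reproduce the occurrence table exactly), and every
   occurrence becomes one 3-D point at the (backbone-fitted) coordinates of
   the interacting ligand moiety, colored by interaction type (yellow
   hydrophobic, green/red H-bond donor/acceptor, cyan water bridge, dark
   blue π-stacking, orange metal, ...).
5. **Stable waters.** A water is *stable* across a frame transition when its
   oxygen moves < 1 Å; pooled stable positions are clustered with DBSCAN
   (eps = 1 Å, min_samples = 2) into hydration sites, filed into five
   coverage tiers (25/50/75/90/99 % of frames), each with a representative
   water and the receptor residues within 3.5 Å. Water-bridge records are
   additionally attributed to the specific waters that mediate them.

A synthetic-system generator (`trajfp.fixtures`) builds toy PDB/DCD/SDF
systems with *scripted* interaction schedules and water plans, so every
stage can be verified against exact construction-time ground truth — no
downloads, no force field.

## Worked example

Generate a 10-frame toy system in which a ligand hydroxyl donates a hydrogen
bond to an ASN in frames 0–4, a methyl touches a LEU in every frame, and a
water bridge to a SER is present in frames 2–7:

```bash
cat > spec.yaml <<EOF
n_frames: 10
seed: 1
schedule:
  - {itype: hbond_donor, frames: "0-4"}
  - {itype: hydrophobic, frames: "0-9"}
  - {itype: water_bridge, frames: "2-7"}
waters:
  - {site: [9.0, 9.0, 6.0], frames: "0-9"}
EOF
trajfp synth --config spec.yaml --out toy
trajfp analyze -t toy/topology.pdb -x toy/traj.dcd -l toy/ligand.sdf --out out
```

`out/occurrences.csv` then reads

```
itype,ligand_atoms,residue,count,frequency_pct
hydrophobic,85,LEU1A,10,100.0
water_bridge,92,SER4A,6,60.0
hbond_donor,89,ASN2A,5,50.0
```

— the three scheduled interactions at exactly their scripted frequencies
(the hydrogen bond was present in 5 of 10 frames → 50 %). All three keys
pass the 40 % threshold, and the overlap pattern yields four binding modes
(`out/binding_modes.csv`):

```
mode_id,key_set,occurrence_count,occurrence_pct,representative_frame
0,hbond_donor:89:ASN2A;hydrophobic:85:LEU1A;water_bridge:92:SER4A,3,30.0,4
1,hydrophobic:85:LEU1A;water_bridge:92:SER4A,3,30.0,6
2,hbond_donor:89:ASN2A;hydrophobic:85:LEU1A,2,20.0,0
3,hydrophobic:85:LEU1A,2,20.0,8
```

The mode percentages sum to 100 — modes partition the trajectory. The
stable-water stage (`out/stable_waters/clusters.csv`) finds the planted
hydration site plus the bridging water:

```
cluster_id,n_entries,coverage_pct,tiers,rep_x,rep_y,rep_z,nearby_residues
0,9,90.0,25+50+75+90,8.985,9.012,5.98,
1,5,50.0,25+50,2.975,-5.153,0.0,SER4A
```

The planted water was at its site in all 10 frames → 9 of 9 transitions are
stable → 90 % coverage, tiers 25–90. The bridge water is stable only while
the bridge exists and sits next to SER4. `out/` also contains the
transition graph (GraphML + DOT), barcodes, the point-cloud JSON, per-mode
representative PDBs and an atom→color highlight map for 2D depiction.

Real systems are analyzed the same way:
`trajfp analyze -t topology.pdb -x traj.dcd -l ligand.sdf
[-ref reference.pdb] [-nuc] [--special HEM]`.

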
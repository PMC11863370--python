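# Methods

## Detection model

All interaction detection is geometric: candidate functional groups are
perceived once from the topology, then distance/angle criteria are applied
per frame. The assumptions are those of any profiling approach of this
family: the trajectory is already imaged and aligned (no re-wrapping is
done), explicit hydrogens are present (MD topologies have them; a donor
without a hydrogen is simply never entered into the donor table), and the
receptor's protonation states are frozen at their topology values.

Perception rules:

* **Donors** — any N/O/S carrying at least one bonded hydrogen, on either
  side.
* **Acceptors** — standard amino acids use a per-residue name lookup
  (backbone O/OXT for all; side-chain O of ASP/GLU/ASN/GLN/SER/THR/TYR;
  HIS ring N only when unprotonated; MET SD, CYS SG). Ligand, special
  residues and waters use valence/charge rules: O with non-positive formal
  charge; N with no bonded H, ≤ 3 bonds and charge ≤ 0; S with ≤ 2 bonds
  and no H. In nucleic mode, base/sugar O plus H-free N accept.
* **Apolar atoms** — C or S bonded exclusively to C/H (so a ring carbon
  stops being hydrophobic the moment it carries a Cl or an O substituent).
* **Rings** — ligand aromatic rings come from the SDF (RDKit aromaticity);
  without an SDF, 5/6-membered C/N/O/S cycles with out-of-plane RMS
  < 0.15 Å are used. Receptor rings come from name lookups
  (PHE/TYR/TRP/HIS; purine/pyrimidine rings in nucleic mode).
* **Charged groups** — ARG guanidinium (CZ/NH1/NH2 centroid), LYS NZ,
  doubly protonated HIS; ASP/GLU carboxylates. Ligand-side: N with formal
  +1 (or four bonds), and carboxylate/sulfonate/phosphate-like patterns
  (≥ 2 terminal O on a C/S/P centre with a negative formal charge).
* **Halogen donors** — ligand Cl/Br/I bonded to exactly one carbon
  (fluorine never qualifies). **Metals** — Fe/Zn/Mg/Mn/Cu/Ni/Co/Ca/Na/K
  atoms in ion residues or inside special residues (e.g. heme iron).

## Cutoffs (DetectionConfig, all overridable)

| parameter | default | meaning |
|---|---|---|
| hydrophobic_dist_max | 4.0 Å | apolar–apolar contact |
| hbond_dist_max / hbond_don_angle_min | 4.1 Å / 100° | heavy D–A distance, D–H···A floor |
| wb_dist_min–wb_dist_max | 2.5–4.1 Å | water-bridge leg window |
| wb_omega | 75–140° | ligand–water-O–receptor angle |
| saltbridge_dist_max | 5.5 Å | charged-group centroid distance |
| pistack_dist_max / parallel / T / offset | 5.5 Å / ≤ 30° / 60–90° / 2.0 Å | ring stacking |
| pication_dist_max | 6.0 Å | cation–ring centroid |
| halogen dist / C–X···Y / Y-neighbour | 4.0 Å / 165° ± 30° / 120° ± 30° | σ-hole geometry |
| metal_dist_max | 3.0 Å | coordination distance |

These follow the default tolerances common to geometric interaction
profilers; systems with unusual chemistry (e.g. flavin stacking against
RNA bases) may need looser values, which is why every one is a constructor
argument and recorded in the pipeline's `config.json`.

Bookkeeping choices: hydrophobic contacts are deduplicated to one record
per (ligand atom, receptor residue), keeping the closest pair; hydrogen
bonds are enumerated per (donor, acceptor) pair with the best hydrogen;
water bridges are enumerated per water, so two waters bridging the same
pair in one frame give two records that count once in the occurrence table.
A water-bridge leg accepts either donation direction (partner→water or
water→partner). Metal coordination to waters or to receptor atoms is
reported but flagged and key-less; only ligand coordination enters
fingerprints. Interplanar angles are folded into [0°, 90°] because plane
normals are sign-ambiguous; the stacking offset is the smaller of the two
in-plane projections of the centroid–centroid vector.

## Fingerprints, modes, transitions

A key qualifies when its frequency is **≥** the threshold (the default
40 % reads as an inclusive floor). A frame's fingerprint is the set of
qualifying keys present in it; the empty fingerprint is a first-class mode
so the modes always partition the trajectory. Modes rank by occurrence,
ties broken by earliest first frame. The representative frame minimizes the
mean pairwise ligand heavy-atom RMSD within the mode, computed after a
protein-backbone Kabsch fit — binding modes describe the ligand pose
*relative to the receptor*, hence the backbone fit rather than a ligand
self-fit; ties go to the lowest frame index.

Transition edges carry `occurrence = count/F` (per trajectory frame, even
though only F − 1 transitions exist — kept as the conventional
presentation) and `probability = count / occurrence_count(source)`. With
that convention the outgoing probabilities of every mode sum to 1 except
the final frame's mode, where one visit has no successor and the sum is
1 − 1/occurrence_count.

## Stable waters

Stability is assessed per frame transition (strict `< 1 Å` oxygen
displacement, giving F − 1 opportunities per water); the qualifying
position at the later frame enters the pool. DBSCAN uses eps = 1 Å and
min_samples = 2 — the weakest density demand, chosen because the coverage
tiers (25/50/75/90/99 %, inclusive thresholds, monotone membership) do the
actual filtering; noise points are discarded. A cluster's coverage counts
distinct frames with at least one member. The representative is the member
closest to the cluster centroid (earliest entry on ties); nearby residues
are receptor residues with any heavy atom within 3.5 Å of the
representative, measured at the representative's own frame (clusters pool
positions across frames, so some frame must be chosen; the representative's
frame is the least arbitrary).

## Superposition and RMSD

Rigid fits use the Kabsch SVD construction with the determinant sign fix
(proper rotations only); collinear reference geometry is rejected. RMSD
series fit each frame's protein backbone (N/CA/C) onto frame 0 and report
heavy-atom RMSD of the analysis selection — hydrogens are thermalized noise
and are excluded throughout.

## Residue renumbering (`-ref`)

Per-chain global pairwise alignment of one-letter sequences (match +1,
mismatch −1, gap −2 — chains are expected to be near-identical, so any sane
scheme works); aligned positions inherit the reference numbering, unaligned
residues keep their numbers and are reported. A 50 % identity floor
(matches over the shorter chain) rejects garbage mappings; no chain pair
above the floor is an error. Insertion codes and multi-chain ambiguity
are not resolved beyond best-identity pairing; renumbering is idempotent.

## The synthetic generator

The generator emulates exactly what the analysis measures and nothing
else: a rigid multivalent ligand (hexa-substituted benzene carrying a
methyl, Cl, ammonium arm, two hydroxyls and a carbonyl) surrounded by one
probe residue per interaction type, each on its own axis. Scheduled frames
place the probe at a geometry satisfying its detector with ≥ 10 % margin on
the governing criterion; unscheduled frames translate it 3 Å outward,
violating with ≥ 10 % margin (a built-in validator enforces both at
generation time). Waters are pinned to hydration sites with clipped 0.1 Å
jitter when occupied and teleport across an 18–25 Å shell otherwise, so
they can never count as stable there. The ligand gets a small rigid jitter
(≤ 0.12 Å) so representative-frame selection is non-trivial. Separate RNG
streams drive waters and ligand jitter, so editing one part of a spec does
not change the other's randomness; everything is byte-deterministic given
the seed.

What the generator does **not** emulate: conformational flexibility,
thermal noise on the receptor, competing near-threshold geometries,
periodic-boundary artifacts, or force-field physics. Passing the
end-to-end recovery suite therefore demonstrates that the bookkeeping and
geometry are exact under clean conditions — not that the default cutoffs
are optimal for any particular real system.

The reference study in `scripts/acceptance.py` uses 50 frames, all nine
interaction types in overlapping blocks, and a three-water plan (full
occupancy, 60 % occupancy, and one freely diffusing water) — large enough
for stable percentages, small enough to run in seconds.

## Known limitations

* Ligand formal charges without an SDF rely on valence heuristics; a
  3-coordinate nitrogen's protonation state is genuinely ambiguous, so
  supplying the SDF (`-l`) is strongly recommended for charged ligands.
* No covalent-ligand support, no energy scoring, no receptor–receptor
  interaction analysis, no thermodynamic water scoring.
* π-stacking against cofactors with non-standard ring systems may need a
  looser `pistack_dist_max`; the defaults are deliberately conservative.
* The transition graph is raw counting — no lag times, no detailed-balance
  or Markov-state-model estimation.
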
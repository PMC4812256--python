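# allocross

Trajectory analysis of **bidirectional interdomain allosteric crosstalk**
in two-domain proteins of the Hsp70/DnaK type.

Hsp70 chaperones couple a nucleotide-binding domain (NBD, two lobes) to a
substrate-binding domain (SBD) through a short flexible linker
(DnaK residues 383–396). Which nucleotide sits in the NBD (ADP vs ATP) and
which ligand occupies the SBD (free, substrate peptide, inhibitor) jointly
reshape the linker and the relative arrangement of the two domains; reading
those changes out of MD ensembles requires a specific battery of
statistics. This package implements that battery as a reusable, tested
library plus CLI:

* **gromos conformational clustering** with decomposition of cluster
  populations by ligand-state label. Frames of all runs are concatenated
  into a *meta-trajectory* (the final tail window of each run), clustered
  jointly on a residue subset at an RMSD cutoff, and each cluster's
  population is then split by the source ligand state. The gromos method
  is greedy neighbour counting: among unassigned frames the one with most
  neighbours within the cutoff seeds a cluster, it and its neighbours are
  removed, and the step repeats.
* **Distance-fluctuation (coordination) maps**
  `A_ij = ⟨d_ij²⟩ − ⟨d_ij⟩²`, the temporal variance of the Cα–Cα distance
  of every residue pair; low values mark rigid, coordinated blocks, and
  signed differences between ligand states expose induced rigidification.
* **Centre-of-mass cloud statistics**: after Kabsch-fitting each frame on
  the NBD Cα atoms, the SBD centre of mass traces a 3-D point cloud whose
  distance-from-start and pair-distance distributions quantify interdomain
  flexibility.
* **Persistent contacts and hydrogen bonds** (occupancy ≥ 30% of frames,
  occupancies reported exactly), **interface maps** (time-averaged
  minimum-distance matrices thresholded at 6 Å), **β-strand content** of
  the linker by a minimal backbone H-bond ladder criterion, and **hinge
  dihedral** circular statistics (e.g. ψ of the Thr383-type hinge).

Because no deposited trajectories exist for such systems, the package
ships a first-class **synthetic-data module**: toy two-lobe + appended
domain chains joined by a flexible linker, with programmable interdomain
state mixtures, per-region rigidity, planted H-bond occupancies and
planted strand fractions — every analysis stage can be validated against
construction-based ground truth.

## Worked example

Simulate a two-state hinge (placements 20 Å apart, weights 0.7/0.3,
1000 frames) and recover its structure:

```python
import numpy as np
from allocross.synth import (ToyArchitecture, ToyStructure, StateMixture,
                             NoiseModel, Placement, simulate_hinge_trajectory)
from allocross.core import select
from allocross.clustering import rmsd_matrix, gromos_cluster
from allocross.geometry import (com_cloud, distance_from_start,
                                pair_distance_distribution)

arch = ToyArchitecture(lobe_a=40, lobe_b=40, linker=12, appended=60)
structure = ToyStructure.build(arch)
mixture = StateMixture(
    states=(Placement(), Placement(translation=(2.0, 0.0, 0.0))),  # 20 Å apart
    weights=(0.7, 0.3),
)
sim = simulate_hinge_trajectory(
    structure, mixture,
    NoiseModel(domain_sigma=0.02, linker_sigma=0.05, seed=0), n_frames=1000)

sel = select(structure.topology, (1, arch.n_residues), {"CA"})
clusters = gromos_cluster(rmsd_matrix(sim.trajectory, sel), cutoff=0.35)
print("cluster populations:", np.round(clusters.populations, 3))

fit = select(structure.topology, arch.core_range, {"CA"})
mob = select(structure.topology, arch.appended_range, "all")
cloud = com_cloud([sim.trajectory], fit, mob, (structure.topology, structure.frame))
dist = distance_from_start(cloud)
pairs = pair_distance_distribution(cloud)
print(f"mean COM displacement: {dist.mean:.1f} Å (peak {dist.peak:.0f} Å)")
print(f"pair-distance peak: {pairs.peak:.0f} Å, modes: {pairs.modes(min_separation=5.0)}")
```

Output:

```
cluster populations: [0.678 0.322]
mean COM displacement: 6.6 Å (peak 0 Å)
pair-distance peak: 0 Å, modes: [0.0, 20.0]
```

The clustering recovers the planted 0.7/0.3 mixture (0.678/0.322 is the
realised state count for this seed — exactly right). The mean displacement
≈ 0.3 × 20 Å reflects the minority state; the pair-distance distribution
peaks at 0 Å because same-state pairs (0.7² + 0.3² = 0.58) outnumber
cross-state pairs (2·0.7·0.3 = 0.42), with the secondary mode at the
planted 20 Å separation.

## Workflow CLI

A run set is described by a YAML manifest (reference PDB, frame spacing
`dt_ps`, per-run file paths with ligand tags and replica ids):

```bash
allocross synth hinge --states "0,0,0;20,0,0" --weights 0.7,0.3 \
    --frames 1000 --seed 0 -o run.xtc --ref ref.pdb --truth truth.json
allocross system -m runs.yaml -c analysis.yaml -y ATP-free -o out/
allocross meta   -m runs.yaml -c analysis.yaml -o out/
```

`meta` writes `report.json` (per-system COM/fluctuation/interaction
summaries plus subset clustering with per-ligand-state decomposition
tables), CSV tables, and representative cluster conformations as PDB.
Reports are a pure function of manifest + config + seed: reruns are
byte-identical.

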
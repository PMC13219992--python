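# posestab

Stability-driven evaluation of protein–ligand binding poses from molecular
dynamics trajectories.

Docking programs produce geometrically plausible poses but score them with
static functions that cannot tell a pose that *stays* bound from one that
merely *looks* bound. `posestab` analyzes MD trajectories (typically short,
high-temperature replicas started from each candidate pose) and quantifies
how persistently the pose's native contact network survives the dynamics.
It is aimed at computational chemists doing pose validation, post-docking
re-ranking, and stability-guided lead optimization; it consumes trajectories
and never runs the MD itself.

## The R-value

Given a reference structure (docking pose, experimental pose, or the
trajectory's own representative frame), the native contacts are all
protein/ligand heavy-atom pairs with distance < 4.5 Å. For a configuration
*X* the contact-persistence score is

```
R = (1/N) Σ_ij  1 / (1 + exp[ β (r_ij^X − Λ r_ij⁰) ])
```

with smoothing parameter β = 5.0 Å⁻¹ and contact-fluctuation parameter
Λ = 1.8: each term is ≈1 while a contact stays within Λ times its reference
distance and decays smoothly to 0 once it breaks. The trajectory R-value is
the mean over the pooled analysis window (by default the last 40% of each
replica). On top of this the package provides:

- **Representative-frame selection** — the frame whose retained-pair
  distance vector (pairs with trajectory-mean distance ≤ 6.75 Å) is closest
  to the ensemble average.
- **Per-residue / per-ligand-atom decomposition** — per-residue R-values,
  contributions (r × contact count, summing to N·R) and %Contribution;
  three-way stable / less-stable / unstable atom maps.
- **Pose classification** — SS / SD / US / UD by crossing stability
  (R > 0.70) with similarity to the experimental pose (ligand RMSD < 3.0 Å
  after protein Cα superposition), plus ranking, top-1 / dock-success /
  rescue metrics and threshold-sensitivity grids.
- **Affinity correlation** — Kd → pKd conversion, exclusion of
  non-native-like complexes (R < 0.70), and Pearson correlation of global or
  per-residue stability against pKd.
- **Synthetic generators** — toy complexes, distance series with planted
  per-contact persistence (and a closed-form expected R), coordinate-level
  trajectories with rigid-body excursions, and decoy poses with exactly
  planted RMSD, so the whole pipeline is testable without any MD run.

## Worked example

```python
import posestab as ps

cfg = ps.GeneratorConfig(persistence=0.85, n_frames=150, n_replicas=3, seed=42)
reference = ps.make_toy_complex(cfg)          # stands in for a docking pose
traj, truth = ps.simulate_trajectory(cfg)     # stands in for the MD output

topo = reference.topology
protein = ps.select_atoms(topo, "protein and heavy")
ligand = ps.select_atoms(topo, "ligand and heavy")

windowed = ps.apply_window(traj, ps.AnalysisWindow(discard_fraction=0.6))
contacts = ps.identify_native_contacts(reference, protein, ligand)
series = ps.compute_distance_series(windowed, contacts)
print(ps.r_value_trajectory(series, contacts).r_global)
```

Running `python examples/01_score_trajectory.py` (which is exactly this
pipeline) prints:

```
native contacts (< 4.5 A in the reference): 69
frames analyzed (pooled, post-window):      180
trajectory R-value:                         0.8734
planted in-pocket fraction:                 0.8644
```

The R-value (0.87) tracks the fraction of frames in which the ligand
actually sat in the pocket (0.86): the score reads off the planted
persistence. Values above 0.70 indicate a stable, native-like pose. The
other scripts under `examples/` demonstrate representative-frame selection,
residue/atom stability maps, pose classification and affinity correlation,
one capability each.

A `posestab` command-line interface mirrors the library for shell use
(`posestab rvalue`, `represent`, `residue-map`, `rmsf`, `classify`,
`correlate`, `simulate`); every run echoes its effective configuration and
is byte-for-byte reproducible.

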
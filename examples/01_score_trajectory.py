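"""Score a trajectory's contact persistence against its docking pose.

Builds a synthetic protein-ligand complex, simulates a multi-replica
trajectory in which the ligand occasionally leaves the pocket, then
computes the trajectory R-value against the starting pose.
"""

import posestab as ps

cfg = ps.GeneratorConfig(persistence=0.85, n_frames=150, n_replicas=3, seed=42)
reference = ps.make_toy_complex(cfg)  # the "docking pose"
traj, truth = ps.simulate_trajectory(cfg)

topo = reference.topology
protein = ps.select_atoms(topo, "protein and heavy")
ligand = ps.select_atoms(topo, "ligand and heavy")

# drop the equilibration part of each replica, pool the rest
windowed = ps.apply_window(traj, ps.AnalysisWindow(discard_fraction=0.6))

contacts = ps.identify_native_contacts(reference, protein, ligand)
series = ps.compute_distance_series(windowed, contacts)
result = ps.r_value_trajectory(series, contacts)

print(f"native contacts (< 4.5 A in the reference): {contacts.n_contacts}")
print(f"frames analyzed (pooled, post-window):      {series.n_frames}")
print(f"trajectory R-value:                         {result.r_global:.4f}")
print(f"planted in-pocket fraction:                 {truth.intact_mask.mean():.4f}")
# The R-value tracks the fraction of frames in which the reference contact
# network is intact; values > 0.70 indicate a stable, native-like pose.
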
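# Methods

## Model

`posestab` treats a binding pose as a *contact network*: the set of
protein/ligand heavy-atom pairs closer than a native cutoff (4.5 Å,
strict `<`) in a chosen reference structure. For each trajectory frame the
pipeline evaluates, per native pair, the smoothed indicator

    f(r) = 1 / (1 + exp[ β (r − Λ r⁰) ])

where r is the pair distance in the frame, r⁰ its reference distance,
β = 5.0 Å⁻¹ the smoothing parameter and Λ = 1.8 the contact-fluctuation
parameter. The per-frame R-value is the mean of f over the N native pairs;
the trajectory R-value is the unweighted mean of per-frame values over the
pooled analysis window. Because every pair contributes to every frame, the
per-frame mean and the frame mean commute, so this equals the grand mean of
the frames × pairs term matrix — the package tests this identity directly.

Assumptions worth stating:

- frames are whole-molecule imaged (no periodic minimum-image correction
  is applied; trajectories are expected to come out of the MD pipeline
  already re-imaged);
- hydrogens never enter contact sets — both the native cutoff and the
  retention filter operate on heavy atoms only;
- replica files are positional: file order defines `replica_id`, since no
  trajectory format carries replica metadata.

### Reference modes

The same machinery scores a trajectory against three kinds of reference:
the initial docking pose (`dock`), the experimental pose (`exp`), or the
trajectory's own representative frame (`repr`). Contacts are re-identified
at 4.5 Å on whichever reference is named, so the three scores answer
different questions (did the starting pose persist / did the native pose
persist / is the ensemble internally coherent).

### Analysis window and pooling

Each replica discards its leading `discard_fraction` of frames
(`floor(d·n)` frames; default 0.6, mirroring a 60 ns equilibration of a
100 ns run) and the survivors are concatenated in replica order. All
downstream statistics — ensemble contact matrix, R-values, RMSF — use the
pooled frames. Pooling across replicas (rather than averaging per replica
first) is the choice consistent with reporting a single representative
structure per system; the pooled-frame mean is used for the ensemble
matrix and is configurable in principle by windowing replicas separately.

### Representative frame

All protein–ligand heavy-atom pairs are candidates; pairs whose pooled
trajectory-mean distance is ≤ 6.75 Å (inclusive) are retained. Each frame's
retained-pair distance vector is compared to the ensemble mean vector by
Euclidean norm; the argmin frame wins, with ties broken by the lowest
pooled frame index so degenerate (e.g. static) trajectories resolve
deterministically to the first frame.

### Decompositions

Per-residue: contacts group by the protein residue key
(chain, resseq, insertion code, resname); `r_residue` is the mean sigmoid
term over that residue's frames × pairs block; `contribution` =
`r_residue × contact_count`, which makes Σ contributions = N · R exactly
(tested to 1e-9), and `%Contribution` normalizes to 100. Per-ligand-atom
maps group by ligand heavy atom; atoms without any native contact are
`no_contact` with a null R. The stable / less-stable / unstable category
bounds (0.85 / 0.70) are package defaults for the three-color scheme —
they are reported in every output and configurable, as no canonical
numeric legend exists for them.

## Geometry

Superposition is a standard Kabsch fit (SVD with the determinant sign fix
excluding reflections), requiring ≥ 3 non-collinear fit atoms. Ligand RMSD
superposes on protein Cα by default, applies the transform, and measures
ligand heavy atoms *without re-fitting the ligand* — a drifted ligand in a
well-aligned pocket scores its true displacement. No symmetry-aware RMSD
is attempted (a known limitation for symmetric ligands). RMSF aligns every
frame to the representative on Cα and reports per-residue fluctuation
about the time-mean position; note that removing 6 rigid degrees of
freedom slightly deflates fluctuations when the fit set is small, which is
why the fluctuation-recovery test uses a 60-residue fit set (bias < 2%).

## Classification and metrics

Stability crosses similarity with strict inequalities: SS requires
R > 0.70 *and* RMSD < 3.0 Å; values exactly at a threshold fall in the
unfavorable class. Ranking within a docking ensemble is by descending
R-value with deterministic tie-breaks (lower RMSD, then pose id).
Ensemble metrics per ligand: `top1_hit` (docking-score top pose already
native-like by its initial RMSD), `dock_success` (any pose native-like),
`rescued` (top-1 failed but the R-ranked top pose is SS after MD). The
threshold-sensitivity grid reports global %SS, per-system %SS and
Δ%SS = per-system − global (signed, with absolute values alongside), the
package's operational definition of inter-system dispersion.

## Affinity

Kd values are accepted in M, mM, µM, nM, pM and converted to molar; pKd =
−log₁₀(Kd). IC50/Ki rows are dropped unless explicitly included, and are
never mixed into Kd correlations by default. Complexes with R < 0.70
(strict) are excluded as non-native-like before correlating; outlier
exclusion beyond that is only ever a user-supplied list. Pearson r requires
≥ 3 complete pairs and non-zero variance; per-residue correlations are
computed both for `r_residue` and for `contribution`, side by side, and
residues observed in fewer than 3 ligands are flagged rather than scored.

## Synthetic data

Two generator tiers, because realizing an arbitrary distance matrix
exactly in 3-D is infeasible:

- **Distance level** — each native contact is independently intact per
  frame with probability p (distance = r⁰ + N(0, σ) truncated positive) or
  broken (distance = Λr⁰ + offset + |N(0, σ)|). The expected R-value is
  computed by numerically integrating the emission densities through the
  sigmoid (truncated-normal and half-normal quadrature), giving a
  closed-form oracle for recovery tests.
- **Coordinate level** — a toy pocket (pseudo-residues on a 4.2 Å shell
  around a 1.2 Å ligand blob, evenly spread directions plus seeded jitter)
  whose ligand undergoes rigid-body translation noise and, with
  probability 1 − p, a 10 Å excursion out of the pocket. This tier
  exercises the full pipeline including superposition and
  representative-frame selection.

Defaults (8 residues × 3 atoms, 6 ligand atoms, 3 replicas × 100 frames,
σ = 0.05 Å bound noise, broken offset 4 Å beyond the switching point)
emulate a multi-replica high-temperature ensemble at desk scale; recovery
tests use 500 pooled frames, matching the scale at which sampling error
stays within ±0.03 of the closed-form expectation. All randomness flows
from one seed through named substreams, so adding a generator never
perturbs existing fixtures, and toy-complex coordinates are rounded to
PDB precision (10⁻³ Å) so write/read round trips are exact.

What the generators do *not* emulate: force-field physics, solvent,
correlated contact breaking, ligand internal flexibility, or any specific
real system's geometry. Passing tests therefore demonstrate correctness of
the *analysis* (scoring, selection, decomposition, classification,
correlation) under known ground truth — not the predictive validity of
high-temperature MD itself.

## Numerical choices

- The sigmoid is evaluated with a numerically stable formulation
  (`expit`); exponents routinely exceed 700 for unbound frames and must
  underflow to 0/1 without overflow.
- Native cutoff is strict (< 4.5 Å); retention cutoff is inclusive
  (≤ 6.75 Å). Both are configurable.
- PDB altloc handling keeps the highest-occupancy conformer (ties resolve
  to the first, conventionally 'A'); HETATM residues on the solvent/ion
  drop-list (HOH, WAT, NA, CL, SO4, GOL, common ions) are removed at load.
- XTC coordinates convert nm → Å by exactly ×10 at the reader boundary;
  everything downstream is Å.
- TSV floats are written with shortest-roundtrip repr so read-back is
  exact; reports contain no timestamps, making repeat runs byte-identical.

## Known limitations

No periodic-boundary handling; no symmetry-corrected RMSD; no
interaction-type annotation (H-bond vs van der Waals); no free-energy or
kinetics estimation. The toolkit scores contact persistence — it does not
decide whether high-temperature MD is an appropriate stress test for a
given system.
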
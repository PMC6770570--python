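# Methods

## Problem setting

An intrinsically disordered domain binds a folded receptor through short
segments that transiently form α-helices in the free state
(MoRFs). The analysis chain supported here asks, given a free-state
conformer ensemble, a large rigid-body docking ensemble on the receptor,
and MD trajectories of selected complexes: which IDR segments does the
receptor recognize, which encounter geometries can evolve into the native
complex, and how do downstream segments (the consensus anchors that are
extended on the receptor surface in crystal structures) behave
dynamically?

## Data model and conventions

Structures are parsed from PDB 3.3 fixed-width records via biotite into a
thin wrapper keeping author residue numbering exactly as read. Altlocs
resolve to the highest-occupancy location (ties: first occurrence).
Insertion-coded residues are excluded from numeric ranges with a warning,
since ranges address insertion-free author numbering. Hydrogens are
parsed and retained; `heavy` selections drop them by element, falling
back to the atom-name first letter (after stripping leading digits) when
the element field is blank. HETATM records are excluded from selections
and contact partners by default, with a flag to include them — whether
bound cofactors should count as contact surface is a judgment call the
caller makes explicitly. `mainchain` means N/CA/C/O.

Construct-local numbering is used throughout (e.g. segments 9–18, 37–46
of a ~60-residue construct); any offset to a full-protein numbering is
metadata the caller applies, never applied silently.

## Geometry

**Superposition** is weighted least squares (Kabsch via SVD) with the
determinant sign corrected so only proper rotations are returned;
chirality can never be inverted by a fit. Degenerate inputs (< 3 points,
collinear point sets) are rejected rather than silently fit.

**Segment axis.** The axis of a (partially) helical segment is the
dominant singular direction of its centered CA coordinates, with the sign
fixed so the axis points from the first toward the last residue. The sign
matters: the productive-complex filter must distinguish a segment bound
parallel to the crystallographic helix from one bound antiparallel, and a
sign-free inertia axis would fold both to the same angle. Angles between
axes use atan2(|u×v|, u·v), accurate near 0° and 180°. Note that for a
window covering a non-integer number of helical turns the principal
direction tilts away from the ideal helix axis (≈ 6° for 10 residues at
100°/turn twist); this is a property of the definition, is shared by any
implementation of it, and is far inside the 30° filter width.

**Radius of gyration** is mass-weighted (standard atomic masses from the
element field) over heavy atoms by default, with an unweighted CA-only
option; the underlying primitive accepts arbitrary masses.

**Helix assignment** is a deliberate stand-in for a full
secondary-structure program: a residue is provisionally helical iff
φ ∈ [−100°, −30°] and ψ ∈ [−67°, −7°], and only runs of ≥ 4 consecutive
provisional residues are kept. The window brackets canonical α values
(−57°, −47°) and the run rule suppresses isolated dihedral coincidences.
Termini and residues with missing neighbours get no dihedral and are
never helical. Window and run length are parameters.

## Clustering

gromos-style neighbour counting: all pairwise RMSDs over the chosen atom
set (each pair superposed first by default; a no-fit variant is
available), then iteratively the unassigned conformer with the most
neighbours (strict RMSD < cutoff; a conformer neighbours itself) seeds a
cluster and its neighbourhood is removed. Ties in neighbour count go to
the lowest conformer index, making the procedure deterministic. Clusters
are kept in formation order, which is population order except under ties;
the representative subset for a coverage target is the shortest prefix
whose summed population reaches the target. The default cutoff is 5 Å
(0.5 nm) over mainchain atoms — the coarse cutoff conventionally used for
disordered ensembles, where finer cutoffs shatter the ensemble into
singletons. The superposition atom set for the pairwise fit is
configurable separately from the RMSD atom set because conventions differ
between tools; defaults use the same set for both.

## Docked-pose analysis

Pose sets hold one rigid receptor, one ligand topology, N coordinate
sets and N scalar scores (larger = better). Top-fraction selection keeps
⌈f·N⌉ poses — at f = 0.01 and N = 702,920 that is 7030, matching the
convention of keeping the "top 1%" of a large docking ensemble; note that
published counts do not always follow one consistent rounding rule (a
companion ensemble of 754,118 is reported as 7540 where ceiling gives
7542), so the ceiling convention here is a documented choice, not a
reconstruction. Boundary score ties break by pose index.

A residue is in contact when its minimal heavy-atom distance to the
partner satisfies a strict `< 4 Å` (both the cutoff and the strictness
are parameters). Probabilities are exact pose counts divided by N, which
the profile type enforces. Receptor-side profiles are computed against
the union of the given ligand segments and can be split per receptor
chain for two-chain receptors.

## Productive-encounter filtering

Criteria: a recognition segment, a hot-spot set (receptor residues the
reference crystal helix contacts; default rule ≥ 6 of them within 4 Å),
and a maximum axis angle (default strict < 30°) against the reference
helix orientation. The pass rule is exactly `count ≥ k AND angle <
30°`; segment RMSD is reported alongside but does not gate. RMSD is
computed natively in the reference frame: the pose receptor is superposed
onto the reference receptor over shared CA atoms (shared = same chain and
residue number on both sides, which transparently handles a reference
that lacks terminal residues), the transform is applied to the ligand,
and the segment CA RMSD is taken without refit. When one criteria object
is evaluated, it carries one segment; analyses interested in several
candidate recognition segments run the filter per segment and report each
(see `analysis/03_filter_productive.py`).

## Trajectory metrics

Frames are equally spaced; Δt is supplied by the caller (20 ps per frame
in the default synthetic conditions). RMSD traces superpose each frame
onto a reference over a fit segment (the receptor), then report
no-refit CA RMSD per report segment — the quantity that measures a
segment's displacement in the receptor frame. Minimal-distance traces
are exhaustive atom-pair minima between two disjoint groups. Transient
contact profiles are contact probabilities over frames, same contact
definition as for poses.

The autocorrelation of a distance series is computed on the mean-centered
series (the standard convention; assumed, since conventions are rarely
stated) with FFT via statsmodels, normalized so C(0) = 1. The relaxation
time is, by default, Δt times the sum of C from lag 0 up to (not
including) its first non-positive value — parameter-free, exact for a
geometric/exponential ACF (it returns Δt/(1−φ) ≈ τ + Δt/2 for an AR(1)
with φ = e^(−Δt/τ)) — with a least-squares single-exponential fit over
the same lag range as a cross-check; both are reported. The single-path
spread of the integral estimator is substantial when the series is short
relative to τ: at 10⁵ frames and τ = 100 frames the across-path standard
deviation is ≈ 12%, so individual paths occasionally deviate more than
20% while the across-path mean recovers τ within a few percent; at
trajectory-like lengths (2000 frames) single-path estimates can be off
by ~50% — which is why the acceptance checks quantify recovery as an
aggregate over seeds.

## Synthetic generators

All generators are pure functions of a `SynthSpec` (seed included);
random streams are derived per component (coil dihedrals, helix flags,
pose placement, scores, noise, trajectory, receptor shell) so changing
one field perturbs only its component, and repeated calls are
bit-identical.

*Chains.* Backbones (N/CA/C/O) are built from internal coordinates with
ideal bond geometry and trans peptides. The ideal helix uses
(φ, ψ) = (−57°, −47°), giving 1.5 Å rise, 100° twist and ~2.26 Å CA
radius (CA–CA 3.80 Å). Ensemble conformers sample coil residues from
three extended basins (β, PPII, extended) with ±15° jitter — chosen to
stay outside the helix-assignment window so planted helical flags map
exactly onto measured propensity — and helical segments at canonical
values with σ = 3° noise. Each helix segment is helical in an
independently drawn ~`helix_probability` (default 0.4) fraction of
conformers; the spec type carries `n_conformers` (default 200) and
`helix_probability` because the planted-propensity contract needs both.
Chains are re-sampled (bounded retries) until CA atoms of residues ≥ 3
apart in sequence stay > 3 Å apart.

*Toy receptor and poses.* The receptor is a rigid CA-only pseudo-protein
(default 100 residues, chain R): 9 hot-spot residues placed 3.5 Å from
evenly spaced interior heavy atoms of the recognition segment in its
reference placement (anchoring to interior residues keeps covalently
adjacent flanking residues measurably farther from the groove than the
segment itself), plus filler residues on a shell behind the groove, kept
≥ 6 Å from the reference ligand. Productive poses perturb the reference
placement by a rotation within 0.8× `axis_jitter` (default jitter 20°,
validated < 30°) and sub-Å translation, accepted only if they keep ≥ 6
hot-spot contacts and axis angle < min(jitter, 25°); non-productive poses
are remote placements (verified ≤ 3 hot-spot contacts) or antiparallel
groove placements (verified angle ≥ 90°), roughly 30% antiparallel.
Scores are drawn from N(5, 1) for productive and N(0, 1.5) for
non-productive poses — overlapping, so score-based selection is
enriching, not oracular. The planted mask is exact by construction
(`round(fraction × n)` poses).

*Trajectories.* The receptor is static; the ligand translates rigidly
along the groove normal so the recognition segment's minimal distance to
the receptor follows a discretized Ornstein–Uhlenbeck (AR(1)) process
with relaxation `ou_relaxation` frames (default 100) and stationary
amplitude 3 Å about the bound-contact distance (displacements are floored
at contact). The planted AR series and per-frame bound labels (realized
minimal distance < 4 Å) are returned as ground truth; the series
generator is exposed standalone so long series (10⁵ frames) can be made
without materialising frames.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: no side chains, energetics, solvent or force
field; coil sampling has no long-range compaction, so synthetic ensembles
are more extended than real IDR ensembles (Rg ≈ 40 Å for 60 residues)
and cluster mostly into singletons at the 5 Å cutoff — the clustering
machinery is exercised, but published cluster counts for MD ensembles
(which are temporally correlated) are not comparable and are not a
target; pose scores carry no interface physics; trajectory motion is a
single rigid translation mode, so RMSD and distance traces are perfectly
correlated by construction. Tests on these fixtures validate the
*measurement machinery* (selection, counting, geometry, estimators)
against planted truth, not the biology.

## Pipeline

`run_pipeline` executes stages (synth → cluster → contacts → filter →
traj) from a validated YAML config with CLI overrides, logs per-stage
counts, and writes a manifest (input SHA-256, parameter echo, package
version, output checksums). Tables are written with fixed float formats,
so identical config + inputs reproduce byte-identical outputs. Stage
failures abort with the stage name; outputs written before the failure
are flagged partial in the manifest. Exit codes: 2 validation,
3 stage failure. The file-based `filter` stage requires a criteria
definition; with synthetic inputs the planted criteria are used.

## Reference checks

`encompass.reference` computes the CA RMSD of each actin chain of the
dimeric reference complex (PDB 3M3N) onto the monomeric reference actin
(PDB 2VCP) over shared residue numbers (expected: 0.99 Å chain A,
0.66 Å chain B), with an `exclude_termini` option since deposited
termini are flexible and it is not always stated whether published values
include them. Coordinate files are not bundled; a fetch helper downloads
them where RCSB is reachable.

## Problem sizes

Default test and acceptance scales — 200-conformer ensembles, 200–1000
pose sets, 100 recovery seeds, 20 relaxation seeds at 10⁵ frames,
2000-frame trajectories — were chosen so the full suite and the
acceptance script each run in well under a few minutes while keeping the
statistical contracts (≥ 95/100 recovery, aggregate 20% relaxation
recovery) meaningful.
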
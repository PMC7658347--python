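# Methods

This note documents the models, conventions and numerical choices behind
`tuscmorph`, in the order of the pipeline.

## Atomic models and residue identity

Structures are read from PDB or mmCIF via gemmi and flattened to a plain
chains → residues → atoms hierarchy with Å coordinates.  Residue identity is
always the author numbering of the deposited file plus the insertion code —
never a re-index — because published descriptions of these complexes cite
residues by deposited numbering (e.g. an Spc98 GRIP2 insertion around
residues 626–656).  Altlocs are resolved at parse time: the highest-occupancy
conformer wins, ties go to the alphabetically first altloc id.  Waters and
all-hetero residues are excluded from superposition selections by default.

Segment definitions (name + inclusive residue ranges per chain + atom
subset) come from a YAML config.  GRIP1/GRIP2 domain boundaries are
deliberately *not* hard-coded: no authoritative boundary residue numbers are
published for the Spc/GCP proteins, so the shipped configs carry clearly
labelled, user-editable ranges, and the toy config matches the synthetic
generator exactly.

Residue correspondence between homologous chains is a global
Needleman–Wunsch alignment (Biopython `PairwiseAligner`) with BLOSUM62 and
affine gap penalties (open 10, extend 1); non-standard residues map to `X`
with a warning, gap columns are dropped, and the first optimal alignment is
taken, which is deterministic for fixed inputs.

## Rigid superposition and the morph comparison

`kabsch` is the closed-form SVD solution for the least-squares rigid
superposition; when the determinant of the candidate rotation would be −1
the smallest singular vector's sign is flipped so only proper rotations are
returned.  Inputs with fewer than 3 pairs or a rank-deficient (collinear)
point cloud are rejected: the rotation is not identifiable there.

The morph comparison proceeds exactly as its four steps are documented in
the API: per-segment matched superposition onto the reference, assembly of
the placed segments into a composite, re-anchoring of the composite onto
the query over the union of anchor segments (typically one whole spoke),
and per-segment RMSD between composite and query.  Two conventions matter:

* **Atom subset: Cα by default.**  Published RMSD tables for this kind of
  comparison are captioned per Cα backbone atoms while surrounding text
  sometimes says "protein backbone atoms"; Cα is the stricter documented
  reading, and `BACKBONE` (N, CA, C, O) is available as an option.
* **No iterative pruning by default.**  Interactive matchmaking tools often
  iteratively discard far pairs, which lowers residuals in a way that
  depends on unstated settings.  The default here is the reproducible
  unpruned fit; a single-pass prune (drop pairs > 2.0 Å after the first
  fit, refit once) is available to probe sensitivity.

When query and reference differ in residue count within a segment, the RMSD
is computed over aligned pairs only and coverage is reported alongside.

## Density maps

A map is a scalar field on a regular isotropic grid with
`world = origin + index · voxel_size` and axes in X, Y, Z order; MRC/CCP4
files are read through gemmi with axis permutations normalised on read and
the origin taken from the ORIGIN header, falling back to the start indices.

Simulation places an isotropic Gaussian on every atom with
σ = sigma_factor × resolution.  The default sigma_factor 1/(π√2) ≈ 0.2251
is a widely used resolution convention; it is configurable because analyses
in the literature typically rely on a tool default they do not print.  Each
atom's kernel is truncated at 5σ (keeping > 99.9% of its mass) and the grid
covers the atom bounding box plus 3σ padding by default.  A sampling guard
rejects resolution < 2 × voxel size.

Cross-correlation is the normalised inner product over an optional voxel
mask, with means subtracted by default (Pearson form).  Both the mean
convention and the mask are explicit arguments because the segmentation
behind published per-segment correlation values is generally not defined;
when reproducing such values both conventions should be computed and
reported.

Rigid-body fitting maximises the mean interpolated map value at the atom
positions over the six rigid degrees of freedom.  Scoring interpolates a
tricubic B-spline of the grid rather than the trilinear field: the
trilinear interpolant is piecewise linear and its kinks displace the score
maximum by a noticeable fraction of a voxel, while the cubic interpolant is
smooth and keeps the maximiser at the true placement (verified by the
recovery tests: a 2 Å / 5° perturbation is recovered to ~0.005 Å / 0.05°).
The optimiser is a deterministic coarse-to-fine coordinate ascent (steps
halving from 1 Å / 4°) followed by a Nelder–Mead polish, stopping below
0.01 Å / 0.01°.  It is strictly local by design, matching interactive
map-fitting practice; global search is out of scope.

Zone masking zeroes (or exclusively keeps) voxels whose *center* lies
within the radius of any atom, inclusive at the boundary; keep and remove
outputs partition the map exactly.  Ligand-site scoring reports the mean
map value in the zone of each ligand moiety and the ratio of a probe moiety
(e.g. the γ-phosphate) to the mean of the others; a ratio below 0.5 labels
the site GDP-like, and a near-zero rest mean makes the call indeterminate
rather than dividing by noise.

## Tubulin conformation call

The classifier docks each complete reference β-tubulin (one straight, one
curved) into the γ-tubulin density, then scores only helices α6/α7: Cα RMSD
against the query model *at the docked positions* (no re-superposition —
the docking itself is the evidence) and cross-correlation between density
simulated from the docked helices and the experimental map masked to within
3 Å of those helices.  The label requires both criteria to agree; ties or
disagreement yield "indeterminate".  Helix ranges are config: helices are
cited by name in the literature, and their residue ranges depend on the
reference structure's numbering.  Which reference is "straight" and which
"curved" is likewise a config label, not an assumption baked into code.

## Displacement fields and centroids

Displacement vectors link each shared residue's representative atom (CA)
between the original model and the composite.  A segment's mean arrow is
anchored at the centroid of start positions with the component-wise mean
vector; when the mean vector's magnitude falls below 10% of the mean
per-residue magnitude the arrow is flagged uninformative — the motion is
predominantly rotational and a single arrow misrepresents it.  Centroids
for the γ–γ distance are unweighted CA centroids ("centers" is otherwise
undefined); a mass-weighted option exists.  Distance changes below 0.05 Å
are reported as "unchanged"; a positive delta (query wider than reference
conformation) means the transition moves the γ-bodies closer together.

## Interfaces

Contacts are residue pairs with any heavy-atom pair within 4.5 Å
(inclusive), found with a k-d tree and validated against an all-pairs scan.
The cutoff is a common convention, explicit because interface servers do
not all share one.  Hydrophobic fraction uses the Kyte–Doolittle scale with
"hydrophobic" = positive hydropathy (A, C, F, I, L, M, V); the table is
overridable.  Salt bridges pair Asp/Glu side-chain oxygens with
Lys/Arg/His side-chain nitrogens within 4.0 Å.  Buried surface area is
deliberately not computed — contacts plus character answer the questions
this package asks, and BSA is a substantially larger algorithm.

## Synthetic generator

The toy assembly is two spokes of three rigid blocks each (GRIP1, GRIP2,
γ-body), every block a bundle of ideal poly-alanine α-helices (rise 1.5 Å,
twist 100°, Cα radius 2.3 Å; default 3 helices × 20 residues per block),
the spokes leaning ±20° from vertical in a common plane — a deliberately
minimal Y-shape.  The conformational transition rotates the second spoke's
GRIP2+γ block about the GRIP1/GRIP2 junction, about the axis normal to the
spoke plane, toward the first spoke; the default 15° tilt produces γ-body
displacements of the same order as those measured between open- and
closed-state fungal complexes.  Gaussian coordinate noise (default 0) is
added to the second state only, so the ground-truth transforms map state 1
to the noise-free state 2 exactly, and expected per-segment RMSDs are
computed by applying those transforms directly.  Sequences are identical
poly-alanine by construction (the mutation option renames a seeded fraction
of residues to exercise the alignment path separately).

What the toys do *not* emulate: side chains and real secondary-structure
packing, B-factors/disorder, solvent, map artefacts beyond i.i.d. Gaussian
voxel noise, and the resolution anisotropy of real reconstructions.
Passing the synthetic suite therefore demonstrates the correctness of the
geometry, density arithmetic and bookkeeping — not robustness to the full
messiness of experimental maps, which is what the accession-based
regression (user-downloaded files) is for.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run at desk scale: toy
assemblies of 360 Cα atoms, maps of ~10⁴–10⁵ voxels, 10–20 seed
replicates for stochastic checks — sizes chosen so the entire verification
runs in seconds while leaving every code path exercised.  All stochastic
steps draw from `numpy.random.default_rng` seeded from a single explicit
seed; identical seeds give bit-identical structures, maps and reports.

## Known limitations

* The rigid-body fit is local; a bad starting placement converges to the
  nearest optimum (helical pseudo-periodicity can cause register shifts).
* mmCIF is read but not written; PDB output imposes its text precision
  (~10⁻³ Å) on round trips.
* Correlation values depend on the mask and mean convention; reproducing a
  published number requires matching those conventions, and both are
  surfaced as arguments rather than fixed.
* Only the first model of multi-model files is used, and anisotropic-voxel
  maps are rejected rather than resampled.
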
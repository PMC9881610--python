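# Methods

This note documents the models implemented in `fragdock`, the numerical
choices behind them, what the synthetic fixtures do and do not emulate, and
the known limitations.

## Grid free-energy maps

A FragMap is an axis-aligned orthogonal grid (default 1 Å spacing) of
per-voxel free energies for one probe type. The Boltzmann transform maps a
normalized occupancy probability `p` to `-kB·T·ln p` with
`kB = 0.0019872 kcal/mol/K` and T = 300 K by default. Two capping rules
make downstream scores well behaved: voxels with `p = 0` and voxels whose
transform would exceed the cap are set to `gfe_cap` (default
+3.0 kcal/mol ≈ 5 kBT at 300 K), and the same cap is returned for lookups
outside the grid. The cap value is a package choice: it must be finite so
that Monte-Carlo moves through unvisited space remain comparable, and
unfavorable enough that occupied voxels dominate. It is configurable
everywhere it appears.

Voxel lookup is **nearest-voxel** — index `floor((x-origin)/spacing + 0.5)`
per axis, half-way points rounding up — rather than trilinear
interpolation. Two reasons: occupancy-derived maps represent voxel
occupation rather than a smooth field, and nearest-voxel keeps the ligand
score exactly linear in the per-type weights, which the weight optimizer's
fast path requires. Interpolation is deliberately not offered; smoothness
can be had by generating smoother maps.

I/O uses the OpenDX scalar-field dialect (`object 1 class gridpositions`
header, three axis-aligned delta lines, values in row-major z-fastest
order). The parser validates the declared item count against both the grid
dimensions and the data payload and reports the offending line on failure.
Non-orthogonal delta vectors are rejected; rotated grids are out of scope.

## Ligand model and atom classification

Ligands are explicit graphs (element, formal charge, attached-hydrogen
count, bond orders, 3D coordinates); SDF ingestion and emission go through
rdkit, with per-record failures skipped and logged rather than fatal.

Each heavy atom receives exactly one FragMap-type label from an ordered,
first-match-wins rule table; hydrogens are never scored (maps are built
from heavy-atom densities). The default table implements the precedence
charged > donor > acceptor > apolar:

1. N with positive formal charge → MAMN
2. O with negative formal charge → ACEO
3. O double-bonded into a group containing a negatively charged O
   (carboxylate resonance partner) → ACEO
4. N/O with ≥ 1 attached hydrogen → GEND
5. remaining N/O → GENA
6. C → GENN
7. anything else → UNCLASSIFIED (zero score, warning)

This table is a documented approximation of the generic apolar-scale
classification scheme used with production FragMaps, whose full definition
lives in supplementary material not reproduced here; users can load a
replacement table from YAML. Classification is a pure function of graph and
charges — coordinates never enter — and the rule in item 3 requires the
double bond so that chain ethers adjacent to charged oxygens are not
misclassified.

Rotatable bonds are single, acyclic bonds whose endpoints are heavy atoms
with at least two heavy neighbors; ring membership is decided by
connectivity after bond removal, which also yields the movable atom set.
Terminal-group rotations are excluded because they cannot move heavy atoms.

## Scoring, ionization weighting, and pIC50

`LGFE = Σ_a w[label(a)] · GFE_{label(a)}(x_a)`, an exact sum of per-atom
terms; group sums over any atom partition reproduce the total exactly,
which supports per-moiety decomposition of a pose. Missing maps for a label
contribute zero with a warning rather than failing, so partial map sets
remain usable.

Ionization-state weighting mixes the neutral- and charged-state LGFEs
linearly by Henderson–Hasselbalch fractions at pH 7.4 (base:
`f_charged = 1/(1+10^(pH-pKa))`; acid: mirrored). Mixing energies linearly
(rather than Boltzmann-averaging affinities) treats the reported score as
an ensemble-weighted expectation, is convex by construction, and is the
form the workflow's "ionization-state-weighted LGFE" takes. pKa values are
inputs; no prediction is attempted.

LGFE→pIC50 conversion defaults to the thermodynamic relation at 300 K,
`pIC50 = -LGFE/(ln10·kB·T)` (denominator 1.3727 kcal/mol). The mapping
between a grid score and a measured pIC50 is not uniquely determined, so an
affine mode `a·(-LGFE)+b` with user-fit coefficients is provided; only
MUE depends on the choice, since R, PI and PC are invariant under positive
affine maps.

## Monte-Carlo docking

One run = random placement (centroid uniform in a sphere, default radius
10 Å; orientation uniform via random quaternion) → greedy minimization
(accept only score-lowering moves; default 10,000) → Metropolis MC at
300 K (default 10,000) → simulated annealing with a **linear** temperature
ramp from 300 K to 0 K (default 40,000 steps; only the endpoints are
prescribed, linearity is the package's choice). The move set picks
uniformly among rigid translation, rigid rotation about the centroid, and
torsion rotation (when rotatable bonds exist); perturbations are uniform
within amplitudes of 1.0 Å / 0.25 rad / 0.5 rad. The amplitudes are
package defaults chosen to keep acceptance rates moderate on voxelized
fields. The reported pose is the best seen anywhere in the run, not the
final state.

The multi-run protocol executes up to five independent blocks of up to 50
runs (each block on its own reproducible RNG substream), declaring
convergence when the two lowest run minima agree within 0.5 kcal/mol and
stopping unconditionally at 250 runs. "Two lowest run minima" is one
reading of a tersely specified convergence rule; both the rule's tolerance
and the block structure are configurable.

Intramolecular strain is not modeled: the greedy stage stands in for a
force-field pre-minimization, and an optional
`intramolecular_energy(coords)` callback can be added to the MC energy for
ligands where strain matters. For the rigid and semi-rigid fixtures used
throughout the tests this changes nothing; for highly flexible real
ligands the pure-grid energy can favor overly compact conformers.

## Weight optimization (BML)

Because LGFE is linear in `w`, fixed poses reduce to a feature table
`g[i, t]` and the predicted pIC50 is an affine map of `g·w`. The optimizer
is Markov-chain MC simulated annealing: start at `w = 1`; per step perturb
one randomly chosen weight uniformly within ±0.05; accept by Metropolis on
the loss `-metric + penalty` under an effective temperature decaying
geometrically from 1.0 to 1e-4 over the chain (default 50,000 steps);
return the best-loss weights seen. The penalty is flat-bottom:
`k·max(0, w-upper)² + k·max(0, lower-w)²` with k = 5000 kcal/mol and
bounds [0.05, 2.0]. The chain length, proposal width and temperature
schedule are package defaults (the production schedule is not public);
all are configurable. Because Pearson R is scale-invariant, weights are
identifiable only up to a common factor — recovery tests therefore assert
predicted-pIC50 agreement, not weight equality.

Training is train-once/apply-everywhere: one weight set fitted on the
training split is applied unchanged to every evaluation set. Final metrics
come from **redocking** all compounds under the trained weights, since
reweighting moves pose optima; the redock report includes per-compound
centroid shifts versus the original poses as an overfitting sentinel
(weights that only look good because every pose moved are suspect).

## Descriptor and consensus models

The physicochemical property model is ordinary least squares with
intercept over logP, logS, TPSA, MW and van der Waals volume, consumed
from an input table (descriptor computation is not normative; any provider
with the same schema plugs in). Rank deficiency raises an error naming the
collinear columns, found by testing each column against the span of the
others. The consensus model appends the structure-based predicted pIC50
(neutral, charged or HH-weighted variant) as a sixth regressor and refits
jointly; an average-of-predictions combination is available as an
alternative. No regularization or feature selection is performed.

## Metrics

- MUE: mean |pred − exp| in pIC50 log units.
- Pearson R, with a guard returning 0 (with a warning) on zero-variance
  input so optimizer objectives stay finite.
- PI: `Σ w_ij c_ij / Σ w_ij` over pairs i<j with `w_ij = |exp_j − exp_i|`;
  `c_ij` is ±1 by sign agreement of the predicted and experimental
  differences, 0 for prediction ties. Experimental ties carry zero weight;
  all-equal experimental input leaves PI undefined (error).
- PC: for each reference compound, the fraction of the other n−1 compounds
  whose relative order is predicted with strictly matching sign; averaged
  over references. Ties count as incorrect by default (configurable to
  half credit). Random independent predictions give PC ≈ 0.5, PI ≈ 0.

Tie conventions are package choices where the source definitions are
silent; both are documented and the PC convention is configurable.

## Synthetic fixtures

The generator exists so every stage is testable with no external data. It
emulates the *shape* of real inputs, not their content:

- **Maps**: a capped baseline plus negative Gaussian wells
  (`depth·exp(-r²/2σ²)`), superposed additively. Real maps are rugged and
  multi-basin; Gaussian wells give known global minima for exhaustive-scan
  oracles.
- **Ligands**: zig-zag heavy-atom chains (1.5 Å bonds) whose class labels
  are fixed by construction — chemically simplistic by design, since the
  scoring/docking/BML mathematics sees only labels and coordinates.
- **BML tables**: features uniform[-5, 0] on a per-ligand random sparsity
  pattern (each type present with probability 0.7, ≥1 per ligand);
  affinities are the true-weight prediction plus Gaussian pIC50 noise
  (default σ = 0.3 log units, matching the scale on which model error is
  expressed).
- **End-to-end studies** (`write_fixture_study`): one broad shared basin
  per map type (depth −6 kcal/mol, width 6 Å, co-located), chains of 5–9
  atoms, affinities generated from poses docked under non-unit true
  weights, optionally mixed with a linear descriptor signal. Co-locating
  the wells makes composition, not pose competition, carry the affinity
  signal, so the score stays near-linear in the weights and the
  weight-recovery property is well posed; with wells at distinct sites,
  pose switching under reweighting makes the fixed-pose table a poor guide
  to redocked scores — a real phenomenon, but not the property these
  fixtures are built to isolate.

Consequently, passing tests demonstrate the correctness of the machinery
(scoring identities, sampling distributions, optimizer recovery, pipeline
plumbing, determinism), not predictive performance on real hERG blockers,
which depends on map quality and chemistry outside the generator's scope.

## Problem sizes and determinism

The test and acceptance workloads use scaled protocols chosen as the
smallest sizes at which each property is comfortably resolved: docking
recovery uses 100/1,000/4,000 steps over 100 seeds on a single-well map;
weight recovery uses 20,000-step chains on 50-ligand tables over 10 seeds;
pipeline studies use 16–24 ligands with 30/150/600-step, 2×2-run docking
and a 5 Å placement radius. Production-scale defaults (10,000/10,000/
40,000 steps, 5×50 runs, 50,000-step chains) remain the constructor
defaults.

Every stochastic component takes an explicit RNG or integer seed;
identical seeds give bit-identical results, including byte-identical
pipeline reports (floats are rounded to 10 decimals at the JSON boundary
to keep reports stable across platforms' float formatting).

## Known limitations

- No intramolecular energy by default; no sterics beyond the GFE field; no
  receptor flexibility.
- Nearest-voxel lookup makes the score piecewise constant, so gradients
  are unavailable and minimization is purely stochastic.
- The classification table is an approximation; substitute the full
  published scheme via YAML for production use.
- S1 and S2 sites are docked and evaluated independently; no simultaneous
  multi-site training.
- Weight identifiability is up to scale under correlation objectives.
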
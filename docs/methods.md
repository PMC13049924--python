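# Methods

This note documents the models and procedures `peroxidyn` implements, the
defaults it ships, and the reasoning behind design choices that were
genuinely open. Units are Å for coordinates, °C for temperatures, Å² for
variances and scores, s⁻¹ for rate constants, μM for concentrations.

## Containers and selections

Structures are parsed from PDB text (via biotite) into an ordered
`Topology` of atom records; alternate locations are resolved to the
highest-occupancy conformer (ties keep the first encountered), insertion
codes are preserved in residue keys, and residue numbering follows the
input file verbatim. Hydrogens are identified by the element field, or —
when a minimal writer leaves it blank — by the atom name's leading letter
after digit stripping. A `TrajectoryEnsemble` holds an F×N×3 coordinate
array with per-frame condition labels and replicate ids, so multi-replicate,
multi-temperature ensembles concatenate without losing provenance.

Selections are declarative (`SelectionSpec`): a residue-id range, a
backbone-only flag (atom names N/CA/C/O), an `include_residue_names` set
that pulls in whole residues such as the heme (`HEM`) and the palmitate
substrate (`PLM`, both names configurable — force fields differ), an
exclude-hydrogens flag, and an explicit atom-name set. Range/backbone
criteria and the named-residue set are OR-ed — matching the idiom "protein
backbone over a residue range, plus heme and substrate, no hydrogens" —
and an empty result raises rather than silently propagating an empty list.
Multi-model PDB is the portable trajectory interchange format; XTC/DCD
reading is available behind the same contract when mdtraj is installed.

## Alignment and essential dynamics

Superposition uses the closed-form SVD (Kabsch) solution with the
determinant correction that excludes reflections; fewer than three or
collinear fit atoms raise a degenerate-fit error. Ensembles are aligned
frame-by-frame onto a reference frame (default: the first frame;
configurable) over the protein backbone heavy atoms, with non-fit atoms
carried by the same rigid transform. Alignment is idempotent to numerical
precision.

PCA operates on the flattened coordinates of an atom selection (default:
all heavy atoms) of the aligned ensemble, pooled across conditions.
The covariance uses the unbiased (F−1) denominator, the common convention
in trajectory analysis. Components are retained up to a cumulative-variance
target (default 0.75); a zero-variance input retains zero components and
warns, rather than silently keeping one. Loading-vector signs are fixed so
each vector's largest-magnitude entry is positive, and eigenvalue ties keep
decomposition order, making outputs deterministic.

The essential-dynamics score is a temperature-factor-like quantity: per
atom, `B_a = (8π²/3) Σ_{k≤K} λ_k ‖v_{k,a}‖²`, where `v_{k,a}` is the
atom's 3-vector block of the k-th unit loading; per residue, the mean of
`B_a` over the residue's analysis atoms (heavy atoms — the same set the
PCA saw). With every component retained the score reduces, by the trace
identity, to `8π²/3` times the atom's total positional variance; with the
truncated K it isolates the share carried by the essential subspace. The
analytic anchor used in tests: an atom whose sample variance (F−1
denominator) is exactly 1 Å² scores `8π²/3 ≈ 26.32 Å²`.

## Conformational states and pseudotrajectories

Frames are clustered in reduced PC space with HDBSCAN (Manhattan metric,
leaf cluster selection), using the first `min(20, K)` score columns.
`min_cluster_size` defaults to `max(10, ⌈0.05·F⌉)` with
`min_samples = min_cluster_size`: leaf selection reports the leaves of the
condensed hierarchy, so the minimum size must be on the order of the
smallest state population one cares to resolve — substantially smaller
values make leaf selection shatter even a compact, well-separated Gaussian
state into density-fluctuation fragments plus noise. Points failing the
density criterion keep the conventional noise label (−1).

Each cluster's medoid is the member frame minimizing the mean pairwise
superposed RMSD to the other members (ties break to the lowest frame
index; agreement with exhaustive search is enforced in tests). The medoid
RMSD matrix is computed over a structural selection — typically the
protein backbone over the catalytically relevant residue range plus heme
and substrate, excluding hydrogens — with each pair superposed before the
RMSD is taken: un-fitted RMSD would depend on arbitrary frame placement.
Pairwise-superposed RMSD need not satisfy the triangle inequality;
violations are logged, not raised.

A pseudotrajectory orders the medoids by a greedy nearest-neighbor
traversal of that matrix (ties to the lowest index), starting by default
from the most-populated cluster's medoid — a reproducible choice; no
canonical start exists. Each medoid is superposed onto its predecessor to
suppress rigid-body drift, and `max(min_frames, ⌈frames_per_Å · d⌉)`
linearly interpolated frames are inserted between successive medoids at
uniform fractions (defaults: 10 frames per Å, minimum 1 for d > 0, none
for d = 0). Morph frames are geometric, not kinetic: outputs are indexed
by frame, never by time. Cα RMSF is computed per residue after two
rounds of align-to-the-iterated-mean over the backbone heavy atoms;
residues lacking a Cα are excluded with a warning.

## Hydrogen-bond networks

Donors are N/O atoms with at least one hydrogen within a covalent
assignment distance (1.2 Å) in the reference frame; acceptors are all N/O
atoms, which lets heme propionates and the substrate carboxylate
participate under the same rules. A bond is present in a frame when the
donor–acceptor heavy-atom distance is ≤ 3.0 Å and the D–H–A angle deviates
from linearity by ≤ 20° — i.e. the cutoff is on the deviation, the
convention of the standard trajectory-analysis tooling for this quantity,
and the distance is heavy-atom to heavy-atom, not H–A. Intra-residue bonds
are excluded by default. Occupancy is the fraction of frames in which a
residue pair shows at least one satisfying triad; it can be computed over a
pseudotrajectory (mirroring a medoid-based pipeline) or over raw ensemble
frames (the statistically conventional option) — both are exposed because
either reading of "frames" is defensible. The differential network between
two conditions keeps pairs with |Δoccupancy| ≥ 0.25 (configurable; a
quarter-occupancy switch is a conservative reporting bar), treats pairs
absent from one table as occupancy 0, and exports a plain edge table.

## Substrate-positioning coupling

Two descriptors summarize substrate positioning per frame: the heme-iron to
substrate-Cβ distance and the Cα–Cβ–Fe angle (vertex at Cβ). Each is
standardized (z-scored, population sd) over the frames of one condition —
standardizing within condition keeps the between-temperature contrast out
of the score itself — and combined as an equal-weight mean by default.
Equal weights are the minimal-assumption combination; the weights are a
parameter precisely because no unique functional form is canonical here.
The coupling profile is the per-residue Pearson correlation between the
frame-wise Cα displacement magnitude (from the ensemble-mean position, on
an aligned ensemble) and the combined z series; per-frame heavy-atom
residue RMSD is a drop-in alternative statistic. Constant descriptor
series raise a degenerate-series error rather than returning silent zeros.

## Surface composition

SASA uses Shrake–Rupley sphere-point quadrature with a deterministic
Fibonacci-lattice point set (default 960 points, probe 1.4 Å) over
Bondi-style van der Waals radii (override table and fallback radius
configurable; an unknown element without a fallback raises). Surface
residues are those whose summed SASA exceeds 2.5 Å², the threshold
convention of the widely used surface-residue scripts this mirrors. The
census counts R/D/E/H/K over the whole protein and over the surface
subset; histidine is included in the positive total but also reported
separately, since its charge is pH-dependent. Note that the quadrature's
*fraction* converges at 1/n_points resolution, so convergence is assessed
against the atom's sphere area — the relative error of a near-zero
accessible area is unbounded for any point quadrature.

## Spectroscopy fits

Three nonlinear models, all fitted by bounded least squares with three
data-driven starts (biexponential fits are initialization-sensitive) and
Jacobian-based standard errors:

* Morrison's quadratic tight-binding equation
  `ΔA(S) = ΔA_max[(E+S+K_d) − √((E+S+K_d)² − 4ES)]/(2E)` for difference
  titrations where enzyme and ligand concentrations are comparable to K_d;
  it reduces to the hyperbola `ΔA_max·S/(S+K_d)` when E ≪ K_d.
* A Boltzmann sigmoid `lower + (upper−lower)/(1+exp((T_m−T)/slope))` for
  thermal melts, T_m at the half-transition and constrained inside the
  scanned range.
* A two-summed-exponential decay `offset + A₁e^(−k₁t) + A₂e^(−k₂t)` for
  stopped-flow traces, reported fast-first; time zero is the first sample
  (no dead-time model), amplitudes may carry either sign, and rates
  collapsing within 1% trigger a warning suggesting a single-exponential
  model. The kinetic isotope effect is the plain ratio k_H/k_D, reported
  raw and rounded.

## What the synthetic data does and does not emulate

Every generator takes a mandatory seed, draws from a single stream, and
returns its ground truth with the data; recovery tests never re-derive
truth from the data. The generators reproduce the *statistical shapes* the
pipeline consumes: low-rank Gaussian covariance modes with strictly
decreasing amplitudes (so PC order is unambiguous); metastable states as
Gaussian clouds around centers planted along orthonormal collective
directions, with `separation` defined on the Cartesian-RMSD (per-atom Å)
scale — the same units as the within-state spread, so a "10× separation"
means the same thing at any atom count — and an `overlap_factor` that
collapses or spreads the centers about their centroid; hydrogen bonds as
independent per-frame Bernoulli switches between a geometry satisfying the
cutoffs and one violating them; substrate coupling as a shared latent
variable driving both geometry descriptors linearly and the coupled
residue's Cα displacement *magnitude* (isotropic direction,
magnitude = base + scale·(ρ·latent + √(1−ρ²)·noise)) — the magnitude is
driven directly because a signed 1-D displacement folds at the ensemble
mean and cannot realize a planted correlation with the score.

They do not emulate force-field physics: no bonded structure beyond the
planted geometry, no solvent, no kinetics (frame order is exchangeable),
no anisotropic or correlated thermal noise, and temperature enters only as
a label selecting planted parameters. Passing tests therefore demonstrate
that the estimators recover what they are defined to estimate under
controlled conditions — not that a particular enzyme behaves any
particular way in real dynamics.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small instances chosen to make
the statistical guarantees sharp: 5–12-residue toy chains, 100–200 frames
per state or condition, 5000 frames for eigenvalue recovery (5%
tolerance), 2000 frames for coupling recovery (|bias| < 0.05 over five
seeds), 200 frames per condition for occupancy recovery (binomial 99%
bounds), 960 quadrature points for SASA (1% against the analytic sphere).
Degenerate inputs fail loudly: zero-variance PCA warns and retains zero
components, empty selections raise, a constant descriptor series raises,
all-noise clusterings refuse medoid search.

## Known limitations

* PCA is linear and pooled-centered; time-lagged or kernel analyses are
  out of scope, as is any Markov-state or kinetic modelling on top of the
  clustering.
* H-bond detection is geometric only — no energetic scoring, no
  water-mediated bridges — and occupancy over a morph pseudotrajectory is
  a structural summary, not an equilibrium population.
* The medoid RMSD matrix is quadratic in cluster size; clusters of tens of
  thousands of frames would need subsampling.
* The charged-residue census trusts standard 3-letter residue names and
  does not assign protonation states.
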
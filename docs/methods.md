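# Methods

This note documents the models, conventions and design choices behind
`pkatraj`, in the spirit of a methods section: what each stage computes, the
parameters that matter, and what the synthetic test bed does and does not
establish about real data.

## Scope and model

`pkatraj` is an orchestration-and-analysis layer over per-structure pKa
predictors. The predictors' energy models are not re-derived: PROPKA and
pKAI are invoked through their published Python entry points, and their
output is parsed, never emulated. Consequently everything downstream treats
pKa values as an opaque per-residue, per-frame scalar plus, for PROPKA, a
buried ratio in [0, 100] %. The package does not replace constant-pH MD:
frames from conventional MD reflect fixed protonation states, and the
analyses here flag where that assumption is under strain rather than
resample under it.

## Trajectory handling

Ensembles are loaded with MDAnalysis (PDB/GRO/PSF topologies; multi-model
PDB, DCD, XTC, TRR trajectories). Frames are sampled with a stride; the
snapshot retains the original (unstrided) frame index. Frame time is taken
as `frame_index x timestep_ps` when the user supplies a timestep, else from
trajectory metadata, else the bare frame index — PDB-format trajectories
carry no time, so supplying `timestep_ps` is recommended there. By default
only protein atoms are passed to the engines (waters and ions are stripped;
`selection="all"` keeps them).

Snapshots destined for file-based engines are written as single-model PDB
files with a fixed-column writer (coordinates at 3 decimals) and deleted
immediately after the engine's output is parsed. Coordinates are therefore
trusted only to PDB precision, and all round-trip equality in the test suite
is defined at 3 decimals (2 decimals for B-factor-encoded values).

Residue names are normalized to the vocabulary the engines recognize before
prediction: ASH→ASP, GLH→GLU, HID/HIE/HIP/HSD/HSE/HSP→HIS, CYX/CYM→CYS,
LYN→LYS, ARN→ARG, TYM→TYR; caps (ACE, NME/NMA) pass through; unknown names
are logged and passed through unchanged. The mapping covers the AMBER and
CHARMM protonation-variant names; it is idempotent and touches no
coordinates.

## Parallel structure and determinism

Frames are partitioned into contiguous near-equal worker ranges (earlier
workers absorb the remainder; surplus workers receive empty ranges).
Contiguous blocks rather than round-robin keep trajectory locality per
worker and make the merge a plain sort. Ranges are processed sequentially
in-process by default; `parallel=True` dispatches them to a process pool in
which each worker re-opens the ensemble from its paths. Both paths feed the
same merge (sorted by snapshot time, duplicate frame indices rejected), so
the output tables are identical for any worker count — this invariance is
asserted byte-for-byte on the CSV serialization in the test suite. Frames on
which the engine fails are logged and listed in a failure manifest rather
than silently dropped, so gaps in the time axis are always explainable; a
run in which every frame fails is an error.

## The mock engine

Tests and examples need an engine that is deterministic, instantaneous and
analytically transparent. The built-in mock predicts, for each ionizable
residue *i*,

    pKa_i = model(resname_i) + 0.1 * d_i
    buried_i = 100 * max(0, 1 - d_i / 20)   (clamped to [0, 100])

where `d_i` (Å) is the distance from residue *i*'s heavy-atom centroid to
the structure's **backbone** heavy-atom centroid (atoms N, CA, C, O, OXT),
and `model()` is a configurable table of typical solution reference values
(ASP 3.80, GLU 4.50, HIS 6.50, CYS 9.00, TYR 10.00, LYS 10.50, ARG 12.50).
The backbone is chosen as the reference frame deliberately: it is invariant
both to rigid translation of the structure and to alanine pseudo-mutations
(which only remove side-chain atoms), so the mock prediction for residue *i*
depends only on residue *i*'s own geometry. That property is what lets the
test suite assert *exact* invariance of non-mutated residues' pKa series
under pseudo-mutation, separating plumbing errors from engine behaviour.
The mock is a test oracle, not a predictor; real engines supply their own
model pKa values, which are parsed from their output and never hardcoded.

## Pseudo-mutation

A pseudo-mutation truncates the target residue to the alanine atom set —
N, CA, C, O, CB, plus OXT on a C-terminal residue (a backbone atom whose
removal would alter the terminus chemistry) and hydrogens bonded to kept
heavy atoms (backbone H, HA, HB*) — renames it ALA, and leaves every other
atom bit-identical. Glycine targets are rejected (no CB); proline is allowed
(ring atoms removed under the same rule). No CB reconstruction or
minimization is performed: the feature is a coordinate-preserving probe of a
neighbour's contribution to pKa shifts in the wild-type ensemble, not a
mutant pKa estimate, which would require sampling the mutant ensemble.
Comparing wild-type and pseudo-mutant profiles reports the per-frame ΔpKa,
its mean (the shift) and the ratio sd(mutant)/sd(wild) (shape modulation: a
neighbour that intermittently hydrogen-bonds the target damps or amplifies
fluctuations, not just the mean).

## Time-series analyses

- **Running average**: centered moving mean over an odd window (even window
  sizes are rounded up); edge windows shrink so output length equals input
  length. Time-based windows (e.g. 5 ns) are converted to frames with the
  ensemble timestep.
- **Summaries**: population standard deviation (a single frame has sd 0);
  `delta_from_model` uses the engine-reported model value.
- **Histograms**: left-closed, right-open bins aligned at integer multiples
  of the bin width (default 0.1 pKa units), so counts are reproducible and
  always sum to the non-missing frame count.
- **Correlation scan**: Pearson by default, Spearman optional; coefficients
  are kept signed and ranked by absolute value; zero-variance series yield a
  missing coefficient, never 0. Property series (typically PC projections,
  which are user input — the package computes no trajectory PCA) are matched
  to frames by row order when lengths agree, else by nearest time within
  half a timestep, since projection files from common tools carry no time
  column.
- **Protonation-sensitivity flags**: default window pH 7.4 ± 1.0 pKa unit;
  ±1 unit corresponds to roughly 10–90 % protonated, i.e. the range where
  both states have significant populations.
- **Cross-replica averaging**: the unweighted mean of per-replica means;
  residues absent from some replicas are averaged over the replicas that
  report them and flagged.

## Environment clustering

Feature columns are pKa values of selected residues, optionally their buried
ratios, and inter-residue distances. Distances are the **minimum heavy-atom
distance** between the two residues (not centroid distance), because contact
formation — e.g. a salt bridge between an acidic and a basic side chain — is
the environmental change that shifts pKa. Frames with any missing value are
dropped with a log entry.

Features are Z-scored per column (population sd; constant columns dropped
with a warning) and optionally PCA-reduced, either to a fixed component
count or to the smallest count reaching a cumulative explained-variance
fraction. Distances between frames are Euclidean in this normalized space
for all methods, Z-scoring having made the features commensurate.

Four algorithms are exposed:

- **k-medoids** (implemented in-package): seeded multi-restart alternating
  assignment/update on the precomputed distance matrix; the update step
  places each medoid at the within-cluster summed-distance minimizer, so
  converged representatives are exactly medoid-optimal (verified by
  exhaustive search in the tests). Deterministic for a fixed seed.
- **greedy**: the leader algorithm — frames scanned in time order join the
  first cluster whose leader lies within a cutoff, else found a new cluster.
  The cutoff is the single hyperparameter exposed to the grid search; the
  leader frame is the cluster representative.
- **DBSCAN** and **HDBSCAN** (scikit-learn): noise frames get label −1; the
  representative is the frame nearest the cluster's feature-space mean.

Quality is the mean silhouette width over non-noise frames (undefined —
NaN — with fewer than two clusters). Grid search evaluates every point,
returns the silhouette maximizer, breaks ties by fewer clusters then grid
order, ranks results with more than 50 % noise below any non-degenerate
result, and errors with per-point detail when every point is degenerate.
Cross-replica clustering concatenates per-replica feature matrices with
(replica, frame) provenance so representatives map back to the right
trajectory.

## Structure mapping

Per-residue scalars (single-frame pKa, trajectory mean, Δ from model,
buried ratio) are written into the B-factor column of an annotated PDB —
the same value on every atom of the residue; residues without a value get a
fill (the value-range midpoint by default, neutral under a symmetric
spectrum) — together with a plain-text PyMOL-style command script that
applies a blue–white–red spectrum anchored at the data range and centered at
0 for delta maps. The annotated-PDB + script route was chosen over writing
binary viewer sessions: it is portable, diffable, and testable (the tests
parse the B-factors back and require 2-decimal agreement). Values with
|v| ≥ 1000 do not fit the column and are rejected.

## Synthetic test bed

The generators make every analysis testable without external data:

- **Peptides**: extended chain, consecutive CA atoms 3.8 Å apart along x,
  template side-chain heavy atoms, OXT on the C-terminus. Idealized rather
  than folded geometry — engines need parseable, sterically sane input, and
  realism is not what the plumbing tests probe.
- **Trajectories**: frame *k* displaces each atom by
  `amplitude * sin(2πk/n)` along a fixed per-atom random unit vector drawn
  from the seed; written as multi-model PDB. Coherent sinusoidal motion
  (rather than white noise) gives the mock engine's pKa series a periodic
  structure that correlation and clustering tests can exploit. Default
  timestep 100 ps, a typical sampling interval for trajectory pKa tracking.
- **Gaussian blobs**: isotropic unit-variance clusters whose centers sit
  `separation_sd` standard deviations from the origin along distinct
  coordinate axes. With the default 10-sd separation in 3 features this
  yields ARI 1.0 and mean silhouette ≈ 0.84 at k = 3 — note that a *minimum
  pairwise* separation of 10 sd would cap the silhouette near 0.78
  regardless of algorithm, which is why the axis placement is part of the
  fixture's definition. The blobs are drawn directly in normalized feature
  space (unit variance, commensurate axes) and are marked normalized:
  re-Z-scoring them would fold the center offsets into the column sd and
  shrink the designed separation.
- **Engine-output fixtures**: text documents in the empirical engine's
  layout (per-group detail section with the buried %, summary section with
  pKa and model pKa), authored from given entries so the parser can be
  tested by exact round-trip.

Passing tests on this bed demonstrates correct orchestration, bookkeeping
and numerics — worker invariance, coordinate conservation, exact parsing,
label recovery. It does not validate predictive accuracy on real proteins,
which is the engines' responsibility, nor does it exercise engine
idiosyncrasies such as residue renumbering or chain merging (the adapter
maps groups back by (resname, resid, chain) and flags what it cannot map).

## Numerical conventions and problem sizes

Population (ddof = 0) standard deviations throughout; Z-score constant-column
threshold sd ≤ 1e−12; z-scored columns standardized to within 1e−10;
full-rank PCA conserves total variance to 1e−8; argmin ties resolve to the
lowest index, making every clustering deterministic for a fixed seed. The
test suite and the acceptance script run on 10–20-frame peptide ensembles,
90-frame blob fixtures and n = 1000 correlation series — sizes chosen so the
properties under test (invariances, exact round-trips, recovery of designed
structure) are already fully expressed while the whole suite runs in
seconds.

## Known limitations

- No trajectory alignment, imaging or solvent handling (assumed done
  upstream); no velocities or box information.
- Only alanine pseudo-mutations; no rotamer building or ΔΔG estimation.
- pKAI reports no model pKa or buried ratio; delta-from-model maps and
  buried features require PROPKA (or the mock).
- Correlation scanning reports coefficients without significance testing;
  with ~10³ correlated frames per trajectory, treat moderate coefficients as
  hypotheses, not findings.
- The greedy method's clustering depends on frame order by construction;
  it is the cheapest method, not the most stable one.
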
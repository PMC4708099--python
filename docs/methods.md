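# Methods

## The model

`hnmmc` simulates the detachment of a short peptide from a class-I-MHC-like
binding groove with a coarse-grained Metropolis Monte Carlo scheme built
from three ingredients.

**Three-point residue representation.** Every amino acid is reduced to an
alpha-carbon bead (CA), a carbonyl-oxygen bead (O), and — except for
glycine — a side-chain bead (SC) placed at the unweighted centroid of the
side-chain heavy atoms (Cβ and beyond). "Centre of the side chain" admits
several weightings; the unweighted heavy-atom centroid is the simplest
reading and is what `coarse_grain_structure` computes. Internal units are
nanometres and Kelvin throughout; PDB Ångströms are converted on read and
back on write.

**Knowledge-based pair potential with short-range damping.** Nonbonded
energy is a sum over bead pairs of a distance-binned table value (bin width
0.05 nm, cutoff 1.5 nm by default; half-open bins, so a pair exactly at the
cutoff scores zero) multiplied by the scaling function

    s(r) = s0 + (1 − s0)(r/r0)^6   for r < r0,   s(r) = 1 otherwise,

with r0 = 0.7 nm (roughly the diameter of a large amino acid) and
s0 = 0.15. The damping keeps coarse-grained beads from locking into
unphysically deep short-range minima, so bound peptides can escape; beyond
0.7 nm the table is used untouched. Energies are dimensionless multiples of
k_B·T_ref with T_ref = 300 K — statistical potentials carry no absolute
scale — so the Metropolis factor at temperature T is exp(−ΔE·T_ref/T).
Pairs within the same chain closer than 3 residues in sequence
(|i−j| ≤ 2, including intra-residue pairs) are excluded, the usual
coarse-grained convention. The numerical content of a production table is
an input artifact: the package ships a neutral default (flat with a
repulsive core) plus a round-trip-exact plain-text format for user tables;
all science-facing tests run on Gō-style tables whose ground truth is known
by construction.

**Hierarchical natural moves.** Degrees of freedom are rigid-body
translations and rotations (3 + 3 per node) of a tree of residue regions.
The default pMHC decomposition gives seven receptor nodes — the β-sheet
floor, and for each groove helix two kink-broken halves nested under a
whole-helix super-region — plus peptide thirds (1–3/4–6/7–9 for a 9-mer)
under a whole-peptide super-region. The kink residues are conserved but
structure-specific, so they are configuration inputs, not constants; the
same applies to the peptide sub-region boundaries. The α3 domain and
β2-microglobulin, when present, stay in the energy sum but belong to no
movable node.

Each step draws a node (uniformly by default; weights are configurable),
proposes a translation uniform in [−t_max, t_max]³ and a rotation about a
uniformly random axis with angle uniform in [−θ_max, θ_max] about the
node's CA centroid — a symmetric proposal, so plain Metropolis acceptance
preserves detailed balance at fixed temperature. Default amplitudes are
t_max = 0.05 nm and θ_max = 5° per node (the whole-peptide node gets a
configurable multiple; see "Fixture calibration").

**Chain closure.** A rigid region move breaks the chain at the region
boundaries. The closure restores every broken CA–CA virtual bond to within
0.02 nm of its pre-move length by cyclic coordinate descent: residues in a
closure zone (3 residues on the moved side of each break) are rotated
about CA–CA virtual-bond axes, with the optimal angle per axis solved in
closed form on the circle traced by the break-side CA. O and SC beads ride
with their residue frames. The smaller-magnitude root is always chosen, so
closure is deterministic. Moves whose closure does not converge within the
sweep limit are rejected outright, and a per-step sanity band of
[0.2, 0.6] nm on all affected virtual bonds rejects any move that would
accumulate geometric drift. Because the closure zone lies inside the moved
region, the set of displaced beads is exactly the region's beads, which
keeps the incremental (node-level) energy bookkeeping exact; a periodic
resync against the full sum (every 2000 steps) guards it at 1e-6 relative
tolerance and raises on violation.

**Periodic simulated annealing.** Temperature follows

    T(k) = s_T + (A/2)(1 + cos(2πk/Ω)),

with defaults A = 600 K, Ω = 5000 steps, s_T = 0 K over 100 000 steps:
repeated heating to 600 K (to escape minima) and quenching to the shift
temperature (to settle into them). The cosine form satisfies the defining
constraints of the protocol — period Ω, minimum s_T, maximum s_T + A — and
is isolated behind `AnnealSchedule` so alternative periodic forms can be
swapped without touching the sampler. With energies in k_B·T_ref units,
T = 300 K corresponds to β = 1.

**Replicas.** Detachment is stochastic, so each system is repeated with
seeds base_seed + i; replica i is bit-reproducible given its seed and
independent of execution order.

## Trajectory analytics

Three CA–CA probe distances monitor the peptide: N-terminal end, middle,
and C-terminal end of the peptide, each against a matched floor residue
(for HLA-A*02:01-like numbering: peptide 1–receptor 99, 5–28, 9–117).
Distances above 3 nm mean full detachment and are clamped to 3 nm.
Per-peptide curves report the mean and SEM (sample SD/√n; undefined for a
single replica) across replicas at each snapshot.

The **detachment score** of a peptide is the mean clamped distance over
all three probes, all snapshots and all replicas; whether to restrict to a
probe subset or a step window is exposed as an option, since "average
distance" admits both readings. Higher scores mean faster or fuller
detachment, so the ROC analysis takes the non-binder as the positive
class; the AROC is computed in its Mann–Whitney rank form with ties
counted 1/2, and affinity correlations use the product-moment coefficient
on log10 IC50 by default (the transform is a configurable choice). When
only IC50 values are given, class labels use a configurable 500 nM
threshold.

**Pathway classes.** Per probe, the detachment time is the first snapshot
from which the clamped distance exceeds a threshold (default 2.0 nm) for a
persistence window (default 10 snapshots). The class cascade is: stable
(no probe detaches); C-first / N-first (one end leads the other by more
than a tie margin, default 5 snapshots, without trailing the middle by
more than the margin); simultaneous-ends (end times within the margin);
middle-first (the middle leads both ends by more than the margin);
ends-inward otherwise. These thresholds are package defaults — the classes
are defined geometrically, not by any printed cutoffs. The margin exists
because the bound pose is bent: the middle probe starts ~0.2 nm further
from the floor than the ends, so during a whole-body exit it crosses any
absolute threshold slightly earlier without the middle having "detached
first" in any mechanistic sense.

**Replica-count bootstrap.** For each n, draw n replicas per peptide with
replacement, average their per-replica scores, compute the AROC over
peptides, repeat B times (default 5000), and report the SD of the B AROC
values. The SD is non-increasing in n in expectation (variance of a mean);
the packaged study asserts a strict decrease over n = 1, 25, 100.

## Synthetic fixtures and what they do (not) show

`make_toy_complex` builds a serpentine receptor chain — two "helix" rails
flanking a floor strip — with a 9-mer peptide bent along the groove (ends
~0.2 nm closer to the floor than the middle, as in crystal structures).
Strands carry a 0.06 nm transverse zigzag: perfectly collinear strands
would put every downstream CA on each virtual-bond axis and leave the CCD
closure with no usable degrees of freedom, a degeneracy no real backbone
has. `make_go_potential` rewards only the native contacts of the initial
pose: peptide–receptor SC–SC contacts within 0.5 nm get a background well
(anchor positions a deeper one), receptor–receptor CA–CA contacts get
strong wells that hold the fold, and every pair has a repulsive core below
0.2 nm.

Fixture calibration, chosen once for the packaged study conditions
(20 replicas × 20 000 steps, snapshot stride 100, default annealing):
background depth −1.2 and anchor depth −15 k_B·T_ref, well outer edge
0.6 nm, whole-peptide move amplitudes 3× the per-node default, and a
pathway tie margin of 15 snapshots for the fixture suite (the 200-snapshot
runs scale the middle probe's bent-pose head start to ~10 snapshots, which
the 5-snapshot default cannot absorb). Under these conditions the
anchor-free toy detaches end-first or from both ends in the majority of
replicas, the two-anchor toy stays majority-stable, and a single anchor at
position 2 biases detachment C-first.

The synthetic replica generator (`make_synthetic_replicas`) emulates only
the *statistical shape* of trajectories: binders fluctuate about the bound
baselines (1.08/1.31/1.09 nm), non-binders rise logistically to the 3 nm
ceiling with per-replica jittered midpoints plus Gaussian noise
(SD 0.15–0.2 nm). The two-class study behind the bootstrap check uses
per-peptide midpoints drawn from overlapping ranges (binders
0.85–1.7 × n_steps, clipped; non-binders 0.35–1.0 × n_steps; jitter 80
snapshots) so that class separation is good but imperfect and the AROC is
genuinely noisy at small replica counts. Passing tests on these fixtures
demonstrate the correctness of the machinery — energies, closure,
sampling calibration, statistics — not the thermodynamic realism of any
real peptide–MHC pair: the fixtures have no solvent, no sequence-specific
potential, and desk-scale sizes (36-residue receptor, 10³–10⁶ steps).

A deliberately minimal fixture, the radial two-well system
(`make_two_well_system`), checks the sampler against an exact oracle: one
mobile bead in a piecewise-constant radial potential (deep well, barrier,
shallow well, shelf, impassable walls) whose equilibrium shell occupancies
follow in closed form from Boltzmann weights times shell volumes. The
fixed-T = 300 K sampler must reproduce the well occupancy ratio within
3 batch-mean standard errors over 10⁶ steps.

## Numerical choices and edge cases

- Distance bins are half-open `[k·w, (k+1)·w)`; r exactly at the cutoff
  scores 0. Bin lookup uses `floor(r/w)`.
- Altloc ambiguity in PDB input resolves to the highest occupancy (logged);
  residues with no side-chain heavy atoms are treated as glycine (logged);
  a missing CA or O is a hard error naming chain and residue.
- Residue numbering gaps (missing loops) suspend the virtual-bond sanity
  check across the gap; insertion codes are tolerated on read.
- Threading a sequence onto a template keeps the backbone fixed, keeps SC
  beads of unchanged residue types bit-identical, repositions changed SC
  beads along the template CA→SC direction at a packaged canonical CA–SC
  distance per residue type, and drops the SC bead for glycine. A residue
  gaining a side chain where the template had none points it away from the
  local backbone axis.
- Proposals at zero amplitude are exact identities; `n_steps = 0` returns
  only the initial snapshot; T = 0 rejects every uphill move.
- The bootstrap, replica seeds and every stochastic fixture take a single
  integer seed and are bit-reproducible on one platform.

## Known limitations

- The closure is deterministic CCD over virtual bonds; it makes no attempt
  to sample closure solutions, so the move set is symmetric but not
  ergodic over ring-closure degrees of freedom.
- Node-level proposals are uniform over nodes; no adaptive amplitudes.
- The neutral default potential is a placeholder for a real knowledge-based
  table, which must be supplied by the user in the documented format.
- All-pairs energy evaluation scales O(n²); fine for grooves and desk-scale
  fixtures, not for large complexes.
- No solvent, electrostatics, replica exchange, or biased forces.
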
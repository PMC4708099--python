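"""Download-free synthetic test systems.

Three generators:

* :func:`make_toy_complex` — a desk-scale groove-peptide complex: two
  "helix" rails flanking a floor strip (one serpentine receptor chain) with
  a 9-mer peptide lying in the groove in the slightly bent pose seen in
  crystal structures (ends closer to the floor than the middle).
* :func:`make_go_potential` — a Go-style native-contact pair potential over
  per-bead unique types: attractive wells only for peptide-receptor SC-SC
  contacts of the initial pose (anchor positions deeper than background)
  plus strong receptor-receptor wells that hold the fold together.  Because
  anchor strength is dialled explicitly, binder/non-binder ground truth is
  known by construction.
* :func:`make_synthetic_replicas` — replica distance data with the
  statistical shape the analysis stage assumes: binders fluctuate around a
  bound baseline, non-binders rise logistically to the 3 nm detachment
  ceiling with per-replica jittered midpoints.

These fixtures exercise contracts; they make no claim of thermodynamic
realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import ProbeSet, ReplicaSet
from .forcefield import PairPotential
from .model import BeadStructure, StructureError, build_pmhc_hierarchy

RECEPTOR_CHAIN = "M"
PEPTIDE_CHAIN = "P"

# default bound-pose probe baselines (nm): N-end, middle, C-end of a 9-mer
DEFAULT_BASELINES = (1.08, 1.31, 1.09)


@dataclass(frozen=True)
class ToySpec:
    """Geometry and energetics of the toy groove-peptide complex."""

    groove_length: int = 12  # residues per helix rail
    floor_width: int = 1  # parallel floor strands
    peptide_length: int = 9
    spacing: float = 0.38  # CA-CA bead spacing along a strand, nm
    anchor_positions: tuple = (2, 9)  # 1-based peptide positions
    anchor_depth: float = -15.0  # k_B*T_ref units
    background_depth: float = -1.2
    seed: int = 0

    def __post_init__(self):
        if self.peptide_length < 3:
            raise StructureError("peptide length must be >= 3")
        for p in self.anchor_positions:
            if not (1 <= p <= self.peptide_length):
                raise StructureError(f"anchor position {p} outside peptide")
        if self.anchor_depth > 0 or self.background_depth > 0:
            raise StructureError("well depths must be <= 0")
        if self.groove_length < 4:
            raise StructureError("groove length must be >= 4")


@dataclass(frozen=True)
class SyntheticReplicaSpec:
    """Shape of synthetic replica probe-distance trajectories."""

    binding_class: str = "binder"  # "binder" | "non_binder"
    n_replicas: int = 100
    n_steps: int = 200
    midpoint: float = 80.0  # logistic detachment midpoint, snapshots
    slope: float = 12.0  # logistic width, snapshots
    midpoint_jitter: float = 30.0  # per-replica uniform jitter half-width
    noise_sd: float = 0.15  # nm
    baselines: tuple = DEFAULT_BASELINES
    ceiling: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.binding_class not in ("binder", "non_binder"):
            raise ValueError(f"unknown class {self.binding_class!r}")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not (0 <= self.midpoint <= self.n_steps):
            raise ValueError("midpoint must lie within [0, n_steps]")


# ----------------------------------------------------------------------
# toy complex
# ----------------------------------------------------------------------

MIN_BEAD_SEPARATION = 0.2  # nm, between beads of different residues


def make_toy_complex(spec=ToySpec()):
    """Build the toy groove-peptide complex.

    Returns ``(structure, hierarchy, probes)``.  The receptor is one
    serpentine chain: rail 1 (+x at y=+0.42), floor strip(s) (-x at y~0),
    rail 2 (+x at y=-0.42), so consecutive CA-CA distances stay inside the
    virtual-bond band.  The hierarchy mirrors the pMHC decomposition
    (7 receptor nodes, peptide thirds + whole peptide).  Probes connect
    peptide residues 1, ceil(L/2), L to the nearest floor residues.
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(10):
        jitter = 0.0 if attempt == 0 else 0.01
        structure, probes = _build_toy_geometry(spec, rng, jitter)
        if _min_inter_residue_distance(structure) >= MIN_BEAD_SEPARATION:
            break
    else:
        raise StructureError("could not place toy beads >= 0.2 nm apart")

    G = spec.groove_length
    W = max(1, spec.floor_width)
    config = {
        "mhc_chain": RECEPTOR_CHAIN,
        "peptide_chain": PEPTIDE_CHAIN,
        "helix1_range": (1, G),
        "helix1_kink": 1 + G // 2,
        "helix2_range": (G + W * G + 1, G + W * G + G),
        "helix2_kink": G + W * G + 1 + G // 2,
        # the peptide needs enough whole-body mobility to leave the groove
        # within desk-scale step counts
        "peptide_amplitude_scale": 3.0,
    }
    hierarchy = build_pmhc_hierarchy(structure, config)
    return structure, hierarchy, probes


def _build_toy_geometry(spec, rng, jitter):
    G = spec.groove_length
    W = max(1, spec.floor_width)
    L = spec.peptide_length
    a = spec.spacing
    # junction CA-CA bonds (rail end -> floor start) equal
    # sqrt(rail_y^2 + rail_z^2) exactly (the zigzags cancel at equal
    # parity) and need >= 0.02 nm headroom inside the [0.2, 0.6] nm band so
    # closure-restored bonds cannot drift out of it
    rail_y, rail_z = 0.42, 0.36
    strand_dy = 0.45
    o_offset = np.array([0.10, 0.10, 0.18])  # |CA-O| ~ 0.23 nm, off-plane
    sc = 0.15  # CA->SC offset magnitude

    # transverse zigzag: perfectly collinear strands would make rotations
    # about CA-CA virtual bonds degenerate (every downstream CA on the
    # axis), which no real backbone exhibits and which would starve the
    # chain-closure of usable degrees of freedom
    zig = 0.06

    def res(num, rtype, ca, sc_dir=None):
        ca = np.asarray(ca, dtype=float)
        if jitter:
            ca = ca + rng.normal(scale=jitter, size=3)
        o = ca + o_offset
        s = None if sc_dir is None else ca + np.asarray(sc_dir) * sc
        return (num, rtype, ca, o, s)

    receptor = []
    num = 1
    # rail 1: +x at y=+rail_y, SC pointing into the groove (-y)
    for i in range(G):
        receptor.append(res(num, "A",
                            (i * a, rail_y, rail_z + zig * (-1) ** i),
                            (0, -1, 0)))
        num += 1
    # floor strands: alternate -x / +x, ordered +y -> -y, to keep the
    # serpentine chain connected within the virtual-bond band
    for w in range(W):
        y = ((W - 1) / 2.0 - w) * strand_dy
        xs = range(G - 1, -1, -1) if w % 2 == 0 else range(G)
        for i in xs:
            receptor.append(res(num, "A", (i * a, y, zig * (-1) ** i),
                                (0, 0, 1)))
            num += 1
    # rail 2: +x at y=-rail_y
    first = G - 1 if W % 2 == 0 else 0
    xs = range(G) if first == 0 else range(G - 1, -1, -1)
    for i in xs:
        receptor.append(res(num, "A",
                            (i * a, -rail_y, rail_z + zig * (-1) ** i),
                            (0, 1, 0)))
        num += 1

    # peptide: along +x, centred over the floor, bent (ends ~0.2 nm lower)
    x0 = (G - L) / 2.0 * a
    peptide = []
    for j in range(L):
        frac = j / (L - 1)
        bend = 0.2 * np.sin(np.pi * frac)  # 0 at ends, 0.2 in the middle
        z = 0.52 + bend
        peptide.append(res(j + 1, "A",
                           (x0 + j * a, zig * (-1) ** j, z), (0, 0, -1)))

    structure = BeadStructure.from_chains(
        [(RECEPTOR_CHAIN, receptor), (PEPTIDE_CHAIN, peptide)])

    floor_start = G + 1
    floor_nums = list(range(floor_start, floor_start + W * G))
    floor_x = {n: structure.coords[structure.ca_index(RECEPTOR_CHAIN, n)][0]
               for n in floor_nums}

    def nearest_floor(pep_pos):
        px = structure.coords[structure.ca_index(PEPTIDE_CHAIN, pep_pos)][0]
        return min(floor_nums, key=lambda n: abs(floor_x[n] - px))

    mid = int(np.ceil(L / 2))
    probes = ProbeSet(
        peptide_chain=PEPTIDE_CHAIN, receptor_chain=RECEPTOR_CHAIN,
        n=(1, nearest_floor(1)), mid=(mid, nearest_floor(mid)),
        c=(L, nearest_floor(L)))
    return structure, probes


def _min_inter_residue_distance(structure):
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(structure.coords))
    same = (structure.bead_chain[:, None] == structure.bead_chain[None, :]) \
        & (structure.bead_res[:, None] == structure.bead_res[None, :])
    d[same] = np.inf
    return float(d.min())


# ----------------------------------------------------------------------
# Go-style potential
# ----------------------------------------------------------------------

def go_bead_types(structure):
    """Unique per-bead type labels used by Go tables."""
    return structure.bead_types(scheme="unique")


def make_go_potential(structure, spec=ToySpec(), bin_width=0.05, cutoff=1.5,
                      contact_cutoff=0.5, receptor_contact_cutoff=0.95,
                      receptor_depth=-10.0, core_radius=0.2,
                      core_energy=25.0, well_outer=0.6,
                      receptor_well_outer=1.0):
    """Native-contact pair potential for a toy complex.

    Wells exist only for contacts of the initial pose: peptide-receptor
    SC-SC pairs within ``contact_cutoff`` get the background depth (anchor
    positions the anchor depth); receptor-receptor CA-CA pairs within
    ``receptor_contact_cutoff`` get ``receptor_depth`` to keep the fold.
    Every type pair carries a repulsive excluded-volume core.  The table
    honours the standard potential format (per-bead unique types).
    """
    types = list(go_bead_types(structure))
    tmap = {t: i for i, t in enumerate(types)}
    n_bins = int(round(cutoff / bin_width))
    E = np.zeros((len(types), len(types), n_bins))
    core_bins = int(np.ceil(core_radius / bin_width))
    E[:, :, :core_bins] = core_energy

    coords = structure.coords
    kinds = structure.kinds
    chain = structure.bead_chain
    res = structure.bead_res
    pep_ci = structure.chain_index(PEPTIDE_CHAIN)
    rec_ci = structure.chain_index(RECEPTOR_CHAIN)
    anchors = {p - 1 for p in spec.anchor_positions}  # residue ordinals

    def well(ti, tj, depth, outer):
        lo_bin, hi_bin = core_bins, min(int(np.ceil(outer / bin_width)), n_bins)
        E[ti, tj, lo_bin:hi_bin] = depth
        E[tj, ti, lo_bin:hi_bin] = depth

    from .model import KIND_CA, KIND_SC
    bead_type_arr = go_bead_types(structure)

    pep_sc = np.nonzero((chain == pep_ci) & (kinds == KIND_SC))[0]
    rec_sc = np.nonzero((chain == rec_ci) & (kinds == KIND_SC))[0]
    for i in pep_sc:
        for j in rec_sc:
            r = np.linalg.norm(coords[i] - coords[j])
            if r < contact_cutoff:
                depth = spec.anchor_depth if int(res[i]) in anchors \
                    else spec.background_depth
                well(tmap[bead_type_arr[i]], tmap[bead_type_arr[j]],
                     depth, well_outer)

    rec_ca = np.nonzero((chain == rec_ci) & (kinds == KIND_CA))[0]
    for ii, i in enumerate(rec_ca):
        for j in rec_ca[ii + 1:]:
            if abs(int(res[i]) - int(res[j])) < 3:
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            if r < receptor_contact_cutoff:
                well(tmap[bead_type_arr[i]], tmap[bead_type_arr[j]],
                     receptor_depth, receptor_well_outer)

    return PairPotential(types, E, bin_width=bin_width)


# ----------------------------------------------------------------------
# two-well radial toy (Boltzmann calibration of the sampler)
# ----------------------------------------------------------------------

TWO_WELL_BINS = {
    # half-open bin-index ranges of the radial CA-CA potential
    "inner_wall": (0, 6, 60.0),     # r < 0.30 nm
    "well1": (6, 8, -2.0),          # 0.30 <= r < 0.40
    "barrier": (8, 12, 1.0),        # 0.40 <= r < 0.60
    "well2": (12, 14, -1.0),        # 0.60 <= r < 0.70
    "shelf": (14, 22, 0.0),         # 0.70 <= r < 1.10
    "outer_wall": (22, 30, 60.0),   # 1.10 <= r < 1.50
}


def make_two_well_system(bin_width=0.05):
    """A single mobile bead in a radial double-well around a fixed bead.

    Two single-residue chains: a fixed anchor ``F`` at the origin and a
    mobile probe ``W`` whose only move is a whole-chain translation
    (amplitude 0.1 nm, no rotation).  The CA-CA row of the table encodes a
    deep inner well, a barrier, a shallower outer well, a flat shelf and
    impassable walls on both sides (wall thickness exceeds the maximum step
    so the probe cannot tunnel out); all rows involving O beads are zero.
    With the scaling floor set to 1 the potential is exactly piecewise
    constant in r, so the equilibrium occupancy of any radial shell follows
    in closed form from Boltzmann weights times shell volumes — the oracle
    for detailed-balance checks of the sampler.

    Returns ``(structure, hierarchy, table, params)``; use
    :func:`two_well_expected_ratio` for the analytic well1/well2 ratio.
    """
    from .forcefield import ScalingParams
    from .model import HierarchyNode, Region, RegionHierarchy

    o_offset = np.array([0.1, 0.1, 0.18])
    structure = BeadStructure.from_chains([
        ("F", [(1, "G", np.zeros(3), o_offset, None)]),
        ("W", [(1, "G", np.array([0.65, 0.0, 0.0]),
                np.array([0.65, 0.0, 0.0]) + o_offset, None)]),
    ])
    hierarchy = RegionHierarchy([HierarchyNode(
        "probe", (Region("W", 1, 1, "probe"),), (),
        max_translation=0.1, max_rotation=0.0)])
    E = np.zeros((2, 2, 30))
    for lo, hi, energy in TWO_WELL_BINS.values():
        E[0, 0, lo:hi] = energy
    table = PairPotential(["CA", "O"], E, bin_width=bin_width)
    params = ScalingParams(s0=1.0, r0=0.7)  # disable short-range damping
    return structure, hierarchy, table, params


def two_well_expected_ratio(beta=1.0, bin_width=0.05):
    """Analytic equilibrium occupancy ratio P(well1)/P(well2)."""
    def weight(lo, hi, energy):
        r_lo, r_hi = lo * bin_width, hi * bin_width
        return np.exp(-beta * energy) * (r_hi ** 3 - r_lo ** 3)

    w1 = weight(*TWO_WELL_BINS["well1"])
    w2 = weight(*TWO_WELL_BINS["well2"])
    return w1 / w2


# ----------------------------------------------------------------------
# synthetic replica data
# ----------------------------------------------------------------------

def make_synthetic_replicas(spec=SyntheticReplicaSpec(), peptide_id=None):
    """Generate a ReplicaSet with the assumed binder/non-binder shapes.

    Binders: bound baseline + Gaussian noise, clamped to (0, ceiling].
    Non-binders: logistic rise from the baseline to the ceiling with a
    per-replica jittered midpoint, plus noise, clamped.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    steps = np.arange(spec.n_steps)
    base = np.asarray(spec.baselines)[None, None, :]  # (1, 1, 3)
    d = np.broadcast_to(base, (spec.n_replicas, spec.n_steps, 3)).copy()
    if spec.binding_class == "non_binder":
        mids = spec.midpoint + rng.uniform(-spec.midpoint_jitter,
                                           spec.midpoint_jitter,
                                           size=spec.n_replicas)
        rise = 1.0 / (1.0 + np.exp(-(steps[None, :] - mids[:, None])
                                   / max(spec.slope, 1e-9)))  # (R, S)
        d = d + (spec.ceiling - base) * rise[:, :, None]
    if spec.noise_sd > 0:
        d = d + rng.normal(scale=spec.noise_sd, size=d.shape)
    d = np.clip(d, 1e-6, spec.ceiling)
    if peptide_id is None:
        peptide_id = f"synthetic-{spec.binding_class}-{spec.seed}"
    return ReplicaSet(peptide_id=peptide_id, sequence="",
                      steps=steps, distances=d, ceiling=spec.ceiling)


def make_replica_study(n_binders=8, n_nonbinders=8, n_replicas=100,
                       n_steps=200, seed=0):
    """A two-class replica study with peptide-level heterogeneity.

    Binders get late (often past-the-end) detachment midpoints, non-binders
    mid-range midpoints, so per-peptide scores overlap across classes and
    the bootstrap AROC is genuinely noisy at small replica counts.
    Returns ``(replica_sets, labels)``.
    """
    rng = np.random.default_rng(seed)
    sets, labels = [], []
    for i in range(n_binders):
        # late (often past-the-end) midpoint => mostly bound, occasional
        # late partial detachment; label reflects ground truth
        mid = float(rng.uniform(0.85 * n_steps, 1.7 * n_steps))
        spec = SyntheticReplicaSpec(
            binding_class="non_binder", n_replicas=n_replicas,
            n_steps=n_steps, midpoint=min(mid, n_steps), slope=20.0,
            midpoint_jitter=80.0, noise_sd=0.2,
            seed=int(rng.integers(2**31)))
        sets.append(make_synthetic_replicas(spec, peptide_id=f"binder-{i}"))
        labels.append("binder")
    for i in range(n_nonbinders):
        mid = float(rng.uniform(0.35 * n_steps, 1.0 * n_steps))
        spec = SyntheticReplicaSpec(
            binding_class="non_binder", n_replicas=n_replicas,
            n_steps=n_steps, midpoint=mid, slope=20.0,
            midpoint_jitter=80.0, noise_sd=0.2,
            seed=int(rng.integers(2**31)))
        sets.append(make_synthetic_replicas(spec, peptide_id=f"non-binder-{i}"))
        labels.append("non-binder")
    return sets, labels
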
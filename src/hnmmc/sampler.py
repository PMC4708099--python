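"""Hierarchical natural-move Monte Carlo engine.

Each step picks one node of the region hierarchy, proposes a rigid-body
translation + rotation of its residues, repairs the chain breaks at the
region boundaries with a deterministic cyclic-coordinate-descent closure
about CA-CA virtual bonds, and applies a Metropolis test at the
step-dependent temperature of a periodic simulated-annealing schedule

    T(k) = s_T + (A/2) * (1 + cos(2*pi*k / Omega)),

whose defaults (A = 600 K, Omega = 5000 steps, s_T = 0 K, 100 000 steps)
repeatedly heat the system to 600 K and quench it to the shift temperature.
Energies are in k_B*T_ref units (T_ref = 300 K), so the acceptance factor is
exp(-dE * T_ref / T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import EnergyEvaluator, ScalingParams, T_REF
from .model import CA_CA_BAND

TWO_PI = 2.0 * math.pi


class SamplerError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# annealing schedule
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Periodic temperature modulation.

    amplitude : peak-to-trough amplitude A in Kelvin (default 600)
    period : steps per modulation period Omega (default 5000)
    shift : minimum temperature s_T in Kelvin (default 0)
    total_steps : default simulation length (default 100 000)
    """

    amplitude: float = 600.0
    period: int = 5000
    shift: float = 0.0
    total_steps: int = 100_000

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.period < 2:
            raise ValueError("period must be >= 2 steps")
        if self.shift < 0:
            raise ValueError("temperature shift must be >= 0")

    def temperature(self, k):
        return temperature_at(k, self)


def temperature_at(k, schedule):
    """Temperature (K) at MC step ``k``: periodic in ``k`` with period Omega,
    minimum ``shift``, maximum ``shift + amplitude``."""
    k = np.asarray(k, dtype=float)
    T = schedule.shift + 0.5 * schedule.amplitude * (
        1.0 + np.cos(TWO_PI * k / schedule.period))
    return float(T) if T.ndim == 0 else T


# ----------------------------------------------------------------------
# move proposals
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MoveProposal:
    """Rigid-body proposal for one hierarchy node."""

    node_index: int
    translation: np.ndarray  # (3,) nm
    axis: np.ndarray  # (3,) unit rotation axis
    angle_deg: float
    pivot: np.ndarray  # (3,) nm, centroid of the node's CA beads


def propose_region_move(state, node_index, rng):
    """Draw a symmetric rigid-body proposal for one node.

    Translation uniform in the cube [-t_max, t_max]^3; rotation axis uniform
    on the sphere; angle uniform in [-theta_max, theta_max]; pivot at the
    centroid of the node's CA beads.  Deterministic given the RNG state.
    """
    node = state.hierarchy.nodes[node_index]
    res = state.resolved[node_index]
    t = rng.uniform(-node.max_translation, node.max_translation, size=3)
    axis = _random_unit_vector(rng)
    angle = rng.uniform(-node.max_rotation, node.max_rotation)
    pivot = state.structure.coords[res["ca_idx"]].mean(axis=0)
    if node.max_translation == 0:
        t = np.zeros(3)
    if node.max_rotation == 0:
        angle = 0.0
    return MoveProposal(node_index, t, axis, angle, pivot)


def _random_unit_vector(rng):
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - astronomically rare
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def rotation_matrix(axis, angle_deg):
    """Right-handed rotation about a unit ``axis`` by ``angle_deg`` degrees."""
    a = math.radians(angle_deg)
    x, y, z = axis
    c, s, C = math.cos(a), math.sin(a), 1.0 - math.cos(a)
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def apply_move(structure, proposal, bead_idx=None):
    """Apply a rigid isometry to the proposal's node beads, in place.

    All other beads are untouched; pairwise distances inside the node are
    preserved exactly (up to floating point).  Returns the structure.
    """
    if bead_idx is None:
        raise ValueError("bead_idx (resolved node beads) is required")
    R = rotation_matrix(proposal.axis, proposal.angle_deg)
    pts = structure.coords[bead_idx]
    structure.coords[bead_idx] = (pts - proposal.pivot) @ R.T \
        + proposal.pivot + proposal.translation
    return structure


# ----------------------------------------------------------------------
# chain closure
# ----------------------------------------------------------------------

@dataclass
class ClosureResult:
    converged: bool
    residuals: dict = field(default_factory=dict)  # (chain_idx, bond_ord) -> nm


def close_chain(structure, spans, pre_move_bonds, zone=3, tolerance=0.02,
                max_sweeps=30):
    """Repair chain breaks at the boundaries of rigidly moved segments.

    ``spans`` are (chain_idx, lo_ord, hi_ord) residue-ordinal ranges of the
    moved node; ``pre_move_bonds`` maps (chain_idx, ord) -> CA-CA distance of
    the virtual bond between residues ord and ord+1 before the move.  The
    closure iteratively rotates up to ``zone`` residues on the moved side of
    each break about CA-CA virtual bonds (closed-form cyclic coordinate
    descent) until every broken bond is back within ``tolerance`` of its
    pre-move length.  O and SC beads ride with their residue frames.

    Whole-chain and terminal segments produce no breaks on the free side and
    are returned unchanged there.  Returns a :class:`ClosureResult`; a
    non-converged result must make the caller reject the move.
    """
    breaks = []  # (chain_idx, side, lo, hi) side: 'N' or 'C'
    for ci, lo, hi in spans:
        chain_len = len(structure.residue_numbers[ci])
        if lo > 0:
            breaks.append((ci, "N", lo, hi))
        if hi < chain_len - 1:
            breaks.append((ci, "C", lo, hi))
    result = ClosureResult(converged=True)
    if not breaks:
        return result

    for _ in range(max_sweeps):
        all_ok = True
        for ci, side, lo, hi in breaks:
            bond_ord = lo - 1 if side == "N" else hi
            d0 = pre_move_bonds[(ci, bond_ord)]
            resid = _close_one_break(structure, ci, side, lo, hi, d0,
                                     zone, tolerance)
            result.residuals[(ci, bond_ord)] = resid
            if resid > tolerance:
                all_ok = False
        if all_ok:
            return result
    result.converged = False
    return result


def _ca(structure, ci, ord_):
    return structure.coords[structure._ca_index[(ci, ord_)]]


def _norm3(v):
    return math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])


def _cross3(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _close_one_break(structure, ci, side, lo, hi, d0, zone, tolerance):
    """One CCD pass over the closure-zone virtual bonds of a single break."""
    if side == "N":
        anchor_ord, end_ord = lo - 1, lo
        axis_orders = range(min(lo + zone, hi), lo, -1)  # j: axis at CA(j)
    else:
        anchor_ord, end_ord = hi + 1, hi
        axis_orders = range(max(hi - zone, lo), hi)
    anchor = _ca(structure, ci, anchor_ord)

    resid = abs(_norm3(_ca(structure, ci, end_ord) - anchor) - d0)
    if resid <= tolerance:
        return resid

    for j in axis_orders:
        if side == "N":
            neighbor = j - 1  # bond axis along CA(j) -> CA(j-1)
            move_lo, move_hi = lo, j - 1
        else:
            neighbor = j + 1
            move_lo, move_hi = j + 1, hi
        origin = _ca(structure, ci, j).copy()
        direction = _ca(structure, ci, neighbor) - origin
        norm = _norm3(direction)
        if norm < 1e-9:
            continue
        u_bond = direction / norm
        # torsion-like rotation about the virtual bond first; if its circle
        # cannot reach the target, bend about the perpendicular axis
        # through the same joint (bond-angle-like degree of freedom)
        for u in (u_bond, None):
            p = _ca(structure, ci, end_ord)
            if u is None:
                perp = _cross3(u_bond, p - origin)
                pn = _norm3(perp)
                if pn < 1e-9:
                    continue
                u = perp / pn
            theta = _ccd_angle(p, origin, u, anchor, d0)
            if theta == 0.0:
                continue
            R = rotation_matrix(u, math.degrees(theta))
            idx = structure.beads_for_ordinals(ci, move_lo, move_hi)
            structure.coords[idx] = (structure.coords[idx] - origin) @ R.T \
                + origin
            resid = abs(_norm3(_ca(structure, ci, end_ord) - anchor) - d0)
            if resid <= tolerance:
                return resid
    return resid


def _ccd_angle(p, origin, u, anchor, d0):
    """Closed-form rotation angle about axis (origin, u) bringing |p-anchor|
    as close as possible to d0.  Returns the smaller-magnitude root."""
    v = p - origin
    z = float(v @ u)
    center = origin + z * u
    r_vec = p - center
    r = _norm3(r_vec)
    if r < 1e-12:
        return 0.0
    e1 = r_vec / r
    e2 = _cross3(u, e1)
    w = anchor - center
    A = float(w @ w) + r * r
    B = -2.0 * r * float(w @ e1)
    C = -2.0 * r * float(w @ e2)
    R = math.hypot(B, C)
    if R < 1e-15:
        return 0.0
    phi = math.atan2(C, B)
    c = (d0 * d0 - A) / R
    c = max(-1.0, min(1.0, c))
    delta = math.acos(c)
    cand = [_wrap_angle(phi + delta), _wrap_angle(phi - delta)]
    return min(cand, key=abs)


def _wrap_angle(a):
    return (a + math.pi) % TWO_PI - math.pi


# ----------------------------------------------------------------------
# Metropolis
# ----------------------------------------------------------------------

def metropolis_accept(delta_e, T, rng):
    """Metropolis criterion with energies in k_B*T_ref units.

    Downhill moves always accept; uphill moves accept with probability
    exp(-delta_e * T_ref / T).  At T = 0 any uphill move is rejected.
    """
    if T < 0:
        raise ValueError("temperature must be >= 0")
    if delta_e <= 0:
        return True
    if T == 0:
        return False
    return bool(rng.random() < math.exp(-delta_e * T_REF / T))


# ----------------------------------------------------------------------
# state / trajectory containers
# ----------------------------------------------------------------------

@dataclass
class MCState:
    structure: object
    hierarchy: object
    resolved: list
    evaluator: EnergyEvaluator
    energy: float
    step: int
    rng: np.random.Generator
    proposals: np.ndarray = None  # per-node counters
    accepts: np.ndarray = None

    def __post_init__(self):
        n = len(self.hierarchy.nodes)
        if self.proposals is None:
            self.proposals = np.zeros(n, dtype=np.int64)
        if self.accepts is None:
            self.accepts = np.zeros(n, dtype=np.int64)


@dataclass
class TrajectoryRecord:
    """Strided snapshots plus the full per-step log of one replica."""

    seed: int
    snapshot_steps: np.ndarray  # (S,)
    snapshot_energies: np.ndarray  # (S,)
    snapshot_temperatures: np.ndarray  # (S,)
    coords: np.ndarray  # (S, n_beads, 3) nm
    step_log: dict  # arrays: step, energy, temperature, node, accepted
    node_labels: tuple
    acceptance: np.ndarray  # per-node accept fraction

    def __post_init__(self):
        if np.any(np.diff(self.snapshot_steps) <= 0):
            raise SamplerError("snapshot step indices must be strictly increasing")


# ----------------------------------------------------------------------
# main loops
# ----------------------------------------------------------------------

def run_mcmc(initial, hierarchy, table, params=ScalingParams(),
             schedule=AnnealSchedule(), seed=0, n_steps=None,
             snapshot_stride=100, bead_types=None, closure_zone=3,
             closure_tolerance=0.02, resync_interval=2000,
             peptide_chain=None):
    """Run one HNMMC replica; bit-reproducible for a fixed seed.

    Per step: pick a node by selection weight, propose a rigid move, apply
    it, close the resulting chain breaks, Metropolis-test at the schedule
    temperature, and update the state.  Moves with non-converged closure or
    a CA-CA virtual bond outside the [0.2, 0.6] nm sanity band are rejected
    outright.  Snapshots (including the initial state) are recorded every
    ``snapshot_stride`` accepted-or-not steps.
    """
    if n_steps is None:
        n_steps = schedule.total_steps
    structure = initial.copy()
    rng = np.random.default_rng(seed)
    evaluator = EnergyEvaluator(structure, table, params,
                                peptide_chain=peptide_chain,
                                bead_types=bead_types)
    resolved = hierarchy.resolve(structure)
    weights = hierarchy.weights()
    state = MCState(structure, hierarchy, resolved, evaluator,
                    evaluator.total(structure.coords).total, 0, rng)

    # bonds adjacent to each node's segments, for pre-move lengths and the
    # band check: keys plus vectorised CA index pairs
    bond_checks = []
    for res in resolved:
        keys, cai, caj = [], [], []
        for ci, lo, hi in res["spans"]:
            chain_len = len(structure.residue_numbers[ci])
            for b in range(max(lo - 1, 0), min(hi + 1, chain_len - 1)):
                if structure.residue_numbers[ci][b + 1] \
                        - structure.residue_numbers[ci][b] == 1:
                    keys.append((ci, b))
                    cai.append(structure._ca_index[(ci, b)])
                    caj.append(structure._ca_index[(ci, b + 1)])
        bond_checks.append((keys, np.asarray(cai, dtype=np.int64),
                            np.asarray(caj, dtype=np.int64)))

    coords = structure.coords
    n_nodes = len(hierarchy.nodes)

    log_step = np.arange(n_steps, dtype=np.int64)
    log_energy = np.empty(n_steps)
    log_temp = np.empty(n_steps)
    log_node = np.empty(n_steps, dtype=np.int32)
    log_accept = np.zeros(n_steps, dtype=bool)

    snaps_steps, snaps_e, snaps_T, snaps_xyz = [0], [state.energy], \
        [temperature_at(0, schedule)], [coords.copy()]

    cum_weights = np.cumsum(weights)
    node_energy_cache = {}

    for k in range(n_steps):
        T = temperature_at(k, schedule)
        node_index = int(np.searchsorted(cum_weights,
                                         rng.random() * cum_weights[-1]))
        state.proposals[node_index] += 1
        prop = propose_region_move(state, node_index, rng)
        res = resolved[node_index]
        bead_idx = res["bead_idx"]

        old_pos = coords[bead_idx].copy()
        bond_keys, cai, caj = bond_checks[node_index]
        diffs = coords[cai] - coords[caj]
        bond_lengths = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
        pre_bonds = dict(zip(bond_keys, bond_lengths))
        # node energies stay valid across rejected moves of any node
        e_old = node_energy_cache.get(node_index)
        if e_old is None:
            e_old = evaluator.node_energy(node_index, bead_idx, coords)
            node_energy_cache[node_index] = e_old

        apply_move(structure, prop, bead_idx)
        closure = close_chain(structure, res["spans"], pre_bonds,
                              zone=closure_zone, tolerance=closure_tolerance)
        ok = closure.converged and _band_ok(coords, cai, caj)
        if ok:
            e_new = evaluator.node_energy(node_index, bead_idx, coords)
            delta = e_new - e_old
            ok = metropolis_accept(delta, T, rng)
        if ok:
            state.energy += delta
            state.accepts[node_index] += 1
            log_accept[k] = True
            node_energy_cache.clear()
            node_energy_cache[node_index] = e_new
        else:
            coords[bead_idx] = old_pos

        log_energy[k] = state.energy
        log_temp[k] = T
        log_node[k] = node_index
        state.step = k + 1

        if (k + 1) % resync_interval == 0:
            full = evaluator.total(coords).total
            if abs(full - state.energy) > 1e-6 * max(1.0, abs(full)):
                raise SamplerError(
                    f"energy desync at step {k+1}: incremental {state.energy} "
                    f"vs full {full} (delta-energy bug)")
            state.energy = full
        if (k + 1) % snapshot_stride == 0:
            snaps_steps.append(k + 1)
            snaps_e.append(state.energy)
            snaps_T.append(temperature_at(k + 1, schedule))
            snaps_xyz.append(coords.copy())

    with np.errstate(invalid="ignore"):
        acc = np.where(state.proposals > 0,
                       state.accepts / np.maximum(state.proposals, 1), 0.0)
    return TrajectoryRecord(
        seed=seed,
        snapshot_steps=np.asarray(snaps_steps),
        snapshot_energies=np.asarray(snaps_e),
        snapshot_temperatures=np.asarray(snaps_T),
        coords=np.asarray(snaps_xyz),
        step_log={"step": log_step, "energy": log_energy,
                  "temperature": log_temp, "node": log_node,
                  "accepted": log_accept},
        node_labels=tuple(n.label for n in hierarchy.nodes),
        acceptance=acc,
    )


def _band_ok(coords, cai, caj):
    if len(cai) == 0:
        return True
    diffs = coords[cai] - coords[caj]
    d2 = np.einsum("ij,ij->i", diffs, diffs)
    lo, hi = CA_CA_BAND
    return bool(d2.min() >= lo * lo and d2.max() <= hi * hi)


def run_replicas(initial, hierarchy, table, params=ScalingParams(),
                 schedule=AnnealSchedule(), n_replicas=1, base_seed=0,
                 probes=None, n_steps=None, snapshot_stride=100,
                 bead_types=None, peptide_id="peptide", peptide_chain=None,
                 keep_trajectories=False, **mcmc_kwargs):
    """Run ``n_replicas`` independent HNMMC repeats (seeds base_seed + i).

    Returns a :class:`hnmmc.analysis.ReplicaSet` of clamped probe-distance
    trajectories (and, optionally, the raw trajectories).  Replicas are
    independent; the result does not depend on execution order.
    """
    from .analysis import ReplicaSet, probe_distances

    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if probes is None:
        raise ValueError("a ProbeSet is required to build a ReplicaSet")
    probe_idx = probes.resolve(initial)

    trajectories = []
    distances = []
    steps = None
    for i in range(n_replicas):
        traj = run_mcmc(initial, hierarchy, table, params, schedule,
                        seed=base_seed + i, n_steps=n_steps,
                        snapshot_stride=snapshot_stride,
                        bead_types=bead_types, peptide_chain=peptide_chain,
                        **mcmc_kwargs)
        if steps is None:
            steps = traj.snapshot_steps
        d = np.stack([probe_distances(xyz, probes, probe_idx)
                      for xyz in traj.coords])
        distances.append(np.minimum(d, probes.ceiling))
        if keep_trajectories:
            trajectories.append(traj)
    replica_set = ReplicaSet(
        peptide_id=peptide_id,
        sequence=initial.sequence(peptide_chain) if peptide_chain else "",
        steps=steps,
        distances=np.asarray(distances),
        ceiling=probes.ceiling,
    )
    if keep_trajectories:
        return replica_set, trajectories
    return replica_set
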
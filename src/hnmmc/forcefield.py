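"""Distance-binned knowledge-based pair potential with short-range scaling.

Energies are dimensionless multiples of k_B*T_ref with T_ref = 300 K
(knowledge-based potentials carry no absolute energy scale), so the
Metropolis factor at temperature T is exp(-dE * T_ref / T).

All pair interactions below a crossover distance r0 are damped by the
continuous scaling function

    s(r) = s0 + (1 - s0) * (r / r0)**6   for r <  r0
    s(r) = 1                             for r >= r0

with defaults r0 = 0.7 nm (about the size of a large amino acid) and
s0 = 0.15, which keeps short contacts soft enough that a peptide can escape
deep minima while leaving everything beyond r0 untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Bead

T_REF = 300.0  # Kelvin; reference temperature of the energy units


class ForceFieldError(ValueError):
    pass


@dataclass(frozen=True)
class ScalingParams:
    """Short-range interaction scaling: floor ``s0`` and crossover ``r0`` (nm)."""

    s0: float = 0.15
    r0: float = 0.7

    def __post_init__(self):
        if not (0.0 < self.s0 <= 1.0):
            raise ForceFieldError(f"s0 must be in (0, 1], got {self.s0}")
        if self.r0 <= 0:
            raise ForceFieldError(f"r0 must be positive, got {self.r0}")


def scale_factor(r, params=ScalingParams()):
    """Evaluate the pair-interaction scaling function s(r).

    Accepts a scalar or array of distances (nm); negative distances raise.
    Exactly 1.0 for r >= r0.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0):
        raise ForceFieldError("distance must be non-negative")
    out = np.where(arr < params.r0,
                   params.s0 + (1.0 - params.s0) * (arr / params.r0) ** 6,
                   1.0)
    if np.isscalar(r) or arr.ndim == 0:
        return float(out)
    return out


class PairPotential:
    """Bead-type-pair x distance-bin energy table.

    Bins are half-open ``[k*w, (k+1)*w)``; a distance exactly at the cutoff
    (= bin_width * n_bins) scores zero.  Pairs of beads closer than
    ``min_seq_sep`` residues along the same chain (|i-j| < min_seq_sep,
    default 3, i.e. separations 0..2 excluded) do not interact.
    """

    def __init__(self, types, energies, bin_width=0.05, cutoff=None,
                 min_seq_sep=3):
        self.types = list(types)
        self.energies = np.asarray(energies, dtype=float)
        T = len(self.types)
        if self.energies.shape[:2] != (T, T):
            raise ForceFieldError("energy table must be (n_types, n_types, n_bins)")
        if not np.all(np.isfinite(self.energies)):
            raise ForceFieldError("energy table contains non-finite values")
        if not np.allclose(self.energies, self.energies.transpose(1, 0, 2)):
            raise ForceFieldError("energy table must be symmetric in the type pair")
        self.bin_width = float(bin_width)
        self.n_bins = self.energies.shape[2]
        expected = self.bin_width * self.n_bins
        if cutoff is None:
            cutoff = expected
        if abs(cutoff - expected) > 1e-9:
            raise ForceFieldError(
                f"cutoff {cutoff} != bin_width*n_bins = {expected}")
        self.cutoff = float(cutoff)
        self.min_seq_sep = int(min_seq_sep)
        self._index = {t: i for i, t in enumerate(self.types)}

    def type_code(self, bead_type):
        try:
            return self._index[bead_type]
        except KeyError:
            raise ForceFieldError(f"unknown bead type {bead_type!r}") from None

    def codes_for(self, bead_types):
        return np.asarray([self.type_code(t) for t in bead_types], dtype=np.int32)

    def lookup(self, t1, t2, bin_index):
        return float(self.energies[self.type_code(t1), self.type_code(t2),
                                   bin_index])

    @classmethod
    def neutral(cls, bin_width=0.05, cutoff=1.5, core_radius=0.25,
                core_energy=10.0, min_seq_sep=3):
        """Packaged default: flat table with a repulsive excluded-volume core.

        Types are ``CA``, ``O`` and ``SC:<aa>`` for the 20 amino acids.
        Users supply real knowledge-based tables via :func:`hnmmc.io.read_potential`.
        """
        from .model import CA_SC_DISTANCE_NM
        types = ["CA", "O"] + [f"SC:{aa}" for aa in sorted(CA_SC_DISTANCE_NM)]
        n_bins = int(round(cutoff / bin_width))
        energies = np.zeros((len(types), len(types), n_bins))
        core_bins = int(np.ceil(core_radius / bin_width))
        energies[:, :, :core_bins] = core_energy
        return cls(types, energies, bin_width=bin_width, min_seq_sep=min_seq_sep)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Total energy and per-pair-class subtotals (k_B*T_ref units)."""

    total: float
    peptide_receptor: float
    intra_receptor: float
    intra_peptide: float

    def __post_init__(self):
        parts = self.peptide_receptor + self.intra_receptor + self.intra_peptide
        if abs(parts - self.total) > 1e-9 * max(1.0, abs(self.total)):
            raise ForceFieldError("energy subtotals do not sum to total")


def _bead_type(bead_or_type):
    if isinstance(bead_or_type, Bead):
        if bead_or_type.kind == "SC":
            return f"SC:{bead_or_type.residue_type}"
        return bead_or_type.kind
    return bead_or_type


def pair_energy(bead_i, bead_j, r, table, params=ScalingParams(),
                same_chain=False, seq_separation=None):
    """Scaled pair energy of two beads at distance ``r`` (nm).

    Returns 0 beyond the cutoff and for pairs excluded by sequence
    separation (``same_chain`` with ``seq_separation < table.min_seq_sep``).
    ``bead_i``/``bead_j`` may be :class:`~hnmmc.model.Bead` objects or bead
    type labels.
    """
    if r < 0:
        raise ForceFieldError("distance must be non-negative")
    if r >= table.cutoff:
        return 0.0
    if same_chain and seq_separation is not None \
            and abs(int(seq_separation)) < table.min_seq_sep:
        return 0.0
    ti = table.type_code(_bead_type(bead_i))
    tj = table.type_code(_bead_type(bead_j))
    b = int(r / table.bin_width)
    return scale_factor(r, params) * float(table.energies[ti, tj, b])


class EnergyEvaluator:
    """Vectorised full and per-node energy evaluation for one structure.

    Binds a structure's topology (bead types, chains, residue ordinals) to a
    potential table once; subsequent evaluations take only coordinates.
    Neighbour pruning is not needed at the system sizes this package
    targets — all-pairs evaluation is exact by construction.
    """

    def __init__(self, structure, table, params=ScalingParams(),
                 peptide_chain=None, bead_types=None):
        self.table = table
        self.params = params
        if bead_types is None:
            bead_types = structure.bead_types()
        self.codes = table.codes_for(bead_types)
        n = structure.n_beads
        self._n = n
        chain = structure.bead_chain
        res = structure.bead_res

        iu, ju = np.triu_indices(n, k=1)
        same = chain[iu] == chain[ju]
        excluded = same & (np.abs(res[iu] - res[ju]) < table.min_seq_sep)
        self._I = iu[~excluded]
        self._J = ju[~excluded]
        T = len(table.types)
        self._rows = (self.codes[self._I].astype(np.int64) * T
                      + self.codes[self._J])
        self._flat = table.energies.reshape(T * T, table.n_bins)

        if peptide_chain is not None:
            pci = structure.chain_index(peptide_chain)
            pi = chain[self._I] == pci
            pj = chain[self._J] == pci
            # 0: intra-receptor, 1: peptide-receptor, 2: intra-peptide
            self._pair_class = pi.astype(np.int8) + pj.astype(np.int8)
        else:
            self._pair_class = np.zeros(len(self._I), dtype=np.int8)

        # per-bead membership -> pair subsets, cached per node key
        self._node_cache = {}

    def _pair_energies(self, coords, I, J, rows):
        d = coords[I] - coords[J]
        r2 = np.einsum("ij,ij->i", d, d)
        inside = r2 < self.table.cutoff * self.table.cutoff
        r = np.sqrt(r2[inside])
        bins = (r * (1.0 / self.table.bin_width)).astype(np.int64)
        e = self._flat[rows[inside], bins]
        p = self.params
        small = r < p.r0
        s = np.ones_like(r)
        s[small] = p.s0 + (1.0 - p.s0) * (r[small] / p.r0) ** 6
        out = np.zeros(len(I))
        out[inside] = e * s
        return out

    def total(self, coords):
        """Full-system :class:`EnergyBreakdown`."""
        e = self._pair_energies(coords, self._I, self._J, self._rows)
        cls = self._pair_class
        return EnergyBreakdown(
            total=float(e.sum()),
            intra_receptor=float(e[cls == 0].sum()),
            peptide_receptor=float(e[cls == 1].sum()),
            intra_peptide=float(e[cls == 2].sum()),
        )

    def node_pair_arrays(self, key, bead_idx):
        """(I, J, row) arrays of all pairs touching ``bead_idx`` (cached)."""
        arrays = self._node_cache.get(key)
        if arrays is None:
            member = np.zeros(self._n, dtype=bool)
            member[bead_idx] = True
            sel = member[self._I] | member[self._J]
            arrays = (self._I[sel], self._J[sel], self._rows[sel])
            self._node_cache[key] = arrays
        return arrays

    def node_energy(self, key, bead_idx, coords):
        """Sum of pair energies over pairs with >= 1 bead in the node."""
        I, J, rows = self.node_pair_arrays(key, bead_idx)
        return float(self._pair_energies(coords, I, J, rows).sum())


def total_energy(structure, table, params=ScalingParams(), peptide_chain=None,
                 bead_types=None):
    """Total potential energy of a structure (all non-excluded bead pairs).

    Deterministic for fixed input; equals the brute-force double loop.
    """
    if structure.n_beads == 0:
        return EnergyBreakdown(0.0, 0.0, 0.0, 0.0)
    ev = EnergyEvaluator(structure, table, params, peptide_chain, bead_types)
    return ev.total(structure.coords)


def delta_energy(structure, moved_region, old_positions, table,
                 params=ScalingParams(), bead_types=None):
    """Energy difference caused by moving one region's beads.

    ``structure`` holds the *new* coordinates; ``old_positions`` the previous
    coordinates of exactly the region's beads (same order as the region's
    bead indices).  Equals ``total_energy(after) - total_energy(before)``.
    """
    ci = structure.chain_index(moved_region.chain_id)
    lo = structure.residue_ordinal(moved_region.chain_id, moved_region.start)
    hi = structure.residue_ordinal(moved_region.chain_id, moved_region.stop)
    bead_idx = structure.beads_for_ordinals(ci, lo, hi)
    old_positions = np.asarray(old_positions, dtype=float).reshape(-1, 3)
    if len(old_positions) != len(bead_idx):
        raise ForceFieldError(
            f"old_positions has {len(old_positions)} rows for a region of "
            f"{len(bead_idx)} beads")
    ev = EnergyEvaluator(structure, table, params, bead_types=bead_types)
    e_new = ev.node_energy("region", bead_idx, structure.coords)
    old_coords = structure.coords.copy()
    old_coords[bead_idx] = old_positions
    e_old = ev.node_energy("region", bead_idx, old_coords)
    return e_new - e_old
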
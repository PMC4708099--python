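"""Coarse-grained structural representation of peptide-MHC complexes.

Each amino acid is reduced to at most three beads: the alpha-carbon (CA),
the carbonyl oxygen (O) and the unweighted centroid of the side-chain heavy
atoms (SC).  Glycine carries no SC bead.  All coordinates are stored in
nanometres; PDB Angstroms are converted on read and write.

The module also owns the *region hierarchy*: the tree of contiguous residue
groups (beta-sheet floor, kink-broken helix halves, whole helices, peptide
sub-regions, whole peptide) whose rigid-body motions are the degrees of
freedom of the Monte Carlo sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

KIND_CA, KIND_O, KIND_SC = 0, 1, 2
KIND_NAMES = ("CA", "O", "SC")

#: sanity band for consecutive CA-CA virtual bonds (nm)
CA_CA_BAND = (0.2, 0.6)

ANGSTROM_PER_NM = 10.0

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common variants collapse onto their parent residue
    "MSE": "M", "SEC": "C", "PYL": "K",
}
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

# Canonical CA -> side-chain-centroid distances (nm), used when threading a
# new sequence onto a template backbone.  Values are typical distances from
# the alpha-carbon to the heavy-atom centroid of each side chain.
CA_SC_DISTANCE_NM = {
    "A": 0.152, "R": 0.410, "N": 0.249, "D": 0.249, "C": 0.232,
    "Q": 0.312, "E": 0.312, "H": 0.316, "I": 0.231, "L": 0.261,
    "K": 0.354, "M": 0.304, "F": 0.341, "P": 0.186, "S": 0.193,
    "T": 0.195, "W": 0.389, "Y": 0.385, "V": 0.196,
}

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclass(frozen=True)
class Bead:
    """A single coarse-grained interaction site.

    Parameters
    ----------
    kind : {"CA", "O", "SC"}
    residue_type : str
        One-letter amino-acid code.
    position : (3,) ndarray
        Cartesian coordinates in nm.
    """

    kind: str
    residue_type: str
    position: np.ndarray

    def __post_init__(self):
        if self.kind not in KIND_NAMES:
            raise StructureError(f"unknown bead kind {self.kind!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError("bead position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.kind == "SC" and self.residue_type == "G":
            raise StructureError("glycine carries no side-chain bead")


class BeadStructure:
    """Three-point coarse-grained structure: ordered chains of residues.

    Beads are stored flat, residue-contiguous, in CA, O, [SC] order.  Author
    residue numbering from the source PDB is preserved per chain.
    """

    def __init__(self, chain_ids, residue_numbers, sequences, coords, kinds,
                 bead_chain, bead_res, validate=True):
        self.chain_ids = tuple(chain_ids)
        self.residue_numbers = tuple(np.asarray(r, dtype=int) for r in residue_numbers)
        self.sequences = tuple(sequences)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.kinds = np.asarray(kinds, dtype=np.int8)
        self.bead_chain = np.asarray(bead_chain, dtype=np.int32)
        self.bead_res = np.asarray(bead_res, dtype=np.int32)
        self._build_index()
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_chains(cls, chains, validate=True):
        """Build from ``[(chain_id, residues), ...]`` where each residue is
        ``(resnum, one_letter_type, ca_xyz, o_xyz, sc_xyz_or_None)``."""
        chain_ids, residue_numbers, sequences = [], [], []
        coords, kinds, bead_chain, bead_res = [], [], [], []
        for ci, (cid, residues) in enumerate(chains):
            chain_ids.append(cid)
            nums, seq = [], []
            for ri, (num, rtype, ca, o, sc) in enumerate(residues):
                nums.append(num)
                seq.append(rtype)
                for kind, xyz in ((KIND_CA, ca), (KIND_O, o), (KIND_SC, sc)):
                    if xyz is None:
                        continue
                    coords.append(np.asarray(xyz, dtype=float))
                    kinds.append(kind)
                    bead_chain.append(ci)
                    bead_res.append(ri)
            residue_numbers.append(np.asarray(nums, dtype=int))
            sequences.append("".join(seq))
        return cls(chain_ids, residue_numbers, sequences,
                   np.array(coords, dtype=float).reshape(-1, 3),
                   kinds, bead_chain, bead_res, validate=validate)

    def _build_index(self):
        # per (chain, residue ordinal): bead index span and CA index
        self._res_beads = {}
        self._ca_index = {}
        for i in range(len(self.coords)):
            key = (int(self.bead_chain[i]), int(self.bead_res[i]))
            self._res_beads.setdefault(key, []).append(i)
            if self.kinds[i] == KIND_CA:
                self._ca_index[key] = i
        self._res_beads = {k: np.asarray(v, dtype=np.int64)
                           for k, v in self._res_beads.items()}

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_beads(self):
        return len(self.coords)

    @property
    def n_chains(self):
        return len(self.chain_ids)

    def chain_index(self, chain_id):
        try:
            return self.chain_ids.index(chain_id)
        except ValueError:
            raise StructureError(f"no chain {chain_id!r} in structure") from None

    def chain_length(self, chain_id):
        return len(self.residue_numbers[self.chain_index(chain_id)])

    def sequence(self, chain_id):
        return self.sequences[self.chain_index(chain_id)]

    def residue_ordinal(self, chain_id, resnum):
        """0-based position of author residue number ``resnum`` in the chain."""
        ci = self.chain_index(chain_id)
        nums = self.residue_numbers[ci]
        hits = np.nonzero(nums == int(resnum))[0]
        if len(hits) == 0:
            raise StructureError(
                f"residue {resnum} not present in chain {chain_id!r}")
        return int(hits[0])

    def ca_index(self, chain_id, resnum):
        ci = self.chain_index(chain_id)
        return self._ca_index[(ci, self.residue_ordinal(chain_id, resnum))]

    def residue_beads(self, chain_idx, res_ordinal):
        return self._res_beads[(int(chain_idx), int(res_ordinal))]

    def beads_for_ordinals(self, chain_idx, lo, hi):
        """Bead indices of residues with ordinals in [lo, hi] (inclusive)."""
        mask = (self.bead_chain == chain_idx) & (self.bead_res >= lo) & (self.bead_res <= hi)
        return np.nonzero(mask)[0]

    def ca_indices_for_ordinals(self, chain_idx, lo, hi):
        idx = self.beads_for_ordinals(chain_idx, lo, hi)
        return idx[self.kinds[idx] == KIND_CA]

    def bead(self, i):
        return Bead(KIND_NAMES[self.kinds[i]],
                    self.sequences[self.bead_chain[i]][self.bead_res[i]],
                    self.coords[i].copy())

    def restype_of_bead(self, i):
        return self.sequences[self.bead_chain[i]][self.bead_res[i]]

    def bead_types(self, scheme="default"):
        """Bead type labels for pair-potential lookup.

        ``default``: ``CA``, ``O`` and ``SC:<one-letter code>`` — the scheme
        of residue-type knowledge-based tables.  ``unique``: one label per
        bead (``<chain>:<resnum>:<kind>``), used by Go-style native-contact
        tables where each site is its own type.
        """
        out = []
        for i in range(self.n_beads):
            ci, ri = int(self.bead_chain[i]), int(self.bead_res[i])
            kind = KIND_NAMES[self.kinds[i]]
            if scheme == "default":
                out.append(f"SC:{self.sequences[ci][ri]}" if kind == "SC" else kind)
            elif scheme == "unique":
                out.append(f"{self.chain_ids[ci]}:{self.residue_numbers[ci][ri]}:{kind}")
            else:
                raise ValueError(f"unknown bead-type scheme {scheme!r}")
        return np.asarray(out)

    def to_chain_records(self):
        """Inverse of :meth:`from_chains` (positions are copies)."""
        chains = []
        for ci, cid in enumerate(self.chain_ids):
            residues = []
            for ri in range(len(self.residue_numbers[ci])):
                beads = self._res_beads[(ci, ri)]
                ca = o = sc = None
                for b in beads:
                    if self.kinds[b] == KIND_CA:
                        ca = self.coords[b].copy()
                    elif self.kinds[b] == KIND_O:
                        o = self.coords[b].copy()
                    else:
                        sc = self.coords[b].copy()
                residues.append((int(self.residue_numbers[ci][ri]),
                                 self.sequences[ci][ri], ca, o, sc))
            chains.append((cid, residues))
        return chains

    def copy(self):
        return BeadStructure(self.chain_ids, [r.copy() for r in self.residue_numbers],
                             self.sequences, self.coords.copy(), self.kinds.copy(),
                             self.bead_chain.copy(), self.bead_res.copy(),
                             validate=False)

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self):
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite bead coordinates")
        for ci, cid in enumerate(self.chain_ids):
            nums = self.residue_numbers[ci]
            seq = self.sequences[ci]
            if len(nums) != len(seq):
                raise StructureError(f"chain {cid!r}: numbering/sequence length mismatch")
            if len(nums) > 1 and np.any(np.diff(nums) <= 0):
                raise StructureError(
                    f"chain {cid!r}: residue numbers not strictly increasing")
            for ri in range(len(nums)):
                beads = self._res_beads.get((ci, ri))
                if beads is None:
                    raise StructureError(f"chain {cid!r} residue {nums[ri]}: no beads")
                kinds = self.kinds[beads]
                if np.sum(kinds == KIND_CA) != 1 or np.sum(kinds == KIND_O) != 1:
                    raise StructureError(
                        f"chain {cid!r} residue {nums[ri]}: needs exactly one CA and one O")
                if seq[ri] == "G" and np.any(kinds == KIND_SC):
                    raise StructureError(
                        f"chain {cid!r} residue {nums[ri]}: glycine with SC bead")
            self._check_band(ci, cid)

    def _check_band(self, ci, cid):
        nums = self.residue_numbers[ci]
        for ri in range(len(nums) - 1):
            if nums[ri + 1] - nums[ri] != 1:
                continue  # numbering gap (missing residues): no bond to check
            d = np.linalg.norm(self.coords[self._ca_index[(ci, ri + 1)]]
                               - self.coords[self._ca_index[(ci, ri)]])
            if not (CA_CA_BAND[0] <= d <= CA_CA_BAND[1]):
                raise StructureError(
                    f"chain {cid!r} residues {nums[ri]}-{nums[ri+1]}: "
                    f"CA-CA distance {d:.3f} nm outside {CA_CA_BAND}")

    def consecutive_ca_distances(self, chain_id=None):
        """CA-CA virtual-bond lengths for consecutively numbered residues."""
        out = []
        chains = [self.chain_index(chain_id)] if chain_id else range(self.n_chains)
        for ci in chains:
            nums = self.residue_numbers[ci]
            for ri in range(len(nums) - 1):
                if nums[ri + 1] - nums[ri] != 1:
                    continue
                out.append(np.linalg.norm(
                    self.coords[self._ca_index[(ci, ri + 1)]]
                    - self.coords[self._ca_index[(ci, ri)]]))
        return np.asarray(out)


# ----------------------------------------------------------------------
# coarse graining
# ----------------------------------------------------------------------

def coarse_grain_structure(all_atom):
    """Convert an all-atom model into the 3-point bead representation.

    Parameters
    ----------
    all_atom : biotite.structure.AtomArray or str or Path
        Parsed PDB content, or a path to a PDB file.  Waters, ions,
        hetero-groups and hydrogens are discarded; altloc ambiguity is
        resolved by occupancy at read time.

    Returns
    -------
    BeadStructure
        CA bead at the alpha-carbon, O bead at the carbonyl oxygen, SC bead
        at the unweighted centroid of the side-chain heavy atoms (Cbeta and
        beyond); no SC bead for glycine.  Coordinates converted to nm.
    """
    import biotite.structure as struc

    if not isinstance(all_atom, struc.AtomArray):
        from .io import load_pdb_atoms
        all_atom = load_pdb_atoms(all_atom)

    atoms = all_atom[~all_atom.hetero]
    atoms = atoms[np.isin(atoms.res_name, list(AA_3TO1))]
    atoms = atoms[~np.isin(atoms.element, ["H", "D"])]
    if atoms.array_length() == 0:
        raise StructureError("no protein chains with backbone atoms found")

    chains = []
    for cid in map(str, _unique_in_order(atoms.chain_id)):
        csel = atoms[atoms.chain_id == cid]
        residues = []
        starts = struc.get_residue_starts(csel, add_exclusive_stop=True)
        for s, e in zip(starts[:-1], starts[1:]):
            res = csel[s:e]
            resnum = int(res.res_id[0])
            rtype = AA_3TO1.get(res.res_name[0], "X")
            names = res.atom_name
            ca = _single_atom(res, names, "CA", cid, resnum)
            o = _single_atom(res, names, "O", cid, resnum)
            side = res[~np.isin(names, list(BACKBONE_ATOM_NAMES))]
            if side.array_length() == 0:
                sc = None
                if rtype != "G":
                    logger.info("chain %s residue %s (%s): no side-chain heavy "
                                "atoms, treated as glycine", cid, resnum, rtype)
                    rtype = "G"
            else:
                sc = side.coord.mean(axis=0) / ANGSTROM_PER_NM
            residues.append((resnum, rtype, ca, o, sc))
        chains.append((cid, residues))
    return BeadStructure.from_chains(chains)


def _single_atom(res, names, name, cid, resnum):
    hit = res[names == name]
    if hit.array_length() == 0:
        raise StructureError(
            f"chain {cid!r} residue {resnum}: missing {name} atom")
    return hit.coord[0] / ANGSTROM_PER_NM


def _unique_in_order(values):
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


# ----------------------------------------------------------------------
# peptide threading
# ----------------------------------------------------------------------

def thread_peptide_sequence(template, chain_id, new_sequence):
    """Thread a new peptide sequence onto a template chain's backbone.

    The backbone beads (CA, O) are kept fixed; each SC bead keeps the
    template's CA->SC direction but is repositioned at the canonical CA-SC
    distance of the new residue type.  Glycine (and unknown ``X``) drop the
    SC bead.  Residues gaining a side chain where the template had none
    (template glycine) point the new SC away from the local backbone.
    """
    new_sequence = str(new_sequence).upper()
    old_len = template.chain_length(chain_id)
    if len(new_sequence) != old_len:
        raise StructureError(
            f"sequence length {len(new_sequence)} does not match template "
            f"chain {chain_id!r} length {old_len}")
    for aa in new_sequence:
        if aa not in CA_SC_DISTANCE_NM and aa not in ("G", "X"):
            raise StructureError(f"unknown residue code {aa!r}")

    records = template.to_chain_records()
    ci = template.chain_index(chain_id)
    cid, residues = records[ci]
    cas = [r[2] for r in residues]
    new_residues = []
    for ri, (num, rtype, ca, o, sc) in enumerate(residues):
        aa = new_sequence[ri]
        if aa == rtype:
            new_residues.append((num, rtype, ca, o, sc))
            continue
        if aa in ("G", "X"):
            new_residues.append((num, "G" if aa == "X" else aa, ca, o, None))
            continue
        if sc is not None:
            direction = sc - ca
        else:
            direction = _outward_direction(cas, ri)
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            direction, norm = np.array([0.0, 0.0, 1.0]), 1.0
        new_sc = ca + direction / norm * CA_SC_DISTANCE_NM[aa]
        new_residues.append((num, aa, ca, o, new_sc))
    records[ci] = (cid, new_residues)
    return BeadStructure.from_chains(records)


def _outward_direction(cas, ri):
    """Direction away from the local backbone axis, for template glycines."""
    if 0 < ri < len(cas) - 1:
        return cas[ri] - 0.5 * (cas[ri - 1] + cas[ri + 1])
    if ri == 0 and len(cas) > 1:
        return cas[0] - cas[1]
    if ri == len(cas) - 1 and len(cas) > 1:
        return cas[-1] - cas[-2]
    return np.array([0.0, 0.0, 1.0])


# ----------------------------------------------------------------------
# region hierarchy
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A contiguous run of residues of one chain (author numbering)."""

    chain_id: str
    start: int
    stop: int  # inclusive
    label: str = ""

    def __post_init__(self):
        if self.stop < self.start:
            raise StructureError(
                f"region {self.label!r}: empty range {self.start}..{self.stop}")

    def residue_numbers(self):
        return range(self.start, self.stop + 1)


@dataclass
class HierarchyNode:
    """A movable node: one or more regions sharing 6 rigid-body DOF."""

    label: str
    segments: tuple  # tuple[Region, ...]
    children: tuple = ()  # indices into RegionHierarchy.nodes
    max_translation: float = 0.05  # nm
    max_rotation: float = 5.0  # degrees
    weight: float = 1.0

    def residue_set(self):
        return {(seg.chain_id, num) for seg in self.segments
                for num in seg.residue_numbers()}

    @property
    def is_leaf(self):
        return len(self.children) == 0


class RegionHierarchy:
    """Forest of movable nodes; internal nodes are super-regions."""

    def __init__(self, nodes):
        self.nodes = list(nodes)
        if not self.nodes:
            raise StructureError("hierarchy needs at least one node")
        self._validate_tree()

    def _validate_tree(self):
        for ni, node in enumerate(self.nodes):
            parent_set = node.residue_set()
            claimed = set()
            for ci in node.children:
                child = self.nodes[ci]
                cset = child.residue_set()
                if not cset <= parent_set:
                    raise StructureError(
                        f"child {child.label!r} not contained in {node.label!r}")
                if claimed & cset:
                    raise StructureError(
                        f"children of {node.label!r} overlap at {claimed & cset}")
                claimed |= cset

    def __len__(self):
        return len(self.nodes)

    def leaves(self):
        return [n for n in self.nodes if n.is_leaf]

    def nodes_for_chain(self, chain_id):
        return [n for n in self.nodes
                if all(seg.chain_id == chain_id for seg in n.segments)]

    def weights(self):
        w = np.array([n.weight for n in self.nodes], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise StructureError("node selection weights must be >= 0, sum > 0")
        return w / w.sum()

    def resolve(self, structure):
        """Bind nodes to a structure: bead/CA indices and ordinal spans.

        Returns a list (parallel to ``nodes``) of dicts with keys
        ``bead_idx``, ``ca_idx``, ``spans`` (chain_idx, lo_ord, hi_ord per
        segment).
        """
        resolved = []
        for node in self.nodes:
            bead_idx, ca_idx, spans = [], [], []
            for seg in node.segments:
                ci = structure.chain_index(seg.chain_id)
                lo = structure.residue_ordinal(seg.chain_id, seg.start)
                hi = structure.residue_ordinal(seg.chain_id, seg.stop)
                spans.append((ci, lo, hi))
                bead_idx.append(structure.beads_for_ordinals(ci, lo, hi))
                ca_idx.append(structure.ca_indices_for_ordinals(ci, lo, hi))
            resolved.append({
                "bead_idx": np.concatenate(bead_idx),
                "ca_idx": np.concatenate(ca_idx),
                "spans": spans,
            })
        return resolved


DEFAULT_AMPLITUDES = {"max_translation": 0.05, "max_rotation": 5.0}


def build_pmhc_hierarchy(structure, config):
    """Build the default pMHC region hierarchy from a config mapping.

    The MHC side yields exactly seven nodes: the beta-sheet floor leaf plus,
    for each of the two groove helices, two kink-broken leaf regions nested
    under a whole-helix super-region.  The peptide yields leaf sub-regions
    (default thirds of the chain) under a whole-peptide super-region.
    Residues of the alpha3 domain / beta2-microglobulin (anything outside the
    configured groove range, and any extra chains) belong to no node and are
    held fixed.

    Config keys: ``mhc_chain``, ``peptide_chain``, ``helix1_range``,
    ``helix1_kink``, ``helix2_range``, ``helix2_kink``; optional
    ``groove_range``, ``peptide_subregions`` (1-based position ranges),
    ``max_translation``, ``max_rotation``, ``peptide_amplitude_scale``.
    """
    mhc = config["mhc_chain"]
    pep = config["peptide_chain"]
    h1 = tuple(config["helix1_range"])
    h2 = tuple(config["helix2_range"])
    k1 = int(config["helix1_kink"])
    k2 = int(config["helix2_kink"])
    tmax = float(config.get("max_translation", DEFAULT_AMPLITUDES["max_translation"]))
    rmax = float(config.get("max_rotation", DEFAULT_AMPLITUDES["max_rotation"]))
    pep_scale = float(config.get("peptide_amplitude_scale", 2.0))

    mhc_nums = structure.residue_numbers[structure.chain_index(mhc)]
    groove = tuple(config.get("groove_range", (int(mhc_nums[0]), int(mhc_nums[-1]))))

    for lo, hi, name in [(h1[0], h1[1], "helix1"), (h2[0], h2[1], "helix2"),
                         (groove[0], groove[1], "groove")]:
        if hi < lo:
            raise StructureError(f"{name} range {lo}..{hi} is empty")
    if not (h1[1] < h2[0] or h2[1] < h1[0]):
        raise StructureError("helix ranges overlap")
    for (lo, hi), k, name in [(h1, k1, "helix1"), (h2, k2, "helix2")]:
        if not (lo < k <= hi):
            raise StructureError(
                f"{name} kink {k} outside ({lo}, {hi}]: would create an "
                "empty sub-region")

    nodes = []

    def add(label, segments, children=(), scale=1.0, weight=1.0):
        nodes.append(HierarchyNode(label, tuple(segments), tuple(children),
                                   tmax * scale, rmax * scale, weight))
        return len(nodes) - 1

    # floor: groove residues not in either helix, as contiguous runs
    helix_nums = set(range(h1[0], h1[1] + 1)) | set(range(h2[0], h2[1] + 1))
    floor_nums = [n for n in mhc_nums if groove[0] <= n <= groove[1]
                  and n not in helix_nums]
    if not floor_nums:
        raise StructureError("no floor residues left after removing helices")
    floor_segments = [Region(mhc, lo, hi, f"floor[{lo}-{hi}]")
                      for lo, hi in _contiguous_runs(floor_nums)]
    add("mhc:floor", floor_segments)

    for name, (lo, hi), k in [("helix1", h1, k1), ("helix2", h2, k2)]:
        a = add(f"mhc:{name}a", [Region(mhc, lo, k - 1, f"{name}a")])
        b = add(f"mhc:{name}b", [Region(mhc, k, hi, f"{name}b")])
        add(f"mhc:{name}", [Region(mhc, lo, hi, name)], children=(a, b))

    # peptide sub-regions (1-based positions along the chain)
    pep_nums = structure.residue_numbers[structure.chain_index(pep)]
    L = len(pep_nums)
    sub = config.get("peptide_subregions")
    if sub is None:
        bounds = np.array_split(np.arange(L), 3)
        sub = [(int(b[0]) + 1, int(b[-1]) + 1) for b in bounds if len(b)]
    pep_children = []
    for j, (p_lo, p_hi) in enumerate(sub, start=1):
        if not (1 <= p_lo <= p_hi <= L):
            raise StructureError(f"peptide sub-region {p_lo}..{p_hi} outside 1..{L}")
        pep_children.append(add(
            f"peptide:sub{j}",
            [Region(pep, int(pep_nums[p_lo - 1]), int(pep_nums[p_hi - 1]),
                    f"pep{p_lo}-{p_hi}")]))
    add("peptide:whole",
        [Region(pep, int(pep_nums[0]), int(pep_nums[-1]), "peptide")],
        children=tuple(pep_children), scale=pep_scale)

    hierarchy = RegionHierarchy(nodes)
    hierarchy.resolve(structure)  # raises if config names absent residues
    return hierarchy


def _contiguous_runs(numbers):
    runs, start, prev = [], numbers[0], numbers[0]
    for n in numbers[1:]:
        if n != prev + 1:
            runs.append((start, prev))
            start = n
        prev = n
    runs.append((start, prev))
    return runs
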
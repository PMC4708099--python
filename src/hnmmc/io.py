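"""File I/O: PDB structures, trajectories, potential tables, label tables.

Coarse-grained structures are written as standard PDB with pseudo-atoms
named CA, O and SC; trajectories as multi-model PDB (MODEL/ENDMDL per
snapshot).  Potential tables round-trip bit-exactly through a documented
plain-text format:

    # hnmmc pair potential
    bin_width <nm>
    cutoff <nm>
    min_seq_sep <int>
    types <tab-separated labels>
    <type_i>\t<type_j>\t<e0> <e1> ... <e_{nbins-1}>

Only the upper triangle of type pairs is stored (the table is symmetric).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcefield import ForceFieldError, PairPotential
from .model import (AA_1TO3, ANGSTROM_PER_NM, KIND_NAMES, BeadStructure,
                    StructureError)

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# all-atom PDB reading
# ----------------------------------------------------------------------

def load_pdb_atoms(path, model=1):
    """Read one model of a PDB file as a biotite AtomArray (altloc by
    occupancy; insertion codes tolerated)."""
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    atoms = pdbio.get_structure(pdb_file, model=model, altloc="occupancy")
    try:
        n_all = pdbio.get_structure(pdb_file, model=model,
                                    altloc="all").array_length()
        if n_all > atoms.array_length():
            logger.info("%s: %d altloc atoms resolved by highest occupancy",
                        path, n_all - atoms.array_length())
    except Exception:  # pragma: no cover - altloc bookkeeping is best-effort
        pass
    return atoms


# ----------------------------------------------------------------------
# coarse-grained PDB writing
# ----------------------------------------------------------------------

def _bead_template(structure):
    import biotite.structure as struc

    n = structure.n_beads
    arr = struc.AtomArray(n)
    for i in range(n):
        ci = int(structure.bead_chain[i])
        ri = int(structure.bead_res[i])
        kind = KIND_NAMES[structure.kinds[i]]
        arr.chain_id[i] = structure.chain_ids[ci]
        arr.res_id[i] = int(structure.residue_numbers[ci][ri])
        arr.res_name[i] = AA_1TO3.get(structure.sequences[ci][ri], "UNK")
        arr.atom_name[i] = kind
        arr.element[i] = "O" if kind == "O" else "C"
        arr.hetero[i] = False
    return arr


def write_beads_pdb(structure, path):
    """Write a BeadStructure as a single-model pseudo-atom PDB (nm -> A)."""
    import biotite.structure.io.pdb as pdbio

    arr = _bead_template(structure)
    arr.coord = structure.coords * ANGSTROM_PER_NM
    f = pdbio.PDBFile()
    pdbio.set_structure(f, arr)
    f.write(str(path))


def write_trajectory_pdb(structure, coords_stack, path):
    """Write snapshot coordinates (S, n_beads, 3 nm) as multi-model PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    template = _bead_template(structure)
    frames = []
    for xyz in np.asarray(coords_stack):
        frame = template.copy()
        frame.coord = np.asarray(xyz) * ANGSTROM_PER_NM
        frames.append(frame)
    f = pdbio.PDBFile()
    pdbio.set_structure(f, struc.stack(frames))
    f.write(str(path))


def write_step_log(trajectory, path):
    """Per-step tab-separated log: step, energy, temperature, node, accepted."""
    log = trajectory.step_log
    pd.DataFrame({
        "step": log["step"],
        "energy": log["energy"],
        "temperature": log["temperature"],
        "node": [trajectory.node_labels[i] for i in log["node"]],
        "accepted": log["accepted"].astype(int),
    }).to_csv(path, sep="\t", index=False, float_format="%.9g")


# ----------------------------------------------------------------------
# potential tables
# ----------------------------------------------------------------------

def write_potential(table, path):
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# hnmmc pair potential\n")
        fh.write(f"bin_width {table.bin_width!r}\n")
        fh.write(f"cutoff {table.cutoff!r}\n")
        fh.write(f"min_seq_sep {table.min_seq_sep}\n")
        fh.write("types\t" + "\t".join(table.types) + "\n")
        for i, ti in enumerate(table.types):
            for j in range(i, len(table.types)):
                row = " ".join(repr(float(e)) for e in table.energies[i, j])
                fh.write(f"{ti}\t{table.types[j]}\t{row}\n")


def read_potential(path):
    path = Path(path)
    header = {}
    types = None
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if types is None:
                key, _, rest = line.partition("\t" if line.startswith("types") else " ")
                if key == "types":
                    types = rest.split("\t")
                else:
                    header[key] = rest
                continue
            ti, tj, values = line.split("\t")
            rows.append((ti, tj, np.fromstring(values, sep=" ")))
    if types is None:
        raise ForceFieldError(f"{path}: missing 'types' header line")
    tmap = {t: i for i, t in enumerate(types)}
    n_bins = len(rows[0][2]) if rows else 0
    E = np.zeros((len(types), len(types), n_bins))
    seen = np.zeros((len(types), len(types)), dtype=bool)
    for ti, tj, vals in rows:
        i, j = tmap[ti], tmap[tj]
        E[i, j] = E[j, i] = vals
        seen[i, j] = seen[j, i] = True
    if not seen.all():
        raise ForceFieldError(f"{path}: missing rows for some type pairs")
    return PairPotential(
        types, E,
        bin_width=float(header.get("bin_width", 0.05)),
        cutoff=float(header["cutoff"]) if "cutoff" in header else None,
        min_seq_sep=int(header.get("min_seq_sep", 3)),
    )


def bead_types_for_table(structure, table):
    """Pick the bead-type scheme matching a table's type labels."""
    if any(":" in t and not t.startswith("SC:") for t in table.types):
        return structure.bead_types(scheme="unique")
    return structure.bead_types(scheme="default")


# ----------------------------------------------------------------------
# labels and configs
# ----------------------------------------------------------------------

def read_binding_labels(path, ic50_threshold_nm=500.0):
    """Read a two-column CSV (sequence, class or IC50_nM) into BindingRecords."""
    from .analysis import BindingRecord

    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "sequence" not in cols:
        raise StructureError(f"{path}: needs a 'sequence' column")
    records = []
    for _, row in frame.iterrows():
        label = None
        ic50 = None
        if "class" in cols and not pd.isna(row[cols["class"]]):
            label = str(row[cols["class"]]).strip()
        if "ic50_nm" in cols and not pd.isna(row[cols["ic50_nm"]]):
            ic50 = float(row[cols["ic50_nm"]])
        records.append(BindingRecord(str(row[cols["sequence"]]).strip(),
                                     label=label, ic50_nm=ic50,
                                     ic50_threshold_nm=ic50_threshold_nm))
    return records


def load_config(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(config, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
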
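"""End-to-end campaign driver: thread peptides, run replicas, analyze.

A campaign is described by one YAML config (documented in the README):

    synthetic: true              # or structure/potential/hierarchy paths
    toy: {groove_length: 12, ...}
    peptides:
      - {id: pep1, sequence: AAAAAAAAA, class: binder}
    replicas: 2
    steps: 500
    stride: 50
    base_seed: 1
    schedule: {amplitude: 600, period: 5000, shift: 0}
    bootstrap: {enabled: false, B: 500, n_values: [1, 25, 100]}

Outputs per peptide: one multi-model trajectory PDB per replica plus a tidy
probe-distance table; campaign-level outputs: score table, ROC points (when
labels are present), optional bootstrap table, and a manifest recording the
config snapshot, seeds and input checksums.  Completed peptides are skipped
on re-run when the config hash matches (resume); a mismatch refuses to run
unless forced.  Every analysis output is a pure function of the recorded
probe tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (ReplicaSet, auroc, detachment_score, mean_sem_curves,
                       pathway_counts, pearson_r, per_replica_scores,
                       bootstrap_auroc_sd)
from .forcefield import ScalingParams
from .io import (bead_types_for_table, dump_config, load_config,
                 read_potential, write_step_log, write_trajectory_pdb)
from .model import build_pmhc_hierarchy, coarse_grain_structure, \
    thread_peptide_sequence
from .sampler import AnnealSchedule, run_replicas
from .synthetic import PEPTIDE_CHAIN, ToySpec, go_bead_types, \
    make_go_potential, make_toy_complex


class CampaignError(RuntimeError):
    pass


def _config_hash(config):
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _file_checksum(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class CampaignSetup:
    structure: object
    hierarchy: object
    table: object
    bead_types: object
    probes: object
    peptide_chain: str
    params: ScalingParams
    schedule: AnnealSchedule


def _setup_from_config(config):
    params = ScalingParams(**config.get("scaling", {}))
    sched_cfg = config.get("schedule", {})
    schedule = AnnealSchedule(
        amplitude=float(sched_cfg.get("amplitude", 600.0)),
        period=int(sched_cfg.get("period", 5000)),
        shift=float(sched_cfg.get("shift", 0.0)),
        total_steps=int(config.get("steps", 100_000)))
    if config.get("synthetic"):
        spec = ToySpec(**config.get("toy", {}))
        structure, hierarchy, probes = make_toy_complex(spec)
        table = make_go_potential(structure, spec)
        bead_types = go_bead_types(structure)
        peptide_chain = PEPTIDE_CHAIN
    else:
        from .analysis import ProbeSet
        structure = coarse_grain_structure(config["structure"])
        hierarchy_cfg = config["hierarchy"]
        if isinstance(hierarchy_cfg, str):
            hierarchy_cfg = load_config(hierarchy_cfg)
        hierarchy = build_pmhc_hierarchy(structure, hierarchy_cfg)
        table = read_potential(config["potential"])
        bead_types = bead_types_for_table(structure, table)
        peptide_chain = hierarchy_cfg["peptide_chain"]
        p = config["probes"]
        probes = ProbeSet(peptide_chain=peptide_chain,
                          receptor_chain=hierarchy_cfg["mhc_chain"],
                          n=tuple(p["n"]), mid=tuple(p["mid"]),
                          c=tuple(p["c"]),
                          ceiling=float(p.get("ceiling", 3.0)))
    return CampaignSetup(structure, hierarchy, table, bead_types, probes,
                         peptide_chain, params, schedule)


def run_campaign(config, out_dir, force=False, seed=None):
    """Run the full workflow for every peptide in the config.

    Returns the output directory path.  ``seed`` overrides the config's
    ``base_seed``.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        config = load_config(config_path)
        checksums = {str(config_path): _file_checksum(config_path)}
    else:
        checksums = {}
    config = dict(config)
    if seed is not None:
        config["base_seed"] = int(seed)
    base_seed = int(config.get("base_seed", 0))
    n_replicas = int(config.get("replicas", 1))
    n_steps = int(config.get("steps", 1000))
    stride = int(config.get("stride", 100))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)

    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != chash and not force:
            raise CampaignError(
                f"{out} holds outputs of a different config "
                f"({old.get('config_hash')!r} != {chash!r}); use force=True")

    peptides = config["peptides"]
    seeds = {p["id"]: base_seed + i * n_replicas
             for i, p in enumerate(peptides)}
    manifest = {
        "package_version": __version__,
        "config": config,
        "config_hash": chash,
        "base_seed": base_seed,
        "replica_seeds": {pid: list(range(s, s + n_replicas))
                          for pid, s in seeds.items()},
        "input_checksums": checksums,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "finished": None,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    setup = _setup_from_config(config)

    score_rows = []
    replica_sets = {}
    for p in peptides:
        pid = p["id"]
        pep_dir = out / pid
        done_marker = pep_dir / ".done"
        probes_path = pep_dir / "probes.tsv"
        if done_marker.exists() and done_marker.read_text().strip() == chash:
            replica_sets[pid] = ReplicaSet.from_tsv(
                probes_path, ceiling=setup.probes.ceiling)
            continue
        pep_dir.mkdir(parents=True, exist_ok=True)
        if p.get("sequence"):
            structure = thread_peptide_sequence(
                setup.structure, setup.peptide_chain, p["sequence"])
            # unique (chain:resnum:kind) Go types survive threading; beads
            # dropped by glycine simply leave unused rows in the table
            bead_types = go_bead_types(structure) if config.get("synthetic") \
                else bead_types_for_table(structure, setup.table)
        else:
            structure = setup.structure
            bead_types = setup.bead_types
        rset, trajectories = run_replicas(
            structure, setup.hierarchy, setup.table, setup.params,
            setup.schedule, n_replicas=n_replicas, base_seed=seeds[pid],
            probes=setup.probes, n_steps=n_steps, snapshot_stride=stride,
            bead_types=bead_types, peptide_id=pid,
            peptide_chain=setup.peptide_chain, keep_trajectories=True)
        for i, traj in enumerate(trajectories):
            write_trajectory_pdb(structure, traj.coords,
                                 pep_dir / f"trajectory_{i:03d}.pdb")
            write_step_log(traj, pep_dir / f"steps_{i:03d}.tsv")
        rset.to_tsv(probes_path)
        mean_sem_curves(rset).to_csv(pep_dir / "curves.tsv", sep="\t",
                                     index=False, float_format="%.9g")
        counts = pathway_counts(rset)
        pd.DataFrame([counts]).to_csv(pep_dir / "pathways.tsv", sep="\t",
                                      index=False)
        done_marker.write_text(chash)
        replica_sets[pid] = rset

    labels, ic50s = {}, {}
    for p in peptides:
        if "class" in p:
            labels[p["id"]] = p["class"]
        if "ic50_nm" in p:
            ic50s[p["id"]] = float(p["ic50_nm"])
    for p in peptides:
        pid = p["id"]
        score_rows.append({
            "peptide": pid,
            "sequence": p.get("sequence", ""),
            "score_nm": detachment_score(replica_sets[pid]),
            "class": labels.get(pid, ""),
            "ic50_nm": ic50s.get(pid, np.nan),
        })
    scores = pd.DataFrame(score_rows)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False,
                  float_format="%.9g")

    if len(set(labels.values())) == 2:
        a = auroc(scores["score_nm"], scores["class"])
        roc = {"auroc": a, "n_peptides": len(scores)}
        if len(ic50s) >= 3:
            sub = scores.dropna(subset=["ic50_nm"])
            roc["pearson_r_log10_ic50"] = pearson_r(
                sub["score_nm"], np.log10(sub["ic50_nm"]))
        (out / "roc.json").write_text(json.dumps(roc, indent=2))

        boot_cfg = config.get("bootstrap", {})
        if boot_cfg.get("enabled"):
            X = np.stack([per_replica_scores(replica_sets[pid])
                          for pid in scores["peptide"]])
            sd = bootstrap_auroc_sd(
                X, scores["class"].to_numpy(),
                n_values=boot_cfg.get("n_values", [1, 25, 100]),
                B=int(boot_cfg.get("B", 500)),
                seed=base_seed)
            pd.DataFrame({"n_replicas": list(sd), "auroc_sd": list(sd.values())}) \
                .to_csv(out / "bootstrap.tsv", sep="\t", index=False,
                        float_format="%.9g")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return out
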
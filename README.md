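# hnmmc

Coarse-grained **h**ierarchical **n**atural-**m**ove **M**onte **C**arlo
simulation and analysis of peptide detachment from MHC-like receptors.

## The problem

Class I MHC molecules present short peptides in a groove formed by two
α-helices above a β-sheet floor; whether a peptide stays bound decides
whether T cells can see it. All-atom molecular dynamics cannot reach the
timescales on which peptides actually leave the groove, so the structural
*detachment pathway* — does the peptide peel off N-terminally,
C-terminally, from both ends? — is inaccessible to standard simulation.
This package implements a protocol that makes detachment observable at
desk scale for structural immunologists and method developers:

1. **Coarse graining** — each residue becomes ≤ 3 beads (Cα, carbonyl O,
   side-chain centroid), scored by a distance-binned knowledge-based pair
   potential whose short-range part is damped by
   `s(r) = s0 + (1 − s0)(r/r0)^6` for `r < r0` (defaults `s0 = 0.15`,
   `r0 = 0.7 nm`) so bound peptides can escape deep minima.
2. **Hierarchical natural moves** — rigid-body translations/rotations of a
   region tree: β-sheet floor, kink-broken helix halves under whole-helix
   super-regions (7 receptor nodes), peptide thirds under a whole-peptide
   node. Chain breaks at region boundaries are repaired by a deterministic
   CCD closure over Cα–Cα virtual bonds.
3. **Periodic simulated annealing** —
   `T(k) = s_T + (A/2)(1 + cos(2πk/Ω))` with defaults `A = 600 K`,
   `Ω = 5000`, `s_T = 0` over 100 000 Metropolis steps, repeated over many
   independent replicas.

The analysis layer turns replica trajectories into the standard detachment
read-outs: three peptide–floor Cα probe distances (N-end, middle, C-end)
clamped at 3 nm, mean ± SEM curves, pathway classes (N-first / C-first /
simultaneous-ends / middle-first / stable), a per-peptide detachment
score (mean clamped probe distance), binder/non-binder discrimination
(ROC area with non-binder as positive class, Mann–Whitney form), Pearson
correlation against log10 IC50, and a replica-count bootstrap that
estimates how many replicas a reliable AROC needs.

Everything is testable offline: `hnmmc.synthetic` generates toy
groove–peptide complexes with Gō-style native-contact potentials in which
anchor-residue strength is dialled explicitly, plus synthetic replica
data with the statistical shape the analysis assumes. See
`docs/methods.md` for the model details and design choices.

## Worked example

Simulate the anchor-contrast experiment on the packaged toy groove: a
9-mer with anchor wells at positions 2 and 9 versus the same system with
no anchors.

```python
from hnmmc.synthetic import ToySpec, make_toy_complex, make_go_potential, go_bead_types
from hnmmc.sampler import run_replicas, AnnealSchedule
from hnmmc.analysis import detachment_score, classify_pathway

for anchors in [(), (2, 9)]:
    spec = ToySpec(anchor_positions=anchors)
    structure, hierarchy, probes = make_toy_complex(spec)
    table = make_go_potential(structure, spec)
    rset = run_replicas(structure, hierarchy, table,
                        schedule=AnnealSchedule(), n_replicas=5,
                        base_seed=0, probes=probes, n_steps=10_000,
                        snapshot_stride=100,
                        bead_types=go_bead_types(structure),
                        peptide_chain="P")
    classes = [classify_pathway(rset.distances[i], margin=15)
               for i in range(rset.n_replicas)]
    print(f"anchors={anchors or 'none'}: detachment score = "
          f"{detachment_score(rset):.2f} nm, classes = {classes}")
```

prints

```
anchors=none: detachment score = 2.53 nm, classes = ['simultaneous-ends', 'C-first', 'simultaneous-ends', 'simultaneous-ends', 'C-first']
anchors=(2, 9): detachment score = 0.87 nm, classes = ['stable', 'stable', 'stable', 'stable', 'stable']
```

Without anchors the peptide leaves the groove within 10 000 steps in every
replica, starting from one or both ends (never from the middle); with both
anchors it stays bound, and its detachment score — the mean clamped
peptide–floor probe distance, here 0.87 nm versus 2.53 nm — separates the
two systems. Higher scores mean weaker binding, which is what the ROC and
bootstrap analyses exploit on labelled peptide panels.

## Command line

```sh
hnmmc synth --out toy/                 # toy complex + Go table + configs
hnmmc coarse-grain in.pdb beads.pdb    # all-atom PDB -> 3-point beads
hnmmc run --structure beads.pdb --potential table.tsv \
          --hierarchy config.yaml --steps 100000 --replicas 10 \
          --seed 1 --out runs/
hnmmc analyze --replicas runs/probes.tsv --out analysis/
hnmmc roc --scores analysis/scores.tsv --labels labels.csv
hnmmc bootstrap --replicas runs/probes.tsv ... --labels labels.csv \
          --n-values 1,25,100 --out bootstrap.tsv
hnmmc campaign campaign.yaml --out campaign_runs/   # the whole workflow
```

Campaign configs are YAML; every option and default is documented in the
docstring of `hnmmc.pipeline` and echoed into the run manifest.

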
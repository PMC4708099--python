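"""Detachment analytics over replica trajectories.

Detachment is monitored through three CA-CA probe distances between the
peptide and the receptor floor: one at the N-terminal end, one at the
peptide middle and one at the C-terminal end.  Distances above a ceiling
(default 3 nm) count as full detachment and are clamped to the ceiling.
The per-peptide *detachment score* is the average clamped probe distance
over probes, snapshots and replicas; higher scores mean faster or fuller
detachment, so the non-binder is the positive class of the ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import StructureError

PROBE_LABELS = ("N", "mid", "C")
PATHWAY_CLASSES = ("C-first", "N-first", "simultaneous-ends",
                   "middle-first", "ends-inward", "stable")


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class ProbeSet:
    """Three peptide-receptor CA-CA probes, labelled N / mid / C.

    Each probe is ``(peptide_resnum, receptor_resnum)`` in author numbering;
    ``ceiling`` is the full-detachment clamp in nm.
    """

    peptide_chain: str
    receptor_chain: str
    n: tuple
    mid: tuple
    c: tuple
    ceiling: float = 3.0

    def __post_init__(self):
        if self.ceiling <= 0:
            raise AnalysisError("clamp ceiling must be positive")

    def resolve(self, structure):
        """CA bead index pairs ((pep, rec) x 3) for a structure."""
        idx = []
        for pep_res, rec_res in (self.n, self.mid, self.c):
            idx.append((structure.ca_index(self.peptide_chain, pep_res),
                        structure.ca_index(self.receptor_chain, rec_res)))
        return tuple(idx)


def probe_distances(coords, probes, resolved=None, structure=None):
    """Unclamped Euclidean CA-CA distances (d_N, d_mid, d_C) in nm.

    ``coords`` is an (n_beads, 3) snapshot; ``resolved`` the output of
    :meth:`ProbeSet.resolve` (or pass ``structure`` to resolve here).
    """
    if resolved is None:
        if structure is None:
            raise AnalysisError("need resolved probe indices or a structure")
        resolved = probes.resolve(structure)
    coords = np.asarray(coords)
    out = np.empty(3)
    for k, (i, j) in enumerate(resolved):
        out[k] = np.linalg.norm(coords[i] - coords[j])
    return out


def clamp_distance(d, ceiling=3.0):
    """Clamp distances above ``ceiling`` (full detachment) to the ceiling."""
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise AnalysisError("distance must be non-negative")
    out = np.minimum(arr, ceiling)
    return float(out) if out.ndim == 0 else out


@dataclass
class ReplicaSet:
    """Clamped probe-distance trajectories of all replicas of one peptide.

    ``distances`` has shape (n_replicas, n_snapshots, 3) with the probe
    order N, mid, C; all replicas share the ``steps`` snapshot grid.
    """

    peptide_id: str
    sequence: str
    steps: np.ndarray
    distances: np.ndarray
    ceiling: float = 3.0

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 3 or self.distances.shape[2] != 3:
            raise AnalysisError("distances must be (replicas, snapshots, 3)")
        if self.distances.shape[1] != len(self.steps):
            raise AnalysisError("snapshot grid does not match distances")
        if np.any(self.distances < 0) or np.any(self.distances > self.ceiling + 1e-9):
            raise AnalysisError("distances must lie in [0, ceiling]")

    @property
    def n_replicas(self):
        return self.distances.shape[0]

    # -- tidy serialization -------------------------------------------------
    def to_frame(self):
        R, S, _ = self.distances.shape
        rep, step, probe = np.meshgrid(np.arange(R), self.steps,
                                       np.arange(3), indexing="ij")
        return pd.DataFrame({
            "peptide": self.peptide_id,
            "sequence": self.sequence,
            "replica": rep.ravel(),
            "step": step.ravel(),
            "probe": np.asarray(PROBE_LABELS)[probe.ravel()],
            "distance_nm": self.distances.ravel(),
        })

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.9g")

    @classmethod
    def from_frame(cls, frame, ceiling=3.0):
        frame = frame.copy()
        pid = str(frame["peptide"].iloc[0])
        seq = str(frame["sequence"].iloc[0]) if "sequence" in frame else ""
        steps = np.sort(frame["step"].unique())
        reps = np.sort(frame["replica"].unique())
        dist = np.full((len(reps), len(steps), 3), np.nan)
        pmap = {p: k for k, p in enumerate(PROBE_LABELS)}
        rmap = {r: k for k, r in enumerate(reps)}
        smap = {s: k for k, s in enumerate(steps)}
        ri = frame["replica"].map(rmap).to_numpy()
        si = frame["step"].map(smap).to_numpy()
        pi = frame["probe"].map(pmap).to_numpy()
        dist[ri, si, pi] = frame["distance_nm"].to_numpy()
        if np.any(np.isnan(dist)):
            raise AnalysisError("replica table has missing (replica, step, probe) cells")
        return cls(pid, seq, steps, dist, ceiling=ceiling)

    @classmethod
    def from_tsv(cls, path, ceiling=3.0):
        return cls.from_frame(pd.read_csv(path, sep="\t"), ceiling=ceiling)


@dataclass(frozen=True)
class BindingRecord:
    """Experimental label of one peptide: binder/non-binder and/or IC50."""

    sequence: str
    label: str = None  # "binder" | "non-binder"
    ic50_nm: float = None
    ic50_threshold_nm: float = 500.0

    def __post_init__(self):
        if self.label is None and self.ic50_nm is None:
            raise AnalysisError("need a class label or an IC50 value")
        if self.label is not None and self.label not in ("binder", "non-binder"):
            raise AnalysisError(f"unknown class {self.label!r}")
        if self.label is not None and self.ic50_nm is not None:
            implied = "binder" if self.ic50_nm <= self.ic50_threshold_nm \
                else "non-binder"
            if implied != self.label:
                raise AnalysisError(
                    f"label {self.label!r} inconsistent with IC50 "
                    f"{self.ic50_nm} nM at threshold {self.ic50_threshold_nm} nM")

    @property
    def binding_class(self):
        if self.label is not None:
            return self.label
        return "binder" if self.ic50_nm <= self.ic50_threshold_nm else "non-binder"


# ----------------------------------------------------------------------
# curves and scores
# ----------------------------------------------------------------------

def mean_sem_curves(replicas):
    """Per-snapshot mean and standard error over replicas, per probe.

    Returns a DataFrame with columns step, probe, mean_nm, sem_nm; the SEM
    (sample SD / sqrt(n)) is NaN for a single replica.
    """
    d = replicas.distances
    n = d.shape[0]
    mean = d.mean(axis=0)
    if n > 1:
        sem = d.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.full(mean.shape, np.nan)
    rows = []
    for k, label in enumerate(PROBE_LABELS):
        rows.append(pd.DataFrame({"step": replicas.steps, "probe": label,
                                  "mean_nm": mean[:, k], "sem_nm": sem[:, k]}))
    return pd.concat(rows, ignore_index=True)


def per_replica_scores(replicas, probe_subset=None, step_window=None):
    """Mean clamped distance per replica (over probes and snapshots)."""
    d = replicas.distances
    if probe_subset is not None:
        cols = [PROBE_LABELS.index(p) for p in probe_subset]
        d = d[:, :, cols]
    if step_window is not None:
        lo, hi = step_window
        mask = (replicas.steps >= lo) & (replicas.steps <= hi)
        if not mask.any():
            raise AnalysisError("step window selects no snapshots")
        d = d[:, mask, :]
    return d.reshape(d.shape[0], -1).mean(axis=1)


def detachment_score(replicas, probe_subset=None, step_window=None):
    """Scalar detachment score: mean clamped probe distance (nm) over all
    probes, snapshots and replicas.  Higher = faster/fuller detachment."""
    return float(per_replica_scores(replicas, probe_subset, step_window).mean())


# ----------------------------------------------------------------------
# pathway classification
# ----------------------------------------------------------------------

def detachment_time(distances_1d, threshold, window):
    """First snapshot index from which the clamped distance stays above
    ``threshold`` for ``window`` consecutive snapshots; inf if never."""
    above = np.asarray(distances_1d) > threshold
    if window <= 1:
        hits = np.nonzero(above)[0]
        return float(hits[0]) if len(hits) else np.inf
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= window:
            return float(i - window + 1)
    return np.inf


def classify_pathway(replica_distances, threshold=2.0, window=10, margin=5):
    """Classify one replica's (n_snapshots, 3) probe trajectory.

    Detachment times are computed per probe; the class cascade is:
    ``stable`` (no probe detaches), ``C-first`` / ``N-first`` (one end leads
    the other by more than the margin and does not trail the middle by more
    than the margin), ``simultaneous-ends`` (end times within the margin of
    each other, both finite), ``middle-first`` (the middle leads both ends
    by more than the margin), else ``ends-inward``.  The margin absorbs the
    head start the middle probe gets from its larger starting distance in
    the bent bound pose.
    """
    d = np.asarray(replica_distances)
    if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] == 0:
        raise AnalysisError("expected a non-empty (n_snapshots, 3) trajectory")
    t_n, t_mid, t_c = (detachment_time(d[:, k], threshold, window)
                       for k in range(3))
    if np.isinf(t_n) and np.isinf(t_mid) and np.isinf(t_c):
        return "stable"
    if t_c + margin < t_n and t_c <= t_mid + margin:
        return "C-first"
    if t_n + margin < t_c and t_n <= t_mid + margin:
        return "N-first"
    if np.isfinite(t_n) and np.isfinite(t_c) and abs(t_n - t_c) <= margin:
        return "simultaneous-ends"
    if t_mid + margin < t_n and t_mid + margin < t_c:
        return "middle-first"
    return "ends-inward"


def pathway_counts(replicas, threshold=2.0, window=10, margin=5):
    """Pathway class counts over all replicas of a ReplicaSet."""
    counts = {c: 0 for c in PATHWAY_CLASSES}
    for r in range(replicas.n_replicas):
        counts[classify_pathway(replicas.distances[r], threshold, window,
                                margin)] += 1
    return counts


# ----------------------------------------------------------------------
# discrimination statistics
# ----------------------------------------------------------------------

def auroc(scores, labels):
    """Area under the ROC curve with non-binder as the positive class.

    Mann-Whitney formulation: the probability that a randomly chosen
    non-binder outscores a randomly chosen binder, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == "non-binder"
    neg = labels == "binder"
    if pos.sum() == 0 or neg.sum() == 0:
        raise AnalysisError("need both binders and non-binders")
    if pos.sum() + neg.sum() != len(labels):
        bad = set(labels) - {"binder", "non-binder"}
        raise AnalysisError(f"unknown labels {bad}")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - pos.sum() * (pos.sum() + 1) / 2.0
    return float(u / (pos.sum() * neg.sum()))


def pearson_r(scores, affinities):
    """Product-moment correlation between detachment scores and (possibly
    transformed) affinities.  Requires >= 3 points and non-constant vectors."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(affinities, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise AnalysisError("need >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("constant vector has no defined correlation")
    return float(stats.pearsonr(x, y).statistic)


def bootstrap_auroc_sd(replica_scores, labels, n_values, B=5000, seed=0):
    """SD of the AROC under replica-count bootstrap, for each n.

    ``replica_scores`` is (n_peptides, R): the per-replica detachment score
    of every peptide (all peptides must share the replica count R).  For
    each ``n`` in ``n_values``: B times, draw n replicas per peptide with
    replacement, average them into per-peptide scores, compute the AROC
    against ``labels``; return {n: SD of the B AROC values}.  Deterministic
    for a fixed seed.
    """
    X = np.asarray(replica_scores, dtype=float)
    if X.ndim != 2:
        raise AnalysisError("replica_scores must be (n_peptides, R)")
    P, R = X.shape
    labels = np.asarray(labels)
    pos = labels == "non-binder"
    n_pos = int(pos.sum())
    n_neg = P - n_pos
    if n_pos == 0 or n_neg == 0:
        raise AnalysisError("need both binders and non-binders")
    rng = np.random.default_rng(seed)
    out = {}
    for n in n_values:
        n = int(n)
        if not (1 <= n <= R):
            raise AnalysisError(f"n = {n} outside 1..{R}")
        draws = rng.integers(0, R, size=(B, P, n))
        means = X[np.arange(P)[None, :, None], draws].mean(axis=2)  # (B, P)
        ranks = stats.rankdata(means, axis=1)
        u = ranks[:, pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
        aurocs = u / (n_pos * n_neg)
        out[n] = float(np.std(aurocs))
    return out
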
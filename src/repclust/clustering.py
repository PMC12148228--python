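"""The three clustering families compared by the pipeline.

* Clonotyping: partition by V/J gene calls, then single-linkage
  clustering on CDRH3 amino-acid identity (clusters are the connected
  components of the thresholded identity graph — exactly equivalent to
  agglomerative single linkage with a flat cutoff).
* CDR-length partition clustering: partition by the 6-tuple of CDR
  lengths, optionally refined by CDRH3 identity (the sequence-only
  ablations of the structure-based approach).
* Structure clustering: within each CDR-length class, framework
  superposition (Kabsch) followed by agglomerative clustering on CDR
  backbone RMSD with a flat cutoff, optionally swept over cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .model_io import AntibodyRecord, BackboneModel, ClusterAssignment
from .pair_curation import normalized_levenshtein

__all__ = [
    "ClonotypeSettings",
    "StructureSettings",
    "clonotype",
    "partition_by_cdr_lengths",
    "cluster_length_identity",
    "superpose_framework",
    "cdr_rmsd",
    "structure_cluster",
    "structure_cluster_sweep",
]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _canonical_assignment(ids: Sequence[str], uf: _UnionFind) -> dict[str, int]:
    """Component ids renumbered by first appearance in sorted id order,
    so the assignment is invariant to input order."""
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for i in order:
        root = uf.find(i)
        if root not in remap:
            remap[root] = len(remap)
        out[ids[i]] = remap[root]
    return out


# ---------------------------------------------------------------------------
# Clonotyping

@dataclass
class ClonotypeSettings:
    """Partition keys and identity cutoff for clonotype assignment.

    The default — matching V and J calls plus CDRH3 identity >= 0.80 —
    is the conventional clonotyping rule; the alternative settings
    (V-only matching, 0.70 cutoff, no gene matching) are the stringency
    variants the comparison sweeps over. Identity uses the max-length
    denominator by default; the sum-of-lengths form is available to
    match the pair-annotation convention.
    """

    v_match: bool = True
    j_match: bool = True
    identity_cutoff: float = 0.80
    require_same_cdrh3_length: bool = False
    identity_denominator: str = "max"  # {sum, max}

    def __post_init__(self):
        if not (0.0 < self.identity_cutoff <= 1.0):
            raise ValueError("identity_cutoff must be in (0,1]")
        if self.identity_denominator not in ("sum", "max"):
            raise ValueError("identity_denominator must be 'sum' or 'max'")


def clonotype(
    records: Sequence[AntibodyRecord], settings: ClonotypeSettings | None = None
) -> ClusterAssignment:
    """Single-linkage clonotyping over V/J partitions.

    Within each partition an edge connects two records whose CDRH3
    identity meets the cutoff; clusters are connected components, so
    chains of pairwise-similar sequences merge (transitive single
    linkage). Every record is assigned.
    """
    settings = settings or ClonotypeSettings()
    missing = [
        r.antibody_id
        for r in records
        if (settings.v_match and not r.v_call) or (settings.j_match and not r.j_call)
    ]
    if missing:
        raise ValueError(f"records missing required gene calls: {missing}")
    ids = [r.antibody_id for r in records]
    uf = _UnionFind(len(records))
    partitions: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        key = (
            r.v_call if settings.v_match else None,
            r.j_call if settings.j_match else None,
            len(r.cdrh3) if settings.require_same_cdrh3_length else None,
        )
        partitions.setdefault(key, []).append(i)
    cutoff = settings.identity_cutoff
    for members in partitions.values():
        # bucket identical CDRH3s first; identical sequences always merge
        by_seq: dict[str, list[int]] = {}
        for i in members:
            by_seq.setdefault(records[i].cdrh3, []).append(i)
        seqs = sorted(by_seq)
        reps = [by_seq[s][0] for s in seqs]
        for s, idxs in by_seq.items():
            for other in idxs[1:]:
                uf.union(idxs[0], other)
        for a in range(len(seqs)):
            la = len(seqs[a])
            for b in range(a + 1, len(seqs)):
                lb = len(seqs[b])
                # length bound: distance >= |la-lb| caps achievable identity
                if settings.identity_denominator == "max":
                    best = 1.0 - abs(la - lb) / max(la, lb)
                else:
                    best = 1.0 - abs(la - lb) / (la + lb)
                if best < cutoff:
                    continue
                ident = normalized_levenshtein(
                    seqs[a], seqs[b], settings.identity_denominator
                )
                if ident >= cutoff:
                    uf.union(reps[a], reps[b])
    return ClusterAssignment(
        method="clonotype", settings=asdict(settings), assignment=_canonical_assignment(ids, uf)
    )


# ---------------------------------------------------------------------------
# CDR-length partition clustering

def partition_by_cdr_lengths(records: Sequence[AntibodyRecord]) -> dict[str, tuple[int, ...]]:
    """Label each record with its 6-tuple of CDR lengths (H1,H2,H3,L1,L2,L3)."""
    labels = {}
    for r in records:
        for chain in ("heavy",):
            for cdr in ("CDR1", "CDR2", "CDR3"):
                if cdr not in r.regions.get(chain, {}):
                    raise ValueError(f"{r.antibody_id}: missing heavy {cdr} boundary")
        labels[r.antibody_id] = r.cdr_lengths()
    return labels


def cluster_length_identity(
    records: Sequence[AntibodyRecord],
    identity_cutoff: float | None = None,
    identity_denominator: str = "max",
) -> ClusterAssignment:
    """CDR-length partition clustering, optionally refined by identity.

    With ``identity_cutoff=None`` the clusters are the length partitions
    themselves; with a cutoff, single-linkage on CDRH3 identity runs
    within each partition (never merging across partitions).
    """
    labels = partition_by_cdr_lengths(records)
    ids = [r.antibody_id for r in records]
    uf = _UnionFind(len(records))
    partitions: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        partitions.setdefault(labels[r.antibody_id], []).append(i)
    for members in partitions.values():
        if identity_cutoff is None:
            for other in members[1:]:
                uf.union(members[0], other)
        else:
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    ident = normalized_levenshtein(
                        records[members[a]].cdrh3,
                        records[members[b]].cdrh3,
                        identity_denominator,
                    )
                    if ident >= identity_cutoff:
                        uf.union(members[a], members[b])
    method = "length" if identity_cutoff is None else "length+identity"
    return ClusterAssignment(
        method=method,
        settings={"identity_cutoff": identity_cutoff, "identity_denominator": identity_denominator},
        assignment=_canonical_assignment(ids, uf),
    )


# ---------------------------------------------------------------------------
# Structure clustering

@dataclass
class StructureSettings:
    rmsd_cutoff: float = 1.25  # Å
    sweep: tuple[float, ...] = (1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5)
    backbone_atoms: tuple[str, ...] = ("N", "CA", "C")
    linkage: str = "single"  # {single, average}

    def __post_init__(self):
        if self.rmsd_cutoff <= 0 or any(c <= 0 for c in self.sweep):
            raise ValueError("RMSD cutoffs must be positive")
        if self.linkage not in ("single", "average"):
            raise ValueError("linkage must be 'single' or 'average'")


def superpose_framework(
    model_a: BackboneModel, model_b: BackboneModel
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of framework backbone atoms.

    Returns (rotation, translation, framework RMSD) such that applying
    ``R @ x + t`` to model_b's coordinates superposes its framework onto
    model_a's. The rotation is proper (det +1; Kabsch with reflection
    guard).
    """
    fa = model_a.coords(cdr=False)
    fb = model_b.coords(cdr=False)
    if fa.shape != fb.shape:
        raise ValueError(
            f"framework atom count mismatch: {model_a.antibody_id} has {fa.shape[0]}, "
            f"{model_b.antibody_id} has {fb.shape[0]}"
        )
    ca, cb = fa.mean(axis=0), fb.mean(axis=0)
    H = (fb - cb).T @ (fa - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = (R @ fb.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fa) ** 2, axis=1))))
    return R, t, rmsd


def cdr_rmsd(model_a: BackboneModel, model_b: BackboneModel) -> float:
    """CDR backbone RMSD after framework superposition (Å)."""
    if model_a.cdr_length_class() != model_b.cdr_length_class():
        raise ValueError(
            f"CDR length class mismatch: {model_a.antibody_id} "
            f"{model_a.cdr_length_class()} vs {model_b.antibody_id} "
            f"{model_b.cdr_length_class()}"
        )
    R, t, _ = superpose_framework(model_a, model_b)
    xa = model_a.coords(cdr=True)
    xb = (R @ model_b.coords(cdr=True).T).T + t
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def _cluster_class(models: list[BackboneModel], cutoff: float, linkage: str, uf, idx):
    n = len(models)
    if n == 1:
        return
    dm = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            dm[a, b] = dm[b, a] = cdr_rmsd(models[a], models[b])
    if linkage == "single":
        for a in range(n):
            for b in range(a + 1, n):
                if dm[a, b] <= cutoff:
                    uf.union(idx[a], idx[b])
    else:
        from scipy.cluster.hierarchy import average as avg_linkage, fcluster
        from scipy.spatial.distance import squareform

        Z = avg_linkage(squareform(dm, checks=False))
        flat = fcluster(Z, t=cutoff, criterion="distance")
        groups: dict[int, list[int]] = {}
        for a, g in enumerate(flat):
            groups.setdefault(int(g), []).append(a)
        for members in groups.values():
            for other in members[1:]:
                uf.union(idx[members[0]], idx[other])


def structure_cluster(
    models: Sequence[BackboneModel],
    settings: StructureSettings | None = None,
    rmsd_cutoff: float | None = None,
) -> ClusterAssignment:
    """Agglomerative structure clustering within CDR-length classes.

    Models are partitioned by their CDR-length class (structures with
    differing CDR lengths are never compared); within a class, clusters
    merge while the inter-cluster CDR RMSD is at or below the cutoff.
    """
    settings = settings or StructureSettings()
    cutoff = settings.rmsd_cutoff if rmsd_cutoff is None else rmsd_cutoff
    ids = [m.antibody_id for m in models]
    uf = _UnionFind(len(models))
    classes: dict[tuple, list[int]] = {}
    for i, m in enumerate(models):
        classes.setdefault(m.cdr_length_class(), []).append(i)
    for cls, idx in classes.items():
        _cluster_class([models[i] for i in idx], cutoff, settings.linkage, uf, idx)
    return ClusterAssignment(
        method="structure",
        settings={**asdict(settings), "rmsd_cutoff": cutoff},
        assignment=_canonical_assignment(ids, uf),
    )


def structure_cluster_sweep(
    models: Sequence[BackboneModel], settings: StructureSettings | None = None
) -> dict[float, ClusterAssignment]:
    """One assignment per cutoff in ``settings.sweep`` (default 1–2.5 Å)."""
    settings = settings or StructureSettings()
    return {c: structure_cluster(models, settings, rmsd_cutoff=c) for c in settings.sweep}
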
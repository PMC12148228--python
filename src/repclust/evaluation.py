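"""Cluster metrics, annotated-pair recovery and the random-clustering null.

The headline comparison table reports, per clustering run: coverage
(number of clustered antibodies), number of clusters, mean cluster
size, number and mean size of multiple-occupancy clusters (two or more
distinct antibodies), and recovery of the annotated functionally
similar pairs — overall and restricted to low-sequence-similarity
pairs (CDRH3 identity < 0.8).

The random clustering rate is the expected number of annotated pairs
co-clustered when antibodies are assigned uniformly at random to
clusters of a fixed size distribution; it is estimated by Monte Carlo
(1000 replicates by default) and computed in closed form alongside:
E = |pairs| * Σ s(s−1) / (n(n−1)), which holds for overlapping pairs by
linearity of expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import AntibodyPair, AntibodyRecord, ClusterAssignment

__all__ = [
    "ClusterMetrics",
    "RandomRateResult",
    "round_half_up",
    "cluster_metrics",
    "pair_confusion",
    "random_clustering_rate",
    "sequence_descriptors",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding (printed percentages, e.g. 100*24/213 -> 11.27)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClusterMetrics:
    method: str
    n_clustered: int
    n_clusters: int
    mean_size: float
    n_multi: int
    mean_multi_size: float
    n_pairs: int
    pairs_recovered: int
    pairs_recovered_pct: float
    low_identity_pairs_recovered: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def cluster_metrics(
    assignment: ClusterAssignment,
    pairs: Sequence[AntibodyPair],
    low_identity_cutoff: float = 0.8,
) -> ClusterMetrics:
    """Summary metrics for one clustering run against the annotated pairs.

    A pair is recovered iff both members share a cluster id (pairs with
    an unassigned member count as not recovered). Low-identity recovery
    is restricted to pairs with CDRH3 identity below the cutoff.
    Percentages are half-up rounded to two decimals.
    """
    if not assignment.assignment:
        raise ValueError("empty cluster assignment")
    sizes = assignment.sizes
    n_clustered = assignment.n_clustered
    n_clusters = assignment.n_clusters
    multi = [s for s in sizes if s >= 2]
    recovered = [p for p in pairs if assignment.co_clustered(p.id_a, p.id_b)]
    low_recovered = [p for p in recovered if p.cdrh3_identity < low_identity_cutoff]
    pct = round_half_up(100.0 * len(recovered) / len(pairs)) if pairs else 0.0
    return ClusterMetrics(
        method=assignment.method,
        n_clustered=n_clustered,
        n_clusters=n_clusters,
        mean_size=round_half_up(n_clustered / n_clusters),
        n_multi=len(multi),
        mean_multi_size=round_half_up(sum(multi) / len(multi)) if multi else 0.0,
        n_pairs=len(pairs),
        pairs_recovered=len(recovered),
        pairs_recovered_pct=pct,
        low_identity_pairs_recovered=len(low_recovered),
    )


def pair_confusion(
    assignment: ClusterAssignment,
    curated_ids: Sequence[str],
    pairs: Sequence[AntibodyPair],
) -> tuple[int, int, float, float]:
    """(TP, FP, sensitivity, precision) over curated-antibody pairs.

    TP: co-clustered curated pairs that are annotated pairs; FP:
    co-clustered curated pairs that are not. Precision is defined as
    1.0 when no curated pair is co-clustered at all.
    """
    annotated = {p.key for p in pairs}
    ids = sorted(set(curated_ids))
    tp = fp = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if assignment.co_clustered(ids[i], ids[j]):
                if (ids[i], ids[j]) in annotated:
                    tp += 1
                else:
                    fp += 1
    sensitivity = tp / len(pairs) if pairs else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    return tp, fp, sensitivity, precision


@dataclass(frozen=True)
class RandomRateResult:
    mean_rate: float
    analytic_rate: float
    std_rate: float  # std of per-replicate co-clustered counts
    n_reps: int
    seed: int

    @property
    def mc_standard_error(self) -> float:
        return self.std_rate / np.sqrt(self.n_reps)


def random_clustering_rate(
    sizes: Sequence[int],
    n_items: int,
    pairs: Sequence[tuple[int, int]] | Sequence[AntibodyPair],
    n_reps: int = 1000,
    seed: int = 0,
    item_ids: Sequence[str] | None = None,
) -> RandomRateResult:
    """Expected number of annotated pairs co-clustered under random
    assignment to clusters of the given sizes.

    Per replicate, a uniform random permutation of the items fills the
    size template and co-clustered annotated pairs are counted; the
    mean over replicates is returned together with the closed-form
    expectation. ``pairs`` may be index pairs over the items or
    :class:`AntibodyPair` objects (then ``item_ids`` maps ids to items).
    """
    sizes = list(sizes)
    if sum(sizes) != n_items:
        raise ValueError(f"sizes sum to {sum(sizes)}, expected n_items={n_items}")
    if pairs and isinstance(pairs[0], AntibodyPair):
        if item_ids is None:
            raise ValueError("item_ids required when pairs are AntibodyPair objects")
        index = {aid: i for i, aid in enumerate(item_ids)}
        idx_pairs = [(index[p.id_a], index[p.id_b]) for p in pairs]
    else:
        idx_pairs = [(int(a), int(b)) for a, b in pairs]
    a_idx = np.array([a for a, _ in idx_pairs], dtype=np.int64)
    b_idx = np.array([b for _, b in idx_pairs], dtype=np.int64)
    cluster_of_slot = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps)
    item_cluster = np.empty(n_items, dtype=np.int64)
    for rep in range(n_reps):
        perm = rng.permutation(n_items)
        item_cluster[perm] = cluster_of_slot
        counts[rep] = int(np.sum(item_cluster[a_idx] == item_cluster[b_idx]))
    s = np.asarray(sizes, dtype=float)
    analytic = len(idx_pairs) * float(np.sum(s * (s - 1))) / (n_items * (n_items - 1))
    return RandomRateResult(
        mean_rate=float(counts.mean()),
        analytic_rate=analytic,
        std_rate=float(counts.std(ddof=1)) if n_reps > 1 else 0.0,
        n_reps=n_reps,
        seed=seed,
    )


def sequence_descriptors(
    records: Sequence[AntibodyRecord],
    mutation_counts: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-record sequence descriptor table for ordination (PCA etc.).

    Columns: amino-acid length of each heavy-chain region (FR1..FR4,
    CDR1..CDR3), full receptor length, V- and J-segment mutation counts
    (0 with ``mutations_missing=True`` when unknown).
    """
    mutation_counts = mutation_counts or {}
    rows = []
    for r in records:
        heavy = r.regions.get("heavy", {})
        if not heavy:
            raise ValueError(f"{r.antibody_id}: missing heavy-chain regions")
        row = {"antibody_id": r.antibody_id, "source": r.source}
        for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"):
            if region not in heavy:
                raise ValueError(f"{r.antibody_id}: missing heavy {region} boundary")
            s, e = heavy[region]
            row[f"{region.lower()}_len"] = e - s
        row["receptor_len"] = len(r.heavy_aa) + len(r.light_aa or "")
        vm_jm = mutation_counts.get(r.antibody_id)
        row["v_mutations"], row["j_mutations"] = vm_jm if vm_jm else (0, 0)
        row["mutations_missing"] = vm_jm is None
        rows.append(row)
    return pd.DataFrame(rows)
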
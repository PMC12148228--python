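"""Curation of functionally similar antibody pairs from epitope tables.

Two antibodies binding the same antigen are called functionally similar
when the Jaccard index of their epitope residue sets is at least a
threshold (default 0.75). Retained pairs are annotated with their CDRH3
sequence identity (normalized Levenshtein) and whether all six CDR
regions have equal length — the quantities the downstream clustering
comparison conditions on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from .model_io import AntibodyPair, AntibodyRecord, EpitopeAnnotation

__all__ = [
    "CurationConfig",
    "jaccard_overlap",
    "levenshtein_distance",
    "normalized_levenshtein",
    "select_pairs",
    "functional_clusters",
]


@dataclass
class CurationConfig:
    """Filters and thresholds for pair selection."""

    jaccard_threshold: float = 0.75
    top_antigens: int = 50
    require_xray: bool = True
    require_human: bool = True
    exclude_scfv: bool = True
    require_chain_assignment: bool = True
    levenshtein_denominator: str = "sum"  # {sum, max}

    def __post_init__(self):
        if not (0.0 < self.jaccard_threshold <= 1.0):
            raise ValueError("jaccard_threshold must be in (0,1]")
        if self.top_antigens < 1:
            raise ValueError("top_antigens must be >= 1")
        if self.levenshtein_denominator not in ("sum", "max"):
            raise ValueError("levenshtein_denominator must be 'sum' or 'max'")


def jaccard_overlap(e1: Iterable, e2: Iterable) -> float:
    """Jaccard index |e1 ∩ e2| / |e1 ∪ e2| of two residue sets."""
    s1, s2 = set(e1), set(e2)
    if not s1 or not s2:
        raise ValueError("epitope residue sets must be non-empty")
    return len(s1 & s2) / len(s1 | s2)


def levenshtein_distance(c1: str, c2: str) -> int:
    """Absolute Levenshtein (edit) distance between two sequences."""
    if not c1 or not c2:
        return max(len(c1), len(c2))
    return edlib.align(c1, c2, task="distance")["editDistance"]


def normalized_levenshtein(c1: str, c2: str, denominator: str = "sum") -> float:
    """Levenshtein-based sequence identity in [0,1].

    denominator="sum": 1 − L/(len(c1)+len(c2)); denominator="max":
    1 − L/max(len). Identical sequences give 1.0 under either form.
    """
    if not c1 and not c2:
        raise ValueError("both sequences empty")
    dist = levenshtein_distance(c1, c2)
    if denominator == "sum":
        denom = len(c1) + len(c2)
    elif denominator == "max":
        denom = max(len(c1), len(c2))
    else:
        raise ValueError("denominator must be 'sum' or 'max'")
    return 1.0 - dist / denom


def _passes_filters(ep: EpitopeAnnotation, config: CurationConfig) -> bool:
    if config.require_xray and ep.structure_method != "xray":
        return False
    if config.require_human and ep.species.lower() != "human":
        return False
    if config.exclude_scfv and ep.scfv:
        return False
    if config.require_chain_assignment and not ep.chains_assigned:
        return False
    return True


def select_pairs(
    epitopes: Sequence[EpitopeAnnotation],
    records: Sequence[AntibodyRecord],
    config: CurationConfig | None = None,
) -> list[AntibodyPair]:
    """Select functionally similar antibody pairs.

    Pipeline: (1) keep assay-positive epitope entries with structures;
    (2) restrict to the ``top_antigens`` antigens with most qualifying
    entries (ties by antigen id); (3) pair within antigens on Jaccard ≥
    threshold; (4) drop pairs whose members fail the structure/species/
    scFv/chain filters; (5) drop pairs with identical full receptor
    sequence or identical CDRH3; (6) annotate. Filters run after pairing
    so per-pair drop provenance is observable; the retained set equals
    filtering first.
    """
    config = config or CurationConfig()
    by_id = {r.antibody_id: r for r in records}
    for ep in epitopes:
        if ep.antibody_id not in by_id:
            raise KeyError(f"epitope references unknown antibody_id {ep.antibody_id!r}")
        rec = by_id[ep.antibody_id]
        if "CDR3" not in rec.regions.get("heavy", {}):
            raise KeyError(f"antibody {ep.antibody_id!r} lacks CDRH3 boundaries")

    # (1) assay-positive entries with a structure flag present
    qualifying = [ep for ep in epitopes if ep.assay_positive]

    # (2) top antigens by qualifying epitope count; ties by antigen id
    counts: dict[str, int] = {}
    for ep in qualifying:
        counts[ep.antigen_id] = counts.get(ep.antigen_id, 0) + 1
    ranked = sorted(counts, key=lambda a: (-counts[a], a))
    keep_antigens = set(ranked[: config.top_antigens])

    by_antigen: dict[str, list[EpitopeAnnotation]] = {}
    for ep in qualifying:
        if ep.antigen_id in keep_antigens:
            by_antigen.setdefault(ep.antigen_id, []).append(ep)

    pairs: dict[tuple[str, str], AntibodyPair] = {}
    for antigen, eps in sorted(by_antigen.items()):
        # (3) all within-antigen pairwise comparisons
        for i in range(len(eps)):
            for j in range(i + 1, len(eps)):
                a, b = eps[i], eps[j]
                if a.antibody_id == b.antibody_id:
                    continue
                jac = jaccard_overlap(a.residues, b.residues)
                if jac < config.jaccard_threshold:
                    continue
                # (4) member-level filters
                if not (_passes_filters(a, config) and _passes_filters(b, config)):
                    continue
                ra, rb = by_id[a.antibody_id], by_id[b.antibody_id]
                # (5) redundancy: identical receptor or identical CDRH3
                full_a = ra.heavy_aa + (ra.light_aa or "")
                full_b = rb.heavy_aa + (rb.light_aa or "")
                if full_a == full_b or ra.cdrh3 == rb.cdrh3:
                    continue
                pair = AntibodyPair(
                    id_a=a.antibody_id,
                    id_b=b.antibody_id,
                    jaccard=jac,
                    cdrh3_identity=normalized_levenshtein(
                        ra.cdrh3, rb.cdrh3, config.levenshtein_denominator
                    ),
                    same_cdr_lengths=ra.cdr_lengths() == rb.cdr_lengths(),
                )
                # keep the highest-overlap annotation when the same pair
                # arises from several epitope entries
                prev = pairs.get(pair.key)
                if prev is None or pair.jaccard > prev.jaccard:
                    pairs[pair.key] = pair
    return sorted(pairs.values(), key=lambda p: p.key)


def functional_clusters(pairs: Sequence[AntibodyPair]) -> list[set[str]]:
    """Connected components over retained pairs — the derived view of
    functional antibody-pair clusters (an antibody may chain several
    pairs into one group)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        for node in p.key:
            parent.setdefault(node, node)
        ra, rb = find(p.id_a), find(p.id_b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return sorted(comps.values(), key=lambda s: (-len(s), sorted(s)))
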
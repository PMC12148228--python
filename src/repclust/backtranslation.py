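"""Germline-guided backtranslation of antibody amino-acid sequences.

An antibody chain is compared against germline V and J nucleotide
references (translated) to find the most similar reference of each
segment. Reference-covered amino acids are rebuilt codon by codon: among
the codons encoding the observed amino acid, the one requiring the
fewest single-nucleotide substitutions from the reference codon wins;
ties are broken by substitution likelihood under a trimer context model
obtained by aggregating a fivemer substitution-likelihood table. When a
codon needs more than one substitution, every mutation order is scored
(context re-derived after each step) and the most likely order is used.

Junction (CDR3) positions have no reference codon; they are filled with
the highest-frequency human codon for each amino acid, a deterministic
rule isolated in :data:`JUNCTION_CODON`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .model_io import AntibodyRecord, ReferenceGene, SubstitutionModel

__all__ = [
    "CODONS_FOR_AA",
    "JUNCTION_CODON",
    "GermlineAlignment",
    "CodonChoice",
    "BacktranslationResult",
    "aggregate_fivemer_to_trimer",
    "site_likelihood",
    "choose_codon",
    "align_to_references",
    "backtranslate",
    "backtranslate_with_stats",
]

#: amino acid -> tuple of codons encoding it (standard nuclear code)
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] += (_codon,)
CODONS_FOR_AA = {aa: tuple(sorted(cs)) for aa, cs in CODONS_FOR_AA.items()}

#: highest-frequency human codon per amino acid, used for junction fill
JUNCTION_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Fivemer -> trimer aggregation

def aggregate_fivemer_to_trimer(fivemer: SubstitutionModel) -> SubstitutionModel:
    """Aggregate fivemer substitution likelihoods to trimer likelihoods.

    For each trimer and each mutating position (start, center, end), the
    likelihood of each substitution is the arithmetic mean over the 16
    fivemers that embed the trimer with its mutating base at the fivemer
    center (e.g. the 16 fivemers N-AAA-N for the center base of "AAA").
    The standard deviation over the 16 values is recorded per entry.
    """
    if fivemer.context_len != 5:
        raise ValueError("input model must be a fivemer model")
    offsets = {"start": 2, "center": 1, "end": 0}  # trimer start index in fivemer
    table: dict[tuple[str, str, str], float] = {}
    dispersion: dict[tuple[str, str, str], float] = {}
    for pos, off in offsets.items():
        for trimer in ("".join(t) for t in itertools.product(_BASES, repeat=3)):
            ref_base = trimer[{"start": 0, "center": 1, "end": 2}[pos]]
            for target in _BASES:
                if target == ref_base:
                    continue
                values = []
                for flanks in itertools.product(_BASES, repeat=2):
                    fm = list("NNNNN")
                    fm[off : off + 3] = trimer
                    free = [i for i in range(5) if fm[i] == "N"]
                    for i, b in zip(free, flanks):
                        fm[i] = b
                    ctx = "".join(fm)
                    key = ("center", ctx, target)
                    if key not in fivemer.table:
                        raise KeyError(f"missing fivemer context entry {key}")
                    values.append(fivemer.table[key])
                n = len(values)
                mean = sum(values) / n
                var = sum((v - mean) ** 2 for v in values) / n
                table[(pos, trimer, target)] = mean
                dispersion[(pos, trimer, target)] = math.sqrt(var)
    return SubstitutionModel(context_len=3, table=table, dispersion=dispersion)


def site_likelihood(seq: Sequence[str], i: int, target: str, model: SubstitutionModel) -> float:
    """Likelihood of substituting position ``i`` of ``seq`` to ``target``
    under a trimer model. Interior positions use the center sub-table;
    the first/last position of the sequence uses the start/end sub-table
    (their context windows cross the terminus)."""
    if model.context_len != 3:
        raise ValueError("site_likelihood requires a trimer model")
    n = len(seq)
    if n < 3:
        raise ValueError("sequence shorter than one context window")
    if i == 0:
        pos, ctx = "start", "".join(seq[0:3])
    elif i == n - 1:
        pos, ctx = "end", "".join(seq[n - 3 : n])
    else:
        pos, ctx = "center", "".join(seq[i - 1 : i + 2])
    return model.likelihood(pos, ctx, target)


# ---------------------------------------------------------------------------
# Codon choice

@dataclass(frozen=True)
class CodonChoice:
    codon: str
    n_substitutions: int
    likelihood: float  # max-over-orders path likelihood; 1.0 for 0 subs
    lexicographic_tie: bool = False


def _path_likelihood(
    ref_codon: str,
    new_codon: str,
    model: SubstitutionModel,
    left: str,
    right: str,
) -> float:
    """Max over mutation orders of the product of stepwise trimer
    likelihoods, context updated after each step."""
    diff = [p for p in range(3) if ref_codon[p] != new_codon[p]]
    if not diff:
        return 1.0
    off = len(left)
    best = 0.0
    for order in itertools.permutations(diff):
        cur = list(left + ref_codon + right)
        prod = 1.0
        for p in order:
            prod *= site_likelihood(cur, off + p, new_codon[p], model)
            cur[off + p] = new_codon[p]
        best = max(best, prod)
    return best


def choose_codon(
    target_aa: str,
    ref_codon: str,
    trimer_model: SubstitutionModel,
    left_flank: str = "",
    right_flank: str = "",
) -> CodonChoice:
    """Pick the codon for ``target_aa`` closest to ``ref_codon``.

    Minimal Hamming distance wins; among equals the maximal path
    likelihood wins; remaining ties resolve to the lexicographically
    smallest codon with ``lexicographic_tie`` set. Flanks are the (up to
    two) neighbouring nucleotides actually adjacent in the sequence —
    pass "" only at a true terminus.
    """
    if target_aa == "*" or target_aa not in CODONS_FOR_AA:
        raise ValueError(f"cannot encode {target_aa!r}: not a standard amino acid")
    if len(ref_codon) != 3:
        raise ValueError(f"ref_codon must have length 3, got {ref_codon!r}")
    left = left_flank[-2:]
    right = right_flank[:2]
    scored = []
    for cand in CODONS_FOR_AA[target_aa]:
        dist = sum(a != b for a, b in zip(cand, ref_codon))
        lik = _path_likelihood(ref_codon, cand, trimer_model, left, right)
        scored.append((dist, -lik, cand))
    scored.sort()
    dist, neg_lik, cand = scored[0]
    tie = len(scored) > 1 and scored[1][:2] == (dist, neg_lik)
    return CodonChoice(cand, dist, -neg_lik, tie)


# ---------------------------------------------------------------------------
# Reference alignment

def _make_aligner() -> Align.PairwiseAligner:
    # pinned scoring: BLOSUM62, affine gaps -11/-1, local mode so the
    # germline segment aligns to its portion of the chain
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


@dataclass
class GermlineAlignment:
    """Pairing of chain amino-acid positions to reference codons."""

    record_id: str
    v_gene: ReferenceGene
    j_gene: ReferenceGene
    #: chain aa position -> (segment, reference codon)
    codon_map: dict[int, tuple[str, str]]
    junction: tuple[int, int]  # uncovered half-open aa interval
    v_score: float
    j_score: float
    v_tied: tuple[str, ...] = ()
    j_tied: tuple[str, ...] = ()

    @property
    def covered_positions(self) -> list[int]:
        return sorted(self.codon_map)


def _segment_mapping(aa_seq: str, gene: ReferenceGene, aligner) -> tuple[float, dict[int, str]]:
    """Best local alignment of the gene translation to the chain; returns
    (score, chain aa position -> reference codon)."""
    ref_aa = gene.translation
    alns = aligner.align(aa_seq, ref_aa)
    if len(alns) == 0:
        return float("-inf"), {}
    aln = alns[0]
    mapping: dict[int, str] = {}
    t_blocks, q_blocks = aln.aligned
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for k in range(te - ts):
            qpos = qs + k
            mapping[ts + k] = gene.coding_nt[3 * qpos : 3 * qpos + 3]
    return aln.score, mapping


def align_to_references(
    aa_seq: str,
    references: Sequence[ReferenceGene],
    record_id: str = "",
) -> GermlineAlignment:
    """Select the most similar V and J references for a chain.

    The best amino-acid alignment score wins per segment; ties are
    reported in ``v_tied``/``j_tied`` for nucleotide-level resolution by
    :func:`backtranslate`. The junction is the maximal uncovered
    interval between V and J coverage.
    """
    v_refs = [g for g in references if g.segment == "V"]
    j_refs = [g for g in references if g.segment == "J"]
    if not v_refs or not j_refs:
        raise ValueError("reference set must contain at least one V and one J gene")
    aligner = _make_aligner()

    def best(refs):
        scored = []
        for g in sorted(refs, key=lambda g: g.name):
            score, mapping = _segment_mapping(aa_seq, g, aligner)
            scored.append((score, g, mapping))
        top = max(s for s, _, _ in scored)
        tied = [(g, m) for s, g, m in scored if s == top]
        return top, tied

    v_score, v_tied = best(v_refs)
    j_score, j_tied = best(j_refs)
    v_gene, v_map = v_tied[0]
    j_gene, j_map = j_tied[0]
    codon_map = _merge_maps(v_map, j_map)
    junction = _junction_interval(len(aa_seq), codon_map)
    return GermlineAlignment(
        record_id=record_id,
        v_gene=v_gene,
        j_gene=j_gene,
        codon_map=codon_map,
        junction=junction,
        v_score=v_score,
        j_score=j_score,
        v_tied=tuple(g.name for g, _ in v_tied),
        j_tied=tuple(g.name for g, _ in j_tied),
    )


def _merge_maps(v_map: dict[int, str], j_map: dict[int, str]) -> dict[int, tuple[str, str]]:
    codon_map = {pos: ("V", codon) for pos, codon in v_map.items()}
    for pos, codon in j_map.items():
        codon_map.setdefault(pos, ("J", codon))  # V wins overlaps
    return codon_map


def _junction_interval(n: int, codon_map: Mapping[int, object]) -> tuple[int, int]:
    uncovered = [p for p in range(n) if p not in codon_map]
    if not uncovered:
        return (0, 0)
    return (uncovered[0], uncovered[-1] + 1)


# ---------------------------------------------------------------------------
# Full-chain reconstruction

@dataclass
class BacktranslationResult:
    record: AntibodyRecord
    alignment: GermlineAlignment
    n_substitutions: int
    covered_nt: int
    log_likelihood: float


def _reconstruct(
    aa_seq: str,
    v_gene: ReferenceGene,
    v_map: dict[int, str],
    j_gene: ReferenceGene,
    j_map: dict[int, str],
    trimer_model: SubstitutionModel,
) -> tuple[str, int, int, float]:
    """Left-to-right codon reconstruction against a reference scaffold.

    Left context comes from the already-built sequence, right context
    from the yet-unmodified scaffold. Returns (nt, n_subs, covered_nt,
    log-likelihood)."""
    codon_map = _merge_maps(v_map, j_map)
    scaffold = []
    for i, aa in enumerate(aa_seq):
        if i in codon_map:
            scaffold.append(codon_map[i][1])
        else:
            scaffold.append(JUNCTION_CODON[aa])
    scaffold_nt = "".join(scaffold)
    built: list[str] = []
    n_subs = 0
    covered = 0
    loglik = 0.0
    for i, aa in enumerate(aa_seq):
        left = "".join(built)[-2:]
        right = scaffold_nt[3 * (i + 1) : 3 * (i + 1) + 2]
        if i in codon_map:
            choice = choose_codon(aa, codon_map[i][1], trimer_model, left, right)
            built.append(choice.codon)
            n_subs += choice.n_substitutions
            covered += 3
            if choice.likelihood > 0:
                loglik += math.log(choice.likelihood)
        else:
            built.append(JUNCTION_CODON[aa])
    return "".join(built), n_subs, covered, loglik


def backtranslate_with_stats(
    record: AntibodyRecord,
    references: Sequence[ReferenceGene],
    trimer_model: SubstitutionModel,
) -> BacktranslationResult:
    """Backtranslate a record's heavy chain, resolving reference ties.

    Amino-acid-level reference ties are resolved by fewest total
    nucleotide substitutions, then by higher total substitution
    likelihood, then by gene name. The returned record translates back
    to the input amino-acid sequence exactly.
    """
    if "CDR3" not in record.regions.get("heavy", {}):
        raise ValueError(f"{record.antibody_id}: CDRH3 boundaries required")
    aa_seq = record.heavy_aa
    aln = align_to_references(aa_seq, references, record.antibody_id)
    aligner = _make_aligner()
    by_name = {g.name: g for g in references}

    candidates = []
    for v_name in aln.v_tied:
        for j_name in aln.j_tied:
            v, j = by_name[v_name], by_name[j_name]
            _, v_map = _segment_mapping(aa_seq, v, aligner)
            _, j_map = _segment_mapping(aa_seq, j, aligner)
            nt, n_subs, covered, loglik = _reconstruct(
                aa_seq, v, v_map, j, j_map, trimer_model
            )
            candidates.append((n_subs, -loglik, v.name, j.name, nt, covered, loglik, v_map, j_map))
    candidates.sort()
    n_subs, _, v_name, j_name, nt, covered, loglik, v_map, j_map = candidates[0]
    v, j = by_name[v_name], by_name[j_name]
    codon_map = _merge_maps(v_map, j_map)
    final_aln = GermlineAlignment(
        record_id=record.antibody_id,
        v_gene=v,
        j_gene=j,
        codon_map=codon_map,
        junction=_junction_interval(len(aa_seq), codon_map),
        v_score=aln.v_score,
        j_score=aln.j_score,
        v_tied=aln.v_tied,
        j_tied=aln.j_tied,
    )
    out = record.with_(heavy_nt=nt, v_call=v.name, j_call=j.name)
    return BacktranslationResult(out, final_aln, n_subs, covered, loglik)


def backtranslate(
    record: AntibodyRecord,
    references: Sequence[ReferenceGene],
    trimer_model: SubstitutionModel,
) -> AntibodyRecord:
    """Convenience wrapper returning only the reconstructed record."""
    return backtranslate_with_stats(record, references, trimer_model).record
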
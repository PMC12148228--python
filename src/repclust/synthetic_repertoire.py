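"""Synthetic data generation: germlines, substitution model, curated
antibody-pair fixture, naive repertoire simulation and spike-in.

Everything here is synthetic, standing in for the external resources a
real analysis would use (database epitope exports, germline reference
sets, an empirical fivemer mutability table, predicted structures), so
the whole pipeline runs and is testable from code alone.

The naive repertoire mixes three somatic-hypermutation tiers: 50% of
sequences unmutated, 36% at the low rate (5.1%) and 14% at the high
rate (11.9%), mutations placed as per-site substitutions over the
germline-covered positions with target bases drawn from the trimer
substitution model.

The curated fixture emulates a set of functionally similar antibody
pairs: 54 antibodies across five antigens forming one large connected
overlap component of 31 antibodies plus ten small clusters of two or
three, 213 pairs at epitope Jaccard >= 0.75 of which exactly 20 share
the lengths of all six CDR regions. Epitope sets are nested prefixes of
a per-cluster residue pool, so every pairwise Jaccard equals the ratio
of the smaller to the larger set size, which makes the pair graph fully
controlled by the frozen size lists below.
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import (
    AMINO_ACIDS,
    AntibodyRecord,
    BackboneModel,
    EpitopeAnnotation,
    ReferenceGene,
    SubstitutionModel,
    translate_nt,
)
from .backtranslation import CODONS_FOR_AA
from .shm_calibration import RateTiers

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "toy_heavy_references",
    "toy_kappa_references",
    "default_fivemer_model",
    "simulate_repertoire",
    "spike_in",
    "PairSpec",
    "make_epitope_fixture",
    "make_study_fixture",
    "make_backbone_fixture",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Toy germline segments
#
# One shared region architecture (IGHV-like framework lengths) so that
# every simulated heavy chain has FR1(25) CDR1(8) FR2(17) CDR2(8)
# FR3(38) | CDR3(variable) | FR4(11).

_HEAVY_FR1 = "EVQLVESGGGLVQPGGSLRLSCAAS"
_HEAVY_CDR1 = "GFTFSSYA"
_HEAVY_FR2 = "MSWVRQAPGKGLEWVSA"
_HEAVY_CDR2 = "ISGSGGST"
_HEAVY_FR3 = "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC"

_HEAVY_V_BASE = _HEAVY_FR1 + _HEAVY_CDR1 + _HEAVY_FR2 + _HEAVY_CDR2 + _HEAVY_FR3

# per-gene amino-acid variants (position, replacement) on the base V
_HEAVY_V_VARIANTS = {
    "IGHV1-SYN": (),
    "IGHV2-SYN": ((27, "Y"), (30, "T"), (57, "N")),
    "IGHV3-SYN": ((5, "D"), (16, "T"), (50, "G"), (75, "T")),
    "IGHV4-SYN": ((12, "K"), (33, "D"), (60, "A"), (82, "S")),
    "IGHV5-SYN": ((2, "K"), (40, "S"), (66, "V"), (90, "F")),
}

_HEAVY_J_FR4 = {
    "IGHJ1-SYN": "WGQGTLVTVSS",
    "IGHJ2-SYN": "WGRGTLVTVSS",
    "IGHJ3-SYN": "WGQGTTVTVSS",
}

_KAPPA_V_BASE = (
    "DIQMTQSPSSLSASVGDRVTITC" "QSISSY" "LNWYQQKPGKAPKLLIY" "AAS"
    "SLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"
)
_KAPPA_V_VARIANTS = {
    "IGKV1-SYN": (),
    "IGKV2-SYN": ((4, "A"), (30, "N")),
    "IGKV3-SYN": ((10, "V"), (50, "T")),
}
_KAPPA_J_FR4 = {"IGKJ1-SYN": "FGQGTKVEIK", "IGKJ2-SYN": "FGGGTKVEIK"}

#: heavy-chain region layout shared by all toy V genes (aa lengths)
HEAVY_REGION_LENGTHS = {
    "FR1": len(_HEAVY_FR1),
    "CDR1": len(_HEAVY_CDR1),
    "FR2": len(_HEAVY_FR2),
    "CDR2": len(_HEAVY_CDR2),
    "FR3": len(_HEAVY_FR3),
}
KAPPA_REGION_LENGTHS = {"FR1": 23, "CDR1": 6, "FR2": 17, "CDR2": 3, "FR3": 36}


def _encode_protein(aa: str, rng: np.random.Generator) -> str:
    """Deterministically encode a protein with varied synonymous codons."""
    return "".join(CODONS_FOR_AA[a][rng.integers(len(CODONS_FOR_AA[a]))] for a in aa)


def _apply_variants(base: str, variants) -> str:
    seq = list(base)
    for pos, aa in variants:
        seq[pos] = aa
    return "".join(seq)


def _gene_rng(name: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(name.encode()) % (2**31))


def toy_heavy_references() -> list[ReferenceGene]:
    """Synthetic heavy-chain germline V and J nucleotide segments."""
    genes = []
    for name, variants in _HEAVY_V_VARIANTS.items():
        aa = _apply_variants(_HEAVY_V_BASE, variants)
        genes.append(ReferenceGene(name, "V", _encode_protein(aa, _gene_rng(name))))
    for name, fr4 in _HEAVY_J_FR4.items():
        genes.append(ReferenceGene(name, "J", _encode_protein(fr4, _gene_rng(name))))
    return genes


def toy_kappa_references() -> list[ReferenceGene]:
    """Synthetic kappa light-chain germline V and J nucleotide segments."""
    genes = []
    for name, variants in _KAPPA_V_VARIANTS.items():
        aa = _apply_variants(_KAPPA_V_BASE, variants)
        genes.append(ReferenceGene(name, "V", _encode_protein(aa, _gene_rng(name))))
    for name, fr4 in _KAPPA_J_FR4.items():
        genes.append(ReferenceGene(name, "J", _encode_protein(fr4, _gene_rng(name))))
    return genes


# ---------------------------------------------------------------------------
# Synthetic fivemer substitution-likelihood table

def default_fivemer_model(seed: int = 0) -> SubstitutionModel:
    """A synthetic fivemer substitution-likelihood table.

    Likelihoods are lognormal around 1 with WRC/GYW hotspot contexts
    (the classic AID targeting motifs) boosted threefold — enough
    structure for context-dependent codon choice to be non-trivial,
    without claiming empirical mutabilities.
    """
    rng = np.random.default_rng(seed)
    table = {}
    w, r, y = set("AT"), set("AG"), set("CT")
    for ctx_t in itertools.product(_BASES, repeat=5):
        ctx = "".join(ctx_t)
        hot = (ctx[2] == "C" and ctx[0] in w and ctx[1] in r) or (
            ctx[2] == "G" and ctx[3] in y and ctx[4] in w
        )
        for target in _BASES:
            if target == ctx[2]:
                continue
            lik = float(rng.lognormal(mean=0.0, sigma=0.5))
            if hot:
                lik *= 3.0
            table[("center", ctx, target)] = lik
    return SubstitutionModel(context_len=5, table=table)


# ---------------------------------------------------------------------------
# Repertoire simulation

@dataclass
class SimConfig:
    """Settings for the naive-repertoire simulator.

    Junction (CDRH3) amino-acid lengths are drawn as 9 + Poisson(2.5)
    clipped to 23, giving the 9–23 range with mode 11 seen in curated
    antibody sets. The chain pair is fixed heavy + kappa.
    """

    n_sequences: int = 10000
    rate_tiers: RateTiers = field(default_factory=RateTiers)
    seed: int = 0
    junction_min: int = 9
    junction_max: int = 23
    junction_poisson_mean: float = 2.5
    uniqueness: str = "nt"  # {nt, aa}
    pair_light_chains: bool = True

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not (3 <= self.junction_min <= self.junction_max):
            raise ValueError("junction length bounds invalid")
        if self.uniqueness not in ("nt", "aa"):
            raise ValueError("uniqueness must be 'nt' or 'aa'")


def _heavy_regions(junction_aa_len: int) -> dict[str, tuple[int, int]]:
    regions = {}
    pos = 0
    for name in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
        ln = HEAVY_REGION_LENGTHS[name]
        regions[name] = (pos, pos + ln)
        pos += ln
    regions["CDR3"] = (pos, pos + junction_aa_len)
    pos += junction_aa_len
    regions["FR4"] = (pos, pos + len(_HEAVY_J_FR4["IGHJ1-SYN"]))
    return regions


def _kappa_regions(cdrl3_len: int) -> dict[str, tuple[int, int]]:
    regions = {}
    pos = 0
    for name in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
        ln = KAPPA_REGION_LENGTHS[name]
        regions[name] = (pos, pos + ln)
        pos += ln
    regions["CDR3"] = (pos, pos + cdrl3_len)
    pos += cdrl3_len
    regions["FR4"] = (pos, pos + len(_KAPPA_J_FR4["IGKJ1-SYN"]))
    return regions


def _random_junction_nt(length_aa: int, rng: np.random.Generator) -> str:
    out = []
    for _ in range(length_aa):
        aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        codons = CODONS_FOR_AA[aa]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _mutate_covered(
    nt: list[str],
    covered: Sequence[tuple[int, int]],
    rate: float,
    trimer_model: SubstitutionModel,
    rng: np.random.Generator,
) -> int:
    """Per-site substitution at ``rate`` over covered nt intervals.

    Target bases are drawn proportionally to the trimer-model
    likelihoods; a substitution that would create a stop codon falls
    back to the next-likeliest base, or is skipped if every alternative
    creates a stop. Returns the realized substitution count."""
    from .backtranslation import site_likelihood

    if rate <= 0:
        return 0
    n_mut = 0
    positions = [p for s, e in covered for p in range(s, e)]
    hits = np.asarray(positions)[rng.random(len(positions)) < rate]
    for pos in hits:
        ref = nt[pos]
        targets = [b for b in _BASES if b != ref]
        liks = np.array([site_likelihood(nt, int(pos), b, trimer_model) for b in targets])
        order = [int(k) for k in np.argsort(-liks)]
        if liks.sum() > 0:
            first = int(rng.choice(3, p=liks / liks.sum()))
            order.remove(first)
            order.insert(0, first)
        codon_start = 3 * (pos // 3)
        for k in order:
            cand = targets[k]
            trial = nt[codon_start : codon_start + 3]
            trial[pos % 3] = cand
            if "".join(trial) not in _STOPS:
                nt[pos] = cand
                n_mut += 1
                break
    return n_mut


def simulate_repertoire(
    config: SimConfig,
    trimer_model: SubstitutionModel | None = None,
    return_meta: bool = False,
):
    """Simulate a naive heavy/kappa-paired repertoire.

    Each heavy chain is a uniformly sampled V segment, a random junction
    insertion and a uniformly sampled J segment. The SHM tier (none /
    low / high) is sampled per sequence from the mixture; substitutions
    are placed over the V+J-covered nucleotides. Duplicates under the
    configured uniqueness key are removed. With ``return_meta`` a
    per-sequence table (tier, realized mutation count, covered length)
    is returned alongside the records.
    """
    if trimer_model is None:
        from .backtranslation import aggregate_fivemer_to_trimer

        trimer_model = aggregate_fivemer_to_trimer(default_fivemer_model())
    rng = np.random.default_rng(config.seed)
    heavy = toy_heavy_references()
    kappa = toy_kappa_references()
    v_genes = [g for g in heavy if g.segment == "V"]
    j_genes = [g for g in heavy if g.segment == "J"]
    kv = [g for g in kappa if g.segment == "V"]
    kj = [g for g in kappa if g.segment == "J"]
    tiers = config.rate_tiers
    records: list[AntibodyRecord] = []
    meta_rows = []
    seen: set[str] = set()
    i = 0
    while len(records) < config.n_sequences:
        i += 1
        v = v_genes[rng.integers(len(v_genes))]
        j = j_genes[rng.integers(len(j_genes))]
        jl = int(min(config.junction_max, max(config.junction_min,
                 config.junction_min + rng.poisson(config.junction_poisson_mean))))
        junction_nt = _random_junction_nt(jl, rng)
        nt = list(v.coding_nt + junction_nt + j.coding_nt)
        v_len = len(v.coding_nt)
        covered = [(0, v_len), (v_len + 3 * jl, len(nt))]
        tier = int(rng.choice(3, p=tiers.mixture))
        rate = tiers.rates[tier]
        n_mut = _mutate_covered(nt, covered, rate, trimer_model, rng)
        nt_str = "".join(nt)
        aa = translate_nt(nt_str)
        if "*" in aa:  # guarded against above, but junction draws avoid stops anyway
            continue
        key = nt_str if config.uniqueness == "nt" else aa
        if key in seen:
            continue
        seen.add(key)
        covered_nt = v_len + len(j.coding_nt)
        regions = {"heavy": _heavy_regions(jl)}
        light_aa = None
        if config.pair_light_chains:
            lkv = kv[rng.integers(len(kv))]
            lkj = kj[rng.integers(len(kj))]
            cdrl3_len = int(rng.integers(8, 11))
            light_aa = (
                lkv.translation
                + translate_nt(_random_junction_nt(cdrl3_len, rng))
                + lkj.translation
            )
            regions["light"] = _kappa_regions(cdrl3_len)
        rec = AntibodyRecord(
            antibody_id=f"sim-{len(records):05d}",
            heavy_aa=aa,
            light_aa=light_aa,
            heavy_nt=nt_str,
            regions=regions,
            v_call=v.name,
            j_call=j.name,
            source="simulated",
            shm_rate=n_mut / covered_nt,
        )
        records.append(rec)
        meta_rows.append(
            {
                "sequence_id": rec.antibody_id,
                "tier": tier,
                "rate": rate,
                "n_mutations": n_mut,
                "covered_nt": covered_nt,
                "junction_aa_len": jl,
            }
        )
    if return_meta:
        import pandas as pd

        return records, pd.DataFrame(meta_rows)
    return records


def spike_in(
    repertoire: Sequence[AntibodyRecord],
    curated: Sequence[AntibodyRecord],
    seed: int = 0,
    uniqueness: str = "nt",
) -> list[AntibodyRecord]:
    """Introduce curated (backtranslated) antibodies into a simulated
    repertoire: concatenate, enforce uniqueness (curated sequences win;
    displaced simulated duplicates are logged), shuffle under the seed."""
    for rec in curated:
        if rec.heavy_nt is None:
            raise ValueError(f"curated record {rec.antibody_id} lacks heavy_nt")
    ids = [r.antibody_id for r in curated] + [r.antibody_id for r in repertoire]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"antibody id collision on spike-in: {dupes}")

    def key(r: AntibodyRecord) -> str:
        return r.heavy_nt if uniqueness == "nt" else r.heavy_aa

    seen = {key(r) for r in curated}
    combined = list(curated)
    for r in repertoire:
        if key(r) in seen:
            logger.info("spike_in: dropping simulated duplicate %s", r.antibody_id)
            continue
        seen.add(key(r))
        combined.append(r)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combined))
    return [combined[i] for i in order]


# ---------------------------------------------------------------------------
# Curated epitope/antibody fixture

@dataclass(frozen=True)
class PairSpec:
    """An intended antibody pair with an exact target Jaccard."""

    id_a: str
    id_b: str
    jaccard: float
    union_size: int = 8
    antigen_id: str = "AG1"


def make_epitope_fixture(
    specs: Sequence[PairSpec],
    seed: int = 0,
    chain: str = "A",
) -> list[EpitopeAnnotation]:
    """Construct epitope annotations achieving each requested Jaccard
    exactly: |intersection| = jaccard * union_size must be an integer
    (else the feasible values for that union size are reported). Ids may
    repeat across specs only as fresh pairs (each spec allocates fresh
    residues), so specs are independent."""
    epitopes: list[EpitopeAnnotation] = []
    counter = itertools.count(1)
    for spec in specs:
        k_float = spec.jaccard * spec.union_size
        k = round(k_float)
        if abs(k_float - k) > 1e-9:
            feas = sorted({i / spec.union_size for i in range(spec.union_size + 1)})
            raise ValueError(
                f"Jaccard {spec.jaccard} infeasible for union size {spec.union_size}; "
                f"feasible values: {feas}"
            )
        extra = spec.union_size - k
        shared = [(chain, next(counter)) for _ in range(k)]
        a_extra = [(chain, next(counter)) for _ in range(math.ceil(extra / 2))]
        b_extra = [(chain, next(counter)) for _ in range(extra // 2)]
        epitopes.append(
            EpitopeAnnotation(spec.id_a, spec.antigen_id, frozenset(shared + a_extra))
        )
        epitopes.append(
            EpitopeAnnotation(spec.id_b, spec.antigen_id, frozenset(shared + b_extra))
        )
    return epitopes


# Frozen design of the study-like curated set (54 antibodies, 213 pairs).
# Epitope sets are nested prefixes, so Jaccard(i, j) = size_min/size_max
# and a pair exists iff that ratio is >= 0.75: the 31 sizes below yield
# exactly 197 pairs in one connected component; the CDRH3 lengths yield
# 13 same-length pairs there, plus 7 from the small clusters = 20.
_BIG_SIZES = (
    24, 25, 26, 29, 30, 31, 33, 34, 35, 37, 39, 40, 41, 42, 43, 44,
    45, 46, 47, 53, 55, 58, 60, 61, 62, 63, 64, 65, 67, 68, 69,
)
_BIG_CDRH3_LEN = (
    12, 20, 18, 11, 13, 12, 15, 15, 10, 9, 19, 13, 18, 15, 12, 20,
    11, 22, 21, 9, 23, 13, 18, 12, 11, 12, 9, 11, 12, 13, 11,
)
# same-length pair cliques within the big component (indices into the
# size/length lists above): CDRH3 families follow these cliques so that
# high-identity chaining co-clusters exactly the annotated pairs and
# clonotyping produces no false positives on the curated set
_BIG_CLIQUES = ((0, 5), (4, 11), (6, 7, 13), (19, 26), (21, 29), (23, 25, 28), (24, 27, 30))

# small clusters: (antigen, cluster sizes as nested-set sizes, CDRH3 lengths)
_SMALL_CLUSTERS = (
    ("AG2-FLU-HA", (24, 30), (11, 11)),
    ("AG2-FLU-HA", (24, 30), (11, 11)),
    ("AG2-FLU-HA", (26, 32), (10, 10)),
    ("AG3-HIV-ENV", (24, 31), (14, 14)),
    ("AG3-HIV-ENV", (25, 33), (11, 13)),
    ("AG3-HIV-ENV", (27, 34), (12, 16)),
    ("AG4-RSV-F", (24, 32), (9, 17)),
    ("AG4-RSV-F", (24, 28, 32), (11, 11, 11)),
    ("AG5-CMV-GB", (24, 28, 32), (10, 12, 15)),
    ("AG5-CMV-GB", (25, 30, 33), (13, 14, 16)),
)
_BIG_ANTIGEN = "AG1-SARS2-SPIKE"


def _family_cdrh3(base: str, member: int) -> str:
    """Member ``member`` of a CDRH3 family: 1–3 cycling point
    substitutions on the family base; members are pairwise distinct
    because each member's substituted position set is distinct and a
    substitution never reproduces the base letter."""
    if member == 0:
        return base
    L = len(base)
    k = 1 + (member - 1) % 3
    letters = "ADEFGHIKLMNPQRSTVY"
    seq = list(base)
    for t in range(k):
        pos = (2 * member + t) % L
        sub = letters[(member + t) % len(letters)]
        if sub == base[pos]:
            sub = letters[(member + t + 1) % len(letters)]
        seq[pos] = sub
    return "".join(seq)


def make_study_fixture(
    seed: int = 0,
    shm_mixture: tuple[float, float, float] = (0.50, 0.36, 0.14),
    rate_tiers: RateTiers | None = None,
) -> tuple[list[EpitopeAnnotation], list[AntibodyRecord]]:
    """The default curated-set fixture: 54 antibodies over five antigens
    whose epitope-overlap graph at Jaccard >= 0.75 has one 31-antibody
    component (197 pairs) and ten 2–3-antibody clusters (16 pairs).

    Heavy chains are built on the toy germlines with per-antibody V/J
    framework substitutions drawn from the SHM tier mixture, so the
    curated set carries the mutation-rate structure the calibration
    stage expects to observe. CDRH3s come in per-length families with
    small substitution counts, giving both high- and low-identity pairs.
    """
    rng = np.random.default_rng(seed)
    tiers = rate_tiers or RateTiers(mixture=shm_mixture)
    heavy = toy_heavy_references()
    v_genes = [g for g in heavy if g.segment == "V"]
    j_genes = [g for g in heavy if g.segment == "J"]
    kappa = toy_kappa_references()
    kv = next(g for g in kappa if g.segment == "V")
    kj = next(g for g in kappa if g.segment == "J")
    # Per-antibody light CDRL3 lengths (frozen graph coloring): two
    # curated antibodies share the full six-CDR-length tuple iff they
    # are an annotated same-length pair. Each same-length pair clique is
    # monochrome; any two units (cliques, big singletons, small
    # clusters) overlapping in CDRH3 length get different light lengths.
    big_light = (10, 8, 8, 10, 9, 10, 9, 9, 9, 9, 8, 9, 9, 9, 11, 9, 7, 8,
                 8, 8, 8, 7, 10, 7, 9, 7, 8, 9, 7, 7, 9)
    small_light = (11, 6, 10, 8, 8, 9, 10, 12, 8, 10)
    light_base = "QQSYSTPLTFGH"

    def _light(cdrl3_len: int):
        return (
            kv.translation + light_base[:cdrl3_len] + kj.translation,
            _kappa_regions(cdrl3_len),
        )

    # CDRH3 families are keyed by (functional cluster, length): members
    # of one family are minor variants of a shared base and share V/J,
    # while same-length antibodies in different functional clusters get
    # unrelated bases (low identity) and independent gene draws.
    base_rng = np.random.default_rng(10_000 + seed)
    family_base: dict[tuple[str, int], str] = {}
    family_member_count: dict[tuple[str, int], int] = {}
    family_vj: dict[tuple[str, int], tuple[ReferenceGene, ReferenceGene]] = {}

    epitopes: list[EpitopeAnnotation] = []
    records: list[AntibodyRecord] = []

    def add_antibody(
        aid: str, light_cdrl3_len: int, family: str, antigen: str, chain: str,
        set_size: int, cdrh3_len: int,
    ):
        residues = frozenset((chain, r) for r in range(1, set_size + 1))
        epitopes.append(EpitopeAnnotation(aid, antigen, residues))
        light_aa, light_regions = _light(light_cdrl3_len)
        fam = (family, cdrh3_len)
        member = family_member_count.get(fam, 0)
        family_member_count[fam] = member + 1
        if fam not in family_vj:
            family_vj[fam] = (
                v_genes[int(rng.integers(len(v_genes)))],
                j_genes[int(rng.integers(len(j_genes)))],
            )
            family_base[fam] = "".join(
                AMINO_ACIDS[base_rng.integers(20)] for _ in range(cdrh3_len)
            )
        v, j = family_vj[fam]
        cdrh3 = _family_cdrh3(family_base[fam], member)
        tier = int(rng.choice(3, p=tiers.mixture))
        v_aa = list(v.translation)
        # an amino-acid substitution costs ~1.9 nt substitutions under the
        # minimal-codon rule here (1.25 nt per changed codon over the V+J
        # nt length), so divide to land the realized nt-level rate on tier
        n_sub = round(tiers.rates[tier] * 3 * (len(v_aa) + len(j.translation)) / 1.9)
        for pos in rng.choice(len(v_aa), size=min(n_sub, len(v_aa)), replace=False):
            cur = v_aa[pos]
            v_aa[pos] = AMINO_ACIDS[(AMINO_ACIDS.index(cur) + 1 + int(rng.integers(18))) % 20]
        heavy_aa = "".join(v_aa) + cdrh3 + j.translation
        records.append(
            AntibodyRecord(
                antibody_id=aid,
                heavy_aa=heavy_aa,
                light_aa=light_aa,
                regions={"heavy": _heavy_regions(cdrh3_len), "light": light_regions},
                source="curated",
            )
        )

    big_family = {i: f"big-solo-{i}" for i in range(len(_BIG_SIZES))}
    for ci, clique in enumerate(_BIG_CLIQUES):
        for i in clique:
            big_family[i] = f"big-clique-{ci}"
    for i, (size, clen) in enumerate(zip(_BIG_SIZES, _BIG_CDRH3_LEN)):
        add_antibody(
            f"cur-A{i:02d}", big_light[i], big_family[i], _BIG_ANTIGEN, "S", size, clen
        )
    for ci, (antigen, sizes, lens) in enumerate(_SMALL_CLUSTERS):
        chain = chr(ord("B") + ci)  # distinct chain per cluster -> disjoint residues
        for mi, (size, clen) in enumerate(zip(sizes, lens)):
            add_antibody(
                f"cur-S{ci:02d}{chr(ord('a') + mi)}", small_light[ci], f"small-{ci}",
                antigen, chain, size, clen,
            )
    return epitopes, records


# ---------------------------------------------------------------------------
# Backbone coordinate fixture

def _template_atoms(record: AntibodyRecord, class_seed: int, group_seed: int | None):
    """Template backbone for one (CDR-length class, conformation group).

    The framework trace depends only on the class, so all same-class
    models superpose exactly on their frameworks; the CDR atoms carry a
    group-specific conformational offset (2 Å Gaussian) so different
    conformation groups sit well apart in CDR RMSD."""
    atoms = []
    conf_rng = np.random.default_rng(group_seed) if group_seed is not None else None
    t = 0
    for chain_name, prefix, offset in (("heavy", "H", 0.0), ("light", "L", 40.0)):
        regmap = record.regions.get(chain_name)
        if not regmap:
            continue
        seq_len = max(e for _, e in regmap.values())
        for res in range(seq_len):
            label = f"{prefix}:FR?"
            for region, (s, e) in regmap.items():
                if s <= res < e:
                    label = f"{prefix}:{region}"
                    break
            ca = np.array([1.5 * t, 8.0 * math.sin(0.35 * t) + offset, 8.0 * math.cos(0.35 * t)])
            res_atoms = [
                (label, res, "N", ca + np.array([-0.45, 0.8, 0.2])),
                (label, res, "CA", ca),
                (label, res, "C", ca + np.array([0.45, 0.8, -0.2])),
            ]
            if "CDR" in label and conf_rng is not None:
                shift = conf_rng.normal(0.0, 2.0, size=3)
                res_atoms = [(l, r, a, xyz + shift) for l, r, a, xyz in res_atoms]
            atoms.extend(res_atoms)
            t += 1
    return atoms


def make_backbone_fixture(
    records: Sequence[AntibodyRecord],
    perturbation_scale: float = 0.5,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> list[BackboneModel]:
    """Backbone models standing in for predicted antibody structures
    (synthetic; no structure prediction involved).

    Records in one CDR-length class share a framework template; CDR
    coordinates come from a conformation template per (class, group) —
    with ``groups`` unset, the whole class shares one conformation.
    Per-antibody Gaussian noise of ``perturbation_scale`` Å is added to
    CDR atoms, then a random rigid rotation + translation is applied to
    the whole model so framework superposition is exercised.

    Passing ``groups`` (antibody_id -> conformation-group label) makes
    structural similarity track functional grouping, emulating the
    premise that same-epitope antibodies adopt similar CDR
    conformations.
    """
    if perturbation_scale < 0:
        raise ValueError("perturbation scale must be >= 0")
    rng = np.random.default_rng(seed)
    templates: dict[tuple, list] = {}
    models = []
    for rec in records:
        cls = rec.cdr_lengths()
        group = (groups or {}).get(rec.antibody_id)
        tkey = (cls, group)
        if tkey not in templates:
            class_seed = (zlib.crc32(repr(cls).encode()) + seed) % (2**31)
            group_seed = (
                None
                if group is None
                else (zlib.crc32(repr((cls, group)).encode()) + seed) % (2**31)
            )
            templates[tkey] = _template_atoms(rec, class_seed, group_seed)
        atoms = []
        for label, res, atom, xyz in templates[tkey]:
            xyz = np.array(xyz, dtype=float)
            if "CDR" in label and perturbation_scale > 0:
                xyz = xyz + rng.normal(0.0, perturbation_scale, size=3)
            atoms.append((label, res, atom, xyz))
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.normal(0.0, 20.0, size=3)
        atoms = [(lab, res, a, rot @ xyz + trans) for lab, res, a, xyz in atoms]
        models.append(BackboneModel(rec.antibody_id, atoms))
    return models
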
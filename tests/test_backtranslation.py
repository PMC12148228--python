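"""Fivemer->trimer aggregation, codon choice and chain reconstruction."""

import itertools
import math

import numpy as np
import pytest

from repclust.backtranslation import (
    CODONS_FOR_AA,
    aggregate_fivemer_to_trimer,
    align_to_references,
    backtranslate_with_stats,
    choose_codon,
    site_likelihood,
)
from repclust.model_io import ReferenceGene, SubstitutionModel, translate_nt
from repclust.shm_calibration import RateTiers
from repclust.synthetic_repertoire import SimConfig, simulate_repertoire

_BASES = "ACGT"


def _uniform_fivemer(value=1.0):
    table = {}
    for ctx in ("".join(c) for c in itertools.product(_BASES, repeat=5)):
        for t in _BASES:
            if t != ctx[2]:
                table[("center", ctx, t)] = value
    return SubstitutionModel(context_len=5, table=table)


class TestAggregation:
    def test_uniform_fivemer_gives_uniform_trimer(self):
        trimer = aggregate_fivemer_to_trimer(_uniform_fivemer(2.5))
        assert all(v == pytest.approx(2.5) for v in trimer.table.values())
        assert all(d == pytest.approx(0.0) for d in trimer.dispersion.values())

    def test_mean_of_1_to_16(self):
        """The 16 embedding fivemers valued 1..16 average to 8.5."""
        fm = _uniform_fivemer()
        flank_pairs = sorted(itertools.product(_BASES, repeat=2))
        for i, (l, r) in enumerate(flank_pairs, start=1):
            fm.table[("center", f"{l}AAA{r}", "G")] = float(i)
        trimer = aggregate_fivemer_to_trimer(fm)
        assert trimer.table[("center", "AAA", "G")] == pytest.approx(8.5)
        expected_sd = math.sqrt(sum((i - 8.5) ** 2 for i in range(1, 17)) / 16)
        assert trimer.dispersion[("center", "AAA", "G")] == pytest.approx(expected_sd)

    def test_center_aggregation_enumerates_n_aaa_n(self):
        """Center-position aggregation of "AAA" averages exactly the 16
        fivemers X-AAA-Y (X, Y over ACGT)."""
        fm = _uniform_fivemer()
        marked = {f"{l}AAA{r}" for l in _BASES for r in _BASES}
        for ctx in marked:
            fm.table[("center", ctx, "C")] = 7.0
        trimer = aggregate_fivemer_to_trimer(fm)
        # only the marked fivemers contribute: exact mean 7.0
        assert trimer.table[("center", "AAA", "C")] == pytest.approx(7.0)
        # a fivemer outside that family must not leak in
        fm.table[("center", "AACAA", "C")] = 1000.0
        assert aggregate_fivemer_to_trimer(fm).table[("center", "AAA", "C")] == pytest.approx(7.0)

    def test_start_and_end_positions(self):
        fm = _uniform_fivemer()
        for l, r in itertools.product(_BASES, repeat=2):
            fm.table[("center", f"{l}{r}ACG", "T")] = 3.0  # trimer ACG at start
        trimer = aggregate_fivemer_to_trimer(fm)
        assert trimer.table[("start", "ACG", "T")] == pytest.approx(3.0)
        assert trimer.table[("center", "ACG", "T")] == pytest.approx(1.0)

    def test_scaling_linearity(self):
        """Scaling all fivemer likelihoods by c scales trimer values by c."""
        fm = SubstitutionModel(
            context_len=5,
            table={
                k: float(v)
                for k, v in zip(
                    _uniform_fivemer().table,
                    np.random.default_rng(3).lognormal(size=3072),
                )
            },
        )
        t1 = aggregate_fivemer_to_trimer(fm)
        fm2 = SubstitutionModel(5, {k: 4.0 * v for k, v in fm.table.items()})
        t2 = aggregate_fivemer_to_trimer(fm2)
        for key in t1.table:
            assert t2.table[key] == pytest.approx(4.0 * t1.table[key])

    def test_missing_context_named(self):
        fm = _uniform_fivemer()
        del fm.table[("center", "ACGTA", "C")]
        with pytest.raises(KeyError, match="ACGTA"):
            aggregate_fivemer_to_trimer(fm)


def _brute_force_path_likelihood(ref, new, model, left, right):
    """Independent path-likelihood oracle: enumerate every mutation
    order recursively, recomputing the context string each step."""
    diff = [p for p in range(3) if ref[p] != new[p]]
    best = 0.0
    for order in itertools.permutations(diff):
        seq = left + ref + right
        prod = 1.0
        for p in order:
            i = len(left) + p
            prod *= site_likelihood(seq, i, new[p], model)
            seq = seq[:i] + new[p] + seq[i + 1 :]
        best = max(best, prod)
    return best if diff else 1.0


class TestChooseCodon:
    def test_identity(self, trimer_model):
        choice = choose_codon("M", "ATG", trimer_model, "AA", "CC")
        assert choice.codon == "ATG" and choice.n_substitutions == 0
        assert choice.likelihood == 1.0

    def test_stop_rejected(self, trimer_model):
        with pytest.raises(ValueError):
            choose_codon("*", "TAA", trimer_model)

    def test_asp_to_glu_single_substitution(self, trimer_model):
        """Ref GAT (Asp) -> Glu: GAA and GAG both need one substitution;
        the likelier third-position change wins (enumerated oracle)."""
        left, right = "CT", "GG"
        choice = choose_codon("E", "GAT", trimer_model, left, right)
        assert choice.codon in ("GAA", "GAG") and choice.n_substitutions == 1
        liks = {
            c: _brute_force_path_likelihood("GAT", c, trimer_model, left, right)
            for c in ("GAA", "GAG")
        }
        assert choice.codon == max(liks, key=liks.get)
        assert choice.likelihood == pytest.approx(liks[choice.codon])

    def test_multi_substitution_matches_factorial_oracle(self, trimer_model):
        """Every (target aa, ref codon) case agrees with the brute-force
        order-enumeration oracle on distance and path likelihood."""
        rng = np.random.default_rng(9)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(200):
            ref = "".join(rng.choice(list(_BASES), 3))
            aa = aas[rng.integers(20)]
            left = "".join(rng.choice(list(_BASES), 2))
            right = "".join(rng.choice(list(_BASES), 2))
            choice = choose_codon(aa, ref, trimer_model, left, right)
            dists = {c: sum(a != b for a, b in zip(c, ref)) for c in CODONS_FOR_AA[aa]}
            dmin = min(dists.values())
            assert choice.n_substitutions == dmin
            best = max(
                _brute_force_path_likelihood(ref, c, trimer_model, left, right)
                for c, d in dists.items()
                if d == dmin
            )
            assert choice.likelihood == pytest.approx(best)

    def test_lexicographic_tie_flag(self):
        trimer = aggregate_fivemer_to_trimer(_uniform_fivemer())
        # uniform model: GAA/GAG tie exactly; lexicographic winner GAA
        choice = choose_codon("E", "GAT", trimer, "AA", "AA")
        assert choice.codon == "GAA" and choice.lexicographic_tie


class TestAlignToReferences:
    def test_identity_chain_selects_its_germline(self, heavy_refs, trimer_model):
        v = next(g for g in heavy_refs if g.name == "IGHV3-SYN")
        j = next(g for g in heavy_refs if g.name == "IGHJ2-SYN")
        aa = v.translation + "ARDYW" + j.translation
        aln = align_to_references(aa, heavy_refs)
        assert aln.v_gene.name == "IGHV3-SYN"
        assert aln.j_gene.name == "IGHJ2-SYN"
        assert aln.junction == (len(v.translation), len(v.translation) + 5)
        # covered positions carry the germline codons verbatim
        for pos in range(len(v.translation)):
            assert aln.codon_map[pos] == ("V", v.coding_nt[3 * pos : 3 * pos + 3])

    def test_single_mismatch_still_selects_best(self, heavy_refs):
        v = next(g for g in heavy_refs if g.name == "IGHV4-SYN")
        j = next(g for g in heavy_refs if g.name == "IGHJ1-SYN")
        aa = list(v.translation + "ARDYW" + j.translation)
        aa[10] = "W" if aa[10] != "W" else "F"
        aln = align_to_references("".join(aa), heavy_refs)
        assert aln.v_gene.name == "IGHV4-SYN"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            align_to_references("MKV", [ReferenceGene("V1", "V", "ATGAAAGTT")])


class TestBacktranslate:
    def _record(self, aa, cdr3_span):
        from repclust.model_io import AntibodyRecord

        return AntibodyRecord(
            antibody_id="bt", heavy_aa=aa, regions={"heavy": {"CDR3": cdr3_span}}
        )

    def test_germline_identity_reconstruction(self, heavy_refs, trimer_model):
        """A chain equal to germline V+J translation reconstructs the
        germline nucleotides exactly over covered positions."""
        v = next(g for g in heavy_refs if g.name == "IGHV1-SYN")
        j = next(g for g in heavy_refs if g.name == "IGHJ1-SYN")
        nv = len(v.translation)
        aa = v.translation + "ARDYW" + j.translation
        res = backtranslate_with_stats(
            self._record(aa, (nv, nv + 5)), heavy_refs, trimer_model
        )
        assert res.n_substitutions == 0
        assert res.record.heavy_nt.startswith(v.coding_nt)
        assert res.record.heavy_nt.endswith(j.coding_nt)
        assert translate_nt(res.record.heavy_nt) == aa
        assert res.record.v_call == "IGHV1-SYN" and res.record.j_call == "IGHJ1-SYN"

    def test_substitution_count_equals_per_codon_minima(self, heavy_refs, trimer_model):
        """With aa changes vs germline, the total substitution count is
        the sum of per-codon minimal Hamming distances."""
        v = next(g for g in heavy_refs if g.name == "IGHV1-SYN")
        j = next(g for g in heavy_refs if g.name == "IGHJ1-SYN")
        nv = len(v.translation)
        aa = list(v.translation + "ARDYW" + j.translation)
        changed = {3: "W", 20: "H", 40: "M"}
        for pos, sub in changed.items():
            assert aa[pos] != sub
            aa[pos] = sub
        aa = "".join(aa)
        res = backtranslate_with_stats(self._record(aa, (nv, nv + 5)), heavy_refs, trimer_model)
        assert translate_nt(res.record.heavy_nt) == aa
        expected = 0
        for pos in res.alignment.codon_map:
            _, ref_codon = res.alignment.codon_map[pos]
            expected += min(
                sum(a != b for a, b in zip(c, ref_codon)) for c in CODONS_FOR_AA[aa[pos]]
            )
        assert res.n_substitutions == expected

    def test_round_trip_on_simulated_records(self, heavy_refs, trimer_model):
        """translate(backtranslate(x)) == x on simulator output."""
        records = simulate_repertoire(
            SimConfig(n_sequences=40, seed=21, pair_light_chains=False), trimer_model
        )
        for rec in records:
            res = backtranslate_with_stats(rec, heavy_refs, trimer_model)
            assert translate_nt(res.record.heavy_nt) == rec.heavy_aa

    def test_per_codon_minimality(self, heavy_refs, trimer_model):
        """No output codon can be swapped for a synonymous codon closer
        to its reference codon (exhaustive per-codon check)."""
        records = simulate_repertoire(
            SimConfig(n_sequences=15, seed=31, pair_light_chains=False), trimer_model
        )
        for rec in records:
            res = backtranslate_with_stats(rec, heavy_refs, trimer_model)
            nt = res.record.heavy_nt
            for pos, (_seg, ref_codon) in res.alignment.codon_map.items():
                out_codon = nt[3 * pos : 3 * pos + 3]
                d_out = sum(a != b for a, b in zip(out_codon, ref_codon))
                d_best = min(
                    sum(a != b for a, b in zip(c, ref_codon))
                    for c in CODONS_FOR_AA[rec.heavy_aa[pos]]
                )
                assert d_out == d_best

    def test_reference_tie_resolved_by_likelihood(self, trimer_model):
        """Two V references with identical translations (so aa scores
        tie) and reconstructions needing one substitution each: the
        winner is the reference whose substitution is likelier."""
        base_aa = "MKVLQGKAEVKKPGASVKVSCKAS"
        nt_a = "".join(CODONS_FOR_AA[a][0] for a in base_aa)
        assert base_aa[6] == "K" and nt_a[18:21] == "AAA"
        nt_b = nt_a[:18] + "AAG" + nt_a[21:]  # synonymous K codon
        refs = [
            ReferenceGene("VA", "V", nt_a),
            ReferenceGene("VB", "V", nt_b),
            ReferenceGene("J1", "J", "TGGGGCCAA"),
        ]
        # chain: K6 -> N, reachable from AAA and AAG with one substitution
        chain = base_aa[:6] + "N" + base_aa[7:] + "DR" + "WGQ"
        rec = self._record(chain, (len(base_aa), len(base_aa) + 2))
        res = backtranslate_with_stats(rec, refs, trimer_model)
        assert set(res.alignment.v_tied) == {"VA", "VB"}
        assert res.n_substitutions == 1
        per_ref = {}
        for name in ("VA", "VB"):
            sub = [g for g in refs if g.name in (name, "J1")]
            per_ref[name] = backtranslate_with_stats(rec, sub, trimer_model)
        assert all(r.n_substitutions == 1 for r in per_ref.values())
        winner = max(per_ref, key=lambda n: per_ref[n].log_likelihood)
        assert per_ref["VA"].log_likelihood != pytest.approx(per_ref["VB"].log_likelihood)
        assert res.record.v_call == winner
        assert res.log_likelihood == pytest.approx(per_ref[winner].log_likelihood)
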
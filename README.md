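# repclust

Sequence- and structure-based antibody clustering, compared on simulated
B-cell receptor (BCR) repertoire data with a spiked-in set of
functionally similar antibody pairs.

## The problem

Clustering is a central step in BCR repertoire analysis. The standard
approach, **clonotyping**, groups sequences that share V/J germline gene
calls and have high CDRH3 amino-acid identity — it finds clonally
related antibodies but misses *functionally converged* ones: antibodies
from different lineages that bind the same epitope. Structure-based
alternatives partition antibodies by the lengths of their six CDR loops
and cluster on the RMSD of CDR backbone atoms after framework
superposition, promising to recover convergent binders that sequence
identity cannot.

`repclust` implements both families plus the evaluation machinery needed
to compare them fairly on a repertoire where ground truth is known:

1. **Pair curation** — antibodies binding the same antigen are declared
   functionally similar when their epitope residue sets overlap with
   Jaccard index J(E₁,E₂) = |E₁∩E₂| / |E₁∪E₂| ≥ 0.75. Each retained
   pair is annotated with CDRH3 identity, 1 − L/(len C₁ + len C₂) for
   Levenshtein distance L, and whether all six CDR lengths match.
2. **Germline-guided backtranslation** — amino-acid chains are rebuilt
   as nucleotide sequences against their most similar germline V/J
   references, choosing per codon the synonym with fewest substitutions
   and breaking ties with a trimer substitution-likelihood model
   (aggregated from a fivemer context table; multi-substitution codons
   score the most likely mutation order).
3. **SHM calibration** — somatic hypermutation rates are counted per
   reference-covered nucleotide (the junction, which has no aligned
   reference, is excluded from the denominator) and reduced to a
   low/high tier pair, by default 5.1% and 11.9%.
4. **Repertoire simulation** — a naive heavy/kappa repertoire with SHM
   mixed as 50% unmutated, 36% low-rate, 14% high-rate; the curated,
   backtranslated antibodies are spiked in (10,490 unique sequences in
   the default configuration).
5. **Clustering** — clonotyping (single linkage = connected components
   of the thresholded identity graph, with V-only / no-gene / 70%
   variants), CDR-length partition clustering with and without an
   identity cutoff, and structure clustering (Kabsch framework
   superposition, CDR backbone RMSD, cutoff sweep 1.0–2.5 Å).
6. **Evaluation** — coverage, cluster-size and multiple-occupancy
   statistics, annotated-pair recovery (overall, and restricted to
   low-identity pairs with CDRH3 identity < 0.8), pair-level
   sensitivity/precision, and the **random clustering rate**: the
   expected number of annotated pairs co-clustered under random
   assignment to a fixed size distribution, estimated by Monte Carlo
   (1000 replicates) and checked against the closed form
   E = |P| · Σ s(s−1) / (n(n−1)).

All external resources are emulated by a first-class synthetic-data
module: toy germline segments, a synthetic fivemer table, backbone
coordinate fixtures, and a curated-set fixture of 54 antibodies / 213
pairs whose epitope-overlap graph (one 31-antibody component plus ten
clusters of 2–3, exactly 20 same-CDR-length pairs) is constructed
exactly via nested residue sets.

## Worked example

```python
from repclust.synthetic_repertoire import (
    make_study_fixture, toy_heavy_references, default_fivemer_model)
from repclust.backtranslation import aggregate_fivemer_to_trimer, backtranslate_with_stats
from repclust.pair_curation import select_pairs
from repclust.clustering import clonotype
from repclust.evaluation import cluster_metrics, pair_confusion

epitopes, records = make_study_fixture(seed=0)
pairs = select_pairs(epitopes, records)
print(f"{len(records)} antibodies, {len(pairs)} functionally similar pairs")
print(f"same-CDR-length pairs: {sum(p.same_cdr_lengths for p in pairs)}")

trimer = aggregate_fivemer_to_trimer(default_fivemer_model())
curated = [backtranslate_with_stats(r, toy_heavy_references(), trimer).record
           for r in records]
assignment = clonotype(curated)
m = cluster_metrics(assignment, pairs)
_, _, _, prec = pair_confusion(assignment, [r.antibody_id for r in curated], pairs)
print(f"clonotype: {m.pairs_recovered} pairs recovered "
      f"({m.pairs_recovered_pct}%), precision {prec:.2f}")
```

prints

```
54 antibodies, 213 functionally similar pairs
same-CDR-length pairs: 20
clonotype: 20 pairs recovered (9.39%), precision 1.00
```

Read: of the 213 annotated same-epitope pairs, default clonotyping on
the curated set alone recovers the 20 whose members come from the same
CDRH3 family, and it co-clusters no functionally unrelated curated
antibodies (precision 1.00). Most pairs (193/213, 90.61%) differ in at
least one CDR length, which also caps what length-partitioned structure
clustering can recover.

The full pipeline — including simulation, spike-in, every clustering
variant and the random-rate null — runs as:

```bash
repclust run --seed 7 --out-dir runs/demo
```

and writes per-stage artifacts (AIRR TSV, CSV tables, `report.json`)
plus a checksum manifest; identical seed and config give identical
checksums. Individual stages are exposed as `repclust
{curate,backtranslate,shm,simulate,cluster,evaluate}`.

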
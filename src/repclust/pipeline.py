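"""End-to-end orchestration: curate -> backtranslate -> calibrate ->
simulate + spike-in -> cluster -> evaluate.

A single global seed deterministically derives one seed per stage
(CRC32 of the stage name mixed into the global seed), so any stage can
be reproduced in isolation and identical configs give byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clustering, evaluation, model_io, pair_curation, shm_calibration, synthetic_repertoire
from .backtranslation import aggregate_fivemer_to_trimer, backtranslate_with_stats
from .clustering import ClonotypeSettings, StructureSettings
from .pair_curation import CurationConfig
from .shm_calibration import RateTiers

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


#: the stringency variants of clonotyping swept by the comparison
CLONOTYPE_VARIANTS: dict[str, ClonotypeSettings] = {
    "clonotype": ClonotypeSettings(),
    "clonotype_v_only_80": ClonotypeSettings(j_match=False),
    "clonotype_vj_70": ClonotypeSettings(identity_cutoff=0.70),
    "clonotype_v_only_70": ClonotypeSettings(j_match=False, identity_cutoff=0.70),
    "clonotype_no_genes_80": ClonotypeSettings(v_match=False, j_match=False),
}


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    ``n_sequences`` defaults to 10436 so the spiked repertoire totals
    10,490 unique sequences once the 54 curated antibodies are added.
    Structure clustering runs on the curated set plus a random
    subsample of ``n_structures`` simulated antibodies (pairwise RMSD
    within every CDR-length class is quadratic in class size).
    """

    seed: int = 7
    out_dir: str = "runs/demo"
    n_sequences: int = 10436
    n_structures: int = 800
    n_random_reps: int = 1000
    curation: CurationConfig = field(default_factory=CurationConfig)
    tiers: RateTiers = field(default_factory=RateTiers)
    structure: StructureSettings = field(default_factory=StructureSettings)
    derive_tiers_from_data: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "curation" in d and isinstance(d["curation"], dict):
            d["curation"] = CurationConfig(**d["curation"])
        if "tiers" in d and isinstance(d["tiers"], dict):
            t = dict(d["tiers"])
            if isinstance(t.get("mixture"), list):
                t["mixture"] = tuple(t["mixture"])
            d["tiers"] = RateTiers(**t)
        if "structure" in d and isinstance(d["structure"], dict):
            s = dict(d["structure"])
            for k in ("sweep", "backbone_atoms"):
                if isinstance(s.get(k), list):
                    s[k] = tuple(s[k])
            d["structure"] = StructureSettings(**s)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (artifact paths + checksums).

    Writes, under ``config.out_dir``: the resolved config, the curated
    epitope table and records, the pair table, the SHM profile table,
    the spiked repertoire (AIRR TSV), one cluster table per method, and
    the evaluation report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    artifacts["config"] = config_path

    # --- stage 1: curated fixture + pair curation
    epitopes, curated = synthetic_repertoire.make_study_fixture(
        seed=stage_seed(config.seed, "fixture"), rate_tiers=config.tiers
    )
    artifacts["epitopes"] = model_io.write_epitope_table(epitopes, out / "epitopes.csv")
    pairs = pair_curation.select_pairs(epitopes, curated, config.curation)
    artifacts["pairs"] = model_io.write_pair_table(pairs, out / "pairs.csv")
    logger.info("curation: %d antibodies, %d pairs", len(curated), len(pairs))

    # --- stage 2: backtranslation of the curated set
    trimer = aggregate_fivemer_to_trimer(synthetic_repertoire.default_fivemer_model())
    references = synthetic_repertoire.toy_heavy_references()
    results = [backtranslate_with_stats(r, references, trimer) for r in curated]
    curated_nt = [res.record for res in results]
    artifacts["curated_airr"] = model_io.write_airr(curated_nt, out / "curated.tsv")

    # --- stage 3: SHM calibration
    profiles = [shm_calibration.profile_from_backtranslation(res) for res in results]
    tiers = (
        shm_calibration.derive_rate_tiers(
            profiles, mixture=config.tiers.mixture, method="variance"
        )
        if config.derive_tiers_from_data
        else config.tiers
    )
    shm_path = out / "shm_profiles.csv"
    import pandas as pd

    pd.DataFrame(
        [
            {
                "antibody_id": p.antibody_id,
                "n_mutations": p.n_mutations,
                "covered_len": p.covered_len,
                "total_len": p.total_len,
                "corrected_rate": p.corrected_rate,
            }
            for p in profiles
        ]
    ).to_csv(shm_path, index=False)
    artifacts["shm_profiles"] = shm_path
    logger.info("tiers: low=%.4f high=%.4f", tiers.low_rate, tiers.high_rate)

    # --- stage 4: repertoire simulation + spike-in
    sim_config = synthetic_repertoire.SimConfig(
        n_sequences=config.n_sequences,
        rate_tiers=tiers,
        seed=stage_seed(config.seed, "simulate"),
    )
    simulated = synthetic_repertoire.simulate_repertoire(sim_config, trimer)
    repertoire = synthetic_repertoire.spike_in(
        simulated, curated_nt, seed=stage_seed(config.seed, "spike")
    )
    artifacts["repertoire"] = model_io.write_airr(repertoire, out / "repertoire.tsv")

    # --- stage 5: clustering (sequence- and structure-based)
    assignments: dict[str, model_io.ClusterAssignment] = {}
    for name, settings in CLONOTYPE_VARIANTS.items():
        assignments[name] = clustering.clonotype(repertoire, settings)
    assignments["length_only"] = clustering.cluster_length_identity(repertoire, None)
    assignments["length_identity_80"] = clustering.cluster_length_identity(repertoire, 0.80)

    import numpy as np

    rng = np.random.default_rng(stage_seed(config.seed, "structures"))
    curated_ids = {r.antibody_id for r in curated_nt}
    sim_only = [r for r in repertoire if r.antibody_id not in curated_ids]
    n_sub = min(config.n_structures, len(sim_only))
    subsample = [sim_only[i] for i in rng.choice(len(sim_only), size=n_sub, replace=False)]
    struct_records = curated_nt + subsample
    groups = {r.antibody_id: r.antibody_id for r in subsample}
    for ci, comp in enumerate(pair_curation.functional_clusters(pairs)):
        for aid in comp:
            groups[aid] = f"functional-{ci}"
    for r in curated_nt:  # curated antibodies outside any pair keep their own conformation
        groups.setdefault(r.antibody_id, r.antibody_id)
    models = synthetic_repertoire.make_backbone_fixture(
        struct_records, seed=stage_seed(config.seed, "backbones"), groups=groups
    )
    assignments["structure"] = clustering.structure_cluster(models, config.structure)
    sweep = clustering.structure_cluster_sweep(models, config.structure)

    for name, assignment in assignments.items():
        path = out / f"clusters_{name}.csv"
        pd.DataFrame(
            sorted(assignment.assignment.items()),
            columns=["antibody_id", "cluster_id"],
        ).to_csv(path, index=False)
        artifacts[f"clusters_{name}"] = path

    # --- stage 6: evaluation
    report: dict = {
        "dataset": {
            "n_curated": len(curated),
            "n_pairs": len(pairs),
            "n_repertoire": len(repertoire),
            "n_same_length_pairs": sum(p.same_cdr_lengths for p in pairs),
        },
        "tiers": {"low_rate": tiers.low_rate, "high_rate": tiers.high_rate},
        "methods": {},
        "structure_sweep": {},
    }
    curated_id_list = sorted(curated_ids)
    for name, assignment in assignments.items():
        metrics = evaluation.cluster_metrics(assignment, pairs)
        tp, fp, sens, prec = evaluation.pair_confusion(assignment, curated_id_list, pairs)
        items = sorted(assignment.assignment)
        rate = evaluation.random_clustering_rate(
            assignment.sizes,
            len(items),
            [p for p in pairs if p.id_a in assignment.assignment and p.id_b in assignment.assignment],
            n_reps=config.n_random_reps,
            seed=stage_seed(config.seed, f"random-{name}"),
            item_ids=items,
        )
        report["methods"][name] = {
            **metrics.as_dict(),
            "tp": tp,
            "fp": fp,
            "sensitivity": sens,
            "precision": prec,
            "random_rate_mc": rate.mean_rate,
            "random_rate_analytic": rate.analytic_rate,
        }
    for cutoff, assignment in sweep.items():
        m = evaluation.cluster_metrics(assignment, pairs)
        report["structure_sweep"][str(cutoff)] = {
            "pairs_recovered": m.pairs_recovered,
            "n_clusters": m.n_clusters,
        }
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    artifacts["report"] = report_path

    manifest = {
        "seed": config.seed,
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
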
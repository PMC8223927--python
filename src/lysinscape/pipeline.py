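"""End-to-end orchestration: simulate/load → curate → features → architecture
→ robust stats → classifier → SSN, with per-stage TSV outputs and a summary.

A single global seed is fanned out to per-stage seeds by stable hashing of
the stage name, so toggling one stage never shifts another stage's
randomness.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import architecture, census, classify, physchem, robust, simulate, ssn
from .curation import CurationConfig, run_curation
from .io import (
    load_host_metadata,
    read_domain_hits,
    read_fasta,
    hits_to_frame,
    records_to_frame,
    write_domain_hits,
    write_fasta,
)

__all__ = ["PipelineConfig", "PipelineError", "stage_seed", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("curate", "physchem", "architecture", "stats", "classify", "ssn")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from the global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: str | Path = "results/pipeline"
    seed: int = 0
    #: generated dataset size per class when no input FASTA is given
    n_per_class: int = 300
    fasta: str | Path | None = None
    hits: str | Path | None = None
    metadata: str | Path | None = None
    signal_flags: str | Path | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {name: True for name in STAGES}
    )
    curation: CurationConfig = field(default_factory=CurationConfig)
    physchem: physchem.PhyschemConfig = field(default_factory=physchem.PhyschemConfig)
    stats: robust.TestConfig = field(default_factory=robust.TestConfig)
    #: SSN runs on planted subfamily blocks sized for quick inspection
    ssn_families: int = 2
    ssn_per_family: int = 15
    ssn_threshold: float = ssn.DEFAULT_THRESHOLD


def _quartile_table(records, cfg: physchem.PhyschemConfig) -> pd.DataFrame:
    rows = []
    for rec in records:
        if rec.length < 4 or rec.gram is None:
            continue
        for q, v in enumerate(
            physchem.quartile_values(rec.sequence, "net_charge", cfg), start=1
        ):
            rows.append(
                {"protein_id": rec.id, "gram": rec.gram.value, "quartile": f"Q{q}",
                 "net_charge": v}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run all enabled stages; write TSVs under ``output_dir``; return a bundle."""
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, object] = {}
    durations: dict[str, float] = {}
    summary: list[str] = []

    def run_stage(name: str, fn):
        if not cfg.stages.get(name, True):
            logger.info("stage %s disabled", name)
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # partial outputs already on disk are kept
            raise PipelineError(name, exc) from exc
        durations[name] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", name, durations[name])
        return result

    metadata = load_host_metadata(cfg.metadata)

    # inputs: load or simulate
    if cfg.fasta is not None:
        records = read_fasta(cfg.fasta)
        hits = read_domain_hits(cfg.hits) if cfg.hits else []
        if cfg.signal_flags:
            flags = pd.read_csv(cfg.signal_flags, sep="\t")
            flagged = dict(zip(flags["protein_id"], flags["signal_peptide"]))
            records = [
                r.copy(signal_peptide=bool(flagged.get(r.id, False))) for r in records
            ]
    else:
        sim_cfg = simulate.GeneratorConfig(
            seed=stage_seed(cfg.seed, "simulate"), n_per_class=cfg.n_per_class
        )
        ds = simulate.generate_dataset(sim_cfg)
        records, hits = ds.records, ds.hits
        write_fasta(records, out / "input.fasta")
        write_domain_hits(hits, out / "input_hits.tsv")
        ds.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        bundle["truth"] = ds.truth

    def stage_curate():
        curated, report = run_curation(records, hits, metadata, cfg.curation)
        write_fasta(curated, out / "curated.fasta")
        pd.DataFrame(
            [
                {"stage": s.name, "n_in": s.n_in, "n_out": s.n_out,
                 "n_removed": len(s.removed_ids)}
                for s in report.stages
            ]
        ).to_csv(out / "curation_report.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"representative": rep, "member": m}
                for rep, members in report.cluster_map.items()
                for m in members
            ]
        ).to_csv(out / "cluster_map.tsv", sep="\t", index=False)
        summary.append(
            "curation: " + " -> ".join(
                f"{s.name}:{s.n_out}" for s in report.stages
            )
        )
        return curated, report

    curated_pair = run_stage("curate", stage_curate)
    curated = curated_pair[0] if curated_pair else list(records)
    bundle["curated"] = curated
    bundle["curation_report"] = curated_pair[1] if curated_pair else None

    def stage_physchem():
        feats = physchem.build_feature_table(curated, hits, cfg.physchem,
                                             cfg.curation.evalue_cutoff)
        feats.to_csv(out / "features.tsv", sep="\t", index=False)
        quart = _quartile_table(curated, cfg.physchem)
        quart.to_csv(out / "quartile_net_charge.tsv", sep="\t", index=False)
        return feats, quart

    phys_pair = run_stage("physchem", stage_physchem)
    bundle["features"] = phys_pair[0] if phys_pair else None

    def stage_architecture():
        arch = architecture.summarize_all(curated, hits)
        arch.to_csv(out / "architecture.tsv", sep="\t", index=False)
        dist, single = architecture.hits_per_protein_distribution(curated, hits)
        dist.to_csv(out / "hits_per_protein.tsv", sep="\t")
        share = architecture.gram_share_per_family(hits, curated)
        share.to_csv(out / "gram_share_per_family.tsv", sep="\t", index=False)
        ct = architecture.crosstab(hits, curated, rows="genus", cols="family")
        ct.counts.to_csv(out / "crosstab_genus_family.tsv", sep="\t")
        for grp, frac in single.items():
            summary.append(f"single-hit fraction [{grp}]: {frac:.3f}")
        return arch, dist, single, share

    run_stage("architecture", stage_architecture)

    def stage_stats():
        if phys_pair is None:
            raise RuntimeError("stats stage needs the physchem stage outputs")
        quart = phys_pair[1]
        res = robust.compare_groups(
            quart, value="net_charge", between="gram", strata="quartile",
            config=cfg.stats,
        )
        res.to_csv(out / "quartile_tests.tsv", sep="\t", index=False)
        for r in res.itertuples():
            summary.append(
                f"net charge {r.label}: p_adj={r.p_adjusted:.3g} zeta={r.zeta:.2f}"
            )
        return res

    bundle["quartile_tests"] = run_stage("stats", stage_stats)

    def stage_classify():
        if phys_pair is None:
            raise RuntimeError("classify stage needs the physchem stage outputs")
        report = classify.fit_evaluate(
            phys_pair[0],
            classify.ClassifierConfig(seed=stage_seed(cfg.seed, "classify")),
        )
        report.roc.to_csv(out / "roc_points.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "metric": ["auc", "best_threshold", "accuracy", "sensitivity",
                           "specificity"],
                "value": [report.auc, report.best_threshold, report.accuracy,
                          report.sensitivity, report.specificity],
            }
        ).to_csv(out / "classifier_report.tsv", sep="\t", index=False)
        report.importances.rename("gini_decrease").to_csv(
            out / "importances.tsv", sep="\t"
        )
        summary.append(
            f"classifier: AUC={report.auc:.3f} acc={report.accuracy:.3f} "
            f"thr={report.best_threshold:.3f}"
        )
        return report

    bundle["classifier"] = run_stage("classify", stage_classify)

    def stage_ssn():
        fam_records, labels = simulate.generate_subfamilies(
            n_families=cfg.ssn_families,
            n_per_family=cfg.ssn_per_family,
            seed=stage_seed(cfg.seed, "ssn"),
        )
        sims = ssn.pairwise_similarity(fam_records)
        graph = ssn.build_network(sims, cfg.ssn_threshold, sequences=fam_records)
        ssn.export_graph(graph, out / "ssn.graphml", "graphml")
        ssn.export_graph(graph, out / "ssn_edges.tsv", "tsv")
        import networkx as nx

        n_comp = nx.number_connected_components(graph)
        summary.append(f"ssn: {graph.number_of_nodes()} nodes, "
                       f"{graph.number_of_edges()} edges, {n_comp} components")
        return graph, labels

    bundle["ssn"] = run_stage("ssn", stage_ssn)

    summary.extend(f"duration[{k}]={v:.2f}s" for k, v in durations.items())
    summary.append(f"seed={cfg.seed}")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    bundle["summary"] = summary
    bundle["durations"] = durations
    bundle["census"] = census.census_summary()
    return bundle
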
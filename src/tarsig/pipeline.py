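"""End-to-end orchestration: counts in, scored and stratified cells out.

``run_pipeline`` executes, as configured: bulk simulation (or load) ->
expression filtering, TMM, log-CPM, moderated contrasts per genotype ->
genotype partition -> homolog mapping -> single-cell simulation (or
load) -> QC, normalization, cluster annotation, keratinocyte-
preferential filtering, composite scoring, stratification and
stress-keratin association -> repeat-response classification. Every
artifact is written under the configured output directory together with
a machine-readable run report; identical config (including seeds)
yields identical artifacts.
"""

from __future__ import annotations

import time
import warnings
from pathlib import Path

import pandas as pd

from . import bulkde, io, repeatclass, scscore, sigderive, synthio
from .config import PipelineConfig

__all__ = ["run_pipeline"]


class _Report:
    def __init__(self, config: PipelineConfig):
        self.payload: dict = {
            "config_hash": config.config_hash(),
            "version": config.version,
            "stages": [],
        }

    def stage(self, name: str, params: dict, dims: dict, warns: list[str],
              elapsed: float) -> None:
        self.payload["stages"].append(
            {"name": name, "params": params, "dims": dims,
             "warnings": warns, "seconds": round(elapsed, 3)}
        )


def _bulk_matrix(config: PipelineConfig, out: Path):
    if config.bulk_input is not None:
        m = io.read_bulk_counts(config.bulk_input.counts, config.bulk_input.design)
        return m, None, {"source": "input"}
    c = config.bulk_sim
    params = synthio.BulkSimParams(
        n_genes=c.n_genes, n_reps=c.n_reps, baseline_log_mu=c.baseline_log_mu,
        baseline_log_sigma=c.baseline_log_sigma, dispersion=c.dispersion,
        effect_wt_only=c.effect_wt_only, effect_shared=c.effect_shared,
        effect_ko_only=c.effect_ko_only, effect_down=c.effect_down,
        n_per_class=c.n_per_class, libsize_range=(c.libsize_min, c.libsize_max),
        seed=c.seed,
    )
    m, truth = synthio.generate_bulk_counts(params)
    io.write_bulk_counts(m, out / "bulk_counts.tsv", out / "bulk_design.tsv")
    io.write_json(truth.to_dict(), out / "bulk_truth.json")
    return m, truth, c.model_dump()


def _sc_matrix(config: PipelineConfig, signature_genes: list[str], out: Path):
    if config.sc_input is not None:
        adata = io.read_mtx_dir(config.sc_input.mtx_dir, config.sc_input.metadata)
        return adata, None, {"source": "input"}
    c = config.sc_sim
    clusters = (
        synthio.ClusterSpec("c0", "KC", c.n_kc, ("KRT10", "KRT15", "KRT2")),
        synthio.ClusterSpec("c1", "Myeloid", c.n_myeloid, ("LYZ",)),
        synthio.ClusterSpec("c2", "TC", c.n_tc, ("CD3D",)),
        synthio.ClusterSpec("c3", "Mel", c.n_mel, ("PMEL",)),
    )
    planted = tuple(signature_genes[: c.n_signature_genes])
    if not planted:
        raise ValueError("no mapped human genes available to plant a signature")
    params = synthio.SCSimParams(
        cluster_spec=clusters,
        signature_spec=synthio.SignatureSpec(
            genes=planted, stressed_fraction=c.stressed_fraction,
            activity_fold=c.activity_fold, coupling_fold=c.coupling_fold,
        ),
        n_background_genes=c.n_background_genes, depth=c.depth,
        dispersion=c.dispersion, qc_fail_fraction=c.qc_fail_fraction, seed=c.seed,
    )
    adata, truth = synthio.generate_sc_counts(params)
    io.write_mtx_dir(adata, out / "sc")
    io.write_json(truth.to_dict(), out / "sc_truth.json")
    return adata, truth, c.model_dump()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the run report (also written
    to ``<out_dir>/run_report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = _Report(config)

    def timed(name, fn, params):
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result, dims = fn()
        report.stage(name, params, dims, [str(w.message) for w in caught],
                     time.perf_counter() - t0)
        return result

    # ---- bulk DE ----------------------------------------------------
    def bulk_stage():
        m, _, src = _bulk_matrix(config, out)
        return (m, src), {"genes": int(m.counts.shape[0]),
                          "samples": int(m.counts.shape[1])}

    matrix, bulk_params = timed("bulk_counts", bulk_stage, {})
    del bulk_params  # recorded per-stage in the report

    def de_stage():
        filtered = bulkde.filter_low_expression(
            matrix, config.de.min_count, config.de.min_total
        )
        factors = bulkde.tmm_factors(filtered)
        logcpm = bulkde.log_cpm(filtered, factors)
        tables = {}
        for genotype in ("WT", "KO"):
            contrast = bulkde.ContrastSpec(
                name=f"{genotype}:TPA-vehicle", genotype=genotype
            )
            de = bulkde.moderated_de(logcpm, filtered.design, contrast)
            de.rename_axis("gene_id").to_csv(out / f"de_{genotype}.tsv", sep="\t")
            tables[genotype] = de
        factors.factors.rename_axis("sample_id").to_csv(
            out / "tmm_factors.tsv", sep="\t"
        )
        return tables, {"genes_after_filter": int(filtered.counts.shape[0])}

    de_tables = timed("bulk_de", de_stage, config.de.model_dump())

    def partition_stage():
        calls = {}
        for genotype, de in de_tables.items():
            for direction in ("up", "down"):
                calls[(genotype, direction)] = sigderive.call_regulated(
                    de, config.de.fc_threshold, config.de.adjp_threshold, direction
                )
        part = sigderive.partition_by_genotype(
            calls[("WT", "up")], calls[("KO", "up")],
            calls[("WT", "down")], calls[("KO", "down")],
            config.de.fc_threshold, config.de.adjp_threshold,
        )
        io.write_json(part.to_dict(), out / "partition.json")
        return part, part.counts()

    partition = timed("partition", partition_stage, {})

    def homolog_stage():
        if config.homolog.table is not None:
            table = sigderive.load_homolog_table(config.homolog.table)
        else:
            universe = list(matrix.gene_ids)
            table = synthio.generate_homolog_table(
                len(universe), config.homolog.p_unmapped,
                config.homolog.p_one_to_many, config.homolog.seed,
                mouse_genes=universe,
            )
            table.to_csv(out / "homolog_table.tsv", sep="\t", index=False)
        human, mapping = sigderive.map_homologs(set(partition.wt_only_up), table)
        io.write_json(mapping.to_dict(), out / "mapping_report.json")
        io.write_json({"human_genes": sorted(human)}, out / "human_geneset.json")
        return sorted(human), mapping.to_dict()

    human_genes = timed("map_homologs", homolog_stage, config.homolog.model_dump())

    # ---- single cell ------------------------------------------------
    def sc_stage():
        adata, _, _ = _sc_matrix(config, human_genes, out)
        return adata, {"cells": int(adata.n_obs), "genes": int(adata.n_vars)}

    adata = timed("sc_counts", sc_stage,
                  {} if config.sc_sim is None else config.sc_sim.model_dump())

    def score_stage():
        thresholds = scscore.QC_PRESETS[config.score.dataset_preset]
        filtered, removed = scscore.qc_filter(adata, thresholds)
        logexpr = scscore.normalize_log(filtered, config.score.scale)
        clusters = filtered.obs["cluster"].astype(str)
        annotation = scscore.annotate_clusters(logexpr, clusters)
        candidates = {g for g in human_genes if g in logexpr.columns}
        kc_genes = scscore.kc_preferential_filter(
            logexpr, clusters, annotation, candidates
        )
        if not kc_genes:
            raise ValueError("keratinocyte-preferential filter retained no genes")
        signature = scscore.SignatureDef(
            name="TAR_synthetic", genes=tuple(sorted(kc_genes))
        )
        scores = scscore.composite_score(logexpr, signature)
        strata, cutoffs = scscore.stratify(
            scores, config.score.high_pct, config.score.med_pct
        )
        strata.rename_axis("barcode").to_csv(out / "cell_scores.tsv", sep="\t")
        associations = {}
        for gene in config.score.association_genes:
            if gene in logexpr.columns:
                associations[gene] = scscore.stratum_association(
                    logexpr, strata["stratum"], gene
                )
        io.write_json(
            {"annotation": annotation, "qc_removed": removed, "cutoffs": cutoffs,
             "signature": list(signature.genes), "associations": associations},
            out / "score_summary.json",
        )
        return (strata, associations), {
            "cells_after_qc": int(filtered.n_obs),
            "signature_size": len(signature.genes),
        }

    timed("score", score_stage, config.score.model_dump())

    def classify_stage():
        if config.classify.table is not None:
            records = repeatclass.load_fold_change_table(config.classify.table)
        else:
            records = repeatclass.load_tar11_fold_changes()
        result = repeatclass.classify_repeat_response(
            records, config.classify.ratio_threshold
        )
        io.write_json(result.to_dict(), out / "repeat_classification.json")
        return result, {"n_genes": len(result.categories),
                        "n_repeat_associated": len(result.repeat_associated)}

    timed("classify_repeat", classify_stage, config.classify.model_dump())

    io.write_json(report.payload, out / "run_report.json")
    return report.payload
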
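"""Declarative pipeline configuration and the end-to-end run.

A ``RunConfig`` captures every stage parameter (seeds included) and is
schema-validated: unknown keys are rejected so a typo cannot silently fall
back to a default.  ``run_pipeline`` executes
QC -> normalize -> scale -> cluster -> cell-cycle score/regress -> signature
scoring/enrichment -> cluster-signature derivation -> pathway classification
on either a supplied count matrix or a freshly simulated one, writes all
stage outputs as TSV plus a config echo and a log, and is bit-reproducible
under a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cell_cycle import cc_regress, cc_score, phase_composition
from .containers import CountMatrix
from .fea import enrichment_table, score_signature
from .io import read_dense_tsv, read_mtx_triplet, write_tables
from .pathway_classes import class_abundance, classify_cells
from .preprocess import cluster_cells, normalize_log, qc_filter, scale_genes
from .signatures import derive_cluster_signature, read_gmt, write_gmt
from .synthetic import SimConfig, simulate_counts


class _Stage(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_Stage):
    n_genes: int = 3000
    n_cells: int = 2000
    n_clusters: int = 4
    program_cluster: int = 1
    program_name: str = "planted_program"
    program_log2_effect: float = 2.0
    program_size: int = 100
    n_lowdepth_cells: int = 0
    n_highmito_cells: int = 0
    n_doublets: int = 0
    qc_min_genes: int = 2000
    qc_max_mito: float = 0.15
    cycle_carrier_fraction: float = 0.3
    cycle_effect_log2: float = 2.0


class InputStage(_Stage):
    mtx_dir: Optional[str] = None
    dense_tsv: Optional[str] = None
    mito_prefix: str = "MT-"


class QCStage(_Stage):
    enabled: bool = True
    min_genes: int = 2000
    max_mito_frac: float = 0.15


class NormalizeStage(_Stage):
    scale: float = 1e4


class ScaleStage(_Stage):
    clip: Optional[float] = 10.0


class ClusterStage(_Stage):
    n_clusters: int = 4
    n_pcs: int = 20


class CellCycleStage(_Stage):
    enabled: bool = False
    regress: bool = False
    n_bins: int = 25
    n_ctrl: int = 50


class SignatureStage(_Stage):
    gmt: Optional[str] = None
    derive_clusters: List[int] = []
    lfc_min: float = 0.25
    alpha: float = 0.05
    min_pct: float = 0.1


class ClassifyStage(_Stage):
    enabled: bool = False
    signature_a: Optional[str] = None
    signature_b: Optional[str] = None
    t_a: float = 0.0
    t_b: float = 0.0
    cluster_id: int = 0


class RunConfig(_Stage):
    seed: int = 0
    outdir: Optional[str] = None
    input: Optional[InputStage] = None
    simulate: SimulateStage = SimulateStage()
    qc: QCStage = QCStage()
    normalize: NormalizeStage = NormalizeStage()
    scale: ScaleStage = ScaleStage()
    cluster: ClusterStage = ClusterStage()
    cellcycle: CellCycleStage = CellCycleStage()
    signatures: SignatureStage = SignatureStage()
    classify: ClassifyStage = ClassifyStage()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_or_simulate(config: RunConfig, log):
    if config.input is not None:
        if config.input.mtx_dir:
            cm = read_mtx_triplet(config.input.mtx_dir, config.input.mito_prefix)
        elif config.input.dense_tsv:
            cm = read_dense_tsv(config.input.dense_tsv, config.input.mito_prefix)
        else:
            raise ValueError("input stage given but no path set")
        log.append(f"loaded matrix: {cm.n_genes} genes x {cm.n_cells} cells")
        return cm, None
    s = config.simulate
    sim = SimConfig(
        n_genes=s.n_genes,
        n_cells=s.n_cells,
        n_clusters=s.n_clusters,
        program_assignments={s.program_cluster: [s.program_name]},
        program_log2_effect={s.program_name: s.program_log2_effect},
        program_size=s.program_size,
        n_lowdepth_cells=s.n_lowdepth_cells,
        n_highmito_cells=s.n_highmito_cells,
        n_doublets=s.n_doublets,
        qc_min_genes=s.qc_min_genes,
        qc_max_mito=s.qc_max_mito,
        seed=config.seed,
    )
    if config.cellcycle.enabled:
        from .cell_cycle import G2M_GENES, S_GENES
        from .synthetic import simulate_cycle_programs

        cm, gt = simulate_cycle_programs(
            sim, S_GENES, G2M_GENES,
            carrier_fraction=s.cycle_carrier_fraction,
            effect_log2=s.cycle_effect_log2,
        )
    else:
        cm, gt = simulate_counts(sim)
    log.append(
        f"simulated matrix: {cm.n_genes} genes x {cm.n_cells} cells, "
        f"program {s.program_name!r} in cluster {s.program_cluster}"
    )
    return cm, gt


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the in-memory report bundle."""
    log = [f"stemsig {__version__} | config {config.config_hash()} | seed {config.seed}"]
    outputs: dict = {}
    stage = "input"
    try:
        counts, gt = _load_or_simulate(config, log)
        if gt is not None:
            outputs["ground_truth"] = pd.DataFrame(
                {"barcode": gt.barcodes, "true_cluster": gt.true_cluster,
                 "qc_fail": gt.qc_fail}
            )

        stage = "qc"
        if config.qc.enabled:
            doublets = gt.doublet_labels() if gt is not None else None
            counts, report = qc_filter(
                counts, config.qc.min_genes, config.qc.max_mito_frac, doublets
            )
            log.append(
                f"qc: {report.n_input} -> {report.n_retained} cells "
                f"(lowdepth {report.n_low_genes}, highmito {report.n_high_mito}, "
                f"doublet {report.n_doublet})"
            )
            outputs["qc_report"] = report.to_frame()

        stage = "normalize"
        norm = normalize_log(counts, config.normalize.scale)
        stage = "scale"
        scaled = scale_genes(norm, config.scale.clip)
        log.append(f"normalized (scale {config.normalize.scale}) and z-scored "
                   f"(clip {config.scale.clip})")

        stage = "cluster"
        clusters = cluster_cells(
            scaled, config.cluster.n_clusters, config.cluster.n_pcs, config.seed
        )
        outputs["clusters"] = pd.DataFrame(
            {"barcode": clusters.barcodes, "cluster": clusters.labels}
        )
        log.append(f"clustered into {config.cluster.n_clusters} clusters "
                   f"({config.cluster.n_pcs} PCs)")

        stage = "cellcycle"
        if config.cellcycle.enabled:
            scores = cc_score(
                norm,
                n_bins=config.cellcycle.n_bins,
                n_ctrl=config.cellcycle.n_ctrl,
                seed=config.seed,
            )
            outputs["cell_cycle"] = scores.to_frame()
            outputs["phase_composition"] = phase_composition(clusters, scores)
            if config.cellcycle.regress:
                scaled = cc_regress(scaled, scores)
                log.append("cell-cycle scored and regressed")
            else:
                log.append("cell-cycle scored")

        stage = "signatures"
        sigs = []
        if config.signatures.gmt:
            sigs = read_gmt(config.signatures.gmt)
            log.append(f"loaded {len(sigs)} signatures from {config.signatures.gmt}")
        elif gt is not None:
            sigs = [gt.signature(p) for p in sorted(gt.program_genes)]
            log.append(f"using {len(sigs)} planted program signatures")

        derived = []
        for cid in config.signatures.derive_clusters:
            table, sig = derive_cluster_signature(
                norm, clusters, cid,
                lfc_min=config.signatures.lfc_min,
                alpha=config.signatures.alpha,
                min_pct=config.signatures.min_pct,
            )
            outputs[f"deg_cluster{cid}"] = table
            if sig is not None:
                derived.append(sig)
        if derived:
            log.append(f"derived {len(derived)} cluster signatures")

        stage = "enrichment"
        all_sigs = sigs + derived
        if all_sigs:
            table = enrichment_table(scaled, all_sigs, clusters)
            outputs["enrichment"] = table
            n_enriched = int(table["enriched"].sum())
            log.append(f"enrichment: {n_enriched} enriched (signature, cluster) pairs")
            score_frames = {
                s.name: score_signature(scaled, s).scores for s in all_sigs
            }
            outputs["signature_scores"] = pd.DataFrame(
                {"barcode": scaled.barcodes, **score_frames}
            )

        stage = "classify"
        if config.classify.enabled:
            by_name = {s.name: s for s in all_sigs}
            a = score_signature(scaled, by_name[config.classify.signature_a])
            b = score_signature(scaled, by_name[config.classify.signature_b])
            labels = classify_cells(a, b, config.classify.t_a, config.classify.t_b)
            outputs["pathway_classes"] = pd.DataFrame(
                {"barcode": labels.barcodes, "class": labels.labels}
            )
            outputs["class_abundance"] = class_abundance(
                labels, clusters, config.classify.cluster_id
            )
            log.append("classified cells into pathway-activity classes")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs["log"] = pd.DataFrame({"message": log})
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        write_tables(outputs, config.outdir)
        echo = dict(config.model_dump(),
                    _hash=config.config_hash(), _version=__version__)
        with open(os.path.join(config.outdir, "config.json"), "w") as fh:
            json.dump(echo, fh, indent=2, sort_keys=True)
        if derived:
            write_gmt(derived, os.path.join(config.outdir, "derived_signatures.gmt"))
    return outputs
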
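"""End-to-end orchestration: preprocess → label → bicluster → assign →
assemble → score → report.

The pipeline is single-process and deterministic: identical config + seed
produce byte-identical results. Every run writes a ``manifest.json``
recording the full configuration and per-stage counts, a ``run.log``, and
the report files from :func:`ctsr.io.write_regulon_report`. A ``.partial``
marker is present while a run is in flight and removed on success, so
leftover outputs from a failed run are recognizable.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .biclustering import BiclusterParams, run_biclustering
from .clustering import cluster_cells
from .modules import assign_modules
from .preprocess import PreprocessParams, filter_matrix, normalize_and_log
from .promoters import extract_promoters, write_promoters_bed
from .regulons import build_regulons, write_hits_tsv
from .scoring import score_regulons
from .types import GeneModule, PipelineError

log = logging.getLogger("ctsr")


@dataclass
class PipelineConfig:
    # inputs
    matrix: str | None = None
    mtx_dir: str | None = None
    labels: str | None = None
    module_list: str | None = None
    genome: str | None = None
    annotation: str | None = None
    motifs: str | None = None
    out_dir: str = "ctsr_out"
    # preprocessing
    cell_min_genes: int = 200
    gene_min_cell_fraction: float = 0.001
    skip_normalize: bool = False
    # clustering fallback
    k: int = 0  # number of clusters when no label file is given
    # biclustering
    q: float = 0.06
    consistency: float = 0.95
    max_biclusters: int = 500
    overlap_filter: float = 0.75
    include_down: bool = False
    fast: bool = False
    # module assignment
    module_alpha: float = 0.05
    # regulon assembly
    promoter_len: int = 1000
    scan_alpha: float = 1e-4
    min_regulon_genes: int = 5
    # scoring
    alpha: float = 0.05
    n_boot: int = 10000
    top_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if (self.matrix is None) == (self.mtx_dir is None):
            raise PipelineError("config: exactly one of matrix / mtx_dir is required")
        if self.genome is None or self.annotation is None or self.motifs is None:
            raise PipelineError("config: genome, annotation and motifs are required")
        if self.labels is None and self.k < 1:
            raise PipelineError("config: either a label file or k >= 1 is required")
        if self.alpha not in (0.001, 0.01, 0.05):
            raise PipelineError("config: alpha must be one of 0.001, 0.01, 0.05")


def read_module_list(path) -> list[GeneModule]:
    """Read a user gene-module file: one gene list per column, header = cell type."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    modules: list[GeneModule] = []
    for i, col in enumerate(df.columns):
        genes = [g for g in df[col].dropna().astype(str) if g.strip()]
        if genes:
            modules.append(GeneModule(
                genes=genes, cell_type=str(col), p_raw=float("nan"),
                p_adj=float("nan"), source_bicluster=-1,
            ))
    if not modules:
        raise PipelineError("module list file contains no genes")
    return modules


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict with per-stage counts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.touch()
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    counts: dict[str, object] = {}
    try:
        # --- input ---
        if config.matrix is not None:
            em = _stage("read_matrix")(cio.read_expression_dense)(config.matrix)
        else:
            em = _stage("read_matrix")(cio.read_expression_mtx)(config.mtx_dir)
        counts["genes_in"], counts["cells_in"] = em.n_genes, em.n_cells

        # --- preprocess ---
        pp = PreprocessParams(config.gene_min_cell_fraction, config.cell_min_genes)
        em = _stage("filter")(filter_matrix)(em, pp)
        if config.skip_normalize:
            import numpy as np
            em = dataclasses.replace(
                em, values=np.log1p(em.values), normalized=True, log_transformed=True
            )
        else:
            em = _stage("normalize")(normalize_and_log)(em)
        counts["genes_kept"], counts["cells_kept"] = em.n_genes, em.n_cells

        # --- labels ---
        if config.labels is not None:
            labeling = _stage("labels")(cio.read_cell_labels)(config.labels)
            em, labeling = _stage("labels")(cio.align_labels)(em, labeling)
            counts["labels"] = "user"
        else:
            labeling = _stage("cluster")(cluster_cells)(em, config.k, seed=config.seed)
            counts["labels"] = "clustered"
        counts["cell_types"] = len(labeling.label_set)

        # --- modules ---
        if config.module_list is not None:
            modules = _stage("module_list")(read_module_list)(config.module_list)
            counts["biclusters"] = 0
            counts["modules_source"] = "user"
        else:
            bp = BiclusterParams(
                q=config.q,
                consistency=config.consistency,
                max_biclusters=100 if config.fast else config.max_biclusters,
                overlap_filter=config.overlap_filter,
                levels=(1, -1) if config.include_down else (1,),
            )
            biclusters = _stage("biclustering")(run_biclustering)(em, bp)
            counts["biclusters"] = len(biclusters)
            modules = _stage("module_assignment")(assign_modules)(
                biclusters, labeling, config.module_alpha
            )
            counts["modules_source"] = "biclustering"
        counts["modules"] = len(modules)

        # --- regulon assembly ---
        annotation = _stage("annotation")(cio.read_gene_annotation)(config.annotation)
        module_genes = sorted({g for m in modules for g in m.genes})
        promoters = _stage("promoters")(extract_promoters)(
            annotation, config.genome, config.promoter_len, genes=module_genes or None
        )
        library = _stage("motifs")(cio.read_motif_library)(config.motifs)
        if modules:
            regulons = _stage("regulon_assembly")(build_regulons)(
                modules, promoters, library,
                min_genes=config.min_regulon_genes, scan_alpha=config.scan_alpha,
            )
        else:
            regulons = []
        counts["regulons"] = len(regulons)

        # --- scoring + report ---
        score_table = _stage("scoring")(score_regulons)(
            em, regulons, labeling,
            alpha=config.alpha, n_boot=config.n_boot,
            seed=config.seed, top_fraction=config.top_fraction,
        )
        counts["ctsrs"] = int(score_table.table["is_ctsr"].sum()) if len(score_table.table) else 0
        _stage("report")(cio.write_regulon_report)(score_table, regulons, out)
        if promoters.promoters:
            write_promoters_bed(promoters, out / "promoters.bed")
        write_hits_tsv(regulons, out / "hits.tsv")

        manifest = {"config": dataclasses.asdict(config), "counts": counts}
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        marker.unlink(missing_ok=True)
        log.info("pipeline finished: %s", counts)
        return {"out_dir": str(out), "counts": counts,
                "score_table": score_table, "regulons": regulons}
    finally:
        log.removeHandler(handler)
        handler.close()
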
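"""Regulon assembly: link active-module genes to TFs via promoter motifs.

For each cell type, the genes of its active modules are pooled and each
gene's promoter is scanned with every motif in the library. Genes with at
least one hit for a TF's motif form that TF's regulon in that cell type
(a nonredundant gene list); motifs sharing a TF name are merged by gene
union. Regulons below ``min_genes`` genes are dropped.
"""
from __future__ import annotations

import logging

from .motifs import pwm_log_odds, score_pvalue_threshold, scan_promoter
from .types import GeneModule, MotifLibrary, PromoterSet, Regulon

log = logging.getLogger("ctsr")


def build_regulons(
    modules: list[GeneModule],
    promoters: PromoterSet,
    library: MotifLibrary,
    min_genes: int = 5,
    scan_alpha: float = 1e-4,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> list[Regulon]:
    """Assemble per-(cell type, TF) regulons from module genes' motif hits."""
    if not modules:
        return []
    by_type: dict[str, list[str]] = {}
    for m in modules:
        pool = by_type.setdefault(m.cell_type, [])
        for g in m.genes:
            if g not in pool:
                pool.append(g)
    all_genes = {g for pool in by_type.values() for g in pool}
    with_promoter = {g for g in all_genes if g in promoters}
    if not with_promoter:
        missing = sorted(all_genes)
        raise ValueError(
            f"no promoters available for any module gene; missing: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    n_missing = len(all_genes) - len(with_promoter)
    if n_missing:
        log.warning("%d module gene(s) lack promoters and are skipped", n_missing)

    scanners = []
    for pwm in library:
        sm = pwm_log_odds(pwm, background)
        threshold, null = score_pvalue_threshold(sm, scan_alpha)
        scanners.append((pwm, sm, threshold, null))

    regulons: list[Regulon] = []
    for cell_type in by_type:
        genes = [g for g in by_type[cell_type] if g in promoters]
        by_tf: dict[str, Regulon] = {}
        for pwm, sm, threshold, null in scanners:
            hit_genes, hits = [], []
            for g in genes:
                gh = scan_promoter(promoters[g].sequence, sm, threshold, null, gene_id=g)
                if gh:
                    hit_genes.append(g)
                    hits.extend(gh)
            if not hit_genes:
                continue
            reg = by_tf.get(pwm.tf_name)
            if reg is None:
                by_tf[pwm.tf_name] = Regulon(
                    cell_type, pwm.tf_name, pwm.motif_id, hit_genes, hits
                )
            else:
                reg.motif_id = f"{reg.motif_id},{pwm.motif_id}"
                reg.genes = reg.genes + [g for g in hit_genes if g not in reg.genes]
                reg.hits = reg.hits + hits
        for tf in sorted(by_tf):
            reg = by_tf[tf]
            if len(reg.genes) >= min_genes:
                reg.genes = sorted(reg.genes)
                regulons.append(reg)
    log.info("assembled %d regulon(s) with >= %d genes", len(regulons), min_genes)
    return regulons


def write_hits_tsv(regulons: list[Regulon], path) -> None:
    """Write all motif hits as hits.tsv (gene, motif, offset, strand, score, p)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tmotif_id\toffset\tstrand\tscore\tp_value\n")
        for reg in regulons:
            for h in sorted(reg.hits, key=lambda h: (h.gene_id, h.motif_id, h.offset, h.strand)):
                fh.write(
                    f"{h.gene_id}\t{h.motif_id}\t{h.offset}\t{h.strand}\t"
                    f"{h.score:.3f}\t{h.p_value:.3e}\n"
                )
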
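"""Readers and writers for every external format the pipeline touches.

Expression matrices arrive either as delimited text (genes × cells, header
row of cell ids) or as a 10x-style triplet directory (Matrix Market
coordinate file + barcodes + features). Motif libraries use the MEME minimal
motif format; gene annotations come from GTF or 6-column BED. All text I/O
is UTF-8 and gzip is handled transparently by file extension.
"""
from __future__ import annotations

import gzip
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    CellLabeling,
    ExpressionMatrix,
    FormatError,
    GeneAnnotation,
    GeneRecord,
    MotifLibrary,
    PWM,
)

log = logging.getLogger("ctsr")


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _infer_delimiter(path, first_line: str) -> str:
    name = os.fspath(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith(".csv"):
        return ","
    if name.endswith((".tsv", ".txt")):
        return "\t" if "\t" in first_line else ("," if "," in first_line else "\t")
    return "\t" if "\t" in first_line else ","


def _dedup_genes(values: np.ndarray, gene_ids: list[str]):
    """Collapse duplicate gene ids, keeping the row with the largest total."""
    if len(set(gene_ids)) == len(gene_ids):
        return values, gene_ids
    totals = values.sum(axis=1)
    best: dict[str, int] = {}
    for i, g in enumerate(gene_ids):
        j = best.get(g)
        if j is None or totals[i] > totals[j]:
            best[g] = i
    kept = sorted(best.values())
    n_dropped = len(gene_ids) - len(kept)
    log.warning("dropped %d duplicate gene id row(s), keeping max-sum rows", n_dropped)
    return values[kept], [gene_ids[i] for i in kept]


def read_expression_dense(path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a delimited genes × cells matrix (first row cells, first column genes)."""
    with _open_text(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty expression file")
    sep = delimiter or _infer_delimiter(path, first)
    df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: no genes or no cells")
    bad_cols = [c for c in df.columns if df[c].dtype == object]
    for c in bad_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        mask = coerced.isna() & df[c].notna()
        if mask.any():
            gene = df.index[mask.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric value at gene {gene!r}, cell {c!r}"
            )
        df[c] = coerced
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"{path}: non-finite value at gene {df.index[i]!r}, cell {df.columns[j]!r}"
        )
    values, gene_ids = _dedup_genes(values, [str(g) for g in df.index])
    return ExpressionMatrix(values, gene_ids, [str(c) for c in df.columns])


def _find_triplet_file(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise FormatError(f"{directory}: none of {stems} found")


def read_expression_mtx(directory) -> ExpressionMatrix:
    """Read a 10x-style triplet directory (matrix.mtx + barcodes + features)."""
    directory = Path(directory)
    mtx_path = _find_triplet_file(directory, ("matrix.mtx",))
    bc_path = _find_triplet_file(directory, ("barcodes.tsv", "barcodes.txt"))
    ft_path = _find_triplet_file(
        directory, ("features.tsv", "genes.tsv", "features.txt")
    )
    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat)
    with _open_text(bc_path) as fh:
        barcodes = [line.split("\t")[0].split(",")[0].strip() for line in fh if line.strip()]
    with _open_text(ft_path) as fh:
        features = [line.split("\t")[0].split(",")[0].strip() for line in fh if line.strip()]
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{mtx_path}: matrix is {mat.shape[0]} x {mat.shape[1]} but found "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    values, gene_ids = _dedup_genes(mat.toarray().astype(float), features)
    return ExpressionMatrix(values, gene_ids, barcodes)


def read_cell_labels(path) -> CellLabeling:
    """Read a two-column (cell id, cell type) file with optional header.

    The first row is treated as a header when its second field is not reused
    as a label by more than one other row.
    """
    rows: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected two columns")
            rows.append((parts[0], parts[1]))
    if not rows:
        raise FormatError(f"{path}: empty label file")
    if len(rows) > 1:
        reuse = sum(1 for _, lab in rows[1:] if lab == rows[0][1])
        if reuse <= 1:
            rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: only a header row found")
    seen: dict[str, str] = {}
    for cell, lab in rows:
        if cell in seen and seen[cell] != lab:
            raise FormatError(
                f"{path}: cell {cell!r} labeled both {seen[cell]!r} and {lab!r}"
            )
        seen[cell] = lab
    cells = list(dict.fromkeys(c for c, _ in rows))
    return CellLabeling(cells, [seen[c] for c in cells])


def align_labels(em: ExpressionMatrix, labeling: CellLabeling) -> tuple[ExpressionMatrix, CellLabeling]:
    """Intersect matrix and labeling by cell id, preserving matrix cell order."""
    lab = labeling.as_dict()
    keep = [i for i, c in enumerate(em.cell_ids) if c in lab]
    if not keep:
        raise FormatError("no cells shared between matrix and label file")
    dropped_mat = em.n_cells - len(keep)
    dropped_lab = len(labeling.cell_ids) - len(keep)
    if dropped_mat:
        log.warning("dropping %d unlabeled cell(s) from the matrix", dropped_mat)
    if dropped_lab:
        log.warning("dropping %d labeled cell(s) absent from the matrix", dropped_lab)
    cells = [em.cell_ids[i] for i in keep]
    em2 = ExpressionMatrix(
        em.values[:, keep], em.gene_ids, cells, em.normalized, em.log_transformed
    )
    return em2, CellLabeling(cells, [lab[c] for c in cells])


def read_motif_library(path) -> MotifLibrary:
    """Parse a MEME minimal-format motif file into position probability matrices.

    Rows of a letter-probability matrix are renormalized when their sum is
    within 1e-3 of 1 and rejected otherwise. Only the ACGT alphabet is
    supported.
    """
    motifs: list[PWM] = []
    alphabet_seen = False
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty motif file")
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alpha = line.split("=", 1)[1].replace(" ", "")
            if alpha.upper() != "ACGT":
                raise FormatError(f"{path}: unsupported alphabet {alpha!r}")
            alphabet_seen = True
        elif line.startswith("MOTIF"):
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: MOTIF line without identifier")
            motif_id = fields[1]
            tf_name = fields[2] if len(fields) > 2 else fields[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id}: no probability matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {motif_id}: no probability matrix")
            rows = []
            i += 1
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                try:
                    vals = [float(x) for x in stripped.split()]
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: motif {motif_id}: bad matrix row {stripped!r}"
                    ) from exc
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: motif {motif_id}: expected 4 columns, got {len(vals)}"
                    )
                rows.append(vals)
                i += 1
            matrix = np.asarray(rows, dtype=float)
            if matrix.shape[0] < 2:
                raise FormatError(f"{path}: motif {motif_id}: width < 2")
            sums = matrix.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise FormatError(
                    f"{path}: motif {motif_id}: row {bad} sums to {sums[bad]:.4f}"
                )
            matrix = matrix / sums[:, None]
            motifs.append(PWM(motif_id, tf_name, matrix))
            continue
        i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    if not alphabet_seen:
        log.warning("%s: no ALPHABET line; assuming ACGT", path)
    return MotifLibrary(motifs)


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " ") or chunk.startswith(key + "="):
            val = chunk[len(key):].strip(" =")
            return val.strip('"')
    return None


def read_gene_annotation(path, format: str | None = None) -> GeneAnnotation:
    """Read gene TSS records from a GTF (gene features) or 6-column BED file.

    GTF: TSS = start for '+' genes, end for '-' genes (1-based). BED intervals
    are 0-based half-open and converted to the same 1-based TSS convention.
    """
    if format is None:
        name = os.fspath(path)
        if name.endswith(".gz"):
            name = name[:-3]
        format = "bed" if name.endswith(".bed") else "gtf"
    if format not in ("gtf", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    records: dict[str, GeneRecord] = {}
    n_skipped = 0
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gtf":
                if len(fields) < 9:
                    raise FormatError(f"{path}:{ln}: GTF line with <9 fields")
                if fields[2] != "gene":
                    continue
                gene_id = _gtf_attribute(fields[8], "gene_id")
                if gene_id is None:
                    raise FormatError(f"{path}:{ln}: gene feature without gene_id")
                chrom, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
                if strand not in ("+", "-"):
                    n_skipped += 1
                    continue
                tss = start if strand == "+" else end
            else:
                if len(fields) < 6:
                    raise FormatError(f"{path}:{ln}: BED line with <6 fields")
                chrom, start0, end0, gene_id, _, strand = fields[:6]
                if strand not in ("+", "-"):
                    n_skipped += 1
                    continue
                tss = int(start0) + 1 if strand == "+" else int(end0)
            if gene_id in records:
                continue
            records[gene_id] = GeneRecord(gene_id, chrom, strand, tss)
    if n_skipped:
        log.warning("%s: skipped %d record(s) without strand", path, n_skipped)
    if not records:
        raise FormatError(f"{path}: no gene records found")
    return GeneAnnotation(records)


REGULON_COLUMNS = [
    "name", "cell_type", "tf", "n_genes", "rss", "p_empirical", "p_adjusted", "is_ctsr",
]


def write_regulon_report(score_table, regulons, out_dir) -> dict[str, Path]:
    """Write regulons.tsv, regulon_genes.tsv and results.json to ``out_dir``.

    ``score_table`` is the table from :func:`ctsr.scoring.call_ctsrs`;
    ``regulons`` the matching list of :class:`~ctsr.types.Regulon`. Output is
    deterministic: reruns on identical inputs are byte-identical.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    df = score_table.table.copy()
    by_name = {r.name: r for r in regulons}
    paths = {
        "regulons": out_dir / "regulons.tsv",
        "genes": out_dir / "regulon_genes.tsv",
        "json": out_dir / "results.json",
    }
    with open(paths["regulons"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(REGULON_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write(
                "\t".join([
                    row["name"], row["cell_type"], row["tf"], str(int(row["n_genes"])),
                    repr(float(row["rss"])), repr(float(row["p_empirical"])),
                    repr(float(row["p_adjusted"])),
                    "true" if bool(row["is_ctsr"]) else "false",
                ]) + "\n"
            )
    with open(paths["genes"], "w", encoding="utf-8") as fh:
        fh.write("name\tgene_id\n")
        for _, row in df.iterrows():
            for g in by_name[row["name"]].genes:
                fh.write(f"{row['name']}\t{g}\n")
    payload = {
        "regulons": [
            {
                "name": row["name"],
                "cell_type": row["cell_type"],
                "tf": row["tf"],
                "n_genes": int(row["n_genes"]),
                "rss": float(row["rss"]),
                "p_empirical": float(row["p_empirical"]),
                "p_adjusted": float(row["p_adjusted"]),
                "is_ctsr": bool(row["is_ctsr"]),
                "genes": list(by_name[row["name"]].genes),
            }
            for _, row in df.iterrows()
        ]
    }
    with open(paths["json"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_regulon_json(path) -> pd.DataFrame:
    """Read results.json back into the score-table layout (round-trip check)."""
    with _open_text(path) as fh:
        payload = json.load(fh)
    rows = [{k: r[k] for k in REGULON_COLUMNS} for r in payload["regulons"]]
    return pd.DataFrame(rows, columns=REGULON_COLUMNS)
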
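"""Shared data model for the regulon-inference pipeline.

The pipeline moves a gene × cell expression matrix through discretization,
biclustering, cell-type assignment, promoter motif scanning and regulon
scoring; the containers below are the contracts between those stages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


@dataclass
class ExpressionMatrix:
    """Gene × cell expression values with identifiers and normalization state.

    ``values`` has one row per entry of ``gene_ids`` and one column per entry
    of ``cell_ids``. ``normalized`` / ``log_transformed`` record what has been
    done to the values so downstream stages can refuse raw input.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}


@dataclass
class CellLabeling:
    """One categorical label (cell type / cluster) per cell."""

    cell_ids: list[str]
    labels: list[str]
    label_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_ids = list(self.cell_ids)
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("one label required per cell")
        if not self.labels:
            raise ValueError("empty labeling")
        if not self.label_set:
            # first-appearance order keeps CT numbering deterministic
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.label_set = list(seen)
        missing = set(self.labels) - set(self.label_set)
        if missing:
            raise ValueError(f"labels outside label_set: {sorted(missing)}")

    def cells_of(self, label: str) -> list[str]:
        return [c for c, l in zip(self.cell_ids, self.labels) if l == label]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # w x 4, rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be w x 4")
        if self.matrix.shape[0] < 2:
            raise FormatError(f"motif {self.motif_id}: width < 2")
        if np.any(self.matrix < 0):
            raise FormatError(f"motif {self.motif_id}: negative probability")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise FormatError(f"motif {self.motif_id}: rows do not sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MotifLibrary:
    motifs: list[PWM]

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass
class GeneRecord:
    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    tss: int  # 1-based transcription start position


@dataclass
class GeneAnnotation:
    """One TSS record per gene, used for promoter extraction."""

    records: dict[str, GeneRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]


@dataclass
class Bicluster:
    """A constant-level gene × cell block of the discretized matrix."""

    genes: list[str]
    cells: list[str]
    level: int  # +1 or -1
    score: int = 0

    def __post_init__(self) -> None:
        if self.level not in (-1, 1):
            raise ValueError("bicluster level must be +1 or -1")
        if len(self.genes) < 2 or len(self.cells) < 2:
            raise ValueError("bicluster needs >= 2 genes and >= 2 cells")
        if not self.score:
            self.score = len(self.genes) * len(self.cells)


@dataclass
class GeneModule:
    """A bicluster's gene set assigned to a cell type by cell enrichment."""

    genes: list[str]
    cell_type: str
    p_raw: float
    p_adj: float
    source_bicluster: int
    best: bool = False


@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str
    chromosome: str
    start: int  # 1-based closed interval on the forward genome
    end: int
    strand: str


@dataclass
class PromoterSet:
    promoters: dict[str, PromoterRecord]
    length: int = 1000

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.promoters

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self.promoters[gene_id]

    def __len__(self) -> int:
        return len(self.promoters)


@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    offset: int  # 0-based within the promoter (forward orientation)
    strand: str  # strand of the match relative to the promoter
    score: float  # log-odds score in bits
    p_value: float


@dataclass
class Regulon:
    """Genes of one cell type sharing a TF's promoter motif."""

    cell_type: str
    tf_name: str
    motif_id: str
    genes: list[str]
    hits: list[MotifHit] = field(default_factory=list)
    name: str = ""
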
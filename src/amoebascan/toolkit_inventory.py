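"""Sex/meiosis gene-toolkit inventory and per-sample detection matrix.

Genomic *presence* (a toolkit query has >= 1 homologous gene model at a
stringent e-value cutoff) and transcriptomic *detection* (the gene
model's transcript is seen in a sample) are kept strictly separate: a
gene can be genome-present yet undetected in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import HitRecord, SampleDetectionTable

TOOLKIT_CLASSES = ("meiosis_specific", "plasmogamy", "karyogamy", "other")

#: The 12 genes whose joint presence constitutes a complete meiosis toolkit.
MEIOSIS_TOOLKIT = ("SPO11", "DMC1", "HOP1", "HOP2", "MER3", "MND1",
                   "MSH4", "MSH5", "ZIP1", "PCH2", "REC8", "ZIP4")


@dataclass(frozen=True)
class ToolkitQuery:
    gene_name: str
    gene_class: str
    query_id: str

    def __post_init__(self) -> None:
        if self.gene_class not in TOOLKIT_CLASSES:
            raise ValueError(f"unknown toolkit class {self.gene_class!r}")


@dataclass(frozen=True)
class InventoryRow:
    gene_name: str
    gene_class: str
    model_ids: tuple[str, ...]

    @property
    def n_copies(self) -> int:
        return len(self.model_ids)

    @property
    def present(self) -> bool:
        return self.n_copies >= 1


@dataclass(frozen=True)
class Inventory:
    rows: tuple[InventoryRow, ...]
    fraction_found: float
    meiosis_complete: bool


@dataclass
class DetectionMatrix:
    """Toolkit gene model x sample matrix of '+'/'-' cells."""

    cells: pd.DataFrame  # index: model ids; columns: sample ids, design order
    conditions: dict[str, str]

    def row_pattern(self, model_id: str) -> str:
        return " ".join(self.cells.loc[model_id])


def inventory(queries: Sequence[ToolkitQuery], hits: Iterable[HitRecord],
              evalue_cutoff: float = 1e-15) -> Inventory:
    """Count distinct genome gene models hit by each toolkit query.

    A query protein's hits are rows with ``query_id`` equal to its id;
    distinct subject (genome model) ids with e <= cutoff are its copies.
    ``meiosis_complete`` requires every canonical meiosis-toolkit gene
    present.
    """
    if not queries:
        raise ValueError("empty toolkit query set")
    by_query: dict[str, set[str]] = {}
    for h in hits:
        if h.evalue <= evalue_cutoff:
            by_query.setdefault(h.query_id, set()).add(h.subject_id)
    rows = []
    for q in queries:
        models = tuple(sorted(by_query.get(q.query_id, ())))
        rows.append(InventoryRow(q.gene_name, q.gene_class, models))
    found = sum(r.present for r in rows)
    present_meiosis = {r.gene_name for r in rows
                       if r.gene_class == "meiosis_specific" and r.present}
    return Inventory(
        rows=tuple(rows),
        fraction_found=found / len(rows),
        meiosis_complete=set(MEIOSIS_TOOLKIT) <= present_meiosis,
    )


def detection_matrix(detection: SampleDetectionTable,
                     model_ids: Sequence[str],
                     detection_min: float = 1.0) -> DetectionMatrix:
    """Build the +/- detection matrix for the given gene models.

    Cell is '+' iff the detection value reaches ``detection_min``.
    Models absent from the table produce an all '-' row with a warning.
    Column order follows the sample design order; row order follows
    ``model_ids``.
    """
    import warnings

    known = {g for g, _ in detection.values}
    data = {}
    for mid in model_ids:
        if mid not in known:
            warnings.warn(f"gene model {mid!r} absent from detection table; "
                          "row is all '-'", stacklevel=2)
        data[mid] = ["+" if detection.value(mid, s) >= detection_min else "-"
                     for s in detection.sample_order]
    cells = pd.DataFrame.from_dict(data, orient="index",
                                   columns=detection.sample_order)
    return DetectionMatrix(cells, dict(detection.conditions))


@dataclass(frozen=True)
class ConditionSummary:
    per_sample: dict[str, int]           # genes detected in each sample
    per_condition: dict[str, int]        # genes detected in >=1 sample of cond
    gene_conditions: dict[str, frozenset[str]]  # conditions per gene


def condition_summary(matrix: DetectionMatrix) -> ConditionSummary:
    """Detection counts per sample / condition and condition sets per gene."""
    if matrix.cells.empty:
        raise ValueError("empty detection matrix")
    per_sample = {s: int((matrix.cells[s] == "+").sum())
                  for s in matrix.cells.columns}
    gene_conditions = {}
    for mid, row in matrix.cells.iterrows():
        gene_conditions[mid] = frozenset(
            matrix.conditions[s] for s in matrix.cells.columns
            if row[s] == "+")
    conditions = sorted(set(matrix.conditions.values()))
    per_condition = {
        cond: sum(1 for conds in gene_conditions.values() if cond in conds)
        for cond in conditions}
    return ConditionSummary(per_sample, per_condition, gene_conditions)
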
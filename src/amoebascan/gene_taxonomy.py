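"""Taxonomic partitioning of predicted gene models from protein best hits.

Each gene is assigned to exactly one of five categories — eukaryote,
bacteria, archaea, virus, or ORFan — from the superkingdom of its best
database hit.  A gene with no hit below the e-value cutoff is an ORFan
(an uncharacterized, possibly lineage-specific gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRecord

CATEGORIES = ("eukaryote", "bacteria", "archaea", "virus", "orfan")

_SUPERKINGDOM_TO_CATEGORY = {
    "Eukaryota": "eukaryote",
    "Bacteria": "bacteria",
    "Archaea": "archaea",
    "Viruses": "virus",
}


@dataclass(frozen=True)
class TaxonomicCall:
    gene_id: str
    category: str
    best_hit: HitRecord | None

    def __post_init__(self) -> None:
        if (self.category == "orfan") != (self.best_hit is None):
            raise ValueError("orfan iff no qualifying best hit")


@dataclass(frozen=True)
class PartitionSummary:
    counts: dict[str, int]
    proportions: dict[str, float]
    total: int


def best_hit(hits: Iterable[HitRecord], evalue_cutoff: float = 1e-3
             ) -> HitRecord | None:
    """Best hit under the cutoff: minimum e-value, ties broken by maximum
    bitscore, then lexicographically smallest subject id.  Order-invariant."""
    best: HitRecord | None = None
    for h in hits:
        if not h.evalue < evalue_cutoff:  # strict: e < cutoff
            continue
        if best is None:
            best = h
            continue
        key = (h.evalue, -h.bitscore, h.subject_id)
        best_key = (best.evalue, -best.bitscore, best.subject_id)
        if key < best_key:
            best = h
    return best


def classify_gene(gene_id: str, hits: Sequence[HitRecord],
                  evalue_cutoff: float = 1e-3) -> TaxonomicCall:
    """Classify one gene from its hits (all sharing the gene's query id)."""
    for h in hits:
        if h.query_id != gene_id:
            raise ValueError(f"hit for {h.query_id!r} passed to gene "
                             f"{gene_id!r}")
    bh = best_hit(hits, evalue_cutoff=evalue_cutoff)
    if bh is None:
        return TaxonomicCall(gene_id, "orfan", None)
    return TaxonomicCall(gene_id, _SUPERKINGDOM_TO_CATEGORY[bh.superkingdom], bh)


def classify_all(gene_hits: Mapping[str, Sequence[HitRecord]],
                 gene_ids: Iterable[str] | None = None,
                 evalue_cutoff: float = 1e-3) -> list[TaxonomicCall]:
    """Classify every gene; ``gene_ids`` supplies hit-less genes (ORFans)."""
    ids = list(gene_ids) if gene_ids is not None else list(gene_hits)
    return [classify_gene(g, gene_hits.get(g, ()), evalue_cutoff=evalue_cutoff)
            for g in ids]


def partition_summary(calls: Sequence[TaxonomicCall]) -> PartitionSummary:
    """Exact counts and proportions per category over all calls."""
    if not calls:
        raise ValueError("no taxonomic calls to summarize")
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    total = len(calls)
    return PartitionSummary(counts, {c: n / total for c, n in counts.items()},
                            total)
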
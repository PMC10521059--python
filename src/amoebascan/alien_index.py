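"""Alien Index scoring and lateral-gene-transfer calling.

The Alien Index (AI) contrasts a gene's best homology within its own
(recipient) lineage — here, eukaryotes — against its best homology in a
candidate donor group (bacteria, archaea, viruses):

    AI = ln(bbh_recipient + c) - ln(bbh_donor + c)

where bbh_* are best-hit e-values (1.0 when the group has no hit) and
c = 1e-200 is a pseudo-count that keeps AI finite when BLAST reports an
e-value of exactly 0.  Large positive AI means the gene looks far more
like the donor group than like its own lineage; genes with AI >= 45 are
called putative lateral gene transfers (LGTs).  With e-values clamped
to [0, 1], |AI| <= ln((1 + c)/c) ~= 460.52, attained at (1.0, 0.0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .gene_taxonomy import TaxonomicCall
from .io_formats import GeneModel, HitRecord, SampleDetectionTable

#: Default pseudo-count added to both e-values before taking logs.
DEFAULT_PSEUDOCOUNT = 1e-200
#: Default AI threshold for calling a putative LGT (boundary inclusive).
DEFAULT_THRESHOLD = 45.0

RECIPIENT_GROUP = frozenset({"Eukaryota"})
DONOR_GROUP = frozenset({"Bacteria", "Archaea", "Viruses"})


@dataclass(frozen=True)
class AlienIndexResult:
    gene_id: str
    bbh_recipient: float
    bbh_donor: float
    ai: float
    is_candidate: bool = False
    donor_superkingdom: str | None = None
    donor_phylum: str | None = None


@dataclass(frozen=True)
class LgtSummary:
    group: str
    n_group_matching: int
    n_candidates: int
    fraction: float
    donor_phylum_distribution: dict[str, float]
    n_expressed: int
    fraction_with_introns: float


def alien_index(bbh_recipient: float, bbh_donor: float,
                c: float = DEFAULT_PSEUDOCOUNT) -> float:
    """AI = ln(bbh_recipient + c) - ln(bbh_donor + c), inputs in [0, 1]."""
    for name, v in (("bbh_recipient", bbh_recipient), ("bbh_donor", bbh_donor)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return math.log(bbh_recipient + c) - math.log(bbh_donor + c)


def _in_group(hit: HitRecord, group: frozenset[str] | set[str]) -> bool:
    # a taxon-set spec matches at any lineage rank, so finer-grained
    # groups ("Mimiviridae") work as well as superkingdoms
    return any(rank in group for rank in hit.lineage)


def best_hits_by_group(hits: Iterable[HitRecord],
                       recipient_group: frozenset[str] | set[str] = RECIPIENT_GROUP,
                       donor_group: frozenset[str] | set[str] = DONOR_GROUP,
                       exclude_lineage: str | None = None,
                       ) -> tuple[float, float]:
    """Best (lowest) e-value on the recipient and donor sides.

    Hits whose lineage contains ``exclude_lineage`` (self-hit guard,
    e.g. "Amoebozoa") are removed first.  E-values are clamped to <= 1;
    a side with no qualifying hit defaults to 1.0.
    """
    if set(recipient_group) & set(donor_group):
        raise ValueError("recipient and donor groups must be disjoint")
    bbh_r = bbh_d = 1.0
    for h in hits:
        if exclude_lineage is not None and exclude_lineage in h.lineage:
            continue
        e = min(h.evalue, 1.0)
        if _in_group(h, recipient_group):
            bbh_r = min(bbh_r, e)
        elif _in_group(h, donor_group):
            bbh_d = min(bbh_d, e)
    return bbh_r, bbh_d


def _best_donor_hit(hits: Iterable[HitRecord],
                    donor_group: frozenset[str] | set[str],
                    exclude_lineage: str | None) -> HitRecord | None:
    best: HitRecord | None = None
    for h in hits:
        if exclude_lineage is not None and exclude_lineage in h.lineage:
            continue
        if not _in_group(h, donor_group):
            continue
        key = (min(h.evalue, 1.0), -h.bitscore, h.subject_id)
        if best is None or key < (min(best.evalue, 1.0), -best.bitscore,
                                  best.subject_id):
            best = h
    return best


def score_genes(gene_hits: Mapping[str, Sequence[HitRecord]],
                recipient_group: frozenset[str] | set[str] = RECIPIENT_GROUP,
                donor_group: frozenset[str] | set[str] = DONOR_GROUP,
                exclude_lineage: str | None = None,
                c: float = DEFAULT_PSEUDOCOUNT) -> list[AlienIndexResult]:
    """Compute per-gene AI with donor attribution (no LGT call yet).

    Donor attribution takes the single best donor-side hit; the donor
    phylum is the first lineage rank below the superkingdom.
    """
    results = []
    for gene_id, hits in gene_hits.items():
        bbh_r, bbh_d = best_hits_by_group(hits, recipient_group, donor_group,
                                          exclude_lineage)
        donor = _best_donor_hit(hits, donor_group, exclude_lineage)
        results.append(AlienIndexResult(
            gene_id=gene_id,
            bbh_recipient=bbh_r,
            bbh_donor=bbh_d,
            ai=alien_index(bbh_r, bbh_d, c=c),
            donor_superkingdom=donor.superkingdom if donor else None,
            donor_phylum=donor.phylum if donor else None,
        ))
    return results


def call_lgt(results: Sequence[AlienIndexResult],
             threshold: float = DEFAULT_THRESHOLD,
             inclusive: bool = True) -> list[AlienIndexResult]:
    """Mark candidates at the AI threshold (``ai >= threshold`` by default)."""
    out = []
    for r in results:
        hit = r.ai >= threshold if inclusive else r.ai > threshold
        out.append(replace(r, is_candidate=hit))
    return out


def summarize_lgt(results: Sequence[AlienIndexResult],
                  calls: Sequence[TaxonomicCall],
                  gene_models: Sequence[GeneModel] = (),
                  detection: SampleDetectionTable | None = None,
                  group: str = "bacteria",
                  detection_min: float = 1.0) -> LgtSummary:
    """Summarize LGT candidates among genes whose best hit matches ``group``.

    ``fraction`` is candidates / group-matching genes (the 546-of-5210
    style headline number).  Intron and expression fractions cover only
    candidates joinable to gene models / the detection table; unjoinable
    ids raise a warning and are excluded from those fractions alone.
    """
    group_ids = {c.gene_id for c in calls if c.category == group}
    in_group = [r for r in results if r.gene_id in group_ids]
    cands = [r for r in in_group if r.is_candidate]

    introns = {m.gene_id: m.intron_count for m in gene_models}
    missing = [r.gene_id for r in cands if gene_models and
               r.gene_id not in introns]
    if missing:
        warnings.warn(f"{len(missing)} candidate gene ids missing from gene "
                      "models; excluded from intron fraction", stacklevel=2)
    joinable = [r for r in cands if r.gene_id in introns]
    frac_introns = (sum(1 for r in joinable if introns[r.gene_id] >= 1)
                    / len(joinable)) if joinable else 0.0

    n_expressed = 0
    if detection is not None:
        for r in cands:
            if any(detection.value(r.gene_id, s) >= detection_min
                   for s in detection.sample_order):
                n_expressed += 1

    phyla: dict[str, int] = {}
    for r in cands:
        if r.donor_phylum is not None:
            phyla[r.donor_phylum] = phyla.get(r.donor_phylum, 0) + 1
    total_attr = sum(phyla.values())
    dist = {p: n / total_attr for p, n in sorted(phyla.items())} if total_attr \
        else {}

    return LgtSummary(
        group=group,
        n_group_matching=len(in_group),
        n_candidates=len(cands),
        fraction=len(cands) / len(in_group) if in_group else 0.0,
        donor_phylum_distribution=dist,
        n_expressed=n_expressed,
        fraction_with_introns=frac_introns,
    )
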
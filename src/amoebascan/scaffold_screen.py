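"""Assembly contamination triage and summary statistics.

Scaffolds from single-cell amoeba assemblies carry co-sequenced food
bacteria.  A scaffold is flagged as contaminant only when three
criteria hold simultaneously: (1) its taxonomy call is non-eukaryote or
no-hit, (2) its GC content is aberrant relative to the host genome, and
(3) its read coverage is below a cutoff (default 10x).  The conjunction
is deliberately conservative: any single criterion failing keeps the
scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .io_formats import CoverageTable, HitRecord, ScaffoldRecord, weighted_gc

TaxonCall = Literal["eukaryote", "non_eukaryote", "no_hit"]


@dataclass(frozen=True)
class ScaffoldAnnotation:
    scaffold_id: str
    taxon_call: TaxonCall
    gc_fraction: float | None
    coverage: float | None
    length: int


@dataclass(frozen=True)
class ScreenDecision:
    scaffold_id: str
    criterion_taxonomy: bool
    criterion_gc: bool
    criterion_coverage: bool

    @property
    def is_contaminant(self) -> bool:
        return (self.criterion_taxonomy and self.criterion_gc
                and self.criterion_coverage)


@dataclass(frozen=True)
class AssemblyStats:
    total_length: int
    n_scaffolds: int
    gc_percent: float
    longest: int
    shortest: int
    mean_length: float
    n50: int


def assign_scaffold_taxon(hits: Iterable[HitRecord],
                          evalue_cutoff: float = 1e-3,
                          rule: Literal["bestsum", "besthit"] = "bestsum",
                          ) -> dict[str, TaxonCall]:
    """Assign a per-scaffold taxonomy call from scaffold-level hits.

    With the default ``bestsum`` rule the superkingdom holding the
    majority of summed bitscore among qualifying hits (e <= cutoff)
    wins; ``besthit`` uses the single highest-bitscore hit.  Ties
    resolve toward ``eukaryote`` (conservative retention).  Scaffolds
    with zero qualifying hits are ``no_hit``.
    """
    mass: dict[str, dict[str, float]] = {}
    for h in hits:
        if h.evalue > evalue_cutoff:
            continue
        per = mass.setdefault(h.query_id, {})
        if rule == "bestsum":
            per[h.superkingdom] = per.get(h.superkingdom, 0.0) + h.bitscore
        else:
            if h.bitscore > per.get(h.superkingdom, float("-inf")):
                per[h.superkingdom] = h.bitscore
    calls: dict[str, TaxonCall] = {}
    for sid, per in mass.items():
        top = max(per.values())
        winners = {k for k, v in per.items() if v == top}
        # any tie involving Eukaryota retains the scaffold
        calls[sid] = ("eukaryote" if "Eukaryota" in winners
                      else "non_eukaryote")
    return calls


def annotate_scaffolds(scaffolds: Sequence[ScaffoldRecord],
                       hits: Iterable[HitRecord],
                       coverage: CoverageTable | None = None,
                       evalue_cutoff: float = 1e-3,
                       rule: Literal["bestsum", "besthit"] = "bestsum",
                       ) -> list[ScaffoldAnnotation]:
    """Join taxonomy calls, GC and coverage into per-scaffold annotations."""
    calls = assign_scaffold_taxon(hits, evalue_cutoff=evalue_cutoff, rule=rule)
    out = []
    for s in scaffolds:
        cov = s.coverage
        if cov is None and coverage is not None:
            cov = coverage.get(s.scaffold_id)
        out.append(ScaffoldAnnotation(
            scaffold_id=s.scaffold_id,
            taxon_call=calls.get(s.scaffold_id, "no_hit"),
            gc_fraction=s.gc_fraction,
            coverage=cov,
            length=s.length,
        ))
    return out


def flag_contaminants(annotations: Sequence[ScaffoldAnnotation],
                      gc_center: float,
                      gc_delta: float = 0.08,
                      coverage_cutoff: float = 10.0,
                      whitelist: Iterable[str] = (),
                      ) -> list[ScreenDecision]:
    """Apply the three-criterion contamination rule to each scaffold.

    ``gc_center`` is normally the assembly-wide length-weighted GC; the
    GC criterion is |gc - gc_center| > gc_delta.  A scaffold with
    missing coverage cannot satisfy the coverage criterion and is
    retained (with a warning).  Whitelisted scaffolds are never flagged.
    """
    import warnings

    if not 0.0 < gc_center < 1.0:
        raise ValueError(f"gc_center must be in (0,1), got {gc_center}")
    wl = set(whitelist)
    decisions = []
    for a in annotations:
        c_tax = a.taxon_call != "eukaryote"
        c_gc = (a.gc_fraction is not None
                and abs(a.gc_fraction - gc_center) > gc_delta)
        if a.coverage is None:
            warnings.warn(f"scaffold {a.scaffold_id!r}: coverage missing; "
                          "coverage criterion undefined, scaffold retained",
                          stacklevel=2)
            c_cov = False
        else:
            c_cov = a.coverage < coverage_cutoff
        if a.scaffold_id in wl:
            c_tax = False  # manual override: treat as verified host
        decisions.append(ScreenDecision(a.scaffold_id, c_tax, c_gc, c_cov))
    return decisions


def assembly_stats(scaffolds: Sequence[ScaffoldRecord]) -> AssemblyStats:
    """Compute whole-assembly summary statistics.

    N50 is the length of the smallest scaffold in the minimal
    descending-length prefix whose cumulative length reaches half the
    total; GC is base-wise over all scaffolds, N-excluded.
    """
    if not scaffolds:
        raise ValueError("empty assembly")
    lengths = np.array([s.length for s in scaffolds], dtype=np.int64)
    total = int(lengths.sum())
    return AssemblyStats(
        total_length=total,
        n_scaffolds=len(scaffolds),
        gc_percent=100.0 * weighted_gc(scaffolds),
        longest=int(lengths.max()),
        shortest=int(lengths.min()),
        mean_length=total / len(scaffolds),
        n50=n50(lengths),
    )


def n50(lengths: Sequence[int] | np.ndarray) -> int:
    """N50 of a length multiset: smallest member of the minimal
    descending-length prefix covering >= 50% of the total."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("no lengths")
    half = arr.sum() / 2
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, half, side="left"))
    return int(arr[idx])


def apply_screen(scaffolds: Sequence[ScaffoldRecord],
                 decisions: Sequence[ScreenDecision],
                 ) -> list[ScaffoldRecord]:
    """Return the retained (non-contaminant) scaffolds, order preserved."""
    flagged = {d.scaffold_id for d in decisions if d.is_contaminant}
    return [s for s in scaffolds if s.scaffold_id not in flagged]
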
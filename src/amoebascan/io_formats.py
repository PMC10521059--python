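"""Readers, writers and domain records for the pipeline's file formats.

All coordinates are GFF3-style 1-based inclusive.  Five formats are
handled: FASTA (scaffolds, SSU copies, proteins), GFF3 gene models,
BLAST tabular hits (12 standard columns plus one appended
semicolon-joined lineage column), a per-scaffold coverage TSV and a
long-format per-sample detection TSV.  Every reader validates its input
hard; every format round-trips through its writer.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUPERKINGDOMS = ("Eukaryota", "Bacteria", "Archaea", "Viruses")

_DNA_OK = frozenset("ACGTN")
_ZERO_RE = re.compile(r"^[+-]?0*\.?0*([eE][+-]?\d+)?$")

#: BLAST tabular (outfmt 6) standard column names, plus the appended lineage.
HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore lineage"
).split()


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class ScaffoldRecord:
    """One assembly scaffold with derived composition statistics.

    ``gc_fraction`` is computed over unambiguous bases only and is
    ``None`` (with ``gc_undefined`` set) for all-N sequences.
    """

    scaffold_id: str
    sequence: str
    coverage: float | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise FormatError(f"scaffold {self.scaffold_id!r}: empty sequence")
        bad = set(seq) - _DNA_OK
        if bad:
            raise FormatError(
                f"scaffold {self.scaffold_id!r}: invalid characters {sorted(bad)}"
            )
        if self.coverage is not None and self.coverage < 0:
            raise FormatError(f"scaffold {self.scaffold_id!r}: negative coverage")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float | None:
        acgt = sum(self.sequence.count(b) for b in "ACGT")
        if acgt == 0:
            return None
        gc = self.sequence.count("G") + self.sequence.count("C")
        return gc / acgt

    @property
    def gc_undefined(self) -> bool:
        return self.gc_fraction is None


@dataclass(frozen=True)
class HitRecord:
    """One homology hit with a semicolon-derived taxonomy lineage.

    ``lineage`` is ordered superkingdom -> species; multiple HSPs per
    (query, subject) pair are allowed.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )
        if not self.lineage:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: empty lineage"
            )
        if self.lineage[0] not in SUPERKINGDOMS:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: unrecognized "
                f"superkingdom {self.lineage[0]!r}"
            )
        object.__setattr__(self, "lineage", tuple(self.lineage))

    @property
    def superkingdom(self) -> str:
        return self.lineage[0]

    @property
    def phylum(self) -> str | None:
        """First lineage rank below the superkingdom, if present."""
        return self.lineage[1] if len(self.lineage) > 1 else None


@dataclass(frozen=True)
class GeneModel:
    """A predicted gene: 1-based inclusive coordinates, exon structure."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    exon_count: int
    protein: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(f"gene {self.gene_id!r}: bad bounds "
                              f"[{self.start}, {self.end}]")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.exon_count < 1:
            raise FormatError(f"gene {self.gene_id!r}: zero exons")

    @property
    def intron_count(self) -> int:
        return self.exon_count - 1


@dataclass
class CoverageTable:
    """Mapping scaffold_id -> non-negative per-scaffold coverage."""

    coverage: dict[str, float]

    def __post_init__(self) -> None:
        for sid, cov in self.coverage.items():
            if cov < 0:
                raise FormatError(f"coverage for {sid!r} is negative")

    def get(self, scaffold_id: str) -> float | None:
        return self.coverage.get(scaffold_id)

    def __len__(self) -> int:
        return len(self.coverage)


@dataclass
class SampleDetectionTable:
    """Per-(gene, sample) detection values with sample condition labels.

    ``values`` maps (gene_id, sample_id) to a non-negative count or
    abundance; ``conditions`` maps each sample to its size class
    (small / medium / large).  ``sample_order`` preserves the design
    order of the columns.
    """

    values: dict[tuple[str, str], float]
    conditions: dict[str, str]
    sample_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_order:
            self.sample_order = list(self.conditions)
        for (gid, sid), v in self.values.items():
            if v < 0:
                raise FormatError(f"detection value for ({gid}, {sid}) negative")
            if sid not in self.conditions:
                raise FormatError(f"sample {sid!r} has no condition label")

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for gid, _ in self.values:
            seen.setdefault(gid)
        return list(seen)

    def value(self, gene_id: str, sample_id: str) -> float:
        return self.values.get((gene_id, sample_id), 0.0)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, coverage: CoverageTable | None = None
               ) -> list[ScaffoldRecord]:
    """Read a FASTA file into validated :class:`ScaffoldRecord` objects.

    File order is preserved.  Duplicate ids, empty sequences and
    non-ACGTN characters are hard errors; the offending record is named.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate scaffold id {rec.id!r} in {path}")
        seen.add(rec.id)
        cov = coverage.get(rec.id) if coverage is not None else None
        records.append(ScaffoldRecord(rec.id, str(rec.seq), coverage=cov))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ScaffoldRecord] | Mapping[str, str],
                path: str | Path, width: int = 70) -> None:
    if isinstance(records, Mapping):
        seqrecs = [SeqRecord(Seq(s), id=k, description="")
                   for k, s in records.items()]
    else:
        seqrecs = [SeqRecord(Seq(r.sequence), id=r.scaffold_id, description="")
                   for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# BLAST tabular hits

def _parse_evalue(text: str, where: str) -> float:
    try:
        v = float(text)
    except ValueError as exc:
        raise FormatError(f"{where}: unparseable e-value {text!r}") from exc
    if v < 0:
        raise FormatError(f"{where}: negative e-value {text!r}")
    if v == 0.0 and not _ZERO_RE.match(text):
        # exponent below the double-denormal range, e.g. "1e-999"
        warnings.warn(f"{where}: e-value {text!r} underflows, clamped to 0",
                      stacklevel=3)
    return v


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read BLAST tabular hits (12 standard columns + lineage column).

    The 13th column holds the subject lineage as semicolon-joined ranks
    from superkingdom downwards.  Rows are returned in file order.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 13:
                raise FormatError(
                    f"{path}:{lineno}: expected >=13 tab-separated columns, "
                    f"got {len(parts)}")
            where = f"{path}:{lineno}"
            lineage = tuple(t.strip() for t in parts[12].split(";") if t.strip())
            hits.append(HitRecord(
                query_id=parts[0],
                subject_id=parts[1],
                percent_identity=float(parts[2]),
                alignment_length=int(parts[3]),
                evalue=_parse_evalue(parts[10], where),
                bitscore=float(parts[11]),
                lineage=lineage,
            ))
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            row = [h.query_id, h.subject_id, f"{h.percent_identity:.1f}",
                   str(h.alignment_length), "0", "0", "1",
                   str(h.alignment_length), "1", str(h.alignment_length),
                   repr(h.evalue), f"{h.bitscore:.1f}", ";".join(h.lineage)]
            fh.write("\t".join(row) + "\n")


def hits_by_query(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    """Group hits by query id, preserving input order within groups."""
    grouped: dict[str, list[HitRecord]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_gff(path: str | Path) -> list[GeneModel]:
    """Read GFF3 gene models (gene / mRNA / exon features, Parent-linked).

    The exon count of each gene is taken from its primary transcript
    (the first mRNA in file order).  A gene with no exons, or an exon
    outside its gene's bounds, is a hard error.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if transcripts:
            exon_parent = transcripts[0]
        else:  # exons attached directly to the gene
            exon_parent = gene
        exons = list(db.children(exon_parent, featuretype="exon",
                                 order_by="start"))
        if not exons:
            raise FormatError(f"gene {gene.id!r} has zero exons")
        for ex in exons:
            if not (gene.start <= ex.start and ex.end <= gene.end):
                raise FormatError(
                    f"exon [{ex.start},{ex.end}] outside gene {gene.id!r} "
                    f"bounds [{gene.start},{gene.end}]")
        models.append(GeneModel(gene.id, gene.seqid, gene.start, gene.end,
                                gene.strand, len(exons)))
    return models


def write_gff(models: Iterable[GeneModel], path: str | Path,
              exon_layouts: Mapping[str, Sequence[tuple[int, int]]] | None = None,
              ) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon).

    If ``exon_layouts`` gives explicit exon intervals for a gene they
    are used verbatim; otherwise the gene span is split into
    ``exon_count`` equal-ish exons separated by 1-bp introns (structure
    only; exact intron sizes are not meaningful for synthetic models).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write("\t".join([m.scaffold_id, "amoebascan", "gene",
                                str(m.start), str(m.end), ".", m.strand, ".",
                                f"ID={m.gene_id}"]) + "\n")
            mid = f"{m.gene_id}.t1"
            fh.write("\t".join([m.scaffold_id, "amoebascan", "mRNA",
                                str(m.start), str(m.end), ".", m.strand, ".",
                                f"ID={mid};Parent={m.gene_id}"]) + "\n")
            if exon_layouts is not None and m.gene_id in exon_layouts:
                intervals = list(exon_layouts[m.gene_id])
            else:
                intervals = _default_exon_layout(m)
            for i, (es, ee) in enumerate(intervals, 1):
                fh.write("\t".join([m.scaffold_id, "amoebascan", "exon",
                                    str(es), str(ee), ".", m.strand, ".",
                                    f"ID={mid}.e{i};Parent={mid}"]) + "\n")


def _default_exon_layout(m: GeneModel) -> list[tuple[int, int]]:
    span = m.end - m.start + 1
    k = m.exon_count
    if span < 2 * k - 1:
        raise FormatError(f"gene {m.gene_id!r}: span {span} too short for "
                          f"{k} exons")
    exon_total = span - (k - 1)  # 1-bp introns
    base, extra = divmod(exon_total, k)
    pos = m.start
    out = []
    for i in range(k):
        elen = base + (1 if i < extra else 0)
        out.append((pos, pos + elen - 1))
        pos += elen + 1
    return out


# ---------------------------------------------------------------------------
# TSV tables

def read_coverage(path: str | Path) -> CoverageTable:
    """Read a two-column TSV (scaffold_id, coverage) with a header."""
    df = pd.read_csv(path, sep="\t")
    if "scaffold_id" not in df.columns or "coverage" not in df.columns:
        raise FormatError(f"{path}: need 'scaffold_id' and 'coverage' columns")
    if df["scaffold_id"].duplicated().any():
        dups = df.loc[df["scaffold_id"].duplicated(), "scaffold_id"].tolist()
        raise FormatError(f"{path}: duplicate scaffold ids {dups}")
    return CoverageTable(dict(zip(df["scaffold_id"].astype(str),
                                  df["coverage"].astype(float))))


def write_coverage(table: CoverageTable, path: str | Path) -> None:
    pd.DataFrame({"scaffold_id": list(table.coverage),
                  "coverage": list(table.coverage.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_detection(path: str | Path) -> SampleDetectionTable:
    """Read a long-format detection TSV: gene_id, sample_id, condition, value."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample_id", "condition", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    conditions: dict[str, str] = {}
    order: list[str] = []
    for sid, cond in zip(df["sample_id"].astype(str), df["condition"]):
        if sid in conditions:
            if conditions[sid] != cond:
                raise FormatError(f"{path}: sample {sid!r} has conflicting "
                                  "condition labels")
        else:
            conditions[sid] = cond
            order.append(sid)
    values = {(g, s): float(v) for g, s, v in
              zip(df["gene_id"].astype(str), df["sample_id"].astype(str),
                  df["value"])}
    if len(values) != len(df):
        raise FormatError(f"{path}: duplicate (gene_id, sample_id) rows")
    return SampleDetectionTable(values, conditions, order)


def write_detection(table: SampleDetectionTable, path: str | Path) -> None:
    rows = [(g, s, table.conditions[s], v)
            for (g, s), v in table.values.items()]
    pd.DataFrame(rows, columns=["gene_id", "sample_id", "condition", "value"]
                 ).to_csv(path, sep="\t", index=False)


def read_toolkit_queries(path: str | Path) -> pd.DataFrame:
    """Read the toolkit query list: gene_name, gene_class, query_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_name", "gene_class", "query_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    if df.duplicated(["gene_name", "gene_class"]).any():
        raise FormatError(f"{path}: duplicate gene_name within class")
    return df


def write_manifest(path: str | Path, params: Mapping[str, object]) -> None:
    """Write a run manifest recording parameters (incl. seed), one per line."""
    with open(path, "w") as fh:
        fh.write("# amoebascan run manifest\n")
        for key in sorted(params):
            fh.write(f"{key}\t{params[key]}\n")


def weighted_gc(records: Sequence[ScaffoldRecord]) -> float:
    """Base-wise GC fraction over all scaffolds, N-excluded."""
    gc = acgt = 0
    for r in records:
        gc += r.sequence.count("G") + r.sequence.count("C")
        acgt += sum(r.sequence.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return gc / acgt
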
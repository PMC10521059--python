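"""Seeded synthetic datasets with planted ground truth for every stage.

The generator emulates the statistical structure of a draft genome of a
polymorphic marine amoeba assembled from single-cell data: a ~37.7% GC
host with low-coverage, GC-aberrant bacterial contaminant scaffolds;
gene models partitioned into eukaryote / ORFan / bacteria / archaea /
virus categories; a planted subset of laterally transferred genes whose
best-hit e-value structure guarantees Alien Index separation; a
giant-virus donor mix dominated by Mimiviridae; a multi-copy SSU-rDNA
family with bounded intragenomic divergence; and a Table-2-shaped
sex/meiosis toolkit detection design over eight single-cell samples
(three small, three medium, two large).

Everything is deterministic under the single global seed: the seed is
split into named per-stage streams (assembly, genes, hits, toolkit,
ssu) via ``numpy.random.SeedSequence.spawn``, so each stage draws from
its own generator and stages can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (CoverageTable, GeneModel, HitRecord,
                         SampleDetectionTable, ScaffoldRecord, write_coverage,
                         write_detection, write_fasta, write_gff,
                         write_hit_table, write_manifest)
from .toolkit_inventory import MEIOSIS_TOOLKIT, ToolkitQuery

#: Single-cell sample design: id -> size condition (3 small, 3 medium, 2 large).
DEFAULT_SAMPLE_DESIGN = (
    ("YT42", "small"), ("YT43", "small"), ("YT44", "small"),
    ("YT45", "medium"), ("YT46", "medium"), ("YT47", "medium"),
    ("YT48", "large"), ("YT49", "large"),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_BACT_GENERA = {
    "Proteobacteria": ("Pseudomonas", "Vibrio", "Shewanella"),
    "Terrabacteria group": ("Bacillus", "Streptomyces", "Mycobacterium"),
    "FCB group": ("Flavobacterium", "Bacteroides", "Chryseobacterium"),
    "PVC group": ("Planctomyces", "Verrucomicrobium", "Chlamydia"),
    "other": ("Aquifex", "Thermotoga", "Deinococcus"),
}
_ARCH_GENERA = {
    "TACK group": ("Thermoproteus", "Sulfolobus"),
    "Euryarchaeota": ("Methanococcus", "Haloferax"),
    "Asgard group": ("Lokiarchaeum", "Heimdallarchaeum"),
    "Candidatus Woesearchaeota": ("Woesearchaeota archaeon",),
}
_MIMI_GENERA = ("Harvfovirus", "Hyperionvirus", "Klosneuvirinae",
                "Tupanvirus", "other Mimiviridae")
_HOST_LINEAGE = ("Eukaryota", "Amoebozoa", "Trichosphaerium sp.")


def _normalized(mix: Mapping[str, float], what: str) -> dict[str, float]:
    total = float(sum(mix.values()))
    if not 0.98 <= total <= 1.02:
        raise ValueError(f"{what} proportions sum to {total}, not ~1")
    return {k: v / total for k, v in mix.items()}


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic study, with the emulated defaults.

    Proportion maps are normalized to sum exactly to one (the published
    rounded percentages sum to 0.997); probabilities must lie in [0, 1].
    """

    seed: int = 0
    n_scaffolds: int = 40
    contaminant_fraction: float = 0.25
    host_gc: float = 0.3769
    contaminant_gc_offsets: tuple[float, ...] = (-0.15, 0.15)
    host_coverage_mean: float = 50.0
    host_coverage_sd: float = 8.0
    host_coverage_min: float = 12.0
    contaminant_coverage_max: float = 8.0
    scaffold_length_median: int = 6000
    scaffold_length_sigma: float = 0.5
    min_scaffold_length: int = 1000
    n_genes: int = 2000
    category_proportions: Mapping[str, float] = field(default_factory=lambda: {
        "eukaryote": 0.476, "orfan": 0.265, "bacteria": 0.190,
        "archaea": 0.009, "virus": 0.057})
    lgt_fraction_bacteria: float = 0.1047
    lgt_fraction_archaea: float = 0.077
    lgt_fraction_virus: float = 0.73
    donor_phylum_mix_bacteria: Mapping[str, float] = field(
        default_factory=lambda: {"Proteobacteria": 0.26,
                                 "Terrabacteria group": 0.28,
                                 "FCB group": 0.18, "PVC group": 0.115,
                                 "other": 0.165})
    donor_phylum_mix_archaea: Mapping[str, float] = field(
        default_factory=lambda: {"TACK group": 0.47, "Euryarchaeota": 0.32,
                                 "Asgard group": 0.105,
                                 "Candidatus Woesearchaeota": 0.105})
    donor_mix_virus: Mapping[str, float] = field(
        default_factory=lambda: {"Mimiviridae": 0.98,
                                 "unclassified dsDNA viruses": 0.02})
    mimiviridae_genus_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Harvfovirus": 0.37, "Hyperionvirus": 0.17,
                                 "Klosneuvirinae": 0.15, "Tupanvirus": 0.12,
                                 "other Mimiviridae": 0.19})
    viral_intron_fraction: float = 0.40
    mean_exons_per_gene: float = 7.7
    mean_exon_bp: float = 154.3
    mean_intron_bp: float = 75.4
    lgt_detected_fraction: float = 0.165
    n_ssu_copies: int = 22
    ssu_length: int = 1800
    ssu_gc: float = 0.45
    ssu_max_divergence: float = 0.029
    sample_design: tuple[tuple[str, str], ...] = DEFAULT_SAMPLE_DESIGN
    detection_probability_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"small": 0.15, "medium": 0.65, "large": 0.75})
    other_query_presence: float = 0.82
    n_toolkit_queries: int = 95
    toolkit_planted_patterns: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_scaffolds < 2:
            raise ValueError("need >= 2 scaffolds (host and contaminant)")
        object.__setattr__(self, "category_proportions",
                           _normalized(self.category_proportions, "category"))
        for name in ("donor_phylum_mix_bacteria", "donor_phylum_mix_archaea",
                     "donor_mix_virus", "mimiviridae_genus_mix"):
            object.__setattr__(self, name, _normalized(getattr(self, name),
                                                       name))
        for p in (self.lgt_fraction_bacteria, self.lgt_fraction_archaea,
                  self.lgt_fraction_virus, self.viral_intron_fraction,
                  self.lgt_detected_fraction, self.other_query_presence,
                  *self.detection_probability_by_condition.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    def as_manifest(self) -> dict[str, object]:
        d = dataclasses.asdict(self)
        return {k: v for k, v in sorted(d.items())}


@dataclass
class GroundTruth:
    """Planted truth tables, consistent row-for-row with the emitted files."""

    scaffolds: pd.DataFrame   # scaffold_id, is_contaminant, source
    genes: pd.DataFrame       # gene_id, scaffold_id, category, is_lgt,
                              # donor_phylum, donor_genus, intron_count
    detection: pd.DataFrame   # gene_id, sample_id, detected
    ssu: pd.DataFrame         # copy_id, n_mutations
    ssu_ancestor: str

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scaffolds.to_csv(directory / "scaffolds.tsv", sep="\t",
                              index=False)
        self.genes.to_csv(directory / "genes.tsv", sep="\t", index=False)
        self.detection.to_csv(directory / "detection.tsv", sep="\t",
                              index=False)
        self.ssu.to_csv(directory / "ssu.tsv", sep="\t", index=False)
        (directory / "ssu_ancestor.txt").write_text(self.ssu_ancestor + "\n")


@dataclass
class SyntheticBundle:
    """One complete in-memory input set plus its ground truth."""

    params: GeneratorParams
    scaffolds: list[ScaffoldRecord]
    coverage: CoverageTable
    scaffold_hits: list[HitRecord]
    gene_models: list[GeneModel]
    gene_exons: dict[str, list[tuple[int, int]]]
    gene_hits: list[HitRecord]
    toolkit_queries: list[ToolkitQuery]
    toolkit_hits: list[HitRecord]
    detection: SampleDetectionTable
    ssu: dict[str, str]
    truth: GroundTruth

    def write(self, directory: str | Path) -> None:
        """Emit the full input bundle plus truth/*.tsv and a manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_fasta(self.scaffolds, d / "assembly.fasta")
        write_coverage(self.coverage, d / "coverage.tsv")
        write_hit_table(self.scaffold_hits, d / "scaffold_hits.tsv")
        write_gff(self.gene_models, d / "genes.gff3",
                  exon_layouts=self.gene_exons)
        write_hit_table(self.gene_hits, d / "gene_hits.tsv")
        pd.DataFrame([dataclasses.asdict(q) for q in self.toolkit_queries]
                     ).to_csv(d / "toolkit_queries.tsv", sep="\t", index=False)
        write_hit_table(self.toolkit_hits, d / "toolkit_hits.tsv")
        write_detection(self.detection, d / "detection.tsv")
        write_fasta(self.ssu, d / "ssu.fasta")
        self.truth.write(d / "truth")
        write_manifest(d / "manifest.txt", self.params.as_manifest())


# ---------------------------------------------------------------------------
# helpers

def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("assembly", "genes", "hits", "toolkit", "ssu")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _log_uniform_evalue(rng: np.random.Generator, lo: float, hi: float
                        ) -> float:
    """e-value with log10(e) ~ Uniform(lo, hi)."""
    return float(10.0 ** rng.uniform(lo, hi))


def _choose(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys]))]


# ---------------------------------------------------------------------------
# stage 1: assembly

def generate_assembly(params: GeneratorParams,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[list[ScaffoldRecord], CoverageTable,
                                 pd.DataFrame]:
    """Host + contaminant scaffolds, per-scaffold coverage, scaffold truth.

    Host scaffolds draw per-base GC at ``host_gc`` and coverage from a
    truncated normal well above the screening cutoff; contaminants get
    an offset GC and coverage below ``contaminant_coverage_max``.  All
    scaffolds are at least ``min_scaffold_length`` bp (short contigs
    are assumed pre-filtered).
    """
    rng = rng if rng is not None else _streams(params.seed)["assembly"]
    n = params.n_scaffolds
    n_cont = int(round(n * params.contaminant_fraction))
    is_cont = np.zeros(n, dtype=bool)
    is_cont[rng.permutation(n)[:n_cont]] = True

    records, cov, rows = [], {}, []
    for i in range(n):
        sid = f"scaffold_{i + 1:05d}"
        length = max(params.min_scaffold_length,
                     int(rng.lognormal(np.log(params.scaffold_length_median),
                                       params.scaffold_length_sigma)))
        if is_cont[i]:
            offset = float(rng.choice(params.contaminant_gc_offsets))
            gc = float(np.clip(params.host_gc + offset, 0.02, 0.98))
            coverage = float(rng.uniform(1.0, params.contaminant_coverage_max))
            source = "contaminant_bacteria"
        else:
            gc = params.host_gc
            coverage = float(max(params.host_coverage_min,
                                 rng.normal(params.host_coverage_mean,
                                            params.host_coverage_sd)))
            source = "host"
        records.append(ScaffoldRecord(sid, _random_dna(rng, length, gc),
                                      coverage=coverage))
        cov[sid] = coverage
        rows.append((sid, bool(is_cont[i]), source))

    truth = pd.DataFrame(rows, columns=["scaffold_id", "is_contaminant",
                                        "source"])
    return records, CoverageTable(cov), truth


# ---------------------------------------------------------------------------
# stage 2: gene models and per-gene truth

def _draw_exon_layout(params: GeneratorParams, rng: np.random.Generator,
                      n_exons: int, start: int) -> tuple[list[tuple[int, int]],
                                                         int]:
    pos = start
    intervals = []
    for k in range(n_exons):
        elen = max(30, int(rng.normal(params.mean_exon_bp, 40)))
        intervals.append((pos, pos + elen - 1))
        pos += elen
        if k < n_exons - 1:
            pos += max(20, int(rng.normal(params.mean_intron_bp, 20)))
    return intervals, pos - 1  # gene end


def generate_genes(params: GeneratorParams, scaffold_truth: pd.DataFrame,
                   scaffolds: Sequence[ScaffoldRecord],
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[GeneModel], dict[str, list[tuple[int, int]]],
                              pd.DataFrame]:
    """Gene models on host scaffolds with planted category / LGT truth.

    Categories follow ``category_proportions``; LGT flags are Bernoulli
    per non-eukaryote category; viral LGTs carry introns with
    probability ``viral_intron_fraction`` and are single-exon otherwise,
    while all other genes draw exon counts around the genome-wide mean.
    """
    rng = rng if rng is not None else _streams(params.seed)["genes"]
    host_ids = scaffold_truth.loc[~scaffold_truth.is_contaminant,
                                  "scaffold_id"].tolist()
    if not host_ids:
        raise ValueError("no host scaffolds to place genes on")
    lengths = {s.scaffold_id: s.length for s in scaffolds}
    host_lengths = np.array([lengths[h] for h in host_ids], dtype=float)
    host_weights = host_lengths / host_lengths.sum()

    cats = list(params.category_proportions)
    cat_p = np.array([params.category_proportions[c] for c in cats])
    lgt_p = {"bacteria": params.lgt_fraction_bacteria,
             "archaea": params.lgt_fraction_archaea,
             "virus": params.lgt_fraction_virus}

    models, layouts, rows = [], {}, []
    for i in range(params.n_genes):
        gid = f"gene_{i + 1:05d}"
        category = cats[rng.choice(len(cats), p=cat_p)]
        is_lgt = bool(rng.random() < lgt_p.get(category, 0.0))

        donor_phylum = donor_genus = ""
        if category == "bacteria":
            donor_phylum = _choose(rng, params.donor_phylum_mix_bacteria)
            donor_genus = str(rng.choice(_BACT_GENERA[donor_phylum]))
        elif category == "archaea":
            donor_phylum = _choose(rng, params.donor_phylum_mix_archaea)
            donor_genus = str(rng.choice(_ARCH_GENERA[donor_phylum]))
        elif category == "virus":
            donor_phylum = _choose(rng, params.donor_mix_virus)
            donor_genus = (_choose(rng, params.mimiviridae_genus_mix)
                           if donor_phylum == "Mimiviridae"
                           else "Pithoviridae")

        if category == "virus" and is_lgt:
            n_exons = (2 + int(rng.poisson(1.5))
                       if rng.random() < params.viral_intron_fraction else 1)
        else:
            n_exons = 1 + int(rng.poisson(params.mean_exons_per_gene - 1))

        sid = host_ids[rng.choice(len(host_ids), p=host_weights)]
        span_cap = lengths[sid]
        start = int(rng.integers(1, max(2, span_cap // 2)))
        intervals, end = _draw_exon_layout(params, rng, n_exons, start)
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gid, sid, start, end, strand, n_exons))
        layouts[gid] = intervals
        rows.append((gid, sid, category, is_lgt, donor_phylum, donor_genus,
                     n_exons - 1))

    truth = pd.DataFrame(rows, columns=["gene_id", "scaffold_id", "category",
                                        "is_lgt", "donor_phylum",
                                        "donor_genus", "intron_count"])
    return models, layouts, truth


# ---------------------------------------------------------------------------
# stage 3: hit tables

def _hit(query: str, subject: str, evalue: float, bitscore: float,
         lineage: tuple[str, ...]) -> HitRecord:
    return HitRecord(query, subject, 80.0, 200, evalue, bitscore, lineage)


def _donor_lineage(category: str, phylum: str, genus: str) -> tuple[str, ...]:
    sk = {"bacteria": "Bacteria", "archaea": "Archaea",
          "virus": "Viruses"}[category]
    return (sk, phylum, genus)


def generate_hit_tables(params: GeneratorParams, scaffold_truth: pd.DataFrame,
                        gene_truth: pd.DataFrame,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[list[HitRecord], list[HitRecord]]:
    """Scaffold- and gene-level hit tables realizing the planted truth.

    Separation laws (log10 e-value scale): a gene's best hit on its
    true-origin side draws from Uniform(-180, -60); the opposite side is
    absent or draws from Uniform(-3, 0).  For non-LGT genes of
    non-eukaryote category the donor best hit undercuts the eukaryote
    best hit by at most 10 decades, keeping the Alien Index below ~23 —
    far under the calling threshold — while leaving the category intact.
    ORFan genes receive nothing below e = 2e-3.
    """
    rng = rng if rng is not None else _streams(params.seed)["hits"]

    scaffold_hits: list[HitRecord] = []
    for row in scaffold_truth.itertuples():
        n_hits = int(rng.integers(2, 6))
        if row.is_contaminant:
            phylum = _choose(rng, params.donor_phylum_mix_bacteria)
            genus = str(rng.choice(_BACT_GENERA[phylum]))
            lineage = ("Bacteria", phylum, genus)
            for _ in range(n_hits):
                scaffold_hits.append(_hit(
                    row.scaffold_id, f"nt|{genus.lower()}",
                    _log_uniform_evalue(rng, -120, -20),
                    float(rng.uniform(100, 300)), lineage))
            if rng.random() < 0.3:  # occasional weak spurious eukaryote hit
                scaffold_hits.append(_hit(
                    row.scaffold_id, "nt|euk_spurious",
                    _log_uniform_evalue(rng, -6, -4),
                    float(rng.uniform(30, 60)), _HOST_LINEAGE))
        else:
            for _ in range(n_hits):
                scaffold_hits.append(_hit(
                    row.scaffold_id, "nt|amoebozoa",
                    _log_uniform_evalue(rng, -120, -20),
                    float(rng.uniform(100, 300)), _HOST_LINEAGE))

    gene_hits: list[HitRecord] = []
    for g in gene_truth.itertuples():
        if g.category == "orfan":
            if rng.random() < 0.5:  # weak, above-cutoff noise hits
                gene_hits.append(_hit(
                    g.gene_id, "nr|weak", float(rng.uniform(2e-3, 1.0)),
                    float(rng.uniform(25, 40)),
                    ("Bacteria", "Proteobacteria", "Vibrio")))
            continue
        if g.category == "eukaryote":
            gene_hits.append(_hit(
                g.gene_id, "nr|amoeba", _log_uniform_evalue(rng, -180, -60),
                float(rng.uniform(150, 400)), _HOST_LINEAGE))
            if rng.random() < 0.5:
                gene_hits.append(_hit(
                    g.gene_id, "nr|bact_weak",
                    _log_uniform_evalue(rng, -3, 0),
                    float(rng.uniform(25, 50)),
                    ("Bacteria", "Proteobacteria", "Shewanella")))
            continue
        # bacteria / archaea / virus category
        lineage = _donor_lineage(g.category, g.donor_phylum, g.donor_genus)
        if g.is_lgt:
            donor_log10 = rng.uniform(-180, -60)
            gene_hits.append(_hit(
                g.gene_id, f"nr|{g.donor_genus.lower().replace(' ', '_')}",
                10.0 ** donor_log10, float(rng.uniform(150, 400)), lineage))
            if rng.random() < 0.5:  # recipient side absent half the time
                gene_hits.append(_hit(
                    g.gene_id, "nr|euk_weak",
                    _log_uniform_evalue(rng, -3, 0),
                    float(rng.uniform(25, 50)), _HOST_LINEAGE))
        else:
            recip_log10 = rng.uniform(-180, -60)
            donor_log10 = recip_log10 - rng.uniform(0.5, 10.0)
            gene_hits.append(_hit(
                g.gene_id, "nr|amoeba", 10.0 ** recip_log10,
                float(rng.uniform(150, 400)), _HOST_LINEAGE))
            gene_hits.append(_hit(
                g.gene_id, f"nr|{g.donor_genus.lower().replace(' ', '_')}",
                10.0 ** donor_log10, float(rng.uniform(160, 410)), lineage))
    return scaffold_hits, gene_hits


# ---------------------------------------------------------------------------
# stage 4: toolkit, detection, SSU

def default_toolkit_queries(params: GeneratorParams) -> list[ToolkitQuery]:
    """The default query manifest: 12 meiosis-specific genes, the
    plasmogamy and karyogamy sets, and generic sex-related placeholders
    up to ``n_toolkit_queries`` genes."""
    queries = [ToolkitQuery(g, "meiosis_specific", f"Q_{g}")
               for g in MEIOSIS_TOOLKIT]
    plasmogamy = ("HAP2", "PRM1", "KEX2", "CD9", "TPM1", "MYO2", "BNI1",
                  "RVS161")
    karyogamy = ("KAR2", "CINI1", "CINI2", "KAR4", "SEC63", "BIK1", "CIN4",
                 "KAR3", "SEC72", "CDC4", "CDC34", "JEM1", "CDC28", "KEM1",
                 "GEX1")
    queries += [ToolkitQuery(g, "plasmogamy", f"Q_{g}") for g in plasmogamy]
    queries += [ToolkitQuery(g, "karyogamy", f"Q_{g}") for g in karyogamy]
    n_other = params.n_toolkit_queries - len(queries)
    queries += [ToolkitQuery(f"SRG-{i + 1:02d}", "other", f"Q_SRG-{i + 1:02d}")
                for i in range(max(0, n_other))]
    return queries


#: genes with a planted extra genome copy (mirrors in-paralog pairs)
_TWO_COPY_GENES = ("SPO11", "ZIP4", "BIK1")
#: genes planted absent from the genome (karyogamy gene missing)
_ABSENT_GENES = ("GEX1",)


def generate_toolkit_and_ssu(params: GeneratorParams,
                             rng: np.random.Generator | None = None,
                             ssu_rng: np.random.Generator | None = None,
                             gene_truth: pd.DataFrame | None = None,
                             ) -> tuple[list[ToolkitQuery], list[HitRecord],
                                        SampleDetectionTable, dict[str, str],
                                        pd.DataFrame, pd.DataFrame, str]:
    """Toolkit hits, per-sample detection, SSU copies, and their truths.

    Named toolkit genes are planted present (SPO11/ZIP4/BIK1 with two
    genome copies, GEX1 absent); placeholder queries are present with
    probability ``other_query_presence``.  Detection per (model, sample)
    is Bernoulli with the condition's probability, overridable per gene
    via ``toolkit_planted_patterns``.  SSU copies are substitution-only
    mutants of one ancestor, each within ``ssu_max_divergence / 2`` of
    it, so all pairwise divergences stay within the bound.
    """
    streams = _streams(params.seed)
    rng = rng if rng is not None else streams["toolkit"]
    ssu_rng = ssu_rng if ssu_rng is not None else streams["ssu"]

    queries = default_toolkit_queries(params)
    toolkit_hits: list[HitRecord] = []
    model_ids: list[str] = []
    model_of_gene: dict[str, list[str]] = {}
    next_model = 10000
    for q in queries:
        if q.gene_name in _ABSENT_GENES:
            # near-miss only: one hit just above the stringent cutoff
            toolkit_hits.append(_hit(q.query_id, f"TRSP{next_model}", 1e-10,
                                     float(rng.uniform(40, 60)),
                                     _HOST_LINEAGE))
            next_model += 1
            continue
        if q.gene_class == "other" and rng.random() >= params.other_query_presence:
            continue
        n_copies = 2 if q.gene_name in _TWO_COPY_GENES else 1
        for _ in range(n_copies):
            mid = f"TRSP{next_model}"
            next_model += 1
            toolkit_hits.append(_hit(q.query_id, mid,
                                     _log_uniform_evalue(rng, -120, -20),
                                     float(rng.uniform(150, 400)),
                                     _HOST_LINEAGE))
            model_ids.append(mid)
            model_of_gene.setdefault(q.gene_name, []).append(mid)

    conditions = dict(params.sample_design)
    order = [s for s, _ in params.sample_design]
    probs = params.detection_probability_by_condition
    values: dict[tuple[str, str], float] = {}
    det_rows = []
    for q in queries:
        for j, mid in enumerate(model_of_gene.get(q.gene_name, ())):
            pattern = None
            if j == 0 and q.gene_name in params.toolkit_planted_patterns:
                pattern = params.toolkit_planted_patterns[q.gene_name].split()
                if len(pattern) != len(order):
                    raise ValueError(f"planted pattern for {q.gene_name!r} "
                                     f"must have {len(order)} cells")
            for k, sid in enumerate(order):
                if pattern is not None:
                    detected = pattern[k] == "+"
                else:
                    detected = bool(rng.random() < probs[conditions[sid]])
                values[(mid, sid)] = float(1 + rng.poisson(4)) if detected \
                    else 0.0
                det_rows.append((mid, sid, detected))

    # expressed LGT candidates: a slice of planted LGTs shows up in
    # medium/large samples of the transcriptome
    if gene_truth is not None:
        ml_samples = [s for s in order if conditions[s] != "small"]
        for g in gene_truth.itertuples():
            if g.is_lgt and rng.random() < params.lgt_detected_fraction:
                sid = str(rng.choice(ml_samples))
                values[(g.gene_id, sid)] = float(1 + rng.poisson(4))
                det_rows.append((g.gene_id, sid, True))

    detection = SampleDetectionTable(values, conditions, order)
    det_truth = pd.DataFrame(det_rows,
                             columns=["gene_id", "sample_id", "detected"])

    # SSU-rDNA copies: bounded substitution mutants of one ancestor
    ancestor = _random_dna(ssu_rng, params.ssu_length, params.ssu_gc)
    max_m = int(params.ssu_length * params.ssu_max_divergence / 2)
    ssu: dict[str, str] = {}
    ssu_rows = []
    for i in range(params.n_ssu_copies):
        m = int(ssu_rng.integers(0, max_m + 1))
        seq = bytearray(ancestor.encode())
        pos = ssu_rng.choice(params.ssu_length, size=m, replace=False)
        for p in pos:
            current = seq[p]
            alts = [b for b in b"ACGT" if b != current]
            seq[p] = alts[int(ssu_rng.integers(0, 3))]
        cid = f"SSU_{i + 1:02d}"
        ssu[cid] = seq.decode()
        ssu_rows.append((cid, m))
    ssu_truth = pd.DataFrame(ssu_rows, columns=["copy_id", "n_mutations"])

    return queries, toolkit_hits, detection, ssu, det_truth, ssu_truth, ancestor


# ---------------------------------------------------------------------------
# full bundle

def generate_bundle(params: GeneratorParams) -> SyntheticBundle:
    """Generate the complete input set with consistent planted truth."""
    streams = _streams(params.seed)
    scaffolds, coverage, scaffold_truth = generate_assembly(
        params, streams["assembly"])
    models, layouts, gene_truth = generate_genes(
        params, scaffold_truth, scaffolds, streams["genes"])
    scaffold_hits, gene_hits = generate_hit_tables(
        params, scaffold_truth, gene_truth, streams["hits"])
    queries, toolkit_hits, detection, ssu, det_truth, ssu_truth, ancestor = \
        generate_toolkit_and_ssu(params, streams["toolkit"], streams["ssu"],
                                 gene_truth)
    truth = GroundTruth(scaffold_truth, gene_truth, det_truth, ssu_truth,
                        ssu_ancestor=ancestor)
    return SyntheticBundle(params, scaffolds, coverage, scaffold_hits, models,
                           layouts, gene_hits, queries, toolkit_hits,
                           detection, ssu, truth)
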
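"""Readers and writers for the external files the pipeline touches.

A single coordinate convention is used throughout the package: 0-based,
half-open intervals on each chromosome. GFF3 and the tab-separated gene
tables are 1-based inclusive at the file boundary and are converted on the
way in and out. Gene midpoints are ``floor((start + end) / 2)`` in internal
coordinates, so they are deterministic across platforms.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A malformed record in an input file, reported with its line number."""


# ---------------------------------------------------------------------------
# core domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    id: str
    length: int
    circular: bool = True

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"chromosome {self.id}: length must be > 0")


@dataclass(frozen=True)
class Gene:
    """A gene on a chromosome, with an optional orthology-class (COG) label.

    ``start``/``end`` are 0-based half-open; ``strand`` is '+' or '-'.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cog: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.id}: need 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: unknown strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class Genome:
    """One genome: its chromosomes and its genes in chromosomal order."""

    def __init__(self, id: str, chromosomes: list[Chromosome], genes: list[Gene]):
        self.id = id
        self.chromosomes: dict[str, Chromosome] = {c.id: c for c in chromosomes}
        for g in genes:
            chrom = self.chromosomes.get(g.chromosome)
            if chrom is None:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chromosome}")
            if g.end > chrom.length:
                raise ValueError(
                    f"gene {g.id}: end {g.end} exceeds chromosome length {chrom.length}"
                )
        order = {c: i for i, c in enumerate(self.chromosomes)}
        self.genes: list[Gene] = sorted(genes, key=lambda g: (order[g.chromosome], g.start))
        self.cog_index: dict[str, list[Gene]] = {}
        for g in self.genes:
            if g.cog is not None:
                self.cog_index.setdefault(g.cog, []).append(g)

    def genes_on(self, chromosome: str) -> list[Gene]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def __contains__(self, gene: Gene) -> bool:
        if not hasattr(self, "_gene_ids"):
            self._gene_ids = {g.id for g in self.genes}
        return gene.id in self._gene_ids

    def copy_number(self, cog: str) -> int:
        return len(self.cog_index.get(cog, ()))


class GenomeCollection:
    """The universe over which synteny is computed: many annotated genomes."""

    def __init__(self, genomes: list[Genome] | None = None):
        self.genomes: dict[str, Genome] = {}
        for g in genomes or []:
            self.add(g)

    def add(self, genome: Genome) -> None:
        if genome.id in self.genomes:
            raise ValueError(f"duplicate genome id {genome.id}")
        self.genomes[genome.id] = genome

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes.values())

    def __getitem__(self, genome_id: str) -> Genome:
        return self.genomes[genome_id]

    @property
    def cogs(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self:
            for c in g.cog_index:
                seen.setdefault(c)
        return list(seen)

    def genomes_with(self, cog: str) -> list[str]:
        return [g.id for g in self if cog in g.cog_index]


# ---------------------------------------------------------------------------
# transcription-level annotation containers
# ---------------------------------------------------------------------------

@dataclass
class Operon:
    id: str
    genes: tuple[str, ...]
    strand: str


class OperonMap:
    """operon-id -> ordered member genes, plus the reverse gene -> operon map."""

    def __init__(self, operons: list[Operon]):
        self.operons: dict[str, Operon] = {o.id: o for o in operons}
        self._of_gene: dict[str, str] = {}
        for o in operons:
            for g in o.genes:
                self._of_gene[g] = o.id

    def operon_of(self, gene_id: str) -> str | None:
        return self._of_gene.get(gene_id)

    def __len__(self):
        return len(self.operons)

    def __iter__(self):
        return iter(self.operons.values())

    def __getitem__(self, operon_id: str) -> Operon:
        return self.operons[operon_id]


@dataclass
class RegulonTable:
    """factor -> regulated operons; kind distinguishes TFs from sigma factors."""

    factors: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, factor: str, kind: str, operons) -> None:
        if kind not in ("TF", "SF"):
            raise ValueError(f"factor kind must be TF or SF, got {kind!r}")
        self.factors[factor] = (kind, frozenset(operons))

    def of_kind(self, kind: str) -> dict[str, frozenset[str]]:
        return {f: ops for f, (k, ops) in self.factors.items() if k == kind}

    def factors_of_operon(self, operon_id: str, kind: str | None = None) -> frozenset[str]:
        out = []
        for f, (k, ops) in self.factors.items():
            if operon_id in ops and (kind is None or k == kind):
                out.append(f)
        return frozenset(out)


@dataclass(frozen=True)
class TSS:
    chromosome: str
    position: int
    strand: str


class TSSList(list):
    """Transcription start sites as (chromosome, position, strand) records."""

    def on(self, chromosome: str, strand: str) -> np.ndarray:
        return np.array(
            sorted(t.position for t in self if t.chromosome == chromosome and t.strand == strand),
            dtype=int,
        )


@dataclass
class TU:
    id: str
    genes: tuple[str, ...]
    kind: str  # "short" | "long"


class TUMap:
    def __init__(self, tus: list[TU]):
        self.tus: dict[str, TU] = {t.id: t for t in tus}
        self._of_gene: dict[tuple[str, str], set[str]] = {}
        for t in tus:
            for g in t.genes:
                self._of_gene.setdefault((g, t.kind), set()).add(t.id)

    def tus_of(self, gene_id: str, kind: str) -> set[str]:
        return self._of_gene.get((gene_id, kind), set())

    def __iter__(self):
        return iter(self.tus.values())

    def of_kind(self, kind: str) -> list[TU]:
        return [t for t in self.tus.values() if t.kind == kind]


class IntervalTrack:
    """BED-style intervals (0-based half-open) indexed by chromosome."""

    def __init__(self, df: pd.DataFrame | None = None):
        cols = ["chromosome", "start", "end", "name", "score", "strand"]
        if df is None:
            df = pd.DataFrame(columns=cols)
        for c in cols:
            if c not in df.columns:
                df[c] = None
        self.df = df[cols].reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def on(self, chromosome: str) -> pd.DataFrame:
        return self.df[self.df.chromosome == chromosome]

    def midpoints(self, chromosome: str) -> np.ndarray:
        sub = self.on(chromosome)
        return ((sub.start.to_numpy(int) + sub.end.to_numpy(int)) // 2)


class CoverageTrack:
    """Per-base coverage for each strand of each chromosome."""

    def __init__(self):
        self._data: dict[tuple[str, str], np.ndarray] = {}

    def set(self, chromosome: str, strand: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if (values < 0).any():
            raise ValueError("coverage values must be >= 0")
        self._data[(chromosome, strand)] = values

    def get(self, chromosome: str, strand: str) -> np.ndarray:
        return self._data[(chromosome, strand)]

    def keys(self):
        return self._data.keys()


# ---------------------------------------------------------------------------
# genome annotation i/o
# ---------------------------------------------------------------------------

def read_genome_annotations(path: str, dialect: str = "table", genome_id: str | None = None) -> Genome:
    """Read one genome's gene annotations (GFF3 or tab-separated table).

    File coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention. Genes without a COG label are retained
    with ``cog=None``.
    """
    if dialect == "gff3":
        return _read_gff3(path, genome_id)
    if dialect == "table":
        return _read_gene_table(path, genome_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gff3(path: str, genome_id: str | None) -> Genome:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    chroms: dict[str, Chromosome] = {}
    # chromosome length/circularity from region features (NCBI convention)
    for feat in db.features_of_type("region"):
        circ = feat.attributes.get("Is_circular", ["false"])[0].lower() == "true"
        chroms[feat.seqid] = Chromosome(feat.seqid, feat.end, circ)
    # fall back to ##sequence-region pragmas
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, seqid, start, end = line.split()[:4]
                chroms.setdefault(seqid, Chromosome(seqid, int(end), True))
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {feat.id}: unknown strand {feat.strand!r}")
        cog = feat.attributes.get("cog", [None])[0] or feat.attributes.get("COG", [None])[0]
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(gid, feat.seqid, feat.start - 1, feat.end, feat.strand, cog))
        chroms.setdefault(feat.seqid, None)
    missing = [c for c, v in chroms.items() if v is None]
    if missing:
        # no declared length: use max gene end
        for c in missing:
            mx = max(g.end for g in genes if g.chromosome == c)
            chroms[c] = Chromosome(c, mx, True)
    gid = genome_id or os.path.splitext(os.path.basename(path))[0]
    return Genome(gid, list(chroms.values()), genes)


_TABLE_COLS = ["chromosome", "start", "end", "strand", "gene", "cog"]


def _read_gene_table(path: str, genome_id: str | None) -> Genome:
    """Tab-separated gene table with ``## chromosome`` header lines.

    Header lines: ``## chromosome <id> <length> <circular|linear>``.
    Data columns: chromosome, start, end, strand, gene, cog ('.' = no COG);
    start/end 1-based inclusive.
    """
    chroms: list[Chromosome] = []
    genes: list[Gene] = []
    declared_id = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("## genome"):
                declared_id = line.split()[2]
                continue
            if line.startswith("## chromosome"):
                parts = line.split()
                chroms.append(Chromosome(parts[2], int(parts[3]), parts[4] == "circular"))
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: expected >= 5 tab-separated fields")
            chrom, start, end, strand, gene = parts[:5]
            cog = parts[5] if len(parts) > 5 and parts[5] not in (".", "") else None
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if end_i < start_i:
                raise FormatError(f"{path}:{ln}: end < start")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: unknown strand {strand!r}")
            genes.append(Gene(gene, chrom, start_i - 1, end_i, strand, cog))
    gid = genome_id or declared_id or os.path.splitext(os.path.basename(path))[0]
    return Genome(gid, chroms, genes)


def write_genome_annotations(genome: Genome, path: str) -> None:
    """Write the table dialect of :func:`read_genome_annotations` (lossless)."""
    with open(path, "w") as fh:
        fh.write(f"## genome {genome.id}\n")
        for c in genome.chromosomes.values():
            kind = "circular" if c.circular else "linear"
            fh.write(f"## chromosome {c.id} {c.length} {kind}\n")
        fh.write("#" + "\t".join(_TABLE_COLS) + "\n")
        for g in genome.genes:
            cog = g.cog if g.cog is not None else "."
            fh.write(f"{g.chromosome}\t{g.start + 1}\t{g.end}\t{g.strand}\t{g.id}\t{cog}\n")


def read_collection(paths: list[str], dialect: str = "table") -> GenomeCollection:
    return GenomeCollection([read_genome_annotations(p, dialect) for p in paths])


# ---------------------------------------------------------------------------
# BED / bedGraph / generic tables
# ---------------------------------------------------------------------------

def read_bed(path: str, chromosome_lengths: dict[str, int] | None = None) -> IntervalTrack:
    """Read a BED file (0-based half-open). Empty files yield an empty track."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start or start < 0:
                raise FormatError(f"{path}:{ln}: invalid interval")
            if chromosome_lengths is not None and chrom in chromosome_lengths:
                if end > chromosome_lengths[chrom]:
                    raise FormatError(f"{path}:{ln}: coordinate outside chromosome")
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 else None
            rows.append((chrom, start, end, name, score, strand))
    return IntervalTrack(pd.DataFrame(rows, columns=["chromosome", "start", "end", "name", "score", "strand"]))


def write_bed(track: IntervalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            fields = [row.chromosome, str(int(row.start)), str(int(row.end))]
            if row.name is not None:
                fields.append(str(row.name))
                if row.score is not None:
                    fields.append(repr(float(row.score)))
                    if row.strand is not None:
                        fields.append(row.strand)
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str, chromosome_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-base arrays, one per chromosome."""
    out = {c: np.zeros(n, dtype=float) for c, n in chromosome_lengths.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            start, end = int(start), int(end)
            if chrom not in out:
                raise FormatError(f"{path}:{ln}: unknown chromosome {chrom}")
            if end > len(out[chrom]) or start < 0 or end < start:
                raise FormatError(f"{path}:{ln}: coordinate outside chromosome")
            out[chrom][start:end] = float(value)
    return out


def write_bedgraph(values: dict[str, np.ndarray], path: str) -> None:
    """Write per-base arrays as a run-length encoded bedGraph."""
    with open(path, "w") as fh:
        for chrom, arr in values.items():
            if len(arr) == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def read_stranded_coverage(path_fwd: str, path_rev: str, chromosome_lengths: dict[str, int]) -> CoverageTrack:
    track = CoverageTrack()
    for strand, path in (("+", path_fwd), ("-", path_rev)):
        for chrom, arr in read_bedgraph(path, chromosome_lengths).items():
            track.set(chrom, strand, arr)
    return track


def read_table(path: str, **kwargs) -> pd.DataFrame:
    """Read a generic tab-separated table (expression matrices, regulons, ...)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# operon / regulon / TSS / TU tables
# ---------------------------------------------------------------------------

def read_operons(path: str) -> OperonMap:
    df = read_table(path, dtype=str)
    ops = [Operon(r.operon, tuple(r.genes.split(",")), r.strand) for r in df.itertuples()]
    return OperonMap(ops)


def write_operons(operons: OperonMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("operon\tstrand\tgenes\n")
        for o in operons:
            fh.write(f"{o.id}\t{o.strand}\t{','.join(o.genes)}\n")


def read_regulons(path: str) -> RegulonTable:
    df = read_table(path, dtype=str)
    table = RegulonTable()
    for r in df.itertuples():
        table.add(r.factor, r.kind, r.operons.split(","))
    return table


def write_regulons(table: RegulonTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("factor\tkind\toperons\n")
        for f, (kind, ops) in table.factors.items():
            fh.write(f"{f}\t{kind}\t{','.join(sorted(ops))}\n")


def read_tss(path: str) -> TSSList:
    df = read_table(path)
    return TSSList(TSS(str(r.chromosome), int(r.position), str(r.strand)) for r in df.itertuples())


def write_tss(tss: TSSList, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\tstrand\n")
        for t in tss:
            fh.write(f"{t.chromosome}\t{t.position}\t{t.strand}\n")


def read_tus(path: str) -> TUMap:
    df = read_table(path, dtype=str)
    return TUMap([TU(r.tu, tuple(r.genes.split(",")), r.kind) for r in df.itertuples()])


def write_tus(tus: TUMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("tu\tkind\tgenes\n")
        for t in tus:
            fh.write(f"{t.id}\t{t.kind}\t{','.join(t.genes)}\n")


# ---------------------------------------------------------------------------
# segment files
# ---------------------------------------------------------------------------

def write_segments(segments, path: str) -> None:
    """One segment per line: genome, chromosome, first/last gene, extent, members."""
    with open(path, "w") as fh:
        fh.write("genome\tchromosome\tfirst_gene\tlast_gene\tspan_start\tspan_end\twraps\tgenes\n")
        for s in segments:
            fh.write(
                f"{s.genome}\t{s.chromosome}\t{s.genes[0]}\t{s.genes[-1]}\t"
                f"{s.span[0]}\t{s.span[1]}\t{int(s.wraps)}\t{','.join(s.genes)}\n"
            )


def read_segments(path: str):
    from .segments import SyntenySegment, SegmentSet

    df = read_table(path)
    segs = [
        SyntenySegment(
            genome=str(r.genome),
            chromosome=str(r.chromosome),
            genes=tuple(str(r.genes).split(",")),
            span=(int(r.span_start), int(r.span_end)),
            wraps=bool(r.wraps),
        )
        for r in df.itertuples()
    ]
    return SegmentSet(segs)
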
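"""Readers and writers for the external file formats.

All public coordinates are 1-based and inclusive, matching GFF3 and the
Bismark cytosine-report convention. Strand is ``+`` or ``-``.

Formats handled here:

* Bismark CX-style per-cytosine reports (7 tab-separated columns:
  chrom, pos, strand, count_methylated, count_unmethylated, context,
  trinucleotide context),
* GFF3 gene annotation (gene and exon features),
* plain TSV count matrices with ``stage_replicate`` sample columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

STAGES = ("embryo", "larva", "prepupa", "pupa", "adult")

_CONTEXT_MAP = {"CG": "CpG", "CpG": "CpG", "CHG": "CHG", "CHH": "CHH"}


class FormatError(ValueError):
    """Raised on malformed input files (message names the offending line)."""


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-resolved cytosine with bisulfite read counts."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    count_meth: int
    count_unmeth: int
    context: str  # CpG / CHG / CHH
    tri_context: str = "CGN"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise FormatError(
                f"negative count at {self.chrom}:{self.pos} "
                f"({self.count_meth}/{self.count_unmeth})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r} at {self.chrom}:{self.pos}")

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: 5' end of the gene."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class Exon:
    gene_id: str
    exon_rank: int  # 1-based, 5'->3' in transcript orientation
    chrom: str
    start: int
    end: int


@dataclass
class GenomeAnnotation:
    """Gene-level annotation: genes, ranked exons and strand-aware TSSs."""

    genes: list[Gene] = field(default_factory=list)
    exons: list[Exon] = field(default_factory=list)

    @property
    def tss(self) -> dict[str, int]:
        return {g.gene_id: g.tss for g in self.genes}

    def genes_by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def exons_of(self, gene_id: str) -> list[Exon]:
        return sorted((e for e in self.exons if e.gene_id == gene_id),
                      key=lambda e: e.exon_rank)


# ---------------------------------------------------------------------------
# Bismark CX report
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path) -> list[CytosineRecord]:
    """Read a Bismark CX-style cytosine report.

    Columns: chrom, 1-based pos, strand, count methylated, count
    unmethylated, context (CG/CHG/CHH), trinucleotide. No context filter is
    applied; records come back in file order.
    """
    records: list[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(
                    f"{path}: line {lineno}: expected 7 tab-separated columns, "
                    f"got {len(parts)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, ctx, tri = parts
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer field ({exc})")
            if meth < 0 or unmeth < 0:
                raise FormatError(f"{path}: line {lineno}: negative count")
            context = _CONTEXT_MAP.get(ctx, ctx)
            if context not in ("CpG", "CHG", "CHH"):
                raise FormatError(f"{path}: line {lineno}: unknown context {ctx!r}")
            records.append(
                CytosineRecord(chrom, pos, strand, meth, unmeth, context, tri)
            )
    return records


def write_cytosine_report(records: Iterable[CytosineRecord], path: str | Path) -> None:
    """Write records in the 7-column CX dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        for r in records:
            ctx = "CG" if r.context == "CpG" else r.context
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count_meth}\t"
                f"{r.count_unmeth}\t{ctx}\t{r.tri_context}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene and exon features from a GFF3 file.

    Exon ``Parent`` attributes may point at a gene directly or at an mRNA
    whose own ``Parent`` is the gene. Exon ranks are recomputed from
    coordinates in transcript orientation (leftmost first on ``+`` genes,
    rightmost first on ``-`` genes) rather than trusted from attributes.
    Orphan exons are skipped with a warning; a gene without a strand is an
    error because the TSS is undefined.
    """
    genes: dict[str, Gene] = {}
    mrna_parent: dict[str, str] = {}
    raw_exons: list[tuple[str, str, int, int]] = []  # parent, chrom, start, end

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = parts
            start, end = int(start_s), int(end_s)
            if start > end:
                raise FormatError(f"{path}: line {lineno}: start > end")
            attrs = _gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}: line {lineno}: gene without ID")
                if strand not in ("+", "-"):
                    raise FormatError(
                        f"{path}: line {lineno}: gene {gid} has no strand"
                    )
                genes[gid] = Gene(gid, chrom, start, end, strand)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid and parent:
                    mrna_parent[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    warnings.warn(f"{path}: line {lineno}: exon without Parent, skipped")
                    continue
                # multiple parents possible; take them all
                for p in parent.split(","):
                    raw_exons.append((p, chrom, start, end))

    exons: list[Exon] = []
    per_gene: dict[str, list[tuple[int, int]]] = {}
    for parent, chrom, start, end in raw_exons:
        gid = parent if parent in genes else mrna_parent.get(parent)
        if gid is None or gid not in genes:
            warnings.warn(f"orphan exon {chrom}:{start}-{end} (parent {parent}), skipped")
            continue
        per_gene.setdefault(gid, [])
        if (start, end) not in per_gene[gid]:  # collapse duplicate exons across isoforms
            per_gene[gid].append((start, end))
    for gid, ivals in per_gene.items():
        g = genes[gid]
        ivals.sort(key=lambda se: se[0], reverse=(g.strand == "-"))
        for rank, (start, end) in enumerate(ivals, start=1):
            exons.append(Exon(gid, rank, g.chrom, start, end))

    return GenomeAnnotation(genes=sorted(genes.values(), key=lambda g: (g.chrom, g.start)),
                            exons=exons)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a TSV count matrix (rows: gene/exon ids; columns: stage_replicate).

    Counts must be non-negative integers; a fractional or negative value is a
    validation error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells in count matrix")
    for col in df.columns:
        vals = df[col]
        as_float = pd.to_numeric(vals, errors="coerce")
        if as_float.isna().any():
            raise FormatError(f"{path}: non-numeric count in column {col}")
        if not (as_float == as_float.round()).all():
            bad = vals[as_float != as_float.round()].iloc[0]
            raise FormatError(f"{path}: non-integer count {bad!r} in column {col}")
        if (as_float < 0).any():
            raise FormatError(f"{path}: negative count in column {col}")
    df = df.astype(int)
    for col in df.columns:
        stage = str(col).rsplit("_", 1)[0]
        if stage not in STAGES:
            raise FormatError(
                f"{path}: sample {col!r} does not encode a known stage "
                f"(expected stage_replicate with stage in {STAGES})"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with the index (round-trips with read_counts)."""
    df.to_csv(path, sep="\t")


def sample_stage(sample_id: str) -> str:
    """Stage label encoded in a ``stage_replicate`` sample id."""
    return str(sample_id).rsplit("_", 1)[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into an uppercase chrom -> sequence dict."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.upper())
            elif line:
                raise FormatError(f"{path}: sequence before first FASTA header")
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene + exon features (exons parented directly to genes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chrom}\tmethylmorph\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for e in annotation.exons_of(g.gene_id):
                fh.write(
                    f"{e.chrom}\tmethylmorph\texon\t{e.start}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{e.exon_rank};Parent={g.gene_id}\n"
                )
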
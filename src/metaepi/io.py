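"""Typed readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Everything internal is 0-based, half-open. GFF3 (1-based, inclusive) is
converted at the boundary, in both directions; BED is passed through.
Modification records on the minus strand are indexed by the plus-strand
coordinate of the modified base, so both strands of a locus share one
coordinate system.
"""

from __future__ import annotations

import enum
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

__all__ = [
    "Kingdom",
    "Genome",
    "GeneTable",
    "ModificationRecord",
    "DistanceMatrix",
    "FormatError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_modifications",
    "write_modifications",
    "read_allele_counts",
    "write_allele_counts",
    "read_hits_table",
    "write_hits_table",
    "read_matrix",
    "write_matrix",
    "read_newick",
    "write_newick",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class Kingdom(str, enum.Enum):
    prokaryote = "prokaryote"
    eukaryote = "eukaryote"
    virus = "virus"
    giant_virus = "giant_virus"


# Characters accepted in input sequences.  IUPAC ambiguity codes are tolerated
# on read but normalized genomes for analysis should be over {A,C,G,T,N}.
_IUPAC_DNA = set("ACGTNRYSWKMBDHV")


@dataclass
class Genome:
    """A (possibly multi-contig) genome with uppercase DNA sequences."""

    genome_id: str
    contigs: list[tuple[str, str]]
    kingdom: Kingdom = Kingdom.prokaryote

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate contig ids in genome {self.genome_id!r}")
        for cid, seq in self.contigs:
            if not seq:
                raise ValidationError(f"empty sequence for contig {cid!r}")
            bad = set(seq) - _IUPAC_DNA
            if bad:
                raise ValidationError(
                    f"contig {cid!r} has non-IUPAC characters: {sorted(bad)}"
                )
        if self.length == 0:
            raise ValidationError("genome has zero total length")

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]


#: columns of a gene table
GENE_COLUMNS = ["contig_id", "start", "end", "strand", "gene_id"]


def _validate_gene_table(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns) != GENE_COLUMNS:
        df = df[GENE_COLUMNS]
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValidationError("gene intervals must satisfy 0 <= start < end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError("gene strand must be '+' or '-'")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r}")
    return df.reset_index(drop=True)


class GeneTable:
    """Gene intervals (0-based half-open) with strand, as a DataFrame wrapper."""

    def __init__(self, rows: pd.DataFrame | Iterable[tuple]) -> None:
        if not isinstance(rows, pd.DataFrame):
            rows = pd.DataFrame(list(rows), columns=GENE_COLUMNS)
        self.df = _validate_gene_table(rows.copy())

    def __len__(self) -> int:
        return len(self.df)

    def for_contig(self, contig_id: str) -> pd.DataFrame:
        return self.df[self.df["contig_id"] == contig_id]


@dataclass(frozen=True)
class ModificationRecord:
    """Per-position, per-strand evidence of base modification."""

    contig_id: str
    position: int  # 0-based, plus-strand coordinate of the modified base
    strand: str
    mod_type: str = "unknown"  # m6A | m4C | unknown
    coverage: int = 0
    qv: float = 0.0
    frac: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand symbol {self.strand!r}")
        if self.position < 0:
            raise ValidationError("position must be >= 0")
        if self.coverage < 0:
            raise ValidationError("coverage must be >= 0")
        if self.qv < 0:
            raise ValidationError("qv must be >= 0")
        if self.frac is not None and not (0.0 <= self.frac <= 1.0):
            raise ValidationError(f"frac {self.frac} outside [0, 1]")


class DistanceMatrix:
    """A symmetric dissimilarity matrix with labels and zero diagonal."""

    def __init__(self, labels: Sequence[str], values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        labels = list(labels)
        if values.shape != (len(labels), len(labels)):
            raise ValidationError("matrix shape does not match label count")
        if not np.all(np.isfinite(values)):
            raise ValidationError("distances must be finite")
        if np.abs(values - values.T).max(initial=0.0) > 1e-9:
            raise ValidationError("matrix not symmetric within 1e-9")
        if np.abs(np.diag(values)).max(initial=0.0) > 1e-12:
            raise ValidationError("diagonal must be zero")
        if (values < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.labels = labels
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _prevalidate_fasta(path: Path) -> None:
    """Light syntactic pass so errors can name a line number."""
    n_since_header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if n_since_header == 0:
                    raise FormatError(f"line {lineno}: empty sequence before this header")
                if len(line) == 1:
                    raise FormatError(f"line {lineno}: header with no identifier")
                n_since_header = 0
            else:
                if n_since_header is None:
                    raise FormatError(f"line {lineno}: sequence data before any header")
                n_since_header += len(line)
    if n_since_header == 0:
        raise FormatError("empty sequence for final record")
    if n_since_header is None:
        raise FormatError("no FASTA records found")


def read_fasta(path: str | Path, genome_id: str | None = None,
               kingdom: Kingdom = Kingdom.prokaryote) -> Genome:
    """Read a multi-FASTA into a Genome (uppercased; U mapped to T)."""
    path = Path(path)
    _prevalidate_fasta(path)
    contigs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        contigs.append((rec.id, seq))
    gid = genome_id if genome_id is not None else path.stem
    return Genome(genome_id=gid, contigs=contigs, kingdom=kingdom)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables (GFF3 gene dialect / BED6)
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gene_table(path: str | Path, dialect: str) -> GeneTable:
    """Read gene intervals from GFF3 (1-based inclusive) or BED6 (half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "gff3":
                if len(f) < 9:
                    raise FormatError(f"line {lineno}: GFF3 needs 9 columns")
                attrs = _parse_gff_attributes(f[8])
                gene_id = attrs.get("ID", f"gene{lineno}")
                rows.append((f[0], int(f[3]) - 1, int(f[4]), f[6], gene_id))
            elif dialect == "bed":
                if len(f) < 6:
                    raise FormatError(f"line {lineno}: BED6 needs 6 columns")
                rows.append((f[0], int(f[1]), int(f[2]), f[5], f[3]))
            else:
                raise ValueError(f"unknown gene-table dialect {dialect!r}")
    return GeneTable(rows)


def write_gene_table(genes: GeneTable, path: str | Path, dialect: str = "gff3") -> None:
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for r in genes.df.itertuples(index=False):
                fh.write(
                    f"{r.contig_id}\tmetaepi\tgene\t{r.start + 1}\t{r.end}\t.\t"
                    f"{r.strand}\t.\tID={r.gene_id}\n"
                )
        elif dialect == "bed":
            for r in genes.df.itertuples(index=False):
                fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.gene_id}\t.\t{r.strand}\n")
        else:
            raise ValueError(f"unknown gene-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Modification records (basemods GFF dialect / TSV)
# ---------------------------------------------------------------------------

_MOD_TSV_COLUMNS = ["contig_id", "position", "strand", "mod_type", "coverage", "qv", "frac"]


def _record_sort_key(r: ModificationRecord) -> tuple:
    return (r.contig_id, r.position, r.strand)


def read_modifications(path: str | Path, dialect: str) -> list[ModificationRecord]:
    """Read per-site modification calls.

    ``basemods_gff``: 1-based inclusive GFF3; score column carries the QV;
    attributes ``coverage=`` and ``frac=``; the feature type column carries the
    modification type. ``tsv``: header row with 0-based positions.
    """
    records: list[ModificationRecord] = []
    if dialect == "basemods_gff":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise FormatError(f"line {lineno}: GFF3 needs 9 columns")
                attrs = _parse_gff_attributes(f[8])
                frac = float(attrs["frac"]) if "frac" in attrs else None
                records.append(
                    ModificationRecord(
                        contig_id=f[0],
                        position=int(f[3]) - 1,
                        strand=f[6],
                        mod_type=f[2] if f[2] in ("m6A", "m4C") else "unknown",
                        coverage=int(attrs.get("coverage", 0)),
                        qv=float(f[5]) if f[5] != "." else 0.0,
                        frac=frac,
                    )
                )
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = set(_MOD_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"modification TSV missing columns {sorted(missing)}")
        for r in df.itertuples(index=False):
            frac = None if pd.isna(r.frac) else float(r.frac)
            records.append(
                ModificationRecord(
                    contig_id=str(r.contig_id),
                    position=int(r.position),
                    strand=str(r.strand),
                    mod_type=str(r.mod_type),
                    coverage=int(r.coverage),
                    qv=float(r.qv),
                    frac=frac,
                )
            )
    else:
        raise ValueError(f"unknown modifications dialect {dialect!r}")
    return sorted(records, key=_record_sort_key)


def write_modifications(records: Iterable[ModificationRecord], path: str | Path,
                        dialect: str = "tsv") -> None:
    records = sorted(records, key=_record_sort_key)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_MOD_TSV_COLUMNS) + "\n")
            for r in records:
                frac = "" if r.frac is None else f"{r.frac:.6g}"
                fh.write(
                    f"{r.contig_id}\t{r.position}\t{r.strand}\t{r.mod_type}\t"
                    f"{r.coverage}\t{r.qv:.6g}\t{frac}\n"
                )
    elif dialect == "basemods_gff":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                attrs = f"coverage={r.coverage}"
                if r.frac is not None:
                    attrs += f";frac={r.frac:.6g}"
                fh.write(
                    f"{r.contig_id}\tmetaepi\t{r.mod_type}\t{r.position + 1}\t"
                    f"{r.position + 1}\t{r.qv:.6g}\t{r.strand}\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown modifications dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

ALLELE_COLUMNS = ["contig_id", "position", "ref_base", "sample_id", "nA", "nC", "nG", "nT"]


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Long-format per-sample nucleotide counts at genomic positions."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ALLELE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"allele-counts TSV missing columns {sorted(missing)}")
    df = df[ALLELE_COLUMNS].copy()
    if (df[["nA", "nC", "nG", "nT"]] < 0).any().any():
        raise ValidationError("negative allele counts")
    if not df["ref_base"].isin(list("ACGT")).all():
        raise ValidationError("ref_base must be one of A/C/G/T")
    return df.sort_values(["contig_id", "position", "sample_id"]).reset_index(drop=True)


def write_allele_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[ALLELE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hits table
# ---------------------------------------------------------------------------

def read_hits_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"query_genome_id", "subject_genome_id", "bit_score"}
    if not need <= set(df.columns):
        raise FormatError(f"hits TSV missing columns {sorted(need - set(df.columns))}")
    if (df["bit_score"] < 0).any():
        raise ValidationError("negative bit score")
    return df[["query_genome_id", "subject_genome_id", "bit_score"]].copy()


def write_hits_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["query_genome_id", "subject_genome_id", "bit_score"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Distance matrices and trees
# ---------------------------------------------------------------------------

def write_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(path)


def read_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
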
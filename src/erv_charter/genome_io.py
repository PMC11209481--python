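"""Shared coordinate model and readers/writers for the standard formats.

Internal convention: 0-based half-open intervals on the plus strand.
External tables (TSV) use 1-based inclusive coordinates, BED uses
0-based half-open, GFF3 is read as 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger("erv_charter")

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open, 0-based interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    # external (1-based inclusive) representation --------------------------
    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end

    @classmethod
    def from_1based(
        cls, chrom: str, start1: int, end1: int, strand: str = "."
    ) -> "GenomicInterval":
        return cls(chrom, start1 - 1, end1, strand)


@dataclass(frozen=True)
class AlignmentHit:
    """One similarity-search hit of a query (consensus) against a genome.

    Query coordinates are 0-based half-open on the plus strand of the
    query, regardless of the hit's strand.
    """

    query: str
    target: GenomicInterval
    q_start: int
    q_end: int
    matches: int
    mismatches: int
    q_gap_bases: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.q_start < 0 or self.q_end <= self.q_start:
            raise ValueError("invalid query span")
        if self.matches < 0 or self.mismatches < 0 or self.q_gap_bases < 0:
            raise ValueError("negative alignment counts")

    @property
    def aligned(self) -> int:
        """Bases aligned (match + mismatch)."""
        return self.matches + self.mismatches

    @property
    def q_gap_ratio(self) -> float:
        denom = self.matches + self.mismatches + self.q_gap_bases
        return self.q_gap_bases / denom if denom else 0.0


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: body, strand-aware TSS, exons."""

    gene_id: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for exon in self.exons:
            if not self.body.contains(exon):
                raise ValueError(
                    f"exon {exon.chrom}:{exon.start}-{exon.end} outside "
                    f"gene body of {self.gene_id}"
                )

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        """0-based transcription start position."""
        return self.body.start if self.body.strand == "+" else self.body.end - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence mapping.

    Rejects duplicate names, empty sequences, and non-IUPAC {ACGTN}
    characters; errors name the offending line.
    """
    records: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _commit(line_no: int) -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {name!r} (line {header_line})")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: invalid characters {sorted(bad)} in record {name!r}"
            )
        if name in records:
            raise FormatError(f"{path}: duplicate sequence name {name!r} (line {header_line})")
        records[name] = seq

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _commit(i)
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}: malformed header at line {i}")
                header_line = i
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before first header at line {i}")
                chunks.append(line)
    _commit(-1)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Similarity-search hit formats (PSL, 12-column tabular BLAST)
# ---------------------------------------------------------------------------

def read_hits(path: str | Path, format: str = "psl") -> list[AlignmentHit]:
    """Read similarity hits from PSL (BLAT) or blast6 (tabular BLAST).

    PSL coordinates are already 0-based half-open and are preserved;
    minus-strand query coordinates are normalized to plus-strand query
    space (as PSL's qStart/qEnd already are). blast6 1-based inclusive
    subject coordinates are converted; a reversed subject range encodes
    a minus-strand hit.
    """
    if format == "psl":
        return _read_psl(path)
    if format == "blast6":
        return _read_blast6(path)
    raise ValueError(f"unknown hit format {format!r} (expected 'psl' or 'blast6')")


def _read_psl(path: str | Path) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue  # optional PSL header block
            fields = line.split("\t")
            if len(fields) != 21:
                raise FormatError(
                    f"{path}: line {i}: expected 21 PSL columns, got {len(fields)}"
                )
            (matches, mismatches, rep_matches, _n_count, _q_gaps, q_gap_bases,
             _t_gaps, _t_gap_bases, strand, q_name, _q_size, q_start, q_end,
             t_name, _t_size, t_start, t_end) = (
                int(fields[0]), int(fields[1]), int(fields[2]), int(fields[3]),
                int(fields[4]), int(fields[5]), int(fields[6]), int(fields[7]),
                fields[8], fields[9], int(fields[10]), int(fields[11]),
                int(fields[12]), fields[13], int(fields[14]), int(fields[15]),
                int(fields[16]),
            )
            hits.append(
                AlignmentHit(
                    query=q_name,
                    target=GenomicInterval(t_name, t_start, t_end, strand[0]),
                    q_start=q_start,
                    q_end=q_end,
                    matches=matches + rep_matches,
                    mismatches=mismatches,
                    q_gap_bases=q_gap_bases,
                    strand=strand[0],
                )
            )
    return hits


def _read_blast6(path: str | Path) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {i}: expected 12 blast6 columns, got {len(fields)}"
                )
            (q_name, t_name, pident, aln_len, _mm, gapopen, q_start, q_end,
             s_start, s_end) = (
                fields[0], fields[1], float(fields[2]), int(fields[3]),
                int(fields[4]), int(fields[5]), int(fields[6]), int(fields[7]),
                int(fields[8]), int(fields[9]),
            )
            mismatches = int(fields[4])
            if s_start <= s_end:
                strand = "+"
                t0, t1 = s_start - 1, s_end
            else:
                strand = "-"
                t0, t1 = s_end - 1, s_start
            q0, q1 = min(q_start, q_end) - 1, max(q_start, q_end)
            matches = aln_len - mismatches
            hits.append(
                AlignmentHit(
                    query=q_name,
                    target=GenomicInterval(t_name, t0, t1, strand),
                    q_start=q0,
                    q_end=q1,
                    matches=matches,
                    mismatches=mismatches,
                    q_gap_bases=0,
                    strand=strand,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features of a GFF3 file into GeneModels.

    Exons are attached to their gene through the Parent chain; an exon
    whose parent cannot be resolved, or which falls outside its gene
    body, raises a validation error naming the feature.
    """
    genes: dict[str, GenomicInterval] = {}
    parent_of: dict[str, str] = {}
    exon_rows: list[tuple[str, GenomicInterval, str]] = []
    order: list[str] = []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {i}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            interval = GenomicInterval.from_1based(chrom, int(start1), int(end1), strand)
            fid = attr.get("ID", "")
            if ftype == "gene":
                genes[fid] = interval
                order.append(fid)
            elif ftype in ("mRNA", "transcript"):
                parent_of[fid] = attr.get("Parent", "")
            elif ftype == "exon":
                exon_rows.append((attr.get("Parent", ""), interval, fid or f"line{i}"))

    exons_by_gene: dict[str, list[GenomicInterval]] = {g: [] for g in genes}
    for parent, interval, fid in exon_rows:
        gene_id = parent_of.get(parent, parent)
        if gene_id not in genes:
            raise FormatError(
                f"{path}: exon {fid!r} has unresolvable parent {parent!r}"
            )
        exons_by_gene[gene_id].append(interval)

    models = []
    for gene_id in order:
        body = genes[gene_id]
        exons = tuple(sorted(exons_by_gene[gene_id], key=lambda e: e.start))
        for exon in exons:
            if not body.contains(exon):
                raise FormatError(
                    f"{path}: exon {exon.chrom}:{exon.start1}-{exon.end1} "
                    f"outside gene body of {gene_id!r}"
                )
        models.append(GeneModel(gene_id, body, exons))
    return models


# ---------------------------------------------------------------------------
# Locus tables (TSV, 1-based) and BED (0-based)
# ---------------------------------------------------------------------------

LOCUS_COLUMNS = [
    "name", "chrom", "strand", "start", "end", "length",
    "element_class", "completeness_pct", "range", "qgap_pct", "indel", "context",
]


def write_locus_table(loci: Iterable, path: str | Path) -> None:
    """Write classified loci as a TSV with 1-based inclusive positions."""
    rows = []
    for locus in loci:
        rows.append(
            {
                "name": locus.name,
                "chrom": locus.interval.chrom,
                "strand": locus.interval.strand,
                "start": locus.interval.start1,
                "end": locus.interval.end1,
                "length": locus.interval.length,
                "element_class": locus.element_class,
                "completeness_pct": f"{100 * locus.completeness:.2f}",
                "range": locus.completeness_bin,
                "qgap_pct": f"{100 * locus.q_gap_ratio:.2f}",
                "indel": ";".join(locus.flags) if locus.flags else "NA",
                "context": locus.context or "NA",
            }
        )
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_locus_table(path: str | Path):
    """Inverse of :func:`write_locus_table` (returns ErvLocus objects)."""
    from .locus_mining import ErvLocus  # cycle kept local

    df = pd.read_csv(path, sep="\t", dtype={"indel": str, "context": str})
    loci = []
    for _, row in df.iterrows():
        flags = () if row["indel"] in ("NA", "", None) or pd.isna(row["indel"]) \
            else tuple(str(row["indel"]).split(";"))
        loci.append(
            ErvLocus(
                name=row["name"],
                interval=GenomicInterval.from_1based(
                    row["chrom"], int(row["start"]), int(row["end"]), row["strand"]
                ),
                element_class=row["element_class"],
                completeness=float(row["completeness_pct"]) / 100,
                completeness_bin=row["range"],
                q_gap_ratio=float(row["qgap_pct"]) / 100,
                context=None if pd.isna(row["context"]) or row["context"] == "NA"
                else row["context"],
                flags=flags,
            )
        )
    return loci


def write_bed(loci: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{locus.name}\t0\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i}: BED needs >= 3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return intervals


# ---------------------------------------------------------------------------
# GMT gene sets and key=value config
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i}: GMT needs >= 3 columns")
            name, _desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set {name!r}")
            sets[name] = {g for g in genes if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` config file ('#' comments allowed)."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {i}: expected 'key = value'")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV, optionally headered."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 2 or fields[0] in ("chrom", "chromosome"):
                continue
            lengths[fields[0]] = int(fields[1])
    if not lengths:
        raise FormatError(f"{path}: no chromosome lengths found")
    return lengths
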
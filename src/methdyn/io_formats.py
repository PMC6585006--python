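"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  File dialects that use
other conventions (CGmap and Bismark coverage: 1-based positions; GTF:
1-based inclusive) are converted on ingest and back on output, so the
rest of the package never does coordinate arithmetic across conventions.

CpG sites are keyed by the position of the cytosine on its own strand;
minus-strand CG records are kept distinct from their plus-strand dyad
partner (symmetric merging, when wanted, is a downstream option).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger("methdyn")

STRANDS = ("+", "-", ".")
CONTEXTS = ("CG", "CHG", "CHH")


class MethdynError(Exception):
    """Base class for package errors."""


class ParseError(MethdynError):
    """A line of an input file could not be parsed."""


class ValidationError(MethdynError):
    """A parsed record violates a structural invariant."""


class ConfigError(MethdynError):
    """A pipeline configuration is invalid."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SiteCounts:
    """Per-cytosine read counts at a 1-based position.

    ``pos`` is the 1-based coordinate of the C on ``strand`` (file-facing
    convention); ``pos0`` gives the internal 0-based coordinate.  The
    methylation level ``meth / total`` is defined only when ``total > 0``.
    """

    chrom: str
    pos: int
    strand: str
    meth: int
    total: int
    context: str = "CG"

    def __post_init__(self) -> None:
        if self.total < self.meth or self.meth < 0:
            raise ValidationError(
                f"{self.chrom}:{self.pos} has meth={self.meth} > total={self.total}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"invalid context {self.context!r}")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def level(self) -> float:
        if self.total == 0:
            raise ValidationError(
                f"level undefined at {self.chrom}:{self.pos} (total=0)"
            )
        return self.meth / self.total


@dataclass(frozen=True)
class GeneModel:
    """A gene span with ordered, disjoint exons (all 0-based half-open)."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be +/-")
        prev_end = None
        for s, e in self.exons:
            if s < self.interval.start or e > self.interval.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene span "
                    f"({self.interval.start},{self.interval.end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons unsorted or overlapping at ({s},{e})"
                )
            if s >= e:
                raise ValidationError(f"gene {self.gene_id}: empty exon ({s},{e})")
            prev_end = e

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """0-based position of the transcription end site."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


# ---------------------------------------------------------------------------
# CGmap
# ---------------------------------------------------------------------------

def read_cgmap(path: str | Path,
               contexts: Sequence[str] = ("CG",)) -> Iterator[SiteCounts]:
    """Stream sites from an 8-column CGmap file.

    Columns: chrom, nucleotide (C/G), 1-based position, context,
    dinucleotide, level, meth count, total count.  Records whose
    nucleotide is G describe the minus strand.  Non-CG contexts are
    dropped by default; pass ``contexts`` to keep them.
    """
    keep = set(contexts)
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(f"{path}:{ln}: expected 8 columns, got {len(fields)}")
            chrom, nuc, pos_s, ctx, _dinuc, _level, meth_s, total_s = fields
            if nuc not in ("C", "G"):
                raise ParseError(f"{path}:{ln}: nucleotide must be C or G, got {nuc!r}")
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                total = int(total_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer field ({exc})") from exc
            if ctx not in CONTEXTS:
                raise ParseError(f"{path}:{ln}: unknown context {ctx!r}")
            if ctx not in keep:
                continue
            if meth > total:
                raise ValidationError(
                    f"{path}:{ln}: meth count {meth} exceeds total {total}"
                )
            strand = "+" if nuc == "C" else "-"
            yield SiteCounts(chrom, pos, strand, meth, total, ctx)


def write_cgmap(sites: Iterable[SiteCounts], path: str | Path) -> None:
    """Write sites in CGmap dialect (inverse of :func:`read_cgmap`)."""
    with open(path, "w") as fh:
        for s in sites:
            nuc = "C" if s.strand == "+" else "G"
            level = f"{s.meth / s.total:.4f}" if s.total else "na"
            dinuc = s.context[:2] if s.context != "CG" else "CG"
            fh.write(f"{s.chrom}\t{nuc}\t{s.pos}\t{s.context}\t{dinuc}\t"
                     f"{level}\t{s.meth}\t{s.total}\n")


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------

def read_bismark_cov(path: str | Path) -> Iterator[SiteCounts]:
    """Stream sites from a 6-column Bismark coverage file.

    Columns: chrom, 1-based start, end, methylation percent, methylated
    count, unmethylated count.  The percent column is recomputed from the
    counts; an inconsistent value is reported as a warning and the counts
    win.  The dialect is unstranded CpG output, so strand is "." and
    context CG.
    """
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{ln}: expected 6 columns, got {len(fields)}")
            chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = fields
            try:
                pos = int(start_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
                pct = float(pct_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: malformed field ({exc})") from exc
            if meth < 0 or unmeth < 0:
                raise ValidationError(f"{path}:{ln}: negative count")
            total = meth + unmeth
            if total > 0 and abs(pct - 100.0 * meth / total) > 0.1:
                warnings.warn(
                    f"{path}:{ln}: percent column {pct} inconsistent with "
                    f"counts {meth}/{total}; counts win",
                    stacklevel=2,
                )
            yield SiteCounts(chrom, pos, ".", meth, total, "CG")


def write_bismark_cov(sites: Iterable[SiteCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            pct = 100.0 * s.meth / s.total if s.total else 0.0
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos}\t{pct:g}\t{s.meth}\t"
                     f"{s.total - s.meth}\n")


# ---------------------------------------------------------------------------
# gene tables (GTF / TSV)
# ---------------------------------------------------------------------------

def _merge_blocks(blocks: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of possibly-overlapping half-open blocks, sorted."""
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def read_gene_table(path: str | Path, dialect: str = "gtf") -> list[GeneModel]:
    """Read gene models from a GTF or the package's TSV gene table.

    GTF: rows with feature ``exon`` are grouped by the ``gene_id``
    attribute; 1-based inclusive coordinates become 0-based half-open.
    The gene span is the hull of its exons unless a ``gene`` row widens it.

    TSV: header gene_id, chrom, strand, start, end, exon_starts,
    exon_ends with 1-based inclusive coordinates and comma-separated exon
    blocks (same convention as GTF, so the two dialects round-trip).
    Overlapping exon blocks are merged in both dialects.
    """
    dialect = dialect.lower()
    if dialect == "gtf":
        genes = _read_gtf(path)
    elif dialect == "tsv":
        genes = _read_gene_tsv(path)
    else:
        raise ConfigError(f"unknown gene-table dialect {dialect!r}")
    return sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def _read_gtf(path: str | Path) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    spans: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "gene"):
                continue
            try:
                start0, end0 = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinate") from exc
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ParseError(f"{path}:{ln}: missing gene_id attribute")
            prev = meta.setdefault(gid, (chrom, strand))
            if prev != (chrom, strand):
                raise ValidationError(f"gene {gid}: inconsistent chrom/strand")
            if feature == "gene":
                spans[gid] = (start0, end0)
            else:
                exons.setdefault(gid, []).append((start0, end0))
    out = []
    for gid, blocks in exons.items():
        chrom, strand = meta[gid]
        merged = _merge_blocks(blocks)
        lo = min(merged[0][0], spans.get(gid, merged[0])[0])
        hi = max(merged[-1][1], spans.get(gid, (0, merged[-1][1]))[1])
        if gid in spans and (merged[0][0] < spans[gid][0] or merged[-1][1] > spans[gid][1]):
            raise ValidationError(f"gene {gid}: exon outside declared gene span")
        out.append(GeneModel(gid, GenomicInterval(chrom, lo, hi, strand), strand, merged))
    return out


def _read_gene_tsv(path: str | Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "chrom", "strand", "start", "end",
                    "exon_starts", "exon_ends"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: TSV gene table must have columns {sorted(required)}")
        for ln, row in enumerate(reader, start=2):
            try:
                start0 = int(row["start"]) - 1
                end0 = int(row["end"])
                starts = [int(x) - 1 for x in row["exon_starts"].split(",") if x]
                ends = [int(x) for x in row["exon_ends"].split(",") if x]
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: malformed field ({exc})") from exc
            if len(starts) != len(ends):
                raise ParseError(f"{path}:{ln}: exon_starts/exon_ends length mismatch")
            blocks = _merge_blocks(list(zip(starts, ends)))
            gid = row["gene_id"]
            if blocks and (blocks[0][0] < start0 or blocks[-1][1] > end0):
                raise ValidationError(f"gene {gid}: exon outside declared gene span")
            out.append(GeneModel(
                gid, GenomicInterval(row["chrom"], start0, end0, row["strand"]),
                row["strand"], blocks,
            ))
    return out


def write_gene_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write the TSV gene dialect (1-based inclusive, comma exon blocks)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(s + 1) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}\t"
                     f"{g.interval.start + 1}\t{g.interval.end}\t{starts}\t{ends}\n")


# ---------------------------------------------------------------------------
# CGI tracks (UCSC cpgIslandExt table / BED)
# ---------------------------------------------------------------------------

def read_cgi_track(path: str | Path, dialect: str = "bed") -> list[GenomicInterval]:
    """Read CpG-island intervals from a BED file or a UCSC cpgIslandExt dump.

    Both dialects are 0-based half-open already.  The UCSC dump may carry
    a leading ``bin`` column, detected by a numeric first field followed
    by a non-numeric chromosome.  Output is sorted; overlapping islands
    are merged with a warning, abutting ones stay distinct.
    """
    dialect = dialect.lower()
    raw: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 3:
                    raise ParseError(f"{path}:{ln}: BED needs >= 3 columns")
                chrom, start_s, end_s = fields[0], fields[1], fields[2]
            elif dialect == "ucsc_table":
                # optional leading bin column
                if len(fields) >= 4 and fields[0].lstrip("-").isdigit():
                    fields = fields[1:]
                if len(fields) < 3:
                    raise ParseError(f"{path}:{ln}: cpgIslandExt needs >= 3 columns")
                chrom, start_s, end_s = fields[0], fields[1], fields[2]
            else:
                raise ConfigError(f"unknown CGI-track dialect {dialect!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinate") from exc
            if end <= start:
                raise ValidationError(f"{path}:{ln}: end {end} <= start {start}")
            raw.append(GenomicInterval(chrom, start, end))
    merged: list[GenomicInterval] = []
    for iv in sorted(raw):
        if merged and iv.chrom == merged[-1].chrom and iv.start < merged[-1].end:
            warnings.warn(
                f"{path}: overlapping CGIs merged at {iv.chrom}:{iv.start}",
                stacklevel=2,
            )
            last = merged.pop()
            merged.append(GenomicInterval(iv.chrom, last.start,
                                          max(last.end, iv.end)))
        else:
            merged.append(iv)
    return merged


def write_bed(intervals: Iterable[GenomicInterval | tuple], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED, optionally with a name column."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv[:3]
            if names is not None:
                fh.write(f"{chrom}\t{start}\t{end}\t{names[i]}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# tabular report I/O
# ---------------------------------------------------------------------------

def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as a header-bearing TSV.

    Column order is the frame's own order (deterministic for all package
    tables); missing values become "."; the file is newline-terminated.
    """
    table.to_csv(path, sep="\t", index=False, na_rep=".")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])
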
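"""Genome annotation layers for the methylome analysis.

Two independent labelings of the genome are built:

* the CGI layer — CpG islands, their 2 kb shores, the 2 kb shelves
  outside the shores, and everything else;
* the gene layer — a strict partition of every position into upstream
  (5 kb before the TSS), exon, intron, downstream (5 kb after the TES)
  or intergenic, with precedence exon > intron > upstream > downstream >
  intergenic applied jointly across genes.

CpG islands follow the classic sequence definition: maximal regions
longer than 200 bp with GC fraction above 0.5 and an observed/expected
CpG ratio above 0.6, where the expected CpG density is (GC/2)^2.
Detection slides a 200 bp window in 1 bp steps, merges overlapping
qualifying windows, and trims merged regions symmetrically until the
criteria hold (region-growing in the Gardiner-Garden tradition).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, GenomicInterval, ValidationError

logger = logging.getLogger("methdyn")

GENE_LAYER = ("exon", "intron", "upstream", "downstream", "intergenic")
CGI_LAYER = ("CGI", "CGI shore", "CGI shelf", "none")
# precedence used both for painting and for classification tie-breaks
_GENE_PRECEDENCE = ("intergenic", "downstream", "upstream", "intron", "exon")
CGI_CLASS_OF = {
    "upstream": "Upstream-CGI",
    "intron": "Intronic-CGI",
    "exon": "Exonic-CGI",
    "downstream": "Downstream-CGI",
    "intergenic": "Intergenic-CGI",
}


@dataclass(frozen=True)
class CgiRecord:
    """A detected or imported CpG island."""

    interval: GenomicInterval
    gc_fraction: float
    obs_exp_ratio: float
    genic_class: str | None = None

    @property
    def length(self) -> int:
        return len(self.interval)


class GenomePartition:
    """Per-chromosome segmentation of the genome into named categories.

    Stores sorted breakpoints and a category code per elementary
    segment; lookups are vectorized binary searches.
    """

    def __init__(self, categories: Sequence[str],
                 bounds: dict[str, np.ndarray],
                 codes: dict[str, np.ndarray]):
        self.categories = tuple(categories)
        self._bounds = bounds
        self._codes = codes

    @classmethod
    def paint(cls, chrom_sizes: Mapping[str, int], base: str,
              layers: Sequence[tuple[str, Mapping[str, Sequence[tuple[int, int]]]]],
              categories: Sequence[str]) -> "GenomePartition":
        """Paint interval layers over a base category.

        ``layers`` are applied in order: later layers take precedence.
        Intervals are clipped at chromosome bounds.
        """
        cat_idx = {c: i for i, c in enumerate(categories)}
        bounds: dict[str, np.ndarray] = {}
        codes: dict[str, np.ndarray] = {}
        # rank in painting order (not category order): later layer wins
        for chrom, size in chrom_sizes.items():
            pts = {0, size}
            per_layer: list[tuple[int, list[tuple[int, int]]]] = []
            for cat, ivmap in layers:
                clipped = []
                for s, e in ivmap.get(chrom, ()):
                    s, e = max(0, s), min(size, e)
                    if s < e:
                        clipped.append((s, e))
                        pts.add(s)
                        pts.add(e)
                per_layer.append((cat_idx[cat], clipped))
            bp = np.array(sorted(pts), dtype=np.int64)
            seg_codes = np.full(len(bp) - 1, cat_idx[base], dtype=np.int16)
            for code, clipped in per_layer:
                for s, e in clipped:
                    i0 = np.searchsorted(bp, s)
                    i1 = np.searchsorted(bp, e)
                    seg_codes[i0:i1] = code
            bounds[chrom] = bp
            codes[chrom] = seg_codes
        return cls(categories, bounds, codes)

    @property
    def chroms(self) -> list[str]:
        return list(self._bounds)

    def label_at(self, chrom: str, positions: np.ndarray | Sequence[int]) -> np.ndarray:
        """Category name for each position on ``chrom``."""
        pos = np.asarray(positions, dtype=np.int64)
        bp = self._bounds[chrom]
        if pos.size and (pos.min() < bp[0] or pos.max() >= bp[-1]):
            raise ValidationError(f"position outside {chrom} [0,{bp[-1]})")
        idx = np.searchsorted(bp, pos, side="right") - 1
        cats = np.asarray(self.categories, dtype=object)
        return cats[self._codes[chrom][idx]]

    def segments(self, chrom: str):
        """Yield (start, end, category) elementary segments."""
        bp = self._bounds[chrom]
        codes = self._codes[chrom]
        for i in range(len(codes)):
            yield int(bp[i]), int(bp[i + 1]), self.categories[codes[i]]

    def category_sizes(self) -> dict[str, int]:
        sizes = dict.fromkeys(self.categories, 0)
        for chrom, bp in self._bounds.items():
            widths = np.diff(bp)
            for code in range(len(self.categories)):
                sizes[self.categories[code]] += int(
                    widths[self._codes[chrom] == code].sum())
        return sizes

    def overlap_by_category(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """Bases of [start, end) covered by each category."""
        bp = self._bounds[chrom]
        codes = self._codes[chrom]
        out = dict.fromkeys(self.categories, 0)
        i0 = max(0, int(np.searchsorted(bp, start, side="right")) - 1)
        for i in range(i0, len(codes)):
            if bp[i] >= end:
                break
            ov = min(end, int(bp[i + 1])) - max(start, int(bp[i]))
            if ov > 0:
                out[self.categories[codes[i]]] += ov
        return out


# ---------------------------------------------------------------------------
# CpG-island detection
# ---------------------------------------------------------------------------

def _seq_arrays(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums of GC bases and CG-dinucleotide starts."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    gc = (is_c | is_g).astype(np.int64)
    cg = np.zeros(len(arr), dtype=np.int64)
    if len(arr) > 1:
        cg[:-1] = (is_c[:-1] & is_g[1:]).astype(np.int64)
    return np.concatenate([[0], np.cumsum(gc)]), np.concatenate([[0], np.cumsum(cg)])


def _region_ok(gc_cum: np.ndarray, cg_cum: np.ndarray, start: int, end: int,
               min_len: int, min_gc: float, min_oe: float) -> bool:
    length = end - start
    if length <= min_len:
        return False
    gc = (gc_cum[end] - gc_cum[start]) / length
    if gc <= min_gc:
        return False
    # CG dinucleotides fully inside [start, end)
    obs = (cg_cum[end - 1] - cg_cum[start]) / length
    exp = (gc / 2.0) ** 2
    return exp > 0 and obs / exp > min_oe


def detect_cgis(sequence: str, chrom: str = "chr", *, min_len: int = 200,
                min_gc: float = 0.5, min_oe: float = 0.6,
                window: int = 200) -> list[CgiRecord]:
    """Detect CpG islands in an uppercase DNA sequence (N allowed).

    Qualifying 200 bp windows (GC > ``min_gc``, obs/exp CpG > ``min_oe``)
    are merged when overlapping; each merged region is then re-tested
    against all three criteria — including length strictly greater than
    ``min_len`` — and shrunk by one base at each end until it passes or
    becomes too short.  Returns maximal regions in coordinate order.
    """
    L = len(sequence)
    if L < window:
        return []
    gc_cum, cg_cum = _seq_arrays(sequence)
    n_win = L - window + 1
    starts = np.arange(n_win)
    gc_counts = gc_cum[starts + window] - gc_cum[starts]
    # CG dinucleotide must lie fully inside the window
    cg_counts = cg_cum[starts + window - 1] - cg_cum[starts]
    gc_frac = gc_counts / window
    exp = (gc_frac / 2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, (cg_counts / window) / exp, 0.0)
    ok = (gc_frac > min_gc) & (oe > min_oe)
    if not ok.any():
        return []
    # merge overlapping qualifying windows: runs of starts closer than window
    qual = np.flatnonzero(ok)
    breaks = np.flatnonzero(np.diff(qual) >= window) + 1
    regions = []
    for run in np.split(qual, breaks):
        s, e = int(run[0]), int(run[-1]) + window
        # trim symmetrically until the merged region itself qualifies
        while e - s > min_len and not _region_ok(gc_cum, cg_cum, s, e,
                                                min_len, min_gc, min_oe):
            s += 1
            e -= 1
        if e - s > min_len and _region_ok(gc_cum, cg_cum, s, e,
                                          min_len, min_gc, min_oe):
            length = e - s
            gc = (gc_cum[e] - gc_cum[s]) / length
            obs = (cg_cum[e - 1] - cg_cum[s]) / length
            regions.append(CgiRecord(
                GenomicInterval(chrom, s, e),
                gc_fraction=float(gc),
                obs_exp_ratio=float(obs / (gc / 2.0) ** 2),
            ))
    return regions


def detect_cgis_genome(sequences: Mapping[str, str], **kwargs) -> list[CgiRecord]:
    """Run :func:`detect_cgis` per chromosome; order-independent result."""
    out: list[CgiRecord] = []
    for chrom in sorted(sequences):
        out.extend(detect_cgis(sequences[chrom], chrom, **kwargs))
    return out


# ---------------------------------------------------------------------------
# CGI layer: shores and shelves
# ---------------------------------------------------------------------------

def _cgi_interval_map(cgis: Iterable[CgiRecord | GenomicInterval],
                      ) -> dict[str, list[tuple[int, int]]]:
    ivmap: dict[str, list[tuple[int, int]]] = {}
    for c in cgis:
        iv = c.interval if isinstance(c, CgiRecord) else c
        ivmap.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in ivmap:
        ivmap[chrom].sort()
    return ivmap


def derive_shores_shelves(cgis: Iterable[CgiRecord | GenomicInterval],
                          chrom_sizes: Mapping[str, int],
                          flank: int = 2000) -> GenomePartition:
    """Build the CGI layer: islands, 2 kb shores, 2 kb shelves, none.

    Shores are the ``flank`` bp outside each island, shelves the
    ``flank`` bp outside the shores; where flanks of neighbouring
    islands collide the precedence CGI > shore > shelf applies, and
    everything is clipped at chromosome ends.
    """
    ivmap = _cgi_interval_map(cgis)
    shelf = {c: [(s - 2 * flank, e + 2 * flank) for s, e in ivs]
             for c, ivs in ivmap.items()}
    shore = {c: [(s - flank, e + flank) for s, e in ivs]
             for c, ivs in ivmap.items()}
    return GenomePartition.paint(
        chrom_sizes, base="none",
        layers=[("CGI shelf", shelf), ("CGI shore", shore), ("CGI", ivmap)],
        categories=CGI_LAYER,
    )


# ---------------------------------------------------------------------------
# gene layer
# ---------------------------------------------------------------------------

def partition_genic(genes: Iterable[GeneModel],
                    chrom_sizes: Mapping[str, int],
                    up: int = 5000, down: int = 5000) -> GenomePartition:
    """Partition the genome into the five genic features.

    Upstream/downstream are strand-aware (5' of the TSS, 3' of the TES);
    precedence exon > intron > upstream > downstream > intergenic is
    applied across all genes jointly, so every position gets exactly one
    label.
    """
    ups: dict[str, list[tuple[int, int]]] = {}
    downs: dict[str, list[tuple[int, int]]] = {}
    introns: dict[str, list[tuple[int, int]]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        chrom = g.interval.chrom
        if g.strand == "+":
            ups.setdefault(chrom, []).append((g.interval.start - up, g.interval.start))
            downs.setdefault(chrom, []).append((g.interval.end, g.interval.end + down))
        else:
            ups.setdefault(chrom, []).append((g.interval.end, g.interval.end + up))
            downs.setdefault(chrom, []).append((g.interval.start - down, g.interval.start))
        introns.setdefault(chrom, []).append((g.interval.start, g.interval.end))
        exons.setdefault(chrom, []).extend(g.exons)
    return GenomePartition.paint(
        chrom_sizes, base="intergenic",
        layers=[("downstream", downs), ("upstream", ups),
                ("intron", introns), ("exon", exons)],
        categories=GENE_LAYER,
    )


def classify_cgis(cgis: Iterable[CgiRecord],
                  gene_layer: GenomePartition) -> list[CgiRecord]:
    """Assign each CGI the genic feature covering > 50% of its length.

    If no single feature exceeds half the island, the largest overlap
    wins, ties broken by exon > intron > upstream > downstream >
    intergenic.
    """
    rank = {c: i for i, c in enumerate(_GENE_PRECEDENCE)}
    out = []
    for c in cgis:
        iv = c.interval
        ov = gene_layer.overlap_by_category(iv.chrom, iv.start, iv.end)
        best = max(ov.items(), key=lambda kv: (kv[1], rank[kv[0]]))
        winner = best[0]
        for cat, bases in ov.items():
            if bases * 2 > len(iv):
                winner = cat
                break
        out.append(replace(c, genic_class=CGI_CLASS_OF[winner]))
    return out


# ---------------------------------------------------------------------------
# promoter CpG-content classes
# ---------------------------------------------------------------------------

def classify_promoters(genes: Iterable[GeneModel],
                       sequences: Mapping[str, str],
                       window: tuple[int, int] = (-1000, 500),
                       oe_threshold: float = 0.48) -> dict[str, str]:
    """Label genes HCP/LCP by promoter CpG observed/expected ratio.

    The promoter window is ``window`` around the TSS in transcription
    coordinates (negative = upstream); it is clipped at chromosome ends.
    The score uses the same (GC/2)^2 expected-density formula as island
    detection; a gene scores HCP when the ratio reaches
    ``oe_threshold``.  An all-N or GC-free window falls to LCP with a
    warning.
    """
    out: dict[str, str] = {}
    for g in genes:
        chrom = g.interval.chrom
        seq = sequences[chrom]
        tss = g.tss
        if g.strand == "+":
            s, e = tss + window[0], tss + window[1]
        else:
            s, e = tss - window[1] + 1, tss - window[0] + 1
        s, e = max(0, s), min(len(seq), e)
        sub = seq[s:e]
        n = len(sub)
        gc = (sub.count("C") + sub.count("G")) / n if n else 0.0
        if gc == 0.0:
            warnings.warn(f"gene {g.gene_id}: promoter window has no GC; "
                          "classed LCP", stacklevel=2)
            out[g.gene_id] = "LCP"
            continue
        obs = sub.count("CG") / n
        score = obs / (gc / 2.0) ** 2
        out[g.gene_id] = "HCP" if score >= oe_threshold else "LCP"
    return out


# ---------------------------------------------------------------------------
# assembled annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """The two genome labelings plus classified CGIs and promoter classes."""

    cgi_layer: GenomePartition
    gene_layer: GenomePartition
    cgis: list[CgiRecord]
    promoter_class: dict[str, str]


def build_annotation(sequences: Mapping[str, str],
                     genes: Sequence[GeneModel],
                     cgis: Sequence[CgiRecord | GenomicInterval] | None = None,
                     *, up: int = 5000, down: int = 5000, flank: int = 2000,
                     promoter_window: tuple[int, int] = (-1000, 500),
                     oe_threshold: float = 0.48,
                     promoter_classes: Mapping[str, str] | None = None,
                     **cgi_kwargs) -> AnnotationSet:
    """Build both layers from sequence + gene models.

    CGIs are detected from sequence unless a precomputed track is given;
    an externally supplied gene→{HCP,LCP} table bypasses promoter
    scoring.
    """
    chrom_sizes = {c: len(s) for c, s in sequences.items()}
    if cgis is None:
        cgi_records = detect_cgis_genome(sequences, **cgi_kwargs)
    else:
        cgi_records = [
            c if isinstance(c, CgiRecord)
            else CgiRecord(c, gc_fraction=float("nan"), obs_exp_ratio=float("nan"))
            for c in cgis
        ]
    gene_layer = partition_genic(genes, chrom_sizes, up=up, down=down)
    cgi_layer = derive_shores_shelves(cgi_records, chrom_sizes, flank=flank)
    classified = classify_cgis(cgi_records, gene_layer)
    if promoter_classes is not None:
        promoters = dict(promoter_classes)
    else:
        promoters = classify_promoters(genes, sequences,
                                       window=promoter_window,
                                       oe_threshold=oe_threshold)
    logger.info("annotation: %d CGIs, %d genes, gene-layer sizes %s",
                len(classified), len(genes), gene_layer.category_sizes())
    return AnnotationSet(cgi_layer, gene_layer, classified, promoters)
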
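"""Binned meta-profiles of methylation over gene and CGI locations.

Gene profiles use the 20 + 40 + 20 scheme: 20 bins over the fixed 5 kb
upstream flank, 40 bins over the (length-scaled) gene body, 20 bins over
the 5 kb downstream flank, oriented 5'→3' along transcription.  CGI
profiles use 20 + 20 + 20 bins with fixed 2 kb flanks and are
unstranded (the left flank is the lower-coordinate side).

Aggregation is per-feature-then-average: each feature's bin value is the
mean of the group-level methylation of the retained CpGs falling in the
bin's coordinate span, and the profile bin is the mean over features
with at least one CpG there — every feature weighs equally regardless of
its CpG count.  Empty bins propagate as missing, never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import CgiRecord
from .io_formats import GeneModel, GenomicInterval, ValidationError
from .methylome import CpGCountMatrix, region_level

logger = logging.getLogger("methdyn")

GENE_BINS = (20, 40, 20)
CGI_BINS = (20, 20, 20)


@dataclass
class ProfileMatrix:
    """Mean methylation per meta-profile bin for one feature class/group."""

    feature_class: str
    group: str
    values: np.ndarray          # (n_bins,) mean level, NaN where empty
    n_features: np.ndarray      # (n_bins,) features contributing
    scheme: tuple[int, int, int]
    flank: int

    @property
    def n_bins(self) -> int:
        return int(sum(self.scheme))

    def to_frame(self) -> pd.DataFrame:
        segs = (["upstream"] * self.scheme[0] + ["body"] * self.scheme[1]
                + ["downstream"] * self.scheme[2])
        return pd.DataFrame({
            "bin": np.arange(self.n_bins),
            "segment": segs,
            "mean_level": self.values,
            "n_features": self.n_features,
        })


def _bin_of(offsets: np.ndarray, span: float, nbins: int) -> np.ndarray:
    """Bin index floor(offset / span * nbins), clamped to [0, nbins)."""
    idx = np.floor(offsets / span * nbins).astype(int)
    return np.clip(idx, 0, nbins - 1)


def _feature_bins(pos: np.ndarray, levels: np.ndarray,
                  start: int, end: int, strand: str,
                  flank: int, scheme: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (sum, count) of CpG levels for one feature.

    ``pos`` are retained-CpG coordinates on the feature's chromosome;
    the three spans (upstream flank, body, downstream flank) partition
    [start - flank, end + flank) in transcription orientation.
    """
    n_up, n_body, n_down = scheme
    nbins = n_up + n_body + n_down
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    if strand == "-":
        # mirror into transcription coordinates: 0 at end+flank-1 moving left
        t = (end + flank - 1) - pos
    else:
        t = pos - (start - flank)
    body_len = end - start
    in_up = t < flank
    in_body = (t >= flank) & (t < flank + body_len)
    in_down = (t >= flank + body_len) & (t < 2 * flank + body_len)
    pieces = (
        (in_up, t, 0.0, flank, n_up, 0),
        (in_body, t, flank, body_len, n_body, n_up),
        (in_down, t, flank + body_len, flank, n_down, n_up + n_body),
    )
    for mask, tt, off, span, nb, base in pieces:
        if not mask.any():
            continue
        b = base + _bin_of(tt[mask] - off, span, nb)
        np.add.at(sums, b, levels[mask])
        np.add.at(counts, b, 1)
    return sums, counts


def _profile(matrix: CpGCountMatrix, group: str,
             features: Sequence[tuple[str, int, int, str]],
             flank: int, scheme: tuple[int, int, int],
             feature_class: str) -> ProfileMatrix:
    nbins = sum(scheme)
    glv = matrix.group_levels(group)
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(chrom_arr):
        m = chrom_arr == chrom
        by_chrom[chrom] = (pos_arr[m], glv[m])
    acc = np.zeros(nbins)
    nfeat = np.zeros(nbins, dtype=int)
    for chrom, start, end, strand in features:
        if chrom not in by_chrom:
            continue
        pos_c, lv_c = by_chrom[chrom]
        lo, hi = start - flank, end + flank
        i0, i1 = np.searchsorted(pos_c, [lo, hi])
        if i0 == i1:
            continue
        sums, counts = _feature_bins(pos_c[i0:i1], lv_c[i0:i1],
                                     start, end, strand, flank, scheme)
        has = counts > 0
        acc[has] += sums[has] / counts[has]
        nfeat[has] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(nfeat > 0, acc / np.maximum(nfeat, 1), np.nan)
    return ProfileMatrix(feature_class, group, values, nfeat, scheme, flank)


def gene_profile(matrix: CpGCountMatrix, genes: Iterable[GeneModel],
                 group: str, subset: Sequence[str] | None = None,
                 flank: int = 5000, scheme: tuple[int, int, int] = GENE_BINS,
                 feature_class: str = "genes") -> ProfileMatrix:
    """20/40/20 metagene profile for one group.

    ``subset`` optionally restricts to gene ids (e.g. the HCP or LCP
    class).  Genes whose body is shorter than the body bin count are
    excluded (their bins would be sub-base).
    """
    wanted = set(subset) if subset is not None else None
    feats = []
    for g in genes:
        if wanted is not None and g.gene_id not in wanted:
            continue
        if len(g.interval) < scheme[1]:
            continue
        feats.append((g.interval.chrom, g.interval.start, g.interval.end, g.strand))
    if not feats:
        raise ValidationError("gene_profile: no usable genes in subset")
    return _profile(matrix, group, feats, flank, scheme, feature_class)


def cgi_profile(matrix: CpGCountMatrix, cgis: Iterable[CgiRecord],
                group: str, genic_class_filter: str | None = None,
                flank: int = 2000, scheme: tuple[int, int, int] = CGI_BINS,
                ) -> ProfileMatrix:
    """20/20/20 CGI profile, optionally for one genic CGI class."""
    feats = []
    for c in cgis:
        if genic_class_filter is not None and c.genic_class != genic_class_filter:
            continue
        if len(c.interval) < scheme[1]:
            continue
        feats.append((c.interval.chrom, c.interval.start, c.interval.end, "+"))
    if not feats:
        raise ValidationError(
            f"cgi_profile: no CGIs of class {genic_class_filter!r}")
    return _profile(matrix, group, feats, flank, scheme,
                    genic_class_filter or "CGI")


@dataclass
class SpecificCgiReport:
    """CGIs whose level is lowest-middle pattern across ordered stages."""

    selected: list[CgiRecord]
    n_uncovered: int
    class_composition: dict[str, float]     # percent of selected per genic class
    overlapping_genes: list[str]
    levels: pd.DataFrame                    # per-CGI region levels per group


def select_specific_cgis(matrix: CpGCountMatrix, cgis: Sequence[CgiRecord],
                         genes: Sequence[GeneModel] | None = None,
                         stages: Sequence[str] | None = None,
                         ) -> SpecificCgiReport:
    """Select CGIs with level(first) < level(middle) and level(first) > level(last).

    Both inequalities are strict.  ``stages`` defaults to the matrix
    group order (e.g. Pre, In, Post).  CGIs without retained CpG
    coverage are excluded and counted; when gene models are supplied the
    genes whose span overlaps a selected CGI are reported.
    """
    if stages is None:
        stages = matrix.group_order
    if len(stages) != 3:
        raise ValidationError("specific-CGI selection needs exactly 3 stages")
    rows = []
    selected = []
    n_uncovered = 0
    for c in cgis:
        lv = [region_level(matrix, c.interval, g) for g in stages]
        if any(np.isnan(x) for x in lv):
            n_uncovered += 1
            continue
        pick = lv[0] < lv[1] and lv[0] > lv[2]
        rows.append({"chrom": c.interval.chrom, "start": c.interval.start,
                     "end": c.interval.end, "genic_class": c.genic_class,
                     **{f"level_{g}": lv[i] for i, g in enumerate(stages)},
                     "selected": pick})
        if pick:
            selected.append(c)
    comp: dict[str, float] = {}
    if selected:
        classes = pd.Series([c.genic_class for c in selected])
        comp = (classes.value_counts(normalize=True) * 100).to_dict()
    overlapping: list[str] = []
    if genes is not None and selected:
        for g in genes:
            if any(g.interval.overlap(c.interval) > 0 for c in selected):
                overlapping.append(g.gene_id)
    logger.info("specific CGIs: %d selected, %d uncovered", len(selected),
                n_uncovered)
    return SpecificCgiReport(selected, n_uncovered, comp, overlapping,
                             pd.DataFrame(rows))
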
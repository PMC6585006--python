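"""Multi-sample CpG count matrix and methylation-level summaries.

The central object is :class:`CpGCountMatrix`: per-CpG methylated/total
read counts across named samples with a sample→group design (the study
design this package targets is three pubertal stages — Pre, In, Post —
with three biological replicates each, but any grouping works).

Only CpGs covered by at least ``min_cov`` reads in *every* sample are
retained ("coexisting" sites), so all downstream statistics are computed
on a common site set.  A site's methylation level is methylated reads
divided by total covered reads; a group's level at a site is the
arithmetic mean of its replicates' levels (count pooling is reserved for
the Fisher testing in :mod:`methdyn.dynamics`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, MethdynError, SiteCounts, ValidationError

logger = logging.getLogger("methdyn")


class EmptyMatrixError(MethdynError):
    """No CpG site survived the coexistence/coverage filter."""


@dataclass
class CpGCountMatrix:
    """Ordered CpG sites with per-sample methylated/total counts.

    ``sites`` has columns chrom, pos (0-based C position), strand and is
    sorted by (chrom, pos, strand); ``meth``/``total`` are parallel
    (n_sites, n_samples) integer arrays.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]
    groups: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_order:
            seen: list[str] = []
            for s in self.samples:
                g = self.groups[s]
                if g not in seen:
                    seen.append(g)
            self.group_order = seen
        for g in self.group_order:
            if not any(self.groups[s] == g for s in self.samples):
                raise ValidationError(f"group {g!r} has no samples")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def _require_sites(self) -> None:
        if self.n_sites == 0:
            raise EmptyMatrixError(
                "no CpG sites survived filtering; nothing to compute")

    def group_samples(self, group: str) -> list[int]:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise ValidationError(f"unknown or empty group {group!r}")
        return idx

    def sample_levels(self) -> np.ndarray:
        """(n_sites, n_samples) per-sample methylation levels."""
        self._require_sites()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    def group_levels(self, group: str | None = None) -> np.ndarray:
        """Mean of replicate levels: (n_sites,) or (n_sites, n_groups)."""
        lv = self.sample_levels()
        if group is not None:
            return lv[:, self.group_samples(group)].mean(axis=1)
        return np.column_stack(
            [lv[:, self.group_samples(g)].mean(axis=1) for g in self.group_order])

    def pooled_counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-summed (meth, total) counts for one group."""
        self._require_sites()
        idx = self.group_samples(group)
        return self.meth[:, idx].sum(axis=1), self.total[:, idx].sum(axis=1)

    def coverage_mask(self, min_cov: int) -> np.ndarray:
        """Sites with total >= min_cov in every sample."""
        return (self.total >= min_cov).all(axis=1)

    def subset(self, mask: np.ndarray) -> "CpGCountMatrix":
        return CpGCountMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask], self.total[mask],
            list(self.samples), dict(self.groups), list(self.group_order),
        )

    def sites_in(self, interval: GenomicInterval) -> np.ndarray:
        """Boolean mask of retained CpGs inside a half-open interval."""
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        return (chrom == interval.chrom) & (pos >= interval.start) & (pos < interval.end)


def build_matrix(sample_sites: Mapping[str, Iterable[SiteCounts]],
                 groups: Mapping[str, str],
                 min_cov: int = 5,
                 group_order: Sequence[str] | None = None) -> CpGCountMatrix:
    """Assemble the coexistence-filtered count matrix.

    Keeps exactly the sites present with total >= ``min_cov`` in *all*
    samples, sorted by (chrom, pos).  An empty survivor set yields a
    valid empty matrix whose downstream operations refuse with a clear
    message.
    """
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    if not sample_sites:
        raise ValidationError("need at least one sample")
    samples = list(sample_sites)
    for s in samples:
        if s not in groups:
            raise ValidationError(f"sample {s!r} missing from group design")
    frames = []
    for name in samples:
        recs = [(sc.chrom, sc.pos0, sc.strand, sc.meth, sc.total)
                for sc in sample_sites[name]]
        df = pd.DataFrame(recs, columns=["chrom", "pos", "strand", "meth", "total"])
        df = df[df["total"] >= min_cov].set_index(["chrom", "pos", "strand"])
        if df.index.has_duplicates:
            raise ValidationError(f"sample {name!r}: duplicate site records")
        frames.append(df)
    common = frames[0].index
    for df in frames[1:]:
        common = common.intersection(df.index)
    common = common.sortlevel()[0] if len(common) else common
    sites = pd.DataFrame(
        list(common), columns=["chrom", "pos", "strand"]
    ).sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    key = pd.MultiIndex.from_frame(sites)
    meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, df in enumerate(frames):
        aligned = df.reindex(key)
        meth[:, j] = aligned["meth"].to_numpy()
        total[:, j] = aligned["total"].to_numpy()
    logger.info("build_matrix: %d CpGs covered >= %dx in all %d samples",
                len(sites), min_cov, len(samples))
    return CpGCountMatrix(sites, meth, total, samples, dict(groups),
                          list(group_order) if group_order else [])


# ---------------------------------------------------------------------------
# level arithmetic
# ---------------------------------------------------------------------------

def site_level(meth: int, total: int) -> float:
    """Methylated reads divided by total covered reads."""
    if total <= 0:
        raise ValidationError("site level undefined for total = 0")
    if not 0 <= meth <= total:
        raise ValidationError(f"invalid counts meth={meth}, total={total}")
    return meth / total


def group_level(levels: Sequence[float]) -> float:
    """Arithmetic mean of per-replicate levels (not pooled counts)."""
    if len(levels) == 0:
        raise ValidationError("group level undefined for empty group")
    return float(np.mean(levels))


def region_level(matrix: CpGCountMatrix, interval: GenomicInterval,
                 group: str) -> float:
    """Unweighted mean of group-level site values inside a region.

    Returns NaN (missing, not zero) when the region holds no retained
    CpG.
    """
    mask = matrix.sites_in(interval)
    if not mask.any():
        return float("nan")
    return float(matrix.group_levels(group)[mask].mean())


# ---------------------------------------------------------------------------
# level distributions
# ---------------------------------------------------------------------------

#: The three headline level classes: below 20%, 50-80%, above 80%.
CLASS_BINS = ((0.0, 0.2), (0.5, 0.8), (0.8, 1.0))


def level_histogram(matrix: CpGCountMatrix, group: str,
                    bins: Sequence[float] | str = "deciles") -> pd.DataFrame:
    """Per-replicate level-bin fractions with the group mean ± SEM.

    ``bins`` is either "deciles", "classes" (the <20%, [20,50), [50,80),
    >80% partition) or explicit edges partitioning [0, 1].  Bins are
    left-closed right-open with the last bin closed, so the masses of a
    partition sum to one per replicate.
    """
    if isinstance(bins, str):
        if bins == "deciles":
            edges = np.linspace(0.0, 1.0, 11)
        elif bins == "classes":
            edges = np.array([0.0, 0.2, 0.5, 0.8, 1.0])
        else:
            raise ValidationError(f"unknown bin scheme {bins!r}")
    else:
        edges = np.asarray(bins, dtype=float)
        if edges[0] != 0.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
            raise ValidationError("explicit bins must partition [0, 1]")
    lv = matrix.sample_levels()
    idx = matrix.group_samples(group)
    rows = []
    for j in idx:
        x = lv[:, j]
        # right=False gives [a, b); fold exact 1.0 into the last bin
        which = np.digitize(x, edges, right=False) - 1
        which[x >= 1.0] = len(edges) - 2
        frac = np.bincount(which, minlength=len(edges) - 1) / len(x)
        rows.append(frac)
    per_rep = np.array(rows)
    mean = per_rep.mean(axis=0)
    sem = (per_rep.std(axis=0, ddof=1) / np.sqrt(len(idx))
           if len(idx) > 1 else np.zeros_like(mean))
    out = pd.DataFrame({
        "bin_start": edges[:-1],
        "bin_end": edges[1:],
        "mean_fraction": mean,
        "sem_fraction": sem,
    })
    for j, col in zip(idx, range(len(idx))):
        out[f"fraction_{matrix.samples[j]}"] = per_rep[col]
    return out


def category_level_summary(matrix: CpGCountMatrix, annotation) -> pd.DataFrame:
    """Mean methylation per annotation category and group (Table-1 twin).

    For the whole genome, the three CGI-layer categories and the five
    gene-layer features: per-replicate mean level over the CpGs in the
    category, summarized as the group mean ± standard error over
    biological replicates.
    """
    matrix._require_sites()
    lv = matrix.sample_levels()
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    masks: list[tuple[str, str, np.ndarray]] = [
        ("genome", "Genomes", np.ones(len(pos_arr), dtype=bool))]
    for layer_name, part, cats in (
            ("cgi", annotation.cgi_layer, ["CGI", "CGI shore", "CGI shelf"]),
            ("gene", annotation.gene_layer,
             ["upstream", "exon", "intron", "downstream", "intergenic"])):
        labels = np.empty(len(pos_arr), dtype=object)
        for chrom in pd.unique(chrom_arr):
            m = chrom_arr == chrom
            labels[m] = part.label_at(chrom, pos_arr[m])
        for cat in cats:
            masks.append((layer_name, cat, labels == cat))
    rows = []
    for layer_name, cat, mask in masks:
        row: dict = {"layer": layer_name, "category": cat,
                     "n_cpg": int(mask.sum())}
        for g in matrix.group_order:
            idx = matrix.group_samples(g)
            if mask.any():
                per_rep = lv[mask][:, idx].mean(axis=0)
                row[f"mean_{g}"] = float(per_rep.mean())
                row[f"sem_{g}"] = (float(per_rep.std(ddof=1) / np.sqrt(len(idx)))
                                   if len(idx) > 1 else 0.0)
            else:
                row[f"mean_{g}"] = np.nan
                row[f"sem_{g}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome windows
# ---------------------------------------------------------------------------

def window_stats(matrix: CpGCountMatrix,
                 chrom_sizes: Mapping[str, int],
                 dmc_sites: pd.DataFrame | None = None,
                 window: int = 1_000_000) -> pd.DataFrame:
    """Non-overlapping tiling-window methylation track.

    Windows tile each chromosome from coordinate 0; the trailing partial
    window is kept.  Per window: mean of site levels per group, retained
    CpG count, and — when a DMC table is supplied — the DMC count
    normalized by the window's CpG count.  Windows without CpGs carry
    missing values and are excluded from downstream correlations.
    """
    matrix._require_sites()
    glv = matrix.group_levels()
    rows = []
    dmc_key = None
    if dmc_sites is not None:
        dmc_key = set(zip(dmc_sites["chrom"], dmc_sites["pos"]))
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    for chrom, size in chrom_sizes.items():
        on_chrom = chrom_arr == chrom
        pos_c = pos_arr[on_chrom]
        glv_c = glv[on_chrom]
        for start in range(0, size, window):
            end = min(start + window, size)
            in_win = (pos_c >= start) & (pos_c < end)
            n = int(in_win.sum())
            row: dict = {"chrom": chrom, "start": start, "end": end, "n_cpg": n}
            for gi, g in enumerate(matrix.group_order):
                row[f"mean_level_{g}"] = (float(glv_c[in_win, gi].mean())
                                          if n else np.nan)
            if dmc_key is not None:
                k = sum((chrom, int(p)) in dmc_key for p in pos_c[in_win])
                row["n_dmc"] = k
                row["dmc_density"] = k / n if n else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p, pairwise-complete.

    Missing entries are dropped pairwise; at least three complete pairs
    are required and either vector having zero variance is an error
    (r undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("pearson: vectors must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise ValidationError("pearson: need >= 3 complete pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("pearson: zero-variance input, r undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)
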
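"""Region enrichment of DMCs/site labels, group t-tests, qPCR folds.

The enrichment statistic is the *relative enrichment* — the DMC rate
inside a region category divided by the DMC rate outside it (an
inside/outside rate ratio, not the Fisher odds ratio); the two-tailed
Fisher exact test on the same 2x2 table supplies the p-value only.
Recomputing published RRBS enrichment tables from their printed counts
matches the printed values only under this rate-ratio definition, which
is why it is fixed here (see docs/methods.md for the verification).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet, GenomePartition
from .dynamics import DmcTable, fisher_two_tailed
from .io_formats import ValidationError
from .methylome import CpGCountMatrix

logger = logging.getLogger("methdyn")


def region_enrichment(n_r: int, k_r: int, N: int, K: int) -> tuple[float, float]:
    """Relative enrichment and Fisher p for one region category.

    ``n_r`` detected CpGs in the region, ``k_r`` of them DMCs, against
    ``N`` total detected and ``K`` total DMCs.  Enrichment is
    (k_r/n_r) / ((K-k_r)/(N-n_r)); when every DMC lies inside the region
    the outside rate is zero and the ratio is infinite.  The p-value
    comes from the table (k_r, n_r-k_r; K-k_r, (N-n_r)-(K-k_r)).
    """
    if not (0 <= k_r <= n_r <= N and k_r <= K <= N):
        raise ValidationError(
            f"invalid enrichment counts n_r={n_r}, k_r={k_r}, N={N}, K={K}")
    if n_r == 0:
        raise ValidationError("region has no detected CpGs")
    if n_r == N:
        raise ValidationError(
            "region covers every detected CpG; outside rate undefined")
    inside = k_r / n_r
    outside = (K - k_r) / (N - n_r)
    enrichment = inside / outside if outside > 0 else math.inf
    p = fisher_two_tailed(k_r, n_r - k_r, K - k_r, (N - n_r) - (K - k_r))
    return enrichment, p


@dataclass
class EnrichmentReport:
    """Per-category detected/selected counts with enrichment and p."""

    table: pd.DataFrame


def site_category_enrichment(detected: pd.DataFrame,
                             selected_mask: np.ndarray,
                             partition: GenomePartition,
                             categories: Sequence[str],
                             comparison: str = "",
                             layer: str = "") -> pd.DataFrame:
    """Enrichment of selected sites per partition category.

    ``detected`` needs chrom/pos columns for the full detected universe;
    ``selected_mask`` marks the selected subset (DMCs, HyperCs, ...).
    A category with zero detected CpGs yields a row with missing
    statistics rather than an error.
    """
    labels = np.empty(len(detected), dtype=object)
    chrom_arr = detected["chrom"].to_numpy()
    pos_arr = detected["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        m = chrom_arr == chrom
        labels[m] = partition.label_at(chrom, pos_arr[m])
    N = len(detected)
    K = int(selected_mask.sum())
    rows = []
    for cat in categories:
        in_cat = labels == cat
        n_r = int(in_cat.sum())
        k_r = int((in_cat & selected_mask).sum())
        if n_r == 0 or n_r == N:
            enr, p = np.nan, np.nan
        else:
            enr, p = region_enrichment(n_r, k_r, N, K)
        rows.append({"comparison": comparison, "layer": layer,
                     "category": cat, "detected": n_r, "selected": k_r,
                     "enrichment": enr, "p": p})
    return pd.DataFrame(rows)


def enrichment_report(annotation: AnnotationSet, matrix: CpGCountMatrix,
                      dmc_tables: Mapping[str, DmcTable] | None = None,
                      label_sets: Mapping[str, np.ndarray] | None = None,
                      region_tables: Mapping[str, pd.DataFrame] | None = None,
                      ) -> EnrichmentReport:
    """Assemble the per-comparison, per-category enrichment table.

    One row per (comparison, layer, category) over the CGI layer (CGI,
    shores, shelves) and the five-way gene layer; the identical
    machinery covers DMC tables, dynamics-label site sets (boolean masks
    over the matrix sites), and DMR interval tables (scored by which
    category their midpoint falls in, against the matrix CpGs as the
    universe of detected positions).
    """
    pieces = []
    layers = [("cgi", annotation.cgi_layer, ["CGI", "CGI shore", "CGI shelf"]),
              ("gene", annotation.gene_layer,
               ["upstream", "exon", "intron", "downstream", "intergenic"])]

    if dmc_tables:
        for comp, dt in dmc_tables.items():
            detected = dt.table[["chrom", "pos"]]
            mask = dt.table["is_dmc"].to_numpy()
            for lname, part, cats in layers:
                pieces.append(site_category_enrichment(
                    detected, mask, part, cats, comparison=comp, layer=lname))
    if label_sets:
        detected = matrix.sites[["chrom", "pos"]]
        for label, mask in label_sets.items():
            for lname, part, cats in layers:
                pieces.append(site_category_enrichment(
                    detected, np.asarray(mask, bool), part, cats,
                    comparison=label, layer=lname))
    if region_tables:
        for comp, regions in region_tables.items():
            detected = matrix.sites[["chrom", "pos"]]
            chrom_arr = detected["chrom"].to_numpy()
            pos_arr = detected["pos"].to_numpy()
            mask = np.zeros(len(detected), dtype=bool)
            for _, r in regions.iterrows():
                mask |= ((chrom_arr == r["chrom"])
                         & (pos_arr >= int(r["start"]))
                         & (pos_arr < int(r["end"])))
            for lname, part, cats in layers:
                pieces.append(site_category_enrichment(
                    detected, mask, part, cats, comparison=comp, layer=lname))
    table = (pd.concat(pieces, ignore_index=True) if pieces
             else pd.DataFrame(columns=["comparison", "layer", "category",
                                        "detected", "selected", "enrichment",
                                        "p"]))
    return EnrichmentReport(table)


def t_test_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classic equal-variance two-sample Student t with two-sided p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValidationError("t-test needs n >= 2 per sample")
    if np.var(xa, ddof=1) == 0 and np.var(ya, ddof=1) == 0:
        raise ValidationError("zero pooled variance; t undefined")
    t, p = stats.ttest_ind(xa, ya, equal_var=True)
    return float(t), float(p)


def fold_change_ddct(ct_target_case: float, ct_ref_case: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """qPCR relative expression by the 2^-ddCt method."""
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValidationError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
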
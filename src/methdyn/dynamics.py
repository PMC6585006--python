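"""Consistent/monotonic CpG classification and DMC/DMR calling.

Site classes over the three ordered stages (Pre, In, Post):

* HyperC — level >= 0.8 in every stage;
* HypoC  — level <= 0.2 in every stage;
* IncrmC — level rises by >= 0.2 at each successive stage;
* DecrmC — level falls by >= 0.2 at each successive stage.

Differentially methylated CpGs (DMCs) are tested per site on a 2x2
table of group-pooled counts (replicate meth and total counts summed
within each group) with a two-tailed Fisher exact test, adjusted by
Benjamini–Hochberg across all tested sites; a DMC needs q <= 0.05, a
pooled level change strictly greater than 0.2, and >= 8x coverage in
every sample.  Pooling is the package's inferential choice for mapping
three replicates per group onto one Fisher table; a per-replicate
mean-delta variant is available via ``delta_method="replicate_mean"``.

Differentially methylated regions (DMRs) come from a dynamic
fragmentation scheme: consecutive >= 5x CpGs closer than ``max_gap`` are
chained into fragments, fragments are split where the inter-group level
difference flips sign against the running mean difference, and each
direction-coherent sub-fragment with enough CpGs is Fisher-tested on
its summed pooled counts (delta gate >= 0.2 on the mean per-site level
difference, per the asymmetric wording of the DMC/DMR definitions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ValidationError
from .methylome import CpGCountMatrix

logger = logging.getLogger("methdyn")

DYNAMICS_LABELS = ("HyperC", "HypoC", "IncrmC", "DecrmC", "none")


def classify_dynamics(group_levels: np.ndarray, hyper: float = 0.8,
                      hypo: float = 0.2, step: float = 0.2) -> np.ndarray:
    """Label each site from its (n_sites, 3) ordered stage levels.

    The four classes are mutually exclusive by construction (a monotone
    site moving >= 2*step cannot stay within either consistency band).
    """
    lv = np.asarray(group_levels, dtype=float)
    if lv.ndim != 2 or lv.shape[1] != 3:
        raise ValidationError("classify_dynamics needs (n_sites, 3) levels")
    labels = np.full(len(lv), "none", dtype=object)
    labels[(lv >= hyper).all(axis=1)] = "HyperC"
    labels[(lv <= hypo).all(axis=1)] = "HypoC"
    d1 = lv[:, 1] - lv[:, 0]
    d2 = lv[:, 2] - lv[:, 1]
    labels[(d1 >= step) & (d2 >= step)] = "IncrmC"
    labels[(-d1 >= step) & (-d2 >= step)] = "DecrmC"
    return labels


# ---------------------------------------------------------------------------
# Fisher exact test (two-tailed) and BH-FDR
# ---------------------------------------------------------------------------

_REL_TOL = 1e-7  # relative slack when comparing hypergeometric masses


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p for the 2x2 table ((a, b), (c, d)).

    Sums, over the hypergeometric support with the observed margins, the
    probabilities of all tables at most as likely as the observed one
    (with relative tolerance 1e-7 on the comparison).  All-zero margins
    give p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValidationError("fisher_two_tailed needs non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if lo == hi:
        return 1.0
    log_denom = _log_binom(n, c1)
    logps = [
        _log_binom(r1, k) + _log_binom(n - r1, c1 - k) - log_denom
        for k in range(lo, hi + 1)
    ]
    p_obs = logps[a - lo]
    cutoff = p_obs + math.log1p(_REL_TOL)
    included = [lp for lp in logps if lp <= cutoff]
    if len(included) == len(logps):
        return 1.0
    return min(1.0, sum(math.exp(lp) for lp in included))


def fisher_two_tailed_many(tables: np.ndarray) -> np.ndarray:
    """Vectorized wrapper over (n, 4) integer tables."""
    t = np.asarray(tables, dtype=np.int64)
    return np.array([fisher_two_tailed(*row) for row in t])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; monotone
    non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# DMC calling
# ---------------------------------------------------------------------------

@dataclass
class DmcTable:
    """Result of one pairwise DMC comparison."""

    comparison: tuple[str, str]
    table: pd.DataFrame      # all tested sites with p, q, delta, is_dmc
    n_tested: int
    n_skipped: int

    @property
    def n_dmc(self) -> int:
        return int(self.table["is_dmc"].sum())

    @property
    def fraction(self) -> float:
        """DMCs as a fraction of tested sites."""
        return self.n_dmc / self.n_tested if self.n_tested else float("nan")

    @property
    def dmcs(self) -> pd.DataFrame:
        return self.table[self.table["is_dmc"]].reset_index(drop=True)


def call_dmcs(matrix: CpGCountMatrix, group_a: str, group_b: str,
              min_cov: int = 8, delta: float = 0.2, q_max: float = 0.05,
              delta_method: str = "pooled") -> DmcTable:
    """Call DMCs between two groups on the coexistence-refiltered matrix.

    Sites must reach ``min_cov`` in *all* samples of the matrix (the
    detected-CpG universe is shared across comparisons).  Counts are
    pooled within each group for the Fisher table; delta is the pooled
    level difference B − A (or the difference of replicate-mean levels
    with ``delta_method="replicate_mean"``), gated strictly (> delta).
    BH adjustment runs over all tested sites.
    """
    if delta_method not in ("pooled", "replicate_mean"):
        raise ValidationError(f"unknown delta_method {delta_method!r}")
    sub = matrix.subset(matrix.coverage_mask(min_cov))
    sub._require_sites()
    ma, ta = sub.pooled_counts(group_a)
    mb, tb = sub.pooled_counts(group_b)
    ok = (ta > 0) & (tb > 0)
    n_skipped = int((~ok).sum())
    sub = sub.subset(ok)
    ma, ta, mb, tb = ma[ok], ta[ok], mb[ok], tb[ok]
    level_a = ma / ta
    level_b = mb / tb
    if delta_method == "pooled":
        dlt = level_b - level_a
    else:
        dlt = sub.group_levels(group_b) - sub.group_levels(group_a)
    tables = np.column_stack([ma, ta - ma, mb, tb - mb])
    p = fisher_two_tailed_many(tables)
    q = bh_fdr(p)
    tab = sub.sites.copy()
    tab["meth_a"], tab["total_a"] = ma, ta
    tab["meth_b"], tab["total_b"] = mb, tb
    tab["level_a"], tab["level_b"] = level_a, level_b
    tab["delta"] = dlt
    tab["p"] = p
    tab["q"] = q
    tab["direction"] = np.where(dlt > 0, "hyper", np.where(dlt < 0, "hypo", "none"))
    tab["is_dmc"] = (q <= q_max) & (np.abs(dlt) > delta)
    out = DmcTable((group_a, group_b), tab, n_tested=len(tab),
                   n_skipped=n_skipped)
    logger.info("DMC %s vs %s: %d / %d tested (%.2f%%)", group_a, group_b,
                out.n_dmc, out.n_tested, 100 * out.fraction)
    return out


# ---------------------------------------------------------------------------
# DMR calling (dynamic fragmentation)
# ---------------------------------------------------------------------------

def _split_coherent(diffs: np.ndarray) -> list[np.ndarray]:
    """Split a fragment into direction-coherent index runs.

    Walks the per-CpG inter-group differences keeping a running mean of
    the current sub-fragment; a CpG whose difference has the opposite
    strict sign to that running mean starts a new sub-fragment.  Zero
    differences never trigger a split.
    """
    runs: list[np.ndarray] = []
    start = 0
    run_sum = 0.0
    for i, d in enumerate(diffs):
        if i > start and d * run_sum < 0:
            runs.append(np.arange(start, i))
            start = i
            run_sum = 0.0
        run_sum += d
    runs.append(np.arange(start, len(diffs)))
    return runs


@dataclass
class DmrTable:
    comparison: tuple[str, str]
    table: pd.DataFrame
    n_fragments_tested: int

    @property
    def n_dmr(self) -> int:
        return int(self.table["is_dmr"].sum())

    @property
    def dmrs(self) -> pd.DataFrame:
        return self.table[self.table["is_dmr"]].reset_index(drop=True)


def call_dmrs(matrix: CpGCountMatrix, group_a: str, group_b: str,
              min_cov: int = 5, delta: float = 0.2, q_max: float = 0.05,
              min_cpgs: int = 5, max_gap: int = 300) -> DmrTable:
    """Call DMRs by dynamic fragmentation between two groups.

    (1) retained CpGs at >= ``min_cov`` in all samples are chained into
    fragments wherever the inter-CpG gap is <= ``max_gap``; (2) each
    fragment is split into direction-coherent sub-fragments where the
    inter-group level difference changes sign against the running mean;
    (3) sub-fragments with >= ``min_cpgs`` CpGs are Fisher-tested on
    their group-pooled, region-summed counts; (4) BH across tested
    fragments; a DMR needs q <= ``q_max`` and |mean per-site level
    difference| >= ``delta``.
    """
    sub = matrix.subset(matrix.coverage_mask(min_cov))
    sub._require_sites()
    ma, ta = sub.pooled_counts(group_a)
    mb, tb = sub.pooled_counts(group_b)
    diffs = mb / tb - ma / ta
    chrom_arr = sub.sites["chrom"].to_numpy()
    pos_arr = sub.sites["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chrom_arr):
        cm = chrom_arr == chrom
        idx = np.flatnonzero(cm)
        if len(idx) < min_cpgs:
            continue
        pos_c = pos_arr[idx]
        breaks = np.flatnonzero(np.diff(pos_c) > max_gap) + 1
        for frag in np.split(idx, breaks):
            if len(frag) < min_cpgs:
                continue
            for run in _split_coherent(diffs[frag]):
                if len(run) < min_cpgs:
                    continue
                sel = frag[run]
                sm_a, st_a = int(ma[sel].sum()), int(ta[sel].sum())
                sm_b, st_b = int(mb[sel].sum()), int(tb[sel].sum())
                rows.append({
                    "chrom": chrom,
                    "start": int(pos_arr[sel[0]]),
                    "end": int(pos_arr[sel[-1]]) + 2,   # cover the CG dyad
                    "n_cpg": len(sel),
                    "meth_a": sm_a, "total_a": st_a,
                    "meth_b": sm_b, "total_b": st_b,
                    "mean_diff": float(diffs[sel].mean()),
                })
    tab = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg",
                                      "meth_a", "total_a", "meth_b",
                                      "total_b", "mean_diff"])
    if len(tab):
        p = fisher_two_tailed_many(np.column_stack([
            tab["meth_a"], tab["total_a"] - tab["meth_a"],
            tab["meth_b"], tab["total_b"] - tab["meth_b"]]))
        tab["p"] = p
        tab["q"] = bh_fdr(p)
        tab["is_dmr"] = (tab["q"] <= q_max) & (tab["mean_diff"].abs() >= delta)
    else:
        tab["p"] = tab["q"] = np.nan
        tab["is_dmr"] = pd.Series(dtype=bool)
    out = DmrTable((group_a, group_b), tab, n_fragments_tested=len(tab))
    logger.info("DMR %s vs %s: %d / %d fragments", group_a, group_b,
                out.n_dmr, out.n_fragments_tested)
    return out
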
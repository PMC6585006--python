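"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities by direct enumeration over
positions, substrings or contingency tables, deliberately avoiding the
package's vectorized/prefix-sum code paths.
"""

from __future__ import annotations

from math import comb


# ---------------------------------------------------------------------------
# CpG-island detection by direct substring testing
# ---------------------------------------------------------------------------

def _window_ok(sub: str, min_gc: float, min_oe: float) -> bool:
    n = len(sub)
    gc = (sub.count("C") + sub.count("G")) / n
    if gc <= min_gc:
        return False
    exp = (gc / 2.0) ** 2
    if exp == 0:
        return False
    return (sub.count("CG") / n) / exp > min_oe


def _region_ok(seq: str, s: int, e: int, min_len: int,
               min_gc: float, min_oe: float) -> bool:
    return e - s > min_len and _window_ok(seq[s:e], min_gc, min_oe)


def cgi_regions_bruteforce(seq: str, min_len: int = 200, min_gc: float = 0.5,
                           min_oe: float = 0.6, window: int = 200,
                           ) -> list[tuple[int, int]]:
    """Test every 200 bp substring directly, merge, trim symmetrically."""
    L = len(seq)
    qual = [i for i in range(0, L - window + 1)
            if _window_ok(seq[i:i + window], min_gc, min_oe)]
    merged: list[list[int]] = []
    for i in qual:
        if merged and i < merged[-1][1]:
            merged[-1][1] = i + window
        else:
            merged.append([i, i + window])
    out = []
    for s, e in merged:
        while e - s > min_len and not _region_ok(seq, s, e, min_len,
                                                 min_gc, min_oe):
            s += 1
            e -= 1
        if _region_ok(seq, s, e, min_len, min_gc, min_oe):
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# per-base genome labeling
# ---------------------------------------------------------------------------

def gene_layer_per_base(genes, chrom: str, size: int,
                        up: int = 5000, down: int = 5000) -> list[str]:
    """Label every position by looping over genes with explicit precedence."""
    labels = ["intergenic"] * size
    rank = {"intergenic": 0, "downstream": 1, "upstream": 2, "intron": 3,
            "exon": 4}

    def put(lo: int, hi: int, cat: str) -> None:
        for p in range(max(0, lo), min(size, hi)):
            if rank[cat] > rank[labels[p]]:
                labels[p] = cat

    for g in genes:
        if g.interval.chrom != chrom:
            continue
        s, e = g.interval.start, g.interval.end
        if g.strand == "+":
            put(s - up, s, "upstream")
            put(e, e + down, "downstream")
        else:
            put(e, e + up, "upstream")
            put(s - down, s, "downstream")
        put(s, e, "intron")
        for xs, xe in g.exons:
            put(xs, xe, "exon")
    return labels


def cgi_layer_per_base(islands: list[tuple[int, int]], size: int,
                       flank: int = 2000) -> list[str]:
    labels = ["none"] * size
    rank = {"none": 0, "CGI shelf": 1, "CGI shore": 2, "CGI": 3}

    def put(lo: int, hi: int, cat: str) -> None:
        for p in range(max(0, lo), min(size, hi)):
            if rank[cat] > rank[labels[p]]:
                labels[p] = cat

    for s, e in islands:
        put(s - 2 * flank, e + 2 * flank, "CGI shelf")
        put(s - flank, e + flank, "CGI shore")
        put(s, e, "CGI")
    return labels


# ---------------------------------------------------------------------------
# exact two-tailed Fisher by table enumeration
# ---------------------------------------------------------------------------

def fisher_two_tailed_exact(a: int, b: int, c: int, d: int):
    """Exact rational two-sided p over all tables with the same margins.

    Probabilities share the denominator C(n, c1), so tables are compared
    by their integer weights C(r1, k) * C(r2, c1 - k) — no floating
    point enters the tail decision.  Returns a float.
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return num / comb(n, c1)


def bh_stepup_exact(pvals):
    """Direct step-up formula: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * m / rank)
        q[i] = best
    return q
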
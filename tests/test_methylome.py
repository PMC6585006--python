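"""Count-matrix assembly, level arithmetic, histograms and windows."""

import numpy as np
import pandas as pd
import pytest

from methdyn.io_formats import GenomicInterval, SiteCounts, ValidationError
from methdyn.methylome import (CpGCountMatrix, EmptyMatrixError, build_matrix,
                               category_level_summary, group_level,
                               level_histogram, pearson, region_level,
                               site_level, window_stats)


def _mk_sites(spec):
    """spec: list of (chrom, pos1, meth, total)."""
    return [SiteCounts(c, p, "+", m, t) for c, p, m, t in spec]


class TestBuildMatrix:
    GROUPS = {"s1": "A", "s2": "A", "s3": "B"}

    def test_low_coverage_in_one_sample_drops_site(self):
        samples = {
            "s1": _mk_sites([("c", 10, 5, 10), ("c", 20, 5, 10)]),
            "s2": _mk_sites([("c", 10, 5, 10), ("c", 20, 5, 10)]),
            "s3": _mk_sites([("c", 10, 2, 4), ("c", 20, 5, 10)]),
        }
        m = build_matrix(samples, self.GROUPS, min_cov=5)
        assert list(m.sites["pos"]) == [19]   # internal 0-based

    def test_min_cov_one_keeps_everything_shared(self):
        samples = {k: _mk_sites([("c", 10, 1, 1), ("c", 20, 0, 2)])
                   for k in self.GROUPS}
        m = build_matrix(samples, self.GROUPS, min_cov=1)
        assert m.n_sites == 2

    def test_surviving_set_equals_intersection_oracle(self, counts, matrix,
                                                      sim_config):
        keep = None
        for name, recs in counts.sample_sites.items():
            s = {(r.chrom, r.pos0) for r in recs if r.total >= 5}
            keep = s if keep is None else keep & s
        got = set(zip(matrix.sites["chrom"], matrix.sites["pos"]))
        assert got == keep

    def test_empty_matrix_refuses_downstream(self):
        samples = {
            "s1": _mk_sites([("c", 10, 1, 2)]),
            "s2": _mk_sites([("c", 99, 1, 2)]),
            "s3": _mk_sites([("c", 10, 1, 2)]),
        }
        m = build_matrix(samples, self.GROUPS, min_cov=1)
        assert m.n_sites == 0
        with pytest.raises(EmptyMatrixError, match="no CpG sites"):
            m.group_levels("A")

    def test_filter_monotonicity(self, counts, sim_config):
        """Raising min_cov never adds sites."""
        prev = None
        for cov in (1, 5, 8, 12):
            m = build_matrix(counts.sample_sites, sim_config.design,
                             min_cov=cov)
            cur = set(zip(m.sites["chrom"], m.sites["pos"]))
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestLevels:
    @pytest.mark.parametrize("meth,total,expect",
                             [(8, 10, 0.8), (0, 7, 0.0), (7, 7, 1.0)])
    def test_site_level(self, meth, total, expect):
        assert site_level(meth, total) == expect

    def test_site_level_zero_total_errors(self):
        with pytest.raises(ValidationError):
            site_level(0, 0)

    def test_group_level_is_mean_of_ratios(self):
        assert group_level([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert group_level([0.7]) == 0.7
        with pytest.raises(ValidationError):
            group_level([])

    def test_group_level_not_pooled(self):
        """Mean of ratios, not ratio of sums: (1/2, 9/10) -> 0.7, not 10/12."""
        assert group_level([0.5, 0.9]) == pytest.approx(0.7)


class TestRegionLevel:
    def _matrix(self):
        samples = {
            "s1": _mk_sites([("c", 10, 1, 10), ("c", 20, 3, 10)]),
            "s2": _mk_sites([("c", 10, 1, 10), ("c", 20, 3, 10)]),
            "s3": _mk_sites([("c", 10, 9, 10), ("c", 20, 9, 10)]),
        }
        return build_matrix(samples, {"s1": "A", "s2": "A", "s3": "B"},
                            min_cov=5)

    def test_mean_of_site_levels(self):
        m = self._matrix()
        assert region_level(m, GenomicInterval("c", 0, 100), "A") == \
            pytest.approx(0.2)

    def test_no_cpg_gives_missing(self):
        m = self._matrix()
        assert np.isnan(region_level(m, GenomicInterval("c", 50, 60), "A"))

    def test_whole_genome_region_equals_global_mean(self, matrix, genome):
        g = matrix.group_order[0]
        whole = np.nanmean([
            region_level(matrix, GenomicInterval(c, 0, size), g)
            for c, size in genome.chrom_sizes.items()
            if matrix.sites_in(GenomicInterval(c, 0, size)).any()
        ])
        # count-weighted mean of per-chromosome means = global mean
        weights = [matrix.sites_in(GenomicInterval(c, 0, size)).sum()
                   for c, size in genome.chrom_sizes.items()]
        per = [region_level(matrix, GenomicInterval(c, 0, size), g)
               for c, size in genome.chrom_sizes.items()]
        weighted = np.average(per, weights=weights)
        assert weighted == pytest.approx(matrix.group_levels(g).mean())

    def test_partition_weighted_mean_invariant(self, matrix):
        """Count-weighted mean over any window partition = global mean."""
        g = matrix.group_order[0]
        glv = matrix.group_levels(g)
        parts = []
        for c in matrix.sites["chrom"].unique():
            for s in range(0, 400_000, 50_000):
                mask = matrix.sites_in(GenomicInterval(c, s, s + 50_000))
                if mask.any():
                    parts.append((glv[mask].mean(), mask.sum()))
        means, ns = zip(*parts)
        assert np.average(means, weights=ns) == pytest.approx(glv.mean())


class TestHistogram:
    def _const_matrix(self, level_counts):
        samples = {}
        for k in ("s1", "s2", "s3"):
            samples[k] = _mk_sites([("c", 10 * (i + 1), m, t)
                                    for i, (m, t) in enumerate(level_counts)])
        return build_matrix(samples, {"s1": "A", "s2": "A", "s3": "A"},
                            min_cov=1)

    def test_all_zero_mass_in_lowest_bin(self):
        m = self._const_matrix([(0, 10)] * 5)
        h = level_histogram(m, "A", bins="deciles")
        assert h["mean_fraction"].iloc[0] == 1.0
        assert h["mean_fraction"].iloc[1:].sum() == 0.0

    def test_masses_sum_to_one_per_replicate(self, matrix):
        g = matrix.group_order[0]
        h = level_histogram(matrix, g, bins="classes")
        for col in [c for c in h.columns if c.startswith("fraction_")]:
            assert h[col].sum() == pytest.approx(1.0)

    def test_boundary_value_follows_left_closed_convention(self):
        m = self._const_matrix([(2, 10)])   # level exactly 0.2
        h = level_histogram(m, "A", bins="classes")
        # edges [0, .2, .5, .8, 1]: 0.2 falls in [0.2, 0.5)
        assert h["mean_fraction"].iloc[1] == 1.0

    def test_exact_one_in_last_bin(self):
        m = self._const_matrix([(10, 10)])
        h = level_histogram(m, "A", bins="deciles")
        assert h["mean_fraction"].iloc[-1] == 1.0

    def test_uniform_levels_fill_bins_proportionally(self, rng):
        pairs = [(int(m), 100) for m in rng.integers(0, 101, 2000)]
        m = self._const_matrix(pairs)
        h = level_histogram(m, "A", bins="deciles")
        assert np.allclose(h["mean_fraction"], 0.1, atol=0.03)


class TestWindows:
    def test_window_mean_and_dmc_density(self):
        samples = {
            "s1": _mk_sites([("c", 100, 4, 10), ("c", 200, 6, 10)]),
            "s2": _mk_sites([("c", 100, 4, 10), ("c", 200, 6, 10)]),
            "s3": _mk_sites([("c", 100, 4, 10), ("c", 200, 6, 10)]),
        }
        m = build_matrix(samples, {"s1": "A", "s2": "A", "s3": "B"}, min_cov=5)
        dmc = pd.DataFrame({"chrom": ["c"], "pos": [99]})
        w = window_stats(m, {"c": 2000}, dmc_sites=dmc, window=1000)
        assert len(w) == 2
        assert w["mean_level_A"].iloc[0] == pytest.approx(0.5)
        assert w["dmc_density"].iloc[0] == pytest.approx(0.5)
        assert np.isnan(w["mean_level_A"].iloc[1])

    def test_rebinning_oracle(self, matrix, genome):
        w = window_stats(matrix, genome.chrom_sizes, window=100_000)
        g = matrix.group_order[0]
        glv = matrix.group_levels(g)
        for _, row in w.iterrows():
            mask = matrix.sites_in(GenomicInterval(row["chrom"],
                                                   int(row["start"]),
                                                   int(row["end"])))
            if row["n_cpg"] == 0:
                assert not mask.any()
            else:
                assert row[f"mean_level_{g}"] == pytest.approx(
                    glv[mask].mean())

    def test_trailing_partial_window_kept(self, matrix):
        w = window_stats(matrix, {"chr1": 350_500}, window=100_000)
        assert w["end"].iloc[-1] == 350_500 and len(w) == 4


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2, 3, 4]
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_formula_oracle(self):
        x = np.array([1.0, 2, 4, 5, 7])
        y = np.array([2.0, 1, 5, 4, 8])
        r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        r, p = pearson(x, y)
        assert r == pytest.approx(r_oracle)
        assert 0 < p < 1

    def test_pairwise_missing_dropped(self):
        r, _ = pearson([1, 2, np.nan, 3, 4], [1, 2, 9, 3, np.nan])
        assert r == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValidationError):
            pearson([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            pearson([1, 1, 1], [1, 2, 3])


def test_category_summary_matches_direct_means(matrix, annot):
    """Table-1-style summary agrees with directly masked replicate means."""
    tab = category_level_summary(matrix, annot)
    genome_row = tab[tab["category"] == "Genomes"].iloc[0]
    lv = matrix.sample_levels()
    g = matrix.group_order[0]
    idx = matrix.group_samples(g)
    per_rep = lv[:, idx].mean(axis=0)
    assert genome_row[f"mean_{g}"] == pytest.approx(per_rep.mean())
    assert genome_row[f"sem_{g}"] == pytest.approx(
        per_rep.std(ddof=1) / np.sqrt(len(idx)))
    # gene-layer CpG counts sum to the genome-wide detected count
    gene_rows = tab[tab["layer"] == "gene"]
    assert gene_rows["n_cpg"].sum() == matrix.n_sites
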
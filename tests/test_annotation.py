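"""CGI detection, shores/shelves, genic partition and classifications."""

import numpy as np
import pytest

from methdyn.annotation import (CgiRecord, classify_cgis, classify_promoters,
                                derive_shores_shelves, detect_cgis,
                                detect_cgis_genome, partition_genic)
from methdyn.io_formats import GeneModel, GenomicInterval

from oracles import cgi_layer_per_base, cgi_regions_bruteforce, gene_layer_per_base


def _random_seq(rng, length, gc=0.40, patches=()):
    """AT-leaning random sequence with optional CG-rich patches."""
    bases = np.array(list("ACGT"))
    pA = (1 - gc) / 2
    seq = list(rng.choice(bases, size=length, p=[pA, gc / 2, gc / 2, pA]))
    for start, plen, density in patches:
        block = []
        while len(block) < plen:
            if rng.random() < density:
                block += ["C", "G"]
            else:
                block.append(str(rng.choice(bases, p=[0.15, 0.3, 0.3, 0.25])))
        seq[start:start + plen] = block[:plen]
    return "".join(seq)


class TestDetectCgis:
    def test_at_sequence_has_no_island(self):
        assert detect_cgis("AT" * 500) == []

    def test_cg_block_yields_one_island_covering_it(self):
        seq = "AT" * 500 + "CG" * 150 + "TA" * 500
        (cgi,) = detect_cgis(seq)
        assert cgi.interval.start <= 1000 and cgi.interval.end >= 1300
        assert cgi.gc_fraction > 0.5 and cgi.obs_exp_ratio > 0.6

    def test_short_sequence_empty(self):
        assert detect_cgis("CG" * 50) == []

    def test_matches_bruteforce_window_oracle(self, rng):
        """Region set equals testing every substring window directly."""
        for _ in range(4):
            patches = [(int(rng.integers(500, 9000)),
                        int(rng.integers(250, 700)),
                        float(rng.uniform(0.1, 0.3)))
                       for _ in range(3)]
            seq = _random_seq(rng, 10_000, patches=patches)
            got = [(c.interval.start, c.interval.end) for c in detect_cgis(seq)]
            assert got == cgi_regions_bruteforce(seq)

    def test_invariant_to_chromosome_order(self, rng):
        seqs = {"a": _random_seq(rng, 3000, patches=[(1000, 400, 0.25)]),
                "b": _random_seq(rng, 3000, patches=[(500, 400, 0.25)])}
        fwd = detect_cgis_genome(seqs)
        rev = detect_cgis_genome(dict(reversed(list(seqs.items()))))
        assert [(c.interval.chrom, c.interval.start) for c in fwd] == \
               [(c.interval.chrom, c.interval.start) for c in rev]


class TestShoresShelves:
    def test_lone_island_layout(self):
        part = derive_shores_shelves([GenomicInterval("c", 10_000, 10_500)],
                                     {"c": 1_000_000})
        lab = part.label_at("c", [7999, 8000, 9999, 10_000, 10_499, 10_500,
                                  12_499, 12_500, 14_499, 14_500, 6000, 5999])
        assert list(lab) == ["CGI shelf", "CGI shore", "CGI shore", "CGI",
                             "CGI", "CGI shore", "CGI shore", "CGI shelf",
                             "CGI shelf", "none", "CGI shelf", "none"]

    def test_close_islands_gap_is_all_shore(self):
        part = derive_shores_shelves(
            [GenomicInterval("c", 10_000, 10_500),
             GenomicInterval("c", 11_500, 12_000)], {"c": 100_000})
        gap = part.label_at("c", np.arange(10_500, 11_500))
        assert set(gap) == {"CGI shore"}

    def test_per_base_oracle_random_islands(self, rng):
        size = 40_000
        starts = np.sort(rng.choice(size - 1200, size=6, replace=False))
        islands = []
        last = -1
        for s in starts:
            if s > last:
                e = s + int(rng.integers(250, 900))
                islands.append((int(s), e))
                last = e
        part = derive_shores_shelves(
            [GenomicInterval("c", s, e) for s, e in islands], {"c": size})
        oracle = cgi_layer_per_base(islands, size)
        got = part.label_at("c", np.arange(size))
        assert list(got) == oracle
        sizes = part.category_sizes()
        assert sum(sizes.values()) == size


class TestGenicPartition:
    def test_single_plus_gene(self):
        g = GeneModel("g", GenomicInterval("c", 10_000, 20_000, "+"), "+",
                      ((10_000, 20_000),))
        part = partition_genic([g], {"c": 100_000})
        lab = part.label_at("c", [4999, 5000, 9999, 10_000, 19_999, 20_000,
                                  24_999, 25_000])
        assert list(lab) == ["intergenic", "upstream", "upstream", "exon",
                             "exon", "downstream", "downstream", "intergenic"]

    def test_minus_strand_mirror(self):
        g = GeneModel("g", GenomicInterval("c", 10_000, 20_000, "-"), "-",
                      ((10_000, 20_000),))
        part = partition_genic([g], {"c": 100_000})
        assert part.label_at("c", [20_000])[0] == "upstream"
        assert part.label_at("c", [9_999])[0] == "downstream"

    def test_per_base_oracle_and_partition_sum(self, rng):
        size = 30_000
        genes = []
        for i in range(4):
            s = int(rng.integers(0, size - 4000))
            e = s + int(rng.integers(1500, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            x1 = (s, s + 300)
            x2 = (e - 300, e)
            genes.append(GeneModel(f"g{i}", GenomicInterval("c", s, e, strand),
                                   strand, (x1, x2)))
        part = partition_genic(genes, {"c": size}, up=1000, down=1000)
        oracle = gene_layer_per_base(genes, "c", size, up=1000, down=1000)
        assert list(part.label_at("c", np.arange(size))) == oracle
        assert sum(part.category_sizes().values()) == size


class TestClassifyCgis:
    def _layer(self):
        g = GeneModel("g", GenomicInterval("c", 1000, 3000, "+"), "+",
                      ((1000, 2000),))
        return partition_genic([g], {"c": 10_000})

    def _cgi(self, s, e):
        return CgiRecord(GenomicInterval("c", s, e), 0.6, 0.8)

    def test_majority_rule(self):
        (c,) = classify_cgis([self._cgi(1500, 2100)], self._layer())
        assert c.genic_class == "Exonic-CGI"   # 500/600 exon

    def test_exact_tie_broken_by_precedence(self):
        (c,) = classify_cgis([self._cgi(1800, 2200)], self._layer())
        # 200 exon / 200 intron: precedence picks exon
        assert c.genic_class == "Exonic-CGI"

    def test_random_placements_match_argmax_oracle(self, rng):
        layer = self._layer()
        oracle = gene_layer_per_base(
            [GeneModel("g", GenomicInterval("c", 1000, 3000, "+"), "+",
                       ((1000, 2000),))], "c", 10_000)
        prec = {"exon": 4, "intron": 3, "upstream": 2, "downstream": 1,
                "intergenic": 0}
        name = {"exon": "Exonic-CGI", "intron": "Intronic-CGI",
                "upstream": "Upstream-CGI", "downstream": "Downstream-CGI",
                "intergenic": "Intergenic-CGI"}
        for _ in range(50):
            s = int(rng.integers(0, 9500))
            e = s + int(rng.integers(201, 500))
            e = min(e, 10_000)
            (c,) = classify_cgis([self._cgi(s, e)], layer)
            counts = {}
            for p in range(s, e):
                counts[oracle[p]] = counts.get(oracle[p], 0) + 1
            over = [k for k, v in counts.items() if 2 * v > e - s]
            if over:
                expect = name[over[0]]
            else:
                expect = name[max(counts, key=lambda k: (counts[k], prec[k]))]
            assert c.genic_class == expect


class TestClassifyPromoters:
    def _gene(self, chrom="c", start=2000, end=5000, strand="+"):
        return GeneModel("g", GenomicInterval(chrom, start, end, strand),
                         strand, ((start, end),))

    def test_cg_repeat_promoter_is_hcp(self):
        seq = "AT" * 500 + "CG" * 2000
        out = classify_promoters([self._gene()], {"c": seq})
        assert out == {"g": "HCP"}

    def test_at_promoter_is_lcp_with_warning(self):
        seq = "AT" * 3000
        with pytest.warns(UserWarning, match="LCP"):
            out = classify_promoters([self._gene()], {"c": seq})
        assert out == {"g": "LCP"}

    def test_threshold_sweep_is_monotone(self, rng):
        seqs = {"c": "".join(rng.choice(list("ACGT"), size=20_000))}
        genes = [GeneModel(f"g{i}", GenomicInterval("c", s, s + 2000, "+"),
                           "+", ((s, s + 2000),))
                 for i, s in enumerate(range(2000, 16_000, 2000))]
        prev_hcp = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            out = classify_promoters(genes, seqs, oe_threshold=thr)
            hcp = {g for g, c in out.items() if c == "HCP"}
            if prev_hcp is not None:
                assert hcp <= prev_hcp   # raising threshold never adds HCP
            prev_hcp = hcp


class TestCrossModuleGenome:
    def test_planted_islands_detected_and_classified(self, genome, annot):
        for truth in genome.cgis:
            hit = [d for d in annot.cgis
                   if d.interval.overlap(truth.interval)
                   >= 0.95 * len(truth.interval)]
            assert hit, f"planted island {truth.interval} not detected"
            assert hit[0].genic_class == truth.genic_class

    def test_promoter_truth_recovered(self, genome, annot):
        assert annot.promoter_class == genome.promoter_class

    def test_gene_layer_partitions_detected_cpgs(self, matrix, annot, genome):
        """Five gene-layer CpG counts sum to the total detected count."""
        labels = []
        for chrom in genome.chrom_sizes:
            m = matrix.sites["chrom"] == chrom
            labels.extend(annot.gene_layer.label_at(
                chrom, matrix.sites.loc[m, "pos"].to_numpy()))
        assert len(labels) == matrix.n_sites
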
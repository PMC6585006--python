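"""Seeded synthetic inputs emulating a staged RRBS methylome study.

The generator produces a fully self-contained dataset: an AT-biased,
CG-depleted background genome with embedded GC-rich CpG islands, gene
models placed so that all five genic features and all five genic CGI
classes are realized, and nine samples (three stages x three biological
replicates) of per-CpG counts.

The count model mirrors the statistical structure the analysis assumes:

* per-CpG baseline levels are bimodal — a low mode (mean ~0.05) for
  CpGs in islands or upstream regions, a high mode (mean ~0.85)
  elsewhere;
* replicate-level true levels scatter around the group truth with beta
  overdispersion (beta-binomial counts, not pure binomial), so the
  pooled Fisher DMC test faces realistic extra-binomial noise;
* read depth per site/sample is negative-binomial with mean 30 by
  default, so both the >=5x and >=8x coexistence filters retain most
  sites while trimming a realistic tail;
* planted effects — DMC sites, DMR blocks, and consistently
  hyper/hypo/monotonically changing sites — shift the true group
  levels by configured deltas, and every planted signal is recorded in
  truth tables sufficient to score recall and FDR of the callers.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import CgiRecord
from .io_formats import (GeneModel, GenomicInterval, MethdynError, SiteCounts,
                         write_bed, write_cgmap, write_gene_tsv, write_report)

logger = logging.getLogger("methdyn")

_SLOT_PLAN = ("gene+upstream_cgi", "gene+exonic_cgi", "intergenic_cgi",
              "gene+intronic_cgi", "gene+downstream_cgi",
              "gene+upstream_cgi", "gene_plain")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    slot: int = 30_000                  # genome is laid out in feature slots
    island_length: int = 800
    groups: tuple[str, ...] = ("Pre", "In", "Post")
    n_replicates: int = 3
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0    # NB size; larger = tighter
    level_low: float = 0.05             # low-mode mean (CGI/upstream CpGs)
    level_high: float = 0.85            # high-mode mean elsewhere
    baseline_concentration: float = 30.0
    replicate_concentration: float = 100.0  # beta-binomial overdispersion
    dmc_fraction: float = 0.05
    dmc_delta: float = 0.3
    n_dmr_blocks: int = 4
    dmr_block_cpgs: int = 10
    dmr_delta: float = 0.5
    n_label_sites: int = 40             # per planted dynamics class
    label_step: float = 0.3             # monotone step of planted Incrm/Decrm
    upstream: int = 5000

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.groups
                for r in range(self.n_replicates)]

    @property
    def design(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_names}


@dataclass
class GenomeTruth:
    sequences: dict[str, str]
    genes: list[GeneModel]
    cgis: list[CgiRecord]               # planted islands with true genic class
    promoter_class: dict[str, str]      # gene -> HCP/LCP truth
    chrom_sizes: dict[str, int]


@dataclass
class CountsTruth:
    sites: pd.DataFrame                 # chrom,pos,true levels,label,role
    regions: pd.DataFrame               # planted DMR blocks
    sample_sites: dict[str, list[SiteCounts]]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _background(rng: np.random.Generator, length: int) -> np.ndarray:
    """AT-biased background with CpG depletion (deamination-style)."""
    arr = _BASES[rng.choice(4, size=length, p=[0.325, 0.175, 0.175, 0.325])]
    is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    hit = np.flatnonzero(is_cg)
    flip = hit[rng.random(len(hit)) < 0.9]
    arr[flip] = ord("T")
    return arr


def _island_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    """GC-rich, CpG-dense island sequence of exactly ``length`` bases."""
    out = bytearray()
    while len(out) < length:
        if rng.random() < 0.25:
            out += b"CG"
        else:
            out.append(int(_BASES[rng.choice(4, p=[0.12, 0.32, 0.32, 0.24])]))
    return np.frombuffer(bytes(out[:length]), dtype=np.uint8).copy()


def simulate_genome(config: SimConfig) -> GenomeTruth:
    """Lay out genes and islands slot by slot and emit the sequence.

    Each ``slot`` hosts one feature from a repeating plan (genes with an
    upstream/exonic/intronic/downstream island, an intergenic island,
    or a plain island-free gene), guaranteeing all five genic features
    and all five genic CGI classes exist.  Genes with an upstream
    island overlapping the promoter window are the HCP truth.
    """
    rng = np.random.default_rng(config.seed)
    n_slots = config.chrom_length // config.slot
    if n_slots < 1 or config.slot < 28_000:
        raise MethdynError(
            f"infeasible layout: slot {config.slot} / chrom {config.chrom_length} "
            "cannot host a gene with 5 kb flanks and shelf room")
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    cgis: list[CgiRecord] = []
    promoter_class: dict[str, str] = {}
    L_isl = config.island_length
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = _background(rng, config.chrom_length)
        for si in range(n_slots):
            plan = _SLOT_PLAN[(ci * n_slots + si) % len(_SLOT_PLAN)]
            base = si * config.slot
            if plan == "intergenic_cgi":
                s = base + config.slot // 2
                arr[s:s + L_isl] = _island_seq(rng, L_isl)
                cgis.append(CgiRecord(GenomicInterval(chrom, s, s + L_isl),
                                      np.nan, np.nan, "Intergenic-CGI"))
                continue
            strand = "+" if (si % 2 == 0) else "-"
            gene_len = int(rng.integers(11_000, 14_001))
            gstart = base + 8_000
            gend = gstart + gene_len
            exons = ((gstart, gstart + 2_500),
                     (gstart + 6_500, gstart + 7_500),
                     (gend - 2_000, gend))
            gid = f"G{ci + 1:02d}{si:02d}"
            genes.append(GeneModel(gid, GenomicInterval(chrom, gstart, gend, strand),
                                   strand, exons))
            tss = gstart if strand == "+" else gend - 1
            has_promoter_island = plan == "gene+upstream_cgi"
            promoter_class[gid] = "HCP" if has_promoter_island else "LCP"
            if plan == "gene_plain":
                continue
            if plan == "gene+upstream_cgi":
                # fully upstream, overlapping the (-1000,+500) promoter window
                s = tss - 200 - L_isl if strand == "+" else tss + 200
                cls = "Upstream-CGI"
            elif plan == "gene+exonic_cgi":
                mid = (exons[0][0] + exons[0][1]) // 2
                s = mid - L_isl // 2
                cls = "Exonic-CGI"
            elif plan == "gene+intronic_cgi":
                mid = (exons[1][1] + exons[2][0]) // 2
                s = mid - L_isl // 2
                cls = "Intronic-CGI"
            else:  # downstream
                s = gend + 1_000 if strand == "+" else gstart - 1_000 - L_isl
                cls = "Downstream-CGI"
            arr[s:s + L_isl] = _island_seq(rng, L_isl)
            cgis.append(CgiRecord(GenomicInterval(chrom, s, s + L_isl),
                                  np.nan, np.nan, cls))
        sequences[chrom] = arr.tobytes().decode("ascii")
    cgis.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    logger.info("simulate_genome: %d chroms, %d genes, %d islands",
                config.n_chroms, len(genes), len(cgis))
    return GenomeTruth(sequences, genes, cgis, promoter_class,
                       {c: len(s) for c, s in sequences.items()})


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def _in_any(pos: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for s, e in intervals:
        mask |= (pos >= s) & (pos < e)
    return mask


def simulate_counts(config: SimConfig, genome: GenomeTruth) -> CountsTruth:
    """Draw per-site, per-sample beta-binomial counts with planted truth.

    Sites are the plus-strand CpG cytosines of the simulated genome.
    Baseline group levels are identical across stages; planted roles
    then overwrite them: DMC sites shift the middle stage by
    ``dmc_delta``, DMR blocks shift it by ``dmr_delta`` over runs of
    consecutive CpGs, and the four dynamics classes get canonical level
    triples (consistent bands at 0.92/0.04, monotone ramps stepping by
    ``label_step``).
    """
    rng = np.random.default_rng(config.seed + 1)
    frames = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        pos = _cpg_positions(seq)
        low_iv = [(c.interval.start, c.interval.end) for c in genome.cgis
                  if c.interval.chrom == chrom]
        for g in genome.genes:
            if g.interval.chrom != chrom:
                continue
            if g.strand == "+":
                low_iv.append((g.interval.start - config.upstream, g.interval.start))
            else:
                low_iv.append((g.interval.end, g.interval.end + config.upstream))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "low_mode": _in_any(pos, low_iv)}))
    sites = pd.concat(frames, ignore_index=True)
    n = len(sites)

    kb = config.baseline_concentration
    mu = np.where(sites["low_mode"], config.level_low, config.level_high)
    base = rng.beta(mu * kb, (1 - mu) * kb)
    levels = np.repeat(base[:, None], 3, axis=1)

    roles = np.full(n, "none", dtype=object)
    block_id = np.full(n, -1, dtype=int)
    free = np.ones(n, dtype=bool)

    # planted DMR blocks: runs of consecutive CpGs with gaps small enough
    # that the caller's default chaining keeps each block in one fragment
    region_rows = []
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    bcount = 0
    attempts = 0
    while bcount < config.n_dmr_blocks and attempts < 2000:
        attempts += 1
        i = int(rng.integers(0, n - config.dmr_block_cpgs))
        j = i + config.dmr_block_cpgs
        if not free[i:j].all():
            continue
        if len(set(chrom_arr[i:j])) != 1:
            continue
        if np.diff(pos_arr[i:j]).max() > 280:
            continue
        sgn = 1.0 if base[i:j].mean() < 0.5 else -1.0
        levels[i:j, 1] = np.clip(levels[i:j, 1] + sgn * config.dmr_delta,
                                 0.01, 0.99)
        roles[i:j] = "dmr"
        block_id[i:j] = bcount
        free[i:j] = False
        region_rows.append({"block": bcount, "chrom": chrom_arr[i],
                            "start": int(pos_arr[i]),
                            "end": int(pos_arr[j - 1]) + 2,
                            "n_cpg": config.dmr_block_cpgs,
                            "delta": sgn * config.dmr_delta})
        bcount += 1
    if bcount < config.n_dmr_blocks:
        raise MethdynError("could not place all DMR blocks; genome too small")

    def _take(count: int) -> np.ndarray:
        avail = np.flatnonzero(free)
        pick = rng.choice(avail, size=count, replace=False)
        free[pick] = False
        return pick

    s = config.label_step
    for label, triple in (("HyperC", (0.92, 0.92, 0.92)),
                          ("HypoC", (0.04, 0.04, 0.04)),
                          ("IncrmC", (0.10, 0.10 + s, 0.10 + 2 * s)),
                          ("DecrmC", (0.10 + 2 * s, 0.10 + s, 0.10))):
        pick = _take(config.n_label_sites)
        levels[pick] = triple
        roles[pick] = label

    n_dmc = int(round(config.dmc_fraction * n))
    pick = _take(n_dmc)
    sgn = np.where(base[pick] < 0.5, 1.0, -1.0)
    levels[pick, 1] = np.clip(levels[pick, 1] + sgn * config.dmc_delta,
                              0.01, 0.99)
    roles[pick] = "dmc"

    truth = sites[["chrom", "pos"]].copy()
    for gi, g in enumerate(config.groups):
        truth[f"level_{g}"] = levels[:, gi]
    truth["role"] = roles
    truth["dmr_block"] = block_id

    # draw counts
    kr = config.replicate_concentration
    size = config.coverage_dispersion
    p_nb = size / (size + config.coverage_mean)
    sample_sites: dict[str, list[SiteCounts]] = {}
    for gi, g in enumerate(config.groups):
        mu_g = np.clip(levels[:, gi], 1e-3, 1 - 1e-3)
        for r in range(config.n_replicates):
            depth = rng.negative_binomial(size, p_nb, size=n)
            rep_level = rng.beta(mu_g * kr, (1 - mu_g) * kr)
            meth = rng.binomial(depth, rep_level)
            name = f"{g}_{r + 1}"
            sample_sites[name] = [
                SiteCounts(c, int(p) + 1, "+", int(m), int(t))
                for c, p, m, t in zip(chrom_arr, pos_arr, meth, depth)
            ]
    regions = pd.DataFrame(region_rows,
                           columns=["block", "chrom", "start", "end",
                                    "n_cpg", "delta"])
    logger.info("simulate_counts: %d CpG sites, %d planted DMCs, %d DMR blocks",
                n, n_dmc, bcount)
    return CountsTruth(truth, regions, sample_sites)


# ---------------------------------------------------------------------------
# caller benchmarks (two-group count simulations with known truth)
# ---------------------------------------------------------------------------

def _beta_binomial_matrix(levels: np.ndarray, groups: tuple[str, ...],
                          n_replicates: int, depth_mean: float,
                          depth_dispersion: float,
                          replicate_concentration: float,
                          rng: np.random.Generator,
                          positions: np.ndarray) -> "CpGCountMatrix":
    from .methylome import CpGCountMatrix  # local import avoids a cycle

    n = len(levels)
    samples, meth_cols, total_cols = [], [], []
    p_nb = depth_dispersion / (depth_dispersion + depth_mean)
    for gi, g in enumerate(groups):
        mu = np.clip(levels[:, gi], 1e-3, 1 - 1e-3)
        for r in range(n_replicates):
            depth = rng.negative_binomial(depth_dispersion, p_nb, size=n)
            rep = rng.beta(mu * replicate_concentration,
                           (1 - mu) * replicate_concentration)
            meth_cols.append(rng.binomial(depth, rep))
            total_cols.append(depth)
            samples.append(f"{g}_{r + 1}")
    sites = pd.DataFrame({"chrom": "chr1", "pos": positions, "strand": "+"})
    return CpGCountMatrix(sites, np.column_stack(meth_cols),
                          np.column_stack(total_cols), samples,
                          {s: s.rsplit("_", 1)[0] for s in samples},
                          list(groups))


def simulate_dmc_benchmark(n_sites: int = 10_000, planted_fraction: float = 0.05,
                           delta: float = 0.3, depth_mean: float = 30.0,
                           n_replicates: int = 3, seed: int = 0,
                           depth_dispersion: float = 8.0,
                           replicate_concentration: float = 100.0,
                           ):
    """Two-group beta-binomial count matrix with planted level shifts.

    Returns (matrix, truth_mask): a boolean mask over the matrix sites
    marking which truly differ between groups A and B by ``delta``.
    Baseline levels are the same bimodal mixture the full generator
    uses; the shift direction keeps levels inside [0.01, 0.99].
    """
    rng = np.random.default_rng(seed)
    low = rng.random(n_sites) < 0.5
    mu = np.where(low, 0.05, 0.85)
    base = np.clip(rng.beta(mu * 30, (1 - mu) * 30), 0.01, 0.99)
    levels = np.column_stack([base, base])
    truth = np.zeros(n_sites, dtype=bool)
    pick = rng.choice(n_sites, size=int(round(planted_fraction * n_sites)),
                      replace=False)
    sgn = np.where(base[pick] < 0.5, 1.0, -1.0)
    levels[pick, 1] = np.clip(base[pick] + sgn * delta, 0.01, 0.99)
    truth[pick] = True
    positions = np.arange(n_sites) * 1000
    matrix = _beta_binomial_matrix(levels, ("A", "B"), n_replicates,
                                   depth_mean, depth_dispersion,
                                   replicate_concentration, rng, positions)
    return matrix, truth


def simulate_dmr_benchmark(n_blocks: int = 5, block_cpgs: int = 10,
                           delta: float = 0.5, depth_mean: float = 100.0,
                           n_replicates: int = 3, seed: int = 0,
                           intra_gap: int = 50, inter_gap: int = 5000,
                           null: bool = False,
                           flank_cpgs: int = 20,
                           replicate_concentration: float = 150.0,
                           ):
    """Blocks of consecutive CpGs with (optionally) shifted group B.

    CpGs within a block sit ``intra_gap`` apart; blocks (and their
    unshifted flanking CpGs) are separated by ``inter_gap`` so the DMR
    caller's default chaining can never merge two blocks.  With
    ``null=True`` no shift is planted, giving a matched null
    simulation.  Returns (matrix, truth_regions DataFrame).
    """
    rng = np.random.default_rng(seed)
    pos_list: list[int] = []
    block_rows = []
    block_of: list[int] = []
    cursor = 1000
    for b in range(n_blocks):
        for k in range(flank_cpgs // 2):
            pos_list.append(cursor)
            block_of.append(-1)
            cursor += intra_gap
        start = cursor
        for k in range(block_cpgs):
            pos_list.append(cursor)
            block_of.append(b)
            cursor += intra_gap
        block_rows.append({"block": b, "chrom": "chr1", "start": start,
                           "end": pos_list[-1] + 2, "n_cpg": block_cpgs})
        for k in range(flank_cpgs // 2):
            pos_list.append(cursor)
            block_of.append(-1)
            cursor += intra_gap
        cursor += inter_gap
    positions = np.asarray(pos_list)
    n = len(positions)
    block_arr = np.asarray(block_of)
    base = np.clip(rng.beta(0.15 * 40, 0.85 * 40, size=n), 0.01, 0.99)
    levels = np.column_stack([base, base])
    if not null:
        shifted = block_arr >= 0
        levels[shifted, 1] = np.clip(base[shifted] + delta, 0.01, 0.99)
    matrix = _beta_binomial_matrix(levels, ("A", "B"), n_replicates,
                                   depth_mean, 8.0,
                                   replicate_concentration, rng, positions)
    return matrix, pd.DataFrame(block_rows)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{iv.chrom}\tmethdyn_sim\tgene\t{iv.start + 1}\t{iv.end}"
                     f"\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{iv.chrom}\tmethdyn_sim\texon\t{s + 1}\t{e}"
                         f"\t.\t{g.strand}\t.\t{attrs}\n")


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate genome + counts and write every file the pipeline reads.

    Emits genome.fa, genes.gtf, genes.tsv, cgis.bed, one CGmap per
    sample, and the truth tables.  Byte-identical under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    counts = simulate_counts(config, genome)
    paths: dict[str, Path] = {}
    paths["fasta"] = out / "genome.fa"
    write_fasta(genome.sequences, paths["fasta"])
    paths["gtf"] = out / "genes.gtf"
    write_gtf(genome.genes, paths["gtf"])
    paths["genes_tsv"] = out / "genes.tsv"
    write_gene_tsv(genome.genes, paths["genes_tsv"])
    paths["cgi_bed"] = out / "cgis.bed"
    write_bed([c.interval for c in genome.cgis], paths["cgi_bed"],
              names=[c.genic_class or "." for c in genome.cgis])
    for name, recs in counts.sample_sites.items():
        p = out / f"{name}.cgmap"
        write_cgmap(recs, p)
        paths[f"cgmap_{name}"] = p
    truth_sites = counts.sites.copy()
    paths["truth_sites"] = out / "truth_sites.tsv"
    write_report(truth_sites, paths["truth_sites"])
    paths["truth_regions"] = out / "truth_regions.tsv"
    write_report(counts.regions, paths["truth_regions"])
    gene_truth = pd.DataFrame(
        {"gene_id": list(genome.promoter_class),
         "promoter_class": list(genome.promoter_class.values())})
    paths["truth_genes"] = out / "truth_genes.tsv"
    write_report(gene_truth, paths["truth_genes"])
    return paths
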
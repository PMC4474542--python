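"""Synthetic genomes, methylomes and expression with regulatory structure.

The generator emulates the statistical signatures that distinguish regulatory
regions in real whole-genome bisulfite data, so the whole pipeline is
testable without any download:

* regulatory regions are hypomethylated with a Gaussian-shaped dip whose
  half-width (default 750 bp) makes the hypomethylation extend far beyond
  the region itself before returning to the background plateau;
* neighbouring mCpG levels are spatially correlated — an autoregressive
  latent field whose correlation length is hundreds of bp inside regulatory
  regions and tens of bp elsewhere;
* CpG density is elevated inside regulatory regions;
* regions switch activity across cell lines; where a region is inactive in a
  cell line (but regulatory elsewhere) its CpGs are *hyper*methylated
  relative to background, which inflates the across-cell-line variance of
  regulatory sites;
* GC-rich 8-mer motifs are planted around a fraction of regulatory CpGs;
* target-gene expression is repressively coupled to regional methylation.

Observed counts are binomial draws at a shifted-Poisson read depth
(minimum 5), so the coverage filter of the readers is exercised.

Two presets encode the two study scenarios: ``promoter_preset`` (background
mean 0.72, regulatory mean 0.34, strong contrasts) and ``enhancer_preset``
(0.84 vs 0.69, weaker and more heterogeneous contrasts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ExpressionTable,
    GeneModel,
    Genome,
    Methylome,
    Region,
    RegionSet,
    ValidationError,
)
from . import io as mio

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (np.uint8(b) for b in b"ACGT")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator (seed-deterministic)."""

    # layout
    n_chromosomes: int = 4
    n_genes: int = 150
    n_regions: int = 100
    region_class: str = "promoter"
    n_exons: int = 4
    exon_length: int = 1000
    intron_min: int = 2000
    intron_max: int = 6000
    upstream_length: int = 10_000
    intergenic_gap: int = 4000
    region_length_min: int = 400
    region_length_max: int = 800

    # methylation field
    background_meth_mean: float = 0.72
    regulatory_meth_mean: float = 0.34
    dip_halfwidth: float = 750.0
    dip_depth_jitter: float = 0.1  # relative U(1-j, 1+j) element strength
    neighbor_corr_length_fg: float = 120.0
    neighbor_corr_length_bg: float = 15.0
    meth_noise_sd: float = 0.12

    # CpG placement and motifs
    cpg_density_fg: float = 0.05
    cpg_density_bg: float = 0.01
    planted_motifs: tuple[str, ...] = ("GGGCGGGG", "TTGCGCAA")
    planting_rate: float = 0.25

    # cell lines
    n_cell_lines: int = 15
    activity_switch_prob: float = 0.4
    inactive_hypermeth_delta: float = 0.08
    read_depth_mean: float = 30.0

    # expression coupling
    expression_intercept: float = 20.0
    expression_slope: float = 15.0
    expression_noise_sd: float = 2.0
    expression_background_mean: float = 8.0
    expression_background_sd: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.cpg_density_fg > 0.5 or self.cpg_density_bg > 0.5:
            raise ValidationError("CpG density above 0.5 is infeasible (CG occupies 2 bp)")
        if self.n_regions > 0 and self.n_genes < self.n_regions:
            raise ValidationError("need at least one host gene per regulatory region")
        for p in (self.activity_switch_prob, self.planting_rate):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        for m in self.planted_motifs:
            if len(m) != 8 or m[3:5] != "CG" or any(b not in "ACGT" for b in m):
                raise ValidationError(f"planted motif {m!r} is not a centered-CpG 8-mer")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


def promoter_preset(**overrides) -> GeneratorConfig:
    """Promoter-like scenario: deep hypomethylation, high CpG density."""
    return GeneratorConfig(region_class="promoter", **overrides)


def enhancer_preset(**overrides) -> GeneratorConfig:
    """Enhancer-like scenario: shallow, heterogeneous hypomethylation,
    moderate density and correlation-length contrasts."""
    base = dict(
        region_class="enhancer",
        background_meth_mean=0.84,
        regulatory_meth_mean=0.69,
        dip_depth_jitter=0.8,
        neighbor_corr_length_fg=80.0,
        cpg_density_fg=0.02,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    genome: Genome
    genes: list[GeneModel]
    regions: RegionSet  # the positive (truth) regions
    activity: np.ndarray  # (n_regions, n_cell_lines) bool
    methylomes: list[Methylome] = field(default_factory=list)
    expression: ExpressionTable | None = None

    @property
    def cell_lines(self) -> list[str]:
        return [m.cell_line for m in self.methylomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.genome.length(c) for c in self.genome.chroms}


# ---------------------------------------------------------------- genome ---


def _layout_genes(config: GeneratorConfig, rng: np.random.Generator):
    """Tile genes (with upstream windows) along chromosomes."""
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    g = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = 0
        for _ in range(per_chrom):
            if g >= config.n_genes:
                break
            cursor += config.intergenic_gap
            strand = "+" if rng.random() < 0.5 else "-"
            introns = rng.integers(config.intron_min, config.intron_max + 1, config.n_exons - 1)
            body = config.n_exons * config.exon_length + int(introns.sum())
            if strand == "+":
                tx_start = cursor + config.upstream_length
            else:
                tx_start = cursor
            tx_end = tx_start + body
            exons = []
            p = tx_start
            for i in range(config.n_exons):
                exons.append((p, p + config.exon_length))
                p += config.exon_length
                if i < config.n_exons - 1:
                    p += int(introns[i])
            genes.append(GeneModel(f"gene{g:05d}", chrom, strand, tx_start, tx_end, tuple(exons)))
            cursor = tx_end if strand == "+" else tx_end + config.upstream_length
            g += 1
        chrom_lengths[chrom] = cursor + config.intergenic_gap
    return genes, chrom_lengths


def _place_regions(config: GeneratorConfig, genes, rng: np.random.Generator) -> RegionSet:
    host_idx = rng.permutation(len(genes))[: config.n_regions]
    regions = []
    for i, gi in enumerate(host_idx):
        gene = genes[int(gi)]
        length = int(rng.integers(config.region_length_min, config.region_length_max + 1))
        if config.region_class == "promoter":
            lo = length // 2 + 50
            hi = config.upstream_length - length // 2 - 50
            dist = int(rng.integers(lo, hi + 1))
            mid = gene.tss - dist if gene.strand == "+" else gene.tss + dist
        else:
            introns = gene.introns
            s, e = introns[int(rng.integers(len(introns)))]
            d = int(rng.integers(1, (e - s) // 2 + 1))
            mid = (s + d) if rng.random() < 0.5 else (e - d)
        start = mid - length // 2
        regions.append(
            Region(
                gene.chrom,
                start,
                start + length,
                label="positive",
                region_class=config.region_class,
                source_id=f"{config.region_class}_{i:04d}",
                target_gene=gene.gene_id,
            )
        )
    return RegionSet(regions)


def _sample_cpg_positions(seg_starts, seg_ends, density, rng) -> np.ndarray:
    """Sample ~density * total_length CpG start positions inside segments,
    spaced >= 2 bp apart (a CG occupies two bases)."""
    lengths = np.maximum(seg_ends - seg_starts - 1, 0)
    total = int(lengths.sum())
    n = int(round(density * total))
    if total <= 0 or n == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.sort(rng.integers(0, total, size=n))
    offsets = np.unique(offsets)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    seg_of = np.searchsorted(cum, offsets, side="right") - 1
    pos = seg_starts[seg_of] + (offsets - cum[seg_of])
    pos = np.sort(pos)
    if len(pos) > 1:
        keep = np.concatenate([[True], np.diff(pos) >= 2])
        pos = pos[keep]
    return pos


def generate_genome(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Sequence + annotation + truth regions + per-cell-line activity states.

    Returns ``(genome, genes, regions, activity)``. The sequence is built by
    erasing all naturally occurring CG dinucleotides from an i.i.d. random
    sequence and then planting CGs at the configured foreground/background
    densities (so CpG density is controlled exactly), followed by motif
    planting around isolated regulatory CpGs.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes, chrom_lengths = _layout_genes(config, rng)
    regions = _place_regions(config, genes, rng)

    seqs: dict[str, str] = {}
    for chrom, length in chrom_lengths.items():
        seq = _BASES[rng.integers(0, 4, size=length)].copy()
        # erase natural CGs: C,G -> C,T (cannot create a new CG)
        cg = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))
        seq[cg + 1] = _T

        fg = sorted(
            (r.start, r.end) for r in regions if r.chrom == chrom
        )
        fg_starts = np.array([max(0, s) for s, _ in fg], dtype=np.int64)
        fg_ends = np.array([min(length, e) for _, e in fg], dtype=np.int64)

        # complement segments of the foreground intervals
        bg_starts, bg_ends, prev = [], [], 0
        for s, e in zip(fg_starts, fg_ends):
            if s > prev:
                bg_starts.append(prev)
                bg_ends.append(s)
            prev = max(prev, e)
        if prev < length:
            bg_starts.append(prev)
            bg_ends.append(length)

        fg_pos = _sample_cpg_positions(fg_starts, fg_ends, config.cpg_density_fg, rng)
        bg_pos = _sample_cpg_positions(
            np.array(bg_starts, dtype=np.int64), np.array(bg_ends, dtype=np.int64),
            config.cpg_density_bg, rng,
        )
        for pos in (fg_pos, bg_pos):
            seq[pos] = _C
            seq[pos + 1] = _G

        # plant motifs around isolated regulatory CpGs
        if config.planting_rate > 0 and len(fg_pos):
            for s, e in zip(fg_starts, fg_ends):
                rpos = fg_pos[(fg_pos >= s) & (fg_pos < e)]
                if len(rpos) == 0:
                    continue
                gaps_ok = np.ones(len(rpos), dtype=bool)
                if len(rpos) > 1:
                    d = np.diff(rpos)
                    gaps_ok[:-1] &= d > 7
                    gaps_ok[1:] &= d > 7
                eligible = rpos[gaps_ok & (rpos >= 4) & (rpos + 6 <= length)]
                # Bernoulli per CpG, so small rates are not rounded away
                n_plant = min(int(rng.binomial(len(rpos), config.planting_rate)), len(eligible))
                if n_plant == 0:
                    continue
                chosen = rng.choice(eligible, size=n_plant, replace=False)
                for p in chosen:
                    motif = config.planted_motifs[int(rng.integers(len(config.planted_motifs)))]
                    if rng.random() < 0.5:
                        motif = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                    word = np.frombuffer(motif.encode(), dtype=np.uint8)
                    seq[p - 3 : p + 5] = word
                    # junction repair: do not let the overwrite create a CG
                    if seq[p - 4] == _C and word[0] == _G:
                        seq[p - 4] = _A
                    if word[-1] == _C and p + 5 < length and seq[p + 5] == _G:
                        seq[p + 5] = _A

        seqs[chrom] = seq.tobytes().decode("ascii")

    genome = Genome.from_dict(seqs)
    activity = np.ones((len(regions), config.n_cell_lines), dtype=bool)
    if config.n_cell_lines > 1:
        activity[:, 1:] = rng.random((len(regions), config.n_cell_lines - 1)) >= config.activity_switch_prob
    return genome, genes, regions, activity


# ------------------------------------------------------------ methylomes ---


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G)).astype(np.int64)


def _ar_noise(pos: np.ndarray, corr_len: np.ndarray, sd: float, rng) -> np.ndarray:
    """Stationary AR(1)-on-distance field: corr(x_i, x_{i-1}) = exp(-d/L_i)."""
    n = len(pos)
    z = rng.standard_normal(n)
    x = np.empty(n)
    if n == 0:
        return x
    x[0] = sd * z[0]
    d = np.diff(pos).astype(float)
    phi = np.exp(-d / corr_len[1:])
    innov = sd * np.sqrt(1.0 - phi**2)
    for i in range(1, n):
        x[i] = phi[i - 1] * x[i - 1] + innov[i - 1] * z[i]
    return x


def generate_methylomes(
    config: GeneratorConfig,
    genome: Genome,
    regions: RegionSet,
    activity: np.ndarray,
    rng: np.random.Generator,
) -> list[Methylome]:
    """Per-cell-line methylomes over every CpG of the genome.

    latent level = background mean
                   - dip (Gaussian around each region active in this line)
                   + hypermethylation delta inside inactive regions
                   + spatially correlated noise, clipped to [0, 1];
    observed counts ~ Binomial(read depth, latent), depth ~ 5 + Poisson.
    """
    chroms = sorted(genome.chroms)
    pos_by_chrom = {c: _cpg_positions(genome.fetch(c, 0, genome.length(c))) for c in chroms}
    region_list = list(regions)
    # per-region dip amplitude: element strength varies between regions but
    # is a fixed property of the element, shared across cell lines
    amp0 = config.background_meth_mean - config.regulatory_meth_mean
    j = config.dip_depth_jitter
    amps = amp0 * rng.uniform(1.0 - j, 1.0 + j, size=len(region_list))

    # correlation length per site: long-range inside regulatory regions
    corr_len: dict[str, np.ndarray] = {}
    in_region: dict[str, np.ndarray] = {}
    for c in chroms:
        pos = pos_by_chrom[c]
        inside = np.zeros(len(pos), dtype=bool)
        for r in region_list:
            if r.chrom == c:
                lo, hi = np.searchsorted(pos, (r.start, r.end))
                inside[lo:hi] = True
        in_region[c] = inside
        corr_len[c] = np.where(
            inside, config.neighbor_corr_length_fg, config.neighbor_corr_length_bg
        )

    methylomes: list[Methylome] = []
    hw2 = 2.0 * config.dip_halfwidth**2
    reach = int(3 * config.dip_halfwidth)
    for ci in range(config.n_cell_lines):
        name = f"cell{ci:02d}"
        chrom_data = {}
        for c in chroms:
            pos = pos_by_chrom[c]
            latent = np.full(len(pos), config.background_meth_mean)
            for ri, r in enumerate(region_list):
                if r.chrom != c:
                    continue
                if activity[ri, ci]:
                    center = r.midpoint
                    lo, hi = np.searchsorted(pos, (center - reach, center + reach))
                    d = pos[lo:hi] - center
                    latent[lo:hi] -= amps[ri] * np.exp(-(d.astype(float) ** 2) / hw2)
                else:
                    lo, hi = np.searchsorted(pos, (r.start, r.end))
                    latent[lo:hi] += config.inactive_hypermeth_delta
            latent += _ar_noise(pos, corr_len[c], config.meth_noise_sd, rng)
            np.clip(latent, 0.0, 1.0, out=latent)
            depth = 5 + rng.poisson(max(config.read_depth_mean - 5.0, 0.0), size=len(pos))
            meth = rng.binomial(depth, latent)
            chrom_data[c] = (pos, meth, depth)
        methylomes.append(Methylome(name, chrom_data))
    return methylomes


# ------------------------------------------------------------ expression ---


def generate_expression(
    config: GeneratorConfig,
    regions: RegionSet,
    genes: list[GeneModel],
    methylomes: list[Methylome],
    rng: np.random.Generator,
) -> ExpressionTable:
    """RPKM table with repressive methylation coupling for target genes.

    Genes targeted by a regulatory region follow
    ``max(0, a - b * regional mean methylation + noise)`` per cell line;
    all other genes are uncoupled background noise.
    """
    import pandas as pd

    cells = [m.cell_line for m in methylomes]
    values = {}
    coupled: dict[str, Region] = {r.target_gene: r for r in regions if r.target_gene}
    for gene in genes:
        row = np.empty(len(cells))
        r = coupled.get(gene.gene_id)
        for ci, m in enumerate(methylomes):
            if r is not None:
                _, lev = m.sites_in(r.chrom, r.start, r.end)
                mm = float(np.mean(lev)) if len(lev) else config.background_meth_mean
                row[ci] = max(
                    0.0,
                    config.expression_intercept
                    - config.expression_slope * mm
                    + rng.normal(0.0, config.expression_noise_sd),
                )
            else:
                row[ci] = max(
                    0.0,
                    rng.normal(config.expression_background_mean, config.expression_background_sd),
                )
        values[gene.gene_id] = row
    frame = pd.DataFrame.from_dict(values, orient="index", columns=cells)
    return ExpressionTable(frame)


# --------------------------------------------------------------- drivers ---


def simulate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Run the full generator; output is fully determined by the config."""
    rng = np.random.default_rng(config.seed)
    genome, genes, regions, activity = generate_genome(config, rng)
    methylomes = generate_methylomes(config, genome, regions, activity, rng)
    expression = generate_expression(config, regions, genes, methylomes, rng)
    return SyntheticDataset(config, genome, genes, regions, activity, methylomes, expression)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Emit the dataset as plain-text files readable by :mod:`methylreg.io`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ds.genome.to_fasta(outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    mio.write_gene_annotation(ds.genes, outdir / "genes.tsv")
    paths["annotation"] = str(outdir / "genes.tsv")
    mio.write_regions(ds.regions, outdir / "regions.bed")
    paths["regions"] = str(outdir / "regions.bed")
    for m in ds.methylomes:
        p = outdir / f"methylome_{m.cell_line}.tsv"
        mio.write_methylome(m, p)
        paths[f"methylome:{m.cell_line}"] = str(p)
    if ds.expression is not None:
        mio.write_expression(ds.expression, outdir / "expression.tsv")
        paths["expression"] = str(outdir / "expression.tsv")
    np.savetxt(outdir / "activity.tsv", ds.activity.astype(int), fmt="%d", delimiter="\t")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(ds.config), fh, indent=2, default=list)
    paths["config"] = str(outdir / "config.json")
    return paths
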
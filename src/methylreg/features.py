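"""Per-region methylation features and the global autocorrelation analysis.

Five features summarise each region for classification:

1. **mean methylation** — unweighted mean level of the region's mCpGs in the
   reference cell line (regulatory regions are hypomethylated);
2. **methylation variance** — mean over sites of the population variance of
   the site's level across cell lines (active/inactive switching inflates it);
3. **methylation autocorrelation** — mean standardised cross-product of level
   deviations over within-region mCpG pairs (neighbouring regulatory mCpGs
   are correlated over hundreds of bp, background mCpGs over tens);
4. **CpG density** — count of CG dinucleotides per bp of region;
5. **motif score** — mean −log10 enrichment p-value of the centered-CpG
   8-mers around the region's mCpGs (see :mod:`methylreg.motifs`).

The pooled autocorrelation profile r(k) over a region set is

    r_k = sum_{pairs at distance k} (x_i - xbar)(x_j - xbar)
          / sum_{all sites} (x_i - xbar)^2

with xbar the grand mean level over all mCpGs of all supplied regions. Pair
distances are binned (default 10 bp); the lag-0 bin holds the self-pairs, so
r(0) == 1 identically. The *extent* of autocorrelation is the smallest
positive lag at which r drops to a threshold (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    DegenerateProfileError,
    ExpressionTable,
    FeatureVector,
    Genome,
    Methylome,
    NoSitesError,
    Region,
    RegionSet,
    UndefinedCorrelationError,
    ValidationError,
)

log = logging.getLogger(__name__)

DEFAULT_MAX_LAG = 2000
DEFAULT_BIN_WIDTH = 10
DEFAULT_MIN_PAIRS = 30
AUTOCORR_THRESHOLD = 0.05


def mean_methylation(region: Region, methylome: Methylome) -> float:
    """Unweighted mean methylation level of the region's mCpGs."""
    _, levels = methylome.sites_in(region.chrom, region.start, region.end)
    if len(levels) == 0:
        raise NoSitesError(f"{region.chrom}:{region.start}-{region.end}: no covered mCpGs")
    return float(np.mean(levels))


def cpg_density(region: Region, genome: Genome) -> float:
    """CG dinucleotides per bp of region (CG cannot overlap itself)."""
    seq = genome.fetch(region.chrom, region.start, region.end)
    return seq.count("CG") / region.length


def cg_content(region: Region, genome: Genome) -> float:
    """Fraction of C and G bases in the region."""
    seq = genome.fetch(region.chrom, region.start, region.end)
    return (seq.count("C") + seq.count("G")) / region.length


def methylation_variance(region: Region, methylomes: list[Methylome]) -> float:
    """Mean across-cell-line variance of the region's mCpG levels.

    Per site, the population variance (divisor n) of its level over the cell
    lines where it passes coverage; sites observed in fewer than two cell
    lines are excluded, not zero-filled. The region value is the mean over
    the remaining sites.
    """
    if len(methylomes) < 2:
        raise ValidationError("methylation_variance needs >= 2 methylomes")
    per_pos: dict[int, list[float]] = {}
    for m in methylomes:
        pos, lev = m.sites_in(region.chrom, region.start, region.end)
        for p, x in zip(pos, lev):
            per_pos.setdefault(int(p), []).append(float(x))
    variances = [np.var(xs) for xs in per_pos.values() if len(xs) >= 2]
    if not variances:
        raise NoSitesError(
            f"{region.chrom}:{region.start}-{region.end}: no site observed in >=2 cell lines"
        )
    return float(np.mean(variances))


@dataclass(slots=True)
class AutocorrelationProfile:
    """Binned methylation autocorrelation r(k) over a set of regions.

    ``lags`` are bin labels in bp (0 for the self-pair bin, then the right
    edge of each (k-1)w < d <= kw bin); bins with fewer than ``min_pairs``
    pairs are suppressed.
    """

    lags: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray
    grand_mean: float
    max_lag: int
    bin_width: int

    def __len__(self) -> int:
        return len(self.lags)


def _collect_region_sites(regions: RegionSet, methylome: Methylome):
    per_region = []
    for reg in regions:
        pos, lev = methylome.sites_in(reg.chrom, reg.start, reg.end)
        if len(pos):
            per_region.append((pos, lev))
    return per_region


def autocorrelation_profile(
    regions: RegionSet,
    methylome: Methylome,
    max_lag: int = DEFAULT_MAX_LAG,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> AutocorrelationProfile:
    """Pooled autocorrelation of methylation levels by genomic distance.

    Pairs are formed within regions only; the denominator pools the squared
    deviations of every site in every supplied region around the grand mean.
    Raises :class:`DegenerateProfileError` when all levels are equal.
    """
    if len(regions) == 0:
        raise ValidationError("autocorrelation_profile: empty region set")
    per_region = _collect_region_sites(regions, methylome)
    if not per_region:
        raise NoSitesError("no mCpGs in any supplied region")

    all_levels = np.concatenate([lev for _, lev in per_region])
    grand_mean = float(np.mean(all_levels))

    n_bins = 1 + (max_lag + bin_width - 1) // bin_width
    num = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=np.int64)

    # the denominator accumulates the identical per-region partial sums as
    # the lag-0 (self-pair) bin, so r(0) == 1 exactly, not merely to rounding
    denom = 0.0
    for pos, lev in per_region:
        dev = lev - grand_mean
        n = len(pos)
        ss = float(np.sum(dev * dev))
        num[0] += ss
        denom += ss
        cnt[0] += n
        for i in range(n):
            hi = int(np.searchsorted(pos, pos[i] + max_lag, side="right"))
            if hi <= i + 1:
                continue
            d = pos[i + 1 : hi] - pos[i]
            bins = 1 + (d - 1) // bin_width
            np.add.at(num, bins, dev[i] * dev[i + 1 : hi])
            np.add.at(cnt, bins, 1)

    if denom == 0.0:
        raise DegenerateProfileError("all methylation levels equal; r undefined")

    keep = cnt >= min_pairs
    lags = np.concatenate([[0], np.arange(1, n_bins) * bin_width])[keep]
    return AutocorrelationProfile(
        lags=lags,
        r=num[keep] / denom,
        n_pairs=cnt[keep],
        grand_mean=grand_mean,
        max_lag=max_lag,
        bin_width=bin_width,
    )


def autocorrelation_extent(
    profile: AutocorrelationProfile, threshold: float = AUTOCORR_THRESHOLD
) -> tuple[int, bool]:
    """Distance at which autocorrelation first reaches the threshold.

    Returns ``(lag_bp, censored)``; when r never drops to the threshold
    within the profiled range the extent is the profile's ``max_lag`` with
    ``censored=True``.
    """
    if len(profile) == 0:
        raise ValidationError("empty autocorrelation profile")
    for lag, r in zip(profile.lags, profile.r):
        if lag > 0 and r <= threshold:
            return int(lag), False
    return int(profile.max_lag), True


def pooled_site_stats(regions: RegionSet, methylome: Methylome) -> tuple[float, float]:
    """Grand mean and population variance of levels over all regions' sites.

    Computed once over the *entire* region set being featurised — positives
    and backgrounds together — so the per-region autocorrelation feature
    carries no label information through its standardisation.
    """
    per_region = _collect_region_sites(regions, methylome)
    if not per_region:
        raise NoSitesError("no mCpGs in any supplied region")
    all_levels = np.concatenate([lev for _, lev in per_region])
    return float(np.mean(all_levels)), float(np.var(all_levels))


def region_autocorrelation_feature(
    region: Region,
    methylome: Methylome,
    grand_mean: float,
    grand_var: float,
    max_lag: int = DEFAULT_MAX_LAG,
) -> tuple[float, bool]:
    """Per-region summary of the pairwise methylation autocorrelation.

    Mean over within-region mCpG pairs (distance <= max_lag) of
    ``(x_i - xbar)(x_j - xbar) / s^2`` with pooled ``xbar`` and ``s^2`` from
    :func:`pooled_site_stats`. Regions without a qualifying pair are imputed
    to 0 with a flag.
    """
    if grand_var <= 0:
        raise DegenerateProfileError("pooled variance is zero")
    pos, lev = methylome.sites_in(region.chrom, region.start, region.end)
    n = len(pos)
    if n < 2:
        return 0.0, True
    dev = lev - grand_mean
    total = 0.0
    count = 0
    for i in range(n):
        hi = int(np.searchsorted(pos, pos[i] + max_lag, side="right"))
        if hi <= i + 1:
            continue
        total += float(np.sum(dev[i] * dev[i + 1 : hi]))
        count += hi - (i + 1)
    if count == 0:
        return 0.0, True
    return total / (count * grand_var), False


def expression_correlation(
    region: Region,
    methylomes: list[Methylome],
    expr: ExpressionTable,
    method: str = "pearson",
) -> float:
    """Correlation between region methylation and target-gene expression
    across cell lines (the negative-coupling QC of regulatory calls).

    Pairs one value per cell line: the region's mean mCpG level in that cell
    line against the target gene's RPKM. Requires >= 3 complete pairs;
    constant methylation or expression raises
    :class:`UndefinedCorrelationError`.
    """
    if region.target_gene is None:
        raise ValidationError("region has no target gene assigned")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    xs, ys = [], []
    for m in methylomes:
        _, lev = m.sites_in(region.chrom, region.start, region.end)
        if len(lev) == 0:
            continue
        y = expr.value(region.target_gene, m.cell_line)
        if np.isnan(y):
            continue
        xs.append(float(np.mean(lev)))
        ys.append(y)
    if len(xs) < 3:
        raise ValidationError(
            f"{region.target_gene}: need >=3 cell lines with methylation and expression, got {len(xs)}"
        )
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError("constant methylation or expression across cell lines")
    if method == "pearson":
        return float(stats.pearsonr(xs, ys).statistic)
    return float(stats.spearmanr(xs, ys).statistic)


def build_feature_vector(
    region: Region,
    methylomes: list[Methylome],
    genome: Genome,
    motif_scorer,
    grand_mean: float,
    grand_var: float,
    max_lag: int = DEFAULT_MAX_LAG,
) -> FeatureVector:
    """Assemble the five features for one region.

    ``motif_scorer(region) -> (score, imputed)`` is supplied by
    :mod:`methylreg.motifs` so the motif table can be rebuilt per training
    fold. Raises :class:`NoSitesError` (region dropped) when the region has
    no covered mCpG in the reference (first) methylome.
    """
    reference = methylomes[0]
    mm = mean_methylation(region, reference)  # raises NoSitesError -> drop
    try:
        var = methylation_variance(region, methylomes)
        var_imputed = False
    except NoSitesError:
        var, var_imputed = 0.0, True
    ac, ac_imputed = region_autocorrelation_feature(region, reference, grand_mean, grand_var, max_lag)
    dens = cpg_density(region, genome)
    score, motif_imputed = motif_scorer(region)
    return FeatureVector(
        region,
        mean_meth=mm,
        meth_variance=var,
        autocorr=ac,
        cpg_density=dens,
        motif_score=score,
        autocorr_imputed=ac_imputed,
        variance_imputed=var_imputed,
        motif_imputed=motif_imputed,
    )


def extract_features(
    regions: RegionSet,
    methylomes: list[Methylome],
    genome: Genome,
    motif_scorer,
    max_lag: int = DEFAULT_MAX_LAG,
) -> tuple[list[FeatureVector], int]:
    """Featurise a region set; returns (vectors, n_dropped).

    Pooled standardisation statistics for the autocorrelation feature are
    computed over the whole set first (never per label stratum).
    """
    reference = methylomes[0]
    grand_mean, grand_var = pooled_site_stats(regions, reference)
    vectors: list[FeatureVector] = []
    dropped = 0
    for region in regions:
        try:
            vectors.append(
                build_feature_vector(
                    region, methylomes, genome, motif_scorer, grand_mean, grand_var, max_lag
                )
            )
        except NoSitesError:
            dropped += 1
    if dropped:
        log.info("extract_features: dropped %d/%d regions without mCpGs", dropped, len(regions))
    return vectors, dropped
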
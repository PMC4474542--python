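"""Feature extraction: means, densities, variance, autocorrelation, expression QC."""

import numpy as np
import pytest

from methylreg.core import (
    DegenerateProfileError,
    ExpressionTable,
    Genome,
    Methylome,
    NoSitesError,
    Region,
    RegionSet,
    UndefinedCorrelationError,
)
from methylreg.features import (
    autocorrelation_extent,
    autocorrelation_profile,
    cg_content,
    cpg_density,
    expression_correlation,
    mean_methylation,
    methylation_variance,
    pooled_site_stats,
    region_autocorrelation_feature,
)


def _methylome(positions, levels, chrom="chr1", depth=10, name="m"):
    levels = np.asarray(levels, dtype=float)
    meth = np.round(levels * depth).astype(int)
    return Methylome(name, {chrom: (np.asarray(positions), meth, np.full(len(levels), depth))})


def _region(start, end, chrom="chr1"):
    return Region(chrom, start, end)


class TestMeanMethylation:
    def test_arithmetic_mean(self):
        m = _methylome([10, 20], [0.2, 0.4])
        assert mean_methylation(_region(0, 100), m) == pytest.approx(0.3)

    def test_single_site(self):
        m = _methylome([10], [0.9])
        assert mean_methylation(_region(0, 100), m) == pytest.approx(0.9)

    def test_no_sites_raises(self):
        m = _methylome([500], [0.5])
        with pytest.raises(NoSitesError):
            mean_methylation(_region(0, 100), m)


class TestSequenceFeatures:
    @pytest.mark.parametrize(
        "seq,density,content",
        [("ACGT", 0.25, 0.5), ("AAAA", 0.0, 0.0), ("CGCGCG", 0.5, 1.0), ("GGGG", 0.0, 1.0)],
    )
    def test_density_and_content(self, seq, density, content):
        genome = Genome.from_dict({"chr1": seq})
        region = _region(0, len(seq))
        assert cpg_density(region, genome) == pytest.approx(density)
        assert cg_content(region, genome) == pytest.approx(content)

    def test_region_beyond_chromosome_is_error(self):
        genome = Genome.from_dict({"chr1": "ACGT"})
        with pytest.raises(Exception):
            cpg_density(_region(0, 10), genome)


class TestMethylationVariance:
    def test_constant_site_has_zero_variance(self):
        ms = [_methylome([10], [0.5], name=f"c{i}") for i in range(3)]
        assert methylation_variance(_region(0, 100), ms) == 0.0

    def test_population_variance_two_cell_lines(self):
        ms = [_methylome([10], [0.0], name="a"), _methylome([10], [1.0], name="b")]
        assert methylation_variance(_region(0, 100), ms) == pytest.approx(0.25)

    def test_bounded_by_quarter(self, promoter_ds):
        vals = [
            methylation_variance(r, promoter_ds.methylomes) for r in promoter_ds.regions
        ]
        assert max(vals) <= 0.25

    def test_sites_in_single_cell_line_excluded(self):
        ms = [_methylome([10], [0.0], name="a"), _methylome([20], [1.0], name="b")]
        with pytest.raises(NoSitesError):
            methylation_variance(_region(0, 100), ms)


def _naive_profile(per_region, max_lag, bin_width):
    """Independent double-loop oracle for the pooled autocorrelation."""
    all_levels = np.concatenate([lev for _, lev in per_region])
    xbar = all_levels.mean()
    denom = ((all_levels - xbar) ** 2).sum()
    num, cnt = {}, {}
    for pos, lev in per_region:
        for i in range(len(pos)):
            for j in range(i, len(pos)):
                d = pos[j] - pos[i]
                if d > max_lag:
                    continue
                b = 0 if d == 0 else bin_width * (1 + (d - 1) // bin_width)
                num[b] = num.get(b, 0.0) + (lev[i] - xbar) * (lev[j] - xbar)
                cnt[b] = cnt.get(b, 0) + 1
    return {b: num[b] / denom for b in num}, cnt


class TestAutocorrelationProfile:
    def test_matches_naive_pairwise_oracle(self, rng):
        regions, data = [], []
        cursor = 0
        for k in range(6):
            n = int(rng.integers(20, 60))
            pos = cursor + np.sort(rng.choice(2000, size=n, replace=False))
            lev = rng.uniform(0, 1, n)
            regions.append(_region(cursor, cursor + 2000))
            data.append((pos, lev))
            cursor += 3000
        pos_all = np.concatenate([p for p, _ in data])
        lev_all = np.concatenate([l for _, l in data])
        meth = Methylome(
            "m",
            {"chr1": (pos_all, np.round(lev_all * 1000).astype(int), np.full(len(pos_all), 1000))},
        )
        lev_q = np.round(lev_all * 1000) / 1000  # quantised by counts
        data_q = []
        i = 0
        for pos, lev in data:
            data_q.append((pos, lev_q[i : i + len(pos)]))
            i += len(pos)

        prof = autocorrelation_profile(
            RegionSet(regions), meth, max_lag=500, bin_width=10, min_pairs=1
        )
        oracle_r, oracle_n = _naive_profile(data_q, max_lag=500, bin_width=10)
        assert set(prof.lags) == set(oracle_r)
        for lag, r, n in zip(prof.lags, prof.r, prof.n_pairs):
            assert r == pytest.approx(oracle_r[lag], abs=1e-9)
            assert n == oracle_n[lag]

    def test_lag_zero_bin_is_exactly_one(self, rng):
        pos = np.arange(0, 1000, 7)
        lev = rng.uniform(0, 1, len(pos))
        m = Methylome("m", {"chr1": (pos, np.round(lev * 100).astype(int), np.full(len(pos), 100))})
        prof = autocorrelation_profile(RegionSet([_region(0, 1000)]), m, min_pairs=1)
        assert prof.lags[0] == 0
        assert prof.r[0] == pytest.approx(1.0, abs=1e-12)

    def test_alternating_levels_oscillate(self):
        pos = np.arange(0, 4000, 10)
        lev = np.where(np.arange(len(pos)) % 2 == 0, 0.1, 0.9)
        m = Methylome("m", {"chr1": (pos, (lev * 10).astype(int), np.full(len(pos), 10))})
        prof = autocorrelation_profile(RegionSet([_region(0, 4000)]), m, min_pairs=1)
        r = dict(zip(prof.lags, prof.r))
        assert r[10] <= -0.8
        assert r[20] >= 0.8

    def test_iid_levels_have_no_spurious_correlation(self, rng):
        pos = np.arange(0, 30_000, 3)
        lev = rng.uniform(0, 1, len(pos))
        m = Methylome(
            "m", {"chr1": (pos, np.round(lev * 1000).astype(int), np.full(len(pos), 1000))}
        )
        prof = autocorrelation_profile(RegionSet([_region(0, 30_000)]), m, max_lag=500)
        nonzero = prof.lags > 0
        assert np.all(np.abs(prof.r[nonzero]) <= 0.05)

    def test_constant_levels_are_degenerate(self):
        pos = np.arange(0, 100, 10)
        m = Methylome("m", {"chr1": (pos, np.full(len(pos), 5), np.full(len(pos), 10))})
        with pytest.raises(DegenerateProfileError):
            autocorrelation_profile(RegionSet([_region(0, 100)]), m, min_pairs=1)

    def test_shift_and_scale_invariance(self, rng):
        # r is invariant under affine maps of the levels; use transforms that
        # stay exactly representable as count ratios (denominator 4000)
        pos = np.sort(rng.choice(5000, 200, replace=False))
        lev = rng.integers(600, 1001, 200) / 2000  # multiples of 1/2000, in [0.3, 0.5]

        def prof_of(levels):
            m = Methylome(
                "m",
                {"chr1": (pos, np.round(levels * 4000).astype(int), np.full(200, 4000))},
            )
            return autocorrelation_profile(RegionSet([_region(0, 5000)]), m, min_pairs=1)

        base = prof_of(lev)
        shifted = prof_of(lev + 0.2)  # stays inside [0,1]: no clipping
        scaled = prof_of(0.25 + 0.5 * lev)  # deviations scaled by c > 0
        assert np.allclose(base.r, shifted.r, atol=1e-9)
        assert np.allclose(base.r, scaled.r, atol=1e-9)


class TestAutocorrelationExtent:
    def test_first_crossing(self, rng):
        pos = np.arange(0, 1000, 5)
        lev = rng.uniform(0, 1, len(pos))
        m = Methylome("m", {"chr1": (pos, np.round(lev * 100).astype(int), np.full(len(pos), 100))})
        prof = autocorrelation_profile(RegionSet([_region(0, 1000)]), m, min_pairs=1)
        prof.r = np.array([1.0, 0.04] + [0.0] * (len(prof.r) - 2))
        lag, censored = autocorrelation_extent(prof)
        assert (lag, censored) == (int(prof.lags[1]), False)

    def test_censored_when_never_crossing(self, rng):
        pos = np.arange(0, 1000, 5)
        lev = rng.uniform(0, 1, len(pos))
        m = Methylome("m", {"chr1": (pos, np.round(lev * 100).astype(int), np.full(len(pos), 100))})
        prof = autocorrelation_profile(RegionSet([_region(0, 1000)]), m, min_pairs=1)
        prof.r = np.full(len(prof.r), 0.5)
        lag, censored = autocorrelation_extent(prof)
        assert (lag, censored) == (prof.max_lag, True)

    def test_regulatory_extent_exceeds_background(self, promoter_ds):
        from methylreg.background import sample_matched_regions

        ref = promoter_ds.methylomes[0]
        pool = sample_matched_regions(
            promoter_ds.regions,
            promoter_ds.genes,
            n_per_region=5,
            seed=9,
            chrom_lengths=promoter_ds.chrom_lengths,
        )
        ext_pos, _ = autocorrelation_extent(autocorrelation_profile(promoter_ds.regions, ref))
        ext_bg, _ = autocorrelation_extent(autocorrelation_profile(pool, ref))
        assert ext_pos > ext_bg


class TestRegionAutocorrelationFeature:
    def test_uniform_offset_gives_positive_feature(self):
        pos = np.arange(0, 100, 10)
        m = Methylome("m", {"chr1": (pos, np.full(10, 8), np.full(10, 10))})
        val, imputed = region_autocorrelation_feature(_region(0, 100), m, 0.5, 0.04)
        assert not imputed and val > 0

    def test_symmetric_pair_gives_negative_feature(self):
        m = Methylome("m", {"chr1": (np.array([10, 20]), np.array([8, 2]), np.array([10, 10]))})
        val, imputed = region_autocorrelation_feature(_region(0, 100), m, 0.5, 0.09)
        assert not imputed and val < 0

    def test_single_site_imputed(self):
        m = Methylome("m", {"chr1": (np.array([10]), np.array([8]), np.array([10]))})
        val, imputed = region_autocorrelation_feature(_region(0, 100), m, 0.5, 0.04)
        assert imputed and val == 0.0

    def test_mean_feature_tracks_pooled_profile(self, rng):
        # exchangeable within-region structure: feature mean ~ profile r
        regions, chrom_pos, chrom_lev = [], [], []
        cursor = 0
        for _ in range(80):
            pos = cursor + np.arange(0, 200, 10)
            offset = rng.normal(0, 0.12)
            lev = np.clip(0.5 + offset + rng.normal(0, 0.03, len(pos)), 0, 1)
            regions.append(_region(cursor, cursor + 200))
            chrom_pos.append(pos)
            chrom_lev.append(lev)
            cursor += 1000
        pos = np.concatenate(chrom_pos)
        lev = np.concatenate(chrom_lev)
        m = Methylome(
            "m", {"chr1": (pos, np.round(lev * 1000).astype(int), np.full(len(pos), 1000))}
        )
        rs = RegionSet(regions)
        grand_mean, grand_var = pooled_site_stats(rs, m)
        feats = [
            region_autocorrelation_feature(r, m, grand_mean, grand_var, max_lag=200)[0]
            for r in regions
        ]
        prof = autocorrelation_profile(rs, m, max_lag=200, min_pairs=1)
        r10 = dict(zip(prof.lags, prof.r))[10]
        assert abs(np.mean(feats) - r10) <= 0.1


class TestExpressionCorrelation:
    def _setup(self, levels, rpkms):
        ms = [
            _methylome([50], [lv], name=f"c{i}") for i, lv in enumerate(levels)
        ]
        expr = ExpressionTable(
            {f"c{i}": {"G": rp} for i, rp in enumerate(rpkms)}
        )
        region = Region("chr1", 0, 100, target_gene="G")
        return region, ms, expr

    def test_perfect_anticorrelation(self):
        region, ms, expr = self._setup([0.0, 0.5, 1.0], [10, 5, 0])
        assert expression_correlation(region, ms, expr) == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        region, ms, expr = self._setup([0.0, 0.5, 1.0], [0, 5, 10])
        assert expression_correlation(region, ms, expr) == pytest.approx(1.0)
        assert expression_correlation(region, ms, expr, "spearman") == pytest.approx(1.0)

    def test_constant_inputs_undefined(self):
        region, ms, expr = self._setup([0.5, 0.5, 0.5], [1, 2, 3])
        with pytest.raises(UndefinedCorrelationError):
            expression_correlation(region, ms, expr)

    def test_repressive_coupling_shifts_positives_negative(self, promoter_ds):
        from scipy.stats import ks_2samp

        from methylreg.background import sample_matched_regions, subsample_negatives
        from methylreg.core import MethylRegError

        pool = sample_matched_regions(
            promoter_ds.regions,
            promoter_ds.genes,
            n_per_region=3,
            seed=4,
            chrom_lengths=promoter_ds.chrom_lengths,
        )
        negs = subsample_negatives(pool, seed=4)

        def corrs(regions):
            out = []
            for r in regions:
                try:
                    out.append(
                        expression_correlation(r, promoter_ds.methylomes, promoter_ds.expression)
                    )
                except MethylRegError:
                    continue
            return out

        c_pos, c_bg = corrs(promoter_ds.regions), corrs(negs)
        assert np.mean(c_pos) < np.mean(c_bg) - 0.3
        assert ks_2samp(c_pos, c_bg).pvalue < 0.01
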
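"""Canonical k-mer enumeration, binomial enrichment, and motif scoring."""

from collections import Counter
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylreg.core import Genome, Methylome, Region, RegionSet, ValidationError
from methylreg.motifs import (
    MotifTable,
    canonical_kmers,
    canonicalize,
    classify_motifs,
    count_motifs,
    motif_composition_summary,
    motif_pvalue,
    motif_pvalue_under,
    motif_score_feature,
    reverse_complement,
)

centered_8mers = st.tuples(
    st.text("ACGT", min_size=3, max_size=3), st.text("ACGT", min_size=3, max_size=3)
).map(lambda t: t[0] + "CG" + t[1])


class TestCanonicalize:
    def test_palindrome_is_fixed_point(self):
        assert canonicalize("AAACGTTT") == "AAACGTTT"

    def test_brute_force_revcomp_comparison(self):
        assert canonicalize("CTTCGAAA") == min("CTTCGAAA", reverse_complement("CTTCGAAA"))
        assert reverse_complement("CTTCGAAA") == "TTTCGAAG"

    @settings(max_examples=200, derandomize=True)
    @given(kmer=centered_8mers)
    def test_idempotent_and_minimal(self, kmer):
        c = canonicalize(kmer)
        assert canonicalize(c) == c
        assert c == min(kmer, reverse_complement(kmer))

    @pytest.mark.parametrize("bad", ["AAACGTT", "AAAGCTTT", "AAACGTTN"])
    def test_invalid_kmers_rejected(self, bad):
        with pytest.raises(ValidationError):
            canonicalize(bad)


class TestCanonicalKmers:
    @pytest.mark.parametrize("k,expected", [(2, 1), (4, 10), (6, 136), (8, 2080)])
    def test_counts_match_closed_form(self, k, expected):
        kmers = canonical_kmers(k)
        assert len(kmers) == expected
        assert len(kmers) == (4 ** (k - 2) + 4 ** ((k - 2) // 2)) // 2

    def test_matches_brute_force_enumeration(self):
        for k in (2, 4, 6):
            half = (k - 2) // 2
            brute = set()
            for flanks in product("ACGT", repeat=k - 2):
                kmer = "".join(flanks[:half]) + "CG" + "".join(flanks[half:])
                brute.add(min(kmer, reverse_complement(kmer)))
            assert canonical_kmers(k) == brute

    def test_odd_k_rejected(self):
        with pytest.raises(ValidationError):
            canonical_kmers(7)


def _dataset(seq: str, sites):
    genome = Genome.from_dict({"chr1": seq})
    pos = np.asarray(sorted(sites))
    meth = Methylome("m", {"chr1": (pos, np.full(len(pos), 5), np.full(len(pos), 10))})
    return genome, meth


class TestCountMotifs:
    def test_single_window(self):
        genome, meth = _dataset("AAACGTTT", [3])
        counts, n = count_motifs(RegionSet([Region("chr1", 0, 8)]), genome, meth)
        assert counts == Counter({"AAACGTTT": 1})
        assert n == 1

    def test_window_with_n_base_skipped(self):
        genome, meth = _dataset("ANACGTTT", [3])
        with pytest.raises(ValidationError):  # the only window is skipped -> none left
            count_motifs(RegionSet([Region("chr1", 0, 8)]), genome, meth)

    def test_window_may_extend_beyond_region(self):
        genome, meth = _dataset("AAACGTTT", [3])
        counts, n = count_motifs(RegionSet([Region("chr1", 2, 6)]), genome, meth)
        assert counts == Counter({"AAACGTTT": 1})

    def test_strand_symmetry(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        genome, _ = _dataset(seq, [])
        fwd_sites = [
            i for i in range(3, len(seq) - 5) if seq[i : i + 2] == "CG"
        ]
        meth_f = Methylome(
            "m",
            {"chr1": (np.array(fwd_sites), np.full(len(fwd_sites), 5), np.full(len(fwd_sites), 10))},
        )
        rc_seq = reverse_complement(seq)
        rc_sites = sorted(len(seq) - 2 - p for p in fwd_sites)
        genome_rc = Genome.from_dict({"chr1": rc_seq})
        meth_r = Methylome(
            "m",
            {"chr1": (np.array(rc_sites), np.full(len(rc_sites), 5), np.full(len(rc_sites), 10))},
        )
        region = RegionSet([Region("chr1", 0, len(seq))])
        counts_f, n_f = count_motifs(region, genome, meth_f)
        counts_r, n_r = count_motifs(region, genome_rc, meth_r)
        assert counts_f == counts_r and n_f == n_r


class TestMotifPvalue:
    def test_strict_upper_tail_examples(self):
        assert motif_pvalue(2, 2, 0.5) == 0.0  # k = n -> full sum
        assert motif_pvalue(0, 2, 0.5) == pytest.approx(0.75)
        assert motif_pvalue(0, 1, 0.3) == pytest.approx(0.3)

    def test_matches_exhaustive_enumeration_small(self):
        for n in (1, 4, 8):
            s_counts = np.array([bin(i).count("1") for i in range(2**n)])
            for p in (0.2, 0.5, 0.7):
                probs = p**s_counts * (1 - p) ** (n - s_counts)
                for k in range(n + 1):
                    assert motif_pvalue(k, n, p) == pytest.approx(
                        probs[s_counts > k].sum(), abs=1e-12
                    )
                    assert motif_pvalue_under(k, n, p) == pytest.approx(
                        probs[s_counts < k].sum(), abs=1e-12
                    )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            motif_pvalue(5, 4, 0.5)


class TestClassifyMotifs:
    def _table(self, fg, fg_total, bg, bg_total, **kw):
        return classify_motifs(Counter(fg), fg_total, Counter(bg), bg_total, **kw)

    def test_null_motif_not_significant(self):
        t = self._table({"AAACGAAA": 100}, 10_000, {"AAACGAAA": 1000}, 100_000)
        assert t.status("AAACGAAA") == "ns"

    def test_planted_motif_overrepresented(self):
        # 10x the background rate at plenty of trials
        t = self._table({"AAACGAAA": 500}, 10_000, {"AAACGAAA": 500}, 100_000)
        assert t.status("AAACGAAA") == "over"

    def test_depleted_motif_underrepresented(self):
        t = self._table({"AAACGAAA": 0}, 10_000, {"AAACGAAA": 5000}, 100_000)
        assert t.status("AAACGAAA") == "under"

    def test_bonferroni_capped_at_one(self):
        t = self._table({"AAACGAAA": 10}, 1000, {"AAACGAAA": 100}, 10_000)
        assert (t.table["p_over_bonferroni"] <= 1.0).all()
        assert (t.table["p_under_bonferroni"] <= 1.0).all()
        assert t.n_tests == 2080

    def test_over_and_under_mutually_exclusive(self, rng):
        fg = Counter({m: int(rng.integers(0, 30)) for m in list(canonical_kmers(8))[:200]})
        bg = Counter({m: int(rng.integers(0, 300)) for m in canonical_kmers(8)})
        t = self._table(fg, sum(fg.values()), bg, sum(bg.values()))
        assert not (set(t.overrepresented()) & set(t.underrepresented()))

    def test_empty_background_is_error(self):
        with pytest.raises(ValidationError):
            self._table({}, 10, {}, 0)

    def test_raw_threshold_flag(self):
        kw = dict(alpha=1e-3)
        fg = {"AAACGAAA": 30}
        t_corr = self._table(fg, 1000, {"AAACGAAA": 100}, 10_000, threshold_on="corrected", **kw)
        t_raw = self._table(fg, 1000, {"AAACGAAA": 100}, 10_000, threshold_on="raw", **kw)
        p_raw = t_raw.table.at["AAACGAAA", "p_over"]
        assert (t_raw.status("AAACGAAA") == "over") == (p_raw < 1e-3)
        assert t_corr.status("AAACGAAA") in ("ns", "over")


class TestComposition:
    def test_examples(self):
        s = motif_composition_summary(["CCCCGGGG"])
        assert s["gc_content"] == pytest.approx(1.0)
        assert s["both_flanks_gc"] == pytest.approx(1.0)
        s = motif_composition_summary(["AAACGTTT"])
        assert s["gc_content"] == pytest.approx(0.25)
        assert s["either_flank_gc"] == pytest.approx(0.0)
        s = motif_composition_summary(["CCCCGGGG", "AAACGTTT"])
        assert s["gc_content"] == pytest.approx(0.625)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            motif_composition_summary([])


def _table_with_pvalues(pvals: dict) -> MotifTable:
    frame = pd.DataFrame(
        {
            "count_fg": 1,
            "count_bg": 1,
            "p_bg": 0.1,
            "p_over": pd.Series(pvals),
            "p_under": 1.0,
            "p_over_bonferroni": 1.0,
            "p_under_bonferroni": 1.0,
            "status": "ns",
        }
    )
    frame.index.name = "motif"
    return MotifTable(frame, 1, 1, 1e-5, 2080)


class TestMotifScoreFeature:
    def test_uninformative_motifs_score_zero(self):
        genome, meth = _dataset("AAACGTTT", [3])
        table = _table_with_pvalues({"AAACGTTT": 1.0})
        score, imputed = motif_score_feature(Region("chr1", 0, 8), genome, meth, table)
        assert (score, imputed) == (0.0, False)

    def test_single_significant_window(self):
        genome, meth = _dataset("AAACGTTT", [3])
        table = _table_with_pvalues({"AAACGTTT": 1e-5})
        score, _ = motif_score_feature(Region("chr1", 0, 8), genome, meth, table)
        assert score == pytest.approx(5.0)

    def test_region_without_windows_imputed(self):
        genome, meth = _dataset("AAACGTTT", [])
        table = _table_with_pvalues({"AAACGTTT": 1e-5})
        score, imputed = motif_score_feature(Region("chr1", 0, 8), genome, meth, table)
        assert (score, imputed) == (0.0, True)

    def test_planted_motifs_separate_classes(self, promoter_ds):
        from methylreg.background import sample_matched_regions, subsample_negatives

        ref = promoter_ds.methylomes[0]
        pool = sample_matched_regions(
            promoter_ds.regions, promoter_ds.genes, n_per_region=10, seed=3,
            chrom_lengths=promoter_ds.chrom_lengths,
        )
        bg_counts, bg_total = count_motifs(pool, promoter_ds.genome, ref)
        fg_counts, fg_total = count_motifs(promoter_ds.regions, promoter_ds.genome, ref)
        table = classify_motifs(fg_counts, fg_total, bg_counts, bg_total)
        negs = subsample_negatives(pool, seed=3)
        s_pos = [motif_score_feature(r, promoter_ds.genome, ref, table)[0] for r in promoter_ds.regions]
        s_bg = [motif_score_feature(r, promoter_ds.genome, ref, table)[0] for r in negs]
        assert np.mean(s_pos) - np.mean(s_bg) > 1.0
        for m in promoter_ds.config.planted_motifs:
            assert table.status(canonicalize(m)) == "over"
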
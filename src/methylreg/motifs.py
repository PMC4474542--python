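"""Centered-CpG 8-mer enrichment around regulatory mCpGs.

An 8-mer with CG at offsets 3-4 (0-based) is extracted around every covered
mCpG of a region set, a word and its reverse complement are collapsed onto
the lexicographically smaller *canonical* form (2080 canonical 8-mers exist:
(4^6 + 4^3) / 2), and each motif's foreground occurrence count is tested
against a binomial null whose success probability is the motif's frequency
in the position-matched background pool:

    pvalue = 1 - sum_{i<=k} C(n, i) p^i (1-p)^(n-i)  =  P(X > k)

i.e. the strict upper tail. Under-representation uses the mirrored strict
lower tail P(X < k). Both tails are Bonferroni-corrected over the number of
canonical motifs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import Genome, Methylome, Region, RegionSet, ValidationError

log = logging.getLogger(__name__)

KMER_SIZE = 8
DEFAULT_ALPHA = 1e-5
PVALUE_FLOOR = 1e-300

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_kmer(kmer: str, k: int) -> None:
    if len(kmer) != k:
        raise ValidationError(f"k-mer {kmer!r} is not length {k}")
    if any(b not in "ACGT" for b in kmer):
        raise ValidationError(f"k-mer {kmer!r} contains non-ACGT characters")
    mid = k // 2 - 1
    if kmer[mid : mid + 2] != "CG":
        raise ValidationError(f"k-mer {kmer!r} lacks CG at center offsets {mid}-{mid + 1}")


def canonicalize(kmer: str, k: int = KMER_SIZE) -> str:
    """Canonical form of a centered-CpG k-mer: min(kmer, reverse complement).

    The reverse complement of a centered-CG word is itself centered-CG, so
    canonicalisation stays within the motif universe.
    """
    _validate_kmer(kmer, k)
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def canonical_kmers(k: int = KMER_SIZE) -> set[str]:
    """All canonical centered-CpG k-mers; |set| = (4^(k-2) + 4^((k-2)/2)) / 2."""
    if k % 2 != 0 or k < 2:
        raise ValidationError("k must be an even integer >= 2")
    half = (k - 2) // 2
    out: set[str] = set()
    for flanks in product("ACGT", repeat=k - 2):
        kmer = "".join(flanks[:half]) + "CG" + "".join(flanks[half:])
        out.add(canonicalize(kmer, k))
    return out


def region_window_kmers(
    region: Region, genome: Genome, methylome: Methylome, k: int = KMER_SIZE
) -> list[str]:
    """Canonical k-mers of the windows centered on the region's mCpGs.

    Each covered mCpG inside [start, end) anchors one window placing its CG at
    the centre; windows may extend past the region boundary but not past the
    chromosome, and windows containing non-ACGT bases (or whose genomic
    sequence is not CG at the anchor) are skipped.
    """
    half = k // 2 - 1
    chrom_len = genome.length(region.chrom)
    pos, _ = methylome.sites_in(region.chrom, region.start, region.end)
    out: list[str] = []
    for p in pos:
        start = int(p) - half
        end = start + k
        if start < 0 or end > chrom_len:
            continue
        window = genome.fetch(region.chrom, start, end)
        if window[half : half + 2] != "CG":
            log.debug("%s:%d: methylome site is not CG in genome; skipped", region.chrom, p)
            continue
        if any(b not in "ACGT" for b in window):
            continue
        out.append(kmer if (kmer := window) <= (rc := reverse_complement(window)) else rc)
    return out


def count_motifs(
    regions: RegionSet, genome: Genome, methylome: Methylome, k: int = KMER_SIZE
) -> tuple[Counter, int]:
    """Occurrences per canonical motif over all mCpG-anchored windows.

    Returns (counts, n_windows); raises when no window could be extracted.
    """
    counts: Counter = Counter()
    n = 0
    for region in regions:
        kmers = region_window_kmers(region, genome, methylome, k)
        counts.update(kmers)
        n += len(kmers)
    if n == 0:
        raise ValidationError("no mCpG-anchored windows in the supplied regions")
    return counts, n


def motif_pvalue(k_obs: int, n_total: int, p_bg: float) -> float:
    """Strict upper-tail binomial probability P(X > k_obs | n_total, p_bg)."""
    if not 0 <= k_obs <= n_total:
        raise ValidationError(f"k_obs {k_obs} outside [0, {n_total}]")
    if not 0.0 <= p_bg <= 1.0:
        raise ValidationError(f"p_bg {p_bg} outside [0, 1]")
    return float(binom.sf(k_obs, n_total, p_bg))


def motif_pvalue_under(k_obs: int, n_total: int, p_bg: float) -> float:
    """Strict lower-tail binomial probability P(X < k_obs | n_total, p_bg)."""
    if not 0 <= k_obs <= n_total:
        raise ValidationError(f"k_obs {k_obs} outside [0, {n_total}]")
    if not 0.0 <= p_bg <= 1.0:
        raise ValidationError(f"p_bg {p_bg} outside [0, 1]")
    if k_obs == 0:
        return 0.0
    return float(binom.cdf(k_obs - 1, n_total, p_bg))


@dataclass(slots=True)
class MotifTable:
    """Per-motif counts, background probabilities and enrichment calls."""

    table: pd.DataFrame  # indexed by canonical motif
    fg_total: int
    bg_total: int
    alpha: float
    n_tests: int

    def status(self, motif: str) -> str:
        return str(self.table.at[motif, "status"]) if motif in self.table.index else "ns"

    def overrepresented(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "over"])

    def underrepresented(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "under"])

    def score_lookup(self) -> dict[str, float]:
        """motif -> -log10(raw over-representation p), floored."""
        p = self.table["p_over"].clip(lower=PVALUE_FLOOR)
        return dict(zip(self.table.index, -np.log10(p)))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="motif")


def classify_motifs(
    fg_counts: Counter,
    fg_total: int,
    bg_counts: Counter,
    bg_total: int,
    alpha: float = DEFAULT_ALPHA,
    k: int = KMER_SIZE,
    threshold_on: str = "corrected",
) -> MotifTable:
    """Binomial enrichment test for every canonical motif.

    Background probability per motif is its frequency in the background pool;
    a motif unseen in the pool is tested against the smallest nonzero
    estimate 1/bg_total (conservative; the reported ``p_bg`` column keeps the
    raw zero). The number of tests for the Bonferroni correction is the
    enumerated canonical-motif count (2080 for k=8), not the number of
    observed motifs.
    ``threshold_on`` selects whether ``alpha`` is applied to the corrected
    (default) or raw p-value.
    """
    if bg_total <= 0:
        raise ValidationError("background pool is empty; cannot form p_bg")
    if threshold_on not in ("corrected", "raw"):
        raise ValidationError(f"threshold_on must be 'corrected' or 'raw', got {threshold_on!r}")
    motifs = sorted(canonical_kmers(k))
    n_tests = len(motifs)

    rows = []
    for motif in motifs:
        k_obs = fg_counts.get(motif, 0)
        bg = bg_counts.get(motif, 0)
        p_bg = bg / bg_total
        # motifs unseen in a finite background pool get the smallest nonzero
        # probability estimate: the verbatim tail at p_bg = 0 would declare
        # any single foreground occurrence infinitely significant
        p_test = p_bg if bg > 0 else 1.0 / bg_total
        # a zero observed count is never evidence of over-representation
        p_over = 1.0 if k_obs == 0 else motif_pvalue(k_obs, fg_total, p_test)
        p_under = motif_pvalue_under(k_obs, fg_total, p_test)
        p_over_c = min(1.0, p_over * n_tests)
        p_under_c = min(1.0, p_under * n_tests)
        t_over = p_over_c if threshold_on == "corrected" else p_over
        t_under = p_under_c if threshold_on == "corrected" else p_under
        if t_over < alpha:
            status = "over"
        elif t_under < alpha:
            status = "under"
        else:
            status = "ns"
        rows.append((motif, k_obs, bg, p_bg, p_over, p_under, p_over_c, p_under_c, status))

    table = pd.DataFrame(
        rows,
        columns=[
            "motif",
            "count_fg",
            "count_bg",
            "p_bg",
            "p_over",
            "p_under",
            "p_over_bonferroni",
            "p_under_bonferroni",
            "status",
        ],
    ).set_index("motif")
    return MotifTable(table, fg_total, bg_total, alpha, n_tests)


def motif_composition_summary(motifs: list[str], k: int = KMER_SIZE) -> dict[str, float]:
    """Nucleotide composition of a motif list.

    Reports the mean GC content, the fraction of motifs with a C or G
    directly flanking the central CpG on either side (offsets k/2-2 and
    k/2+1), and the fraction with C/G on both flanks.
    """
    if not motifs:
        raise ValidationError("empty motif list")
    left, right = k // 2 - 2, k // 2 + 1
    gc, either, both = 0.0, 0, 0
    for m in motifs:
        _validate_kmer(m, k)
        gc += (m.count("C") + m.count("G")) / k
        l_gc = m[left] in "CG"
        r_gc = m[right] in "CG"
        either += l_gc or r_gc
        both += l_gc and r_gc
    n = len(motifs)
    return {
        "gc_content": gc / n,
        "either_flank_gc": either / n,
        "both_flanks_gc": both / n,
    }


def motif_score_feature(
    region: Region,
    genome: Genome,
    methylome: Methylome,
    motif_table: MotifTable,
    k: int = KMER_SIZE,
) -> tuple[float, bool]:
    """Mean -log10 raw over-representation p of the region's mCpG windows.

    Regions without any extractable window are imputed to 0 with a flag.
    """
    scores = motif_table.score_lookup()
    kmers = region_window_kmers(region, genome, methylome, k)
    if not kmers:
        return 0.0, True
    return float(np.mean([scores.get(m, 0.0) for m in kmers])), False


class FoldAwareMotifScorer:
    """Motif scoring with per-training-fold table rebuilds.

    Precomputes every region's canonical window k-mers once; a motif table
    can then be assembled from any subset of positives (plus the fixed
    background pool) in milliseconds, so cross-validation can rebuild the
    table within each training fold without touching held-out regions.
    """

    def __init__(
        self,
        regions: RegionSet,
        genome: Genome,
        methylome: Methylome,
        bg_counts: Counter,
        bg_total: int,
        alpha: float = DEFAULT_ALPHA,
        k: int = KMER_SIZE,
    ) -> None:
        self.k = k
        self.alpha = alpha
        self.bg_counts = bg_counts
        self.bg_total = bg_total
        self.region_kmers: list[list[str]] = [
            region_window_kmers(r, genome, methylome, k) for r in regions
        ]
        self.labels = [r.label for r in regions]

    def table_for(self, train_idx: np.ndarray | list[int]) -> MotifTable:
        """Motif table built from the *positive* regions of a training subset."""
        fg: Counter = Counter()
        fg_total = 0
        for i in train_idx:
            if self.labels[i] == "positive":
                fg.update(self.region_kmers[i])
                fg_total += len(self.region_kmers[i])
        if fg_total == 0:
            raise ValidationError("training subset has no positive windows")
        return classify_motifs(fg, fg_total, self.bg_counts, self.bg_total, self.alpha, self.k)

    def scores(self, motif_table: MotifTable) -> np.ndarray:
        """(score, imputed handled as 0) for every region under a given table."""
        lookup = motif_table.score_lookup()
        return np.array(
            [
                float(np.mean([lookup.get(m, 0.0) for m in kmers])) if kmers else 0.0
                for kmers in self.region_kmers
            ]
        )

    def refit(self, train_idx) -> np.ndarray:
        return self.scores(self.table_for(train_idx))
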
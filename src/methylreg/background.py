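"""Position-matched random background sampling.

Every positive regulatory region is summarised by a *relative coordinate*:
which genic context its midpoint falls in (the 10 kb window upstream of a
TSS, an exon, or an intron of its target gene) and its distance to the
context's anchor, normalised by the context's length. Background regions of
identical length are then placed at the same relative coordinate inside
randomly drawn host genes, rejecting placements that overlap any positive
region. Matching on position (and nothing else) removes location-driven
methylation differences between the positive and negative sets while leaving
every methylation-derived feature free to differ.

Normalising lengths: (transcript span + 10 kb) for the upstream context;
exon length for exons; intron length for introns, with distance measured to
the nearest boundary of the containing exon/intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    GeneModel,
    IntervalIndex,
    NoTargetGeneError,
    Region,
    RegionSet,
    ValidationError,
)

log = logging.getLogger(__name__)

UPSTREAM_WINDOW = 10_000
CONTEXTS = ("upstream", "exon", "intron")


@dataclass(frozen=True, slots=True)
class RelativeCoordinate:
    """A region midpoint expressed relative to its target gene."""

    context: str
    gene_id: str
    rel_dist: float

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if not 0.0 <= self.rel_dist <= 1.0:
            raise ValidationError(f"rel_dist {self.rel_dist} outside [0, 1]")


def assign_target_gene(
    region: Region, genes: list[GeneModel], upstream: int = UPSTREAM_WINDOW
) -> str:
    """Target gene of a region: the gene whose body contains the region
    midpoint, else the immediately downstream gene whose upstream window does.

    Raises :class:`NoTargetGeneError` when the midpoint lies in neither
    context (such regions are excluded from the analysis).
    """
    mid = region.midpoint
    containing = [g for g in genes if g.chrom == region.chrom and g.contains(mid)]
    if containing:
        # innermost / first by start; ties are rare and harmless
        return containing[0].gene_id

    best: GeneModel | None = None
    best_dist: int | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        w_start, w_end = g.upstream_window(upstream)
        if w_start <= mid < w_end:
            dist = (g.tss - mid) if g.strand == "+" else (mid - g.tss)
            if best_dist is None or dist < best_dist:
                best, best_dist = g, dist
    if best is None:
        raise NoTargetGeneError(
            f"{region.chrom}:{region.start}-{region.end}: midpoint in no gene body "
            f"or {upstream} bp upstream window"
        )
    return best.gene_id


def relative_position(
    region: Region, gene: GeneModel, upstream: int = UPSTREAM_WINDOW
) -> RelativeCoordinate:
    """Relative coordinate of the region midpoint within its target gene."""
    mid = region.midpoint
    if gene.chrom != region.chrom:
        raise ValidationError("region and gene on different chromosomes")

    w_start, w_end = gene.upstream_window(upstream)
    if w_start <= mid < w_end:
        dist = (gene.tss - mid) if gene.strand == "+" else (mid - gene.tss)
        norm = gene.coding_length + upstream
        return RelativeCoordinate("upstream", gene.gene_id, dist / norm)

    if gene.contains(mid):
        for s, e in gene.exons:
            if s <= mid < e:
                dist = min(mid - s, e - mid)
                return RelativeCoordinate("exon", gene.gene_id, dist / (e - s))
        for s, e in gene.introns:
            if s <= mid < e:
                dist = min(mid - s, e - mid)
                return RelativeCoordinate("intron", gene.gene_id, dist / (e - s))

    raise ValidationError(
        f"{region.chrom}:{region.start}-{region.end}: midpoint {mid} outside all "
        f"contexts of gene {gene.gene_id}"
    )


def _place_in_gene(
    rc: RelativeCoordinate,
    gene: GeneModel,
    length: int,
    rng: np.random.Generator,
    upstream: int,
    chrom_length: int | None,
) -> Region | None:
    """Map a relative coordinate onto a host gene; None when it cannot fit."""
    if rc.context == "upstream":
        norm = gene.coding_length + upstream
        dist = int(round(rc.rel_dist * norm))
        mid = gene.tss - dist if gene.strand == "+" else gene.tss + dist
        w_start, w_end = gene.upstream_window(upstream)
        if not (w_start <= mid < w_end):
            return None
    else:
        pool = gene.exons if rc.context == "exon" else gene.introns
        if not pool:
            return None
        s, e = pool[int(rng.integers(len(pool)))]
        dist = int(round(rc.rel_dist * (e - s)))
        # distance is to the *nearest* boundary; pick a side at random
        mid = (s + dist) if rng.random() < 0.5 else (e - dist)
        mid = min(max(mid, s), e - 1)

    start = mid - length // 2
    end = start + length
    if start < 0 or (chrom_length is not None and end > chrom_length):
        return None
    return Region(gene.chrom, start, end)


def sample_matched_regions(
    positives: RegionSet,
    genes: list[GeneModel],
    n_per_region: int = 1000,
    seed: int = 0,
    *,
    max_attempts: int = 50,
    rel_tol: float = 0.01,
    upstream: int = UPSTREAM_WINDOW,
    chrom_lengths: dict[str, int] | None = None,
) -> RegionSet:
    """Sample ``n_per_region`` length- and position-matched backgrounds per positive.

    Host genes are drawn uniformly at random; a candidate is accepted when its
    recomputed relative coordinate matches the source context exactly and the
    source ``rel_dist`` within ``rel_tol``, and it overlaps no positive region.
    Deterministic for a given seed. Positives without a target gene, and
    positives for which no placement is found within ``max_attempts`` tries per
    replicate, are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    index = IntervalIndex(positives)
    out: list[Region] = []
    n_skipped = 0

    for i, pos_region in enumerate(positives):
        source_id = pos_region.source_id or f"pos{i}"
        try:
            gene_id = pos_region.target_gene or assign_target_gene(pos_region, genes, upstream)
            gene = next(g for g in genes if g.gene_id == gene_id)
            rc = relative_position(pos_region, gene, upstream)
        except (NoTargetGeneError, ValidationError, StopIteration) as exc:
            log.warning("skipping positive %s: %s", source_id, exc)
            n_skipped += 1
            continue

        for rep in range(n_per_region):
            placed = None
            for _ in range(max_attempts):
                host = genes[int(rng.integers(len(genes)))]
                chrom_len = chrom_lengths.get(host.chrom) if chrom_lengths else None
                cand = _place_in_gene(rc, host, pos_region.length, rng, upstream, chrom_len)
                if cand is None:
                    continue
                if index.overlaps_any(cand.chrom, cand.start, cand.end):
                    continue
                try:
                    rc_new = relative_position(cand, host, upstream)
                except ValidationError:
                    continue
                if rc_new.context != rc.context or abs(rc_new.rel_dist - rc.rel_dist) > rel_tol:
                    continue
                placed = cand.copy(
                    label="background",
                    region_class=pos_region.region_class,
                    source_id=source_id,
                    target_gene=host.gene_id,
                )
                break
            if placed is None:
                log.warning("no placement for %s replicate %d", source_id, rep)
                continue
            out.append(placed)

    if n_skipped:
        log.warning("%d positives skipped during background sampling", n_skipped)
    return RegionSet(out)


def subsample_negatives(backgrounds: RegionSet, seed: int = 0) -> RegionSet:
    """Pick one background per source positive, uniformly from its pool.

    The classifier is trained on a 1:1 positive:background set; the full pool
    is kept for motif background probabilities.
    """
    rng = np.random.default_rng(seed)
    by_source: dict[str, list[Region]] = {}
    for r in backgrounds:
        by_source.setdefault(r.source_id or "?", []).append(r)
    chosen = [pool[int(rng.integers(len(pool)))] for _, pool in sorted(by_source.items())]
    return RegionSet(chosen)
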
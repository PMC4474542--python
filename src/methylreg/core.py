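"""Core data model for methylation-based regulatory-region prediction.

The in-memory containers used throughout the package:

* :class:`MethylationSite` / :class:`Methylome` — per-CpG methylation levels of
  one cell line, indexed by chromosome and position.
* :class:`Region` / :class:`RegionSet` — labelled genomic intervals (positive
  regulatory regions or sampled backgrounds), BED-style 0-based half-open.
* :class:`GeneModel` — one gene with strand-aware TSS and exon structure.
* :class:`ExpressionTable` — gene x cell-line RPKM matrix.
* :class:`Genome` — random-access genome sequence (FASTA-backed or in-memory).
* :class:`FeatureVector` — the five per-region features fed to the classifier.

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

LABELS = ("positive", "background")
REGION_CLASSES = ("promoter", "enhancer")
FEATURE_NAMES = ("mean_meth", "meth_variance", "autocorr", "cpg_density", "motif_score")


class MethylRegError(Exception):
    """Base class for package errors."""


class ParseError(MethylRegError):
    """A malformed input file; carries the offending line number where known."""


class ValidationError(MethylRegError):
    """Structurally valid input violating a domain invariant."""


class NoSitesError(MethylRegError):
    """A region contains no usable mCpG sites; the region is dropped."""


class NoTargetGeneError(MethylRegError):
    """A region lies outside every gene body and 10 kb upstream window."""


class DegenerateProfileError(MethylRegError):
    """All methylation levels equal; the autocorrelation denominator is zero."""


class UndefinedCorrelationError(MethylRegError):
    """Methylation or expression constant across cell lines."""


@dataclass(frozen=True, slots=True)
class MethylationSite:
    """One CpG in one cell line, represented at the forward-strand C position."""

    chrom: str
    pos: int
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: total_count must be positive, got {self.total_count}"
            )
        if not 0 <= self.meth_count <= self.total_count:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: meth_count {self.meth_count} outside "
                f"[0, {self.total_count}]"
            )

    @property
    def level(self) -> float:
        """Methylation level: fraction of reads reporting methylation, in [0, 1]."""
        return self.meth_count / self.total_count


class Methylome:
    """Position-sorted CpG methylation levels for one cell line.

    Sites are stored per chromosome as parallel numpy arrays (position,
    methylated count, total count, level), strictly increasing in position
    with no duplicates.
    """

    def __init__(
        self,
        cell_line: str,
        chrom_data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    ) -> None:
        self.cell_line = cell_line
        self._data: dict[str, dict[str, np.ndarray]] = {}
        for chrom, (pos, meth, total) in (chrom_data or {}).items():
            self._add_chrom(chrom, pos, meth, total)

    def _add_chrom(self, chrom: str, pos, meth, total) -> None:
        pos = np.asarray(pos, dtype=np.int64)
        meth = np.asarray(meth, dtype=np.int64)
        total = np.asarray(total, dtype=np.int64)
        if not (len(pos) == len(meth) == len(total)):
            raise ValidationError(f"{chrom}: ragged site arrays")
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise ValidationError(f"{chrom}: positions not strictly increasing")
        if np.any(total <= 0) or np.any(meth < 0) or np.any(meth > total):
            raise ValidationError(f"{chrom}: invalid methylation counts")
        with np.errstate(invalid="ignore"):
            level = meth / total
        self._data[chrom] = {"pos": pos, "meth": meth, "total": total, "level": level}

    @classmethod
    def from_sites(cls, cell_line: str, sites: Iterable[MethylationSite]) -> "Methylome":
        by_chrom: dict[str, list[MethylationSite]] = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s)
        obj = cls(cell_line)
        for chrom in sorted(by_chrom):
            ss = sorted(by_chrom[chrom], key=lambda s: s.pos)
            for a, b in zip(ss, ss[1:]):
                if a.pos == b.pos:
                    raise ValidationError(f"{chrom}:{a.pos}: duplicate CpG position")
            obj._add_chrom(
                chrom,
                [s.pos for s in ss],
                [s.meth_count for s in ss],
                [s.total_count for s in ss],
            )
        return obj

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    @property
    def n_sites(self) -> int:
        return sum(len(d["pos"]) for d in self._data.values())

    def positions(self, chrom: str) -> np.ndarray:
        d = self._data.get(chrom)
        return d["pos"] if d is not None else np.empty(0, dtype=np.int64)

    def levels(self, chrom: str) -> np.ndarray:
        d = self._data.get(chrom)
        return d["level"] if d is not None else np.empty(0, dtype=float)

    def counts(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        d = self._data.get(chrom)
        if d is None:
            z = np.empty(0, dtype=np.int64)
            return z, z
        return d["meth"], d["total"]

    def sites_in(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Positions and levels of sites with start <= pos < end."""
        d = self._data.get(chrom)
        if d is None:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=float)
        lo, hi = np.searchsorted(d["pos"], (start, end))
        return d["pos"][lo:hi], d["level"][lo:hi]

    def iter_sites(self) -> Iterator[MethylationSite]:
        for chrom, d in self._data.items():
            for p, m, t in zip(d["pos"], d["meth"], d["total"]):
                yield MethylationSite(chrom, int(p), int(m), int(t))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Methylome):
            return NotImplemented
        if self.cell_line != other.cell_line or set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c][k], other._data[c][k])
            for c in self._data
            for k in ("pos", "meth", "total")
        )

    def __repr__(self) -> str:
        return f"Methylome({self.cell_line!r}, {self.n_sites} sites, {len(self._data)} chroms)"


@dataclass(slots=True)
class Region:
    """A labelled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = "positive"
    region_class: str = "promoter"
    source_id: str | None = None
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"{self.chrom}:{self.start}-{self.end}: start >= end")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region_class {self.region_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def copy(self, **changes) -> "Region":
        return replace(self, **changes)


class RegionSet:
    """An ordered collection of :class:`Region` records.

    Overlapping members are permitted (no merge rule is applied); overlaps are
    the caller's to interpret.
    """

    def __init__(self, regions: Iterable[Region] = ()) -> None:
        self.regions: list[Region] = list(regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)))

    def subset(self, label: str | None = None, region_class: str | None = None) -> "RegionSet":
        out = [
            r
            for r in self.regions
            if (label is None or r.label == label)
            and (region_class is None or r.region_class == region_class)
        ]
        return RegionSet(out)

    def count_overlaps(self, other: "RegionSet") -> int:
        """Number of regions in ``self`` overlapping any region in ``other``."""
        index = IntervalIndex(other)
        return sum(index.overlaps_any(r.chrom, r.start, r.end) for r in self.regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionSet({len(self.regions)} regions)"


class IntervalIndex:
    """Sorted-interval overlap queries for a fixed RegionSet.

    Built once, then O(log n + k) per query; sufficient for rejection sampling
    against a few thousand positives.
    """

    def __init__(self, regions: Iterable[Region]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = [s for s, _ in ivs]
            ends = [e for _, e in ivs]
            maxend = list(np.maximum.accumulate(ends))
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._maxend[chrom] = maxend

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        hi = bisect_right(starts, end - 1)
        ends = self._ends[chrom]
        maxend = self._maxend[chrom]
        # scan back only while the running max end can still reach `start`
        for i in range(hi - 1, -1, -1):
            if maxend[i] <= start:
                return False
            if ends[i] > start:
                return True
        return False


@dataclass(slots=True)
class GeneModel:
    """One gene: strand-aware TSS plus ordered, disjoint exons."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValidationError(f"{self.gene_id}: txStart >= txEnd")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValidationError(f"{self.gene_id}: exon {s}-{e} outside gene span")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(f"{self.gene_id}: overlapping exons {e1} > {s2}")
        object.__setattr__(self, "exons", exons)

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def coding_length(self) -> int:
        """Span from TSS to gene end (transcript span in bp)."""
        return self.tx_end - self.tx_start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1)

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos < self.tx_end

    def upstream_window(self, upstream: int = 10_000) -> tuple[int, int]:
        """The [start, end) interval immediately upstream of the TSS."""
        if self.strand == "+":
            return max(0, self.tss - upstream), self.tss
        return self.tx_end, self.tx_end + upstream


class ExpressionTable:
    """Gene x cell-line RPKM matrix; missing values are NaN, never zero."""

    def __init__(self, frame) -> None:
        import pandas as pd

        frame = pd.DataFrame(frame).astype(float)
        if (frame.to_numpy() < 0).any():
            raise ValidationError("negative RPKM value in expression table")
        frame.index.name = "gene_id"
        self.frame = frame

    @property
    def cell_lines(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    def value(self, gene_id: str, cell_line: str) -> float:
        """RPKM for one gene in one cell line; NaN when absent."""
        try:
            return float(self.frame.at[gene_id, cell_line])
        except KeyError:
            return float("nan")

    def __repr__(self) -> str:
        return f"ExpressionTable({self.frame.shape[0]} genes x {self.frame.shape[1]} cell lines)"


class Genome:
    """Random-access genome sequence, uppercased.

    Backed either by an in-memory dict of strings (the synthetic generator) or
    by an indexed FASTA via :mod:`pyfaidx`.
    """

    def __init__(self, seqs: Mapping[str, str]) -> None:
        self._seqs = {c: s.upper() for c, s in seqs.items()}
        self._fasta = None

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "Genome":
        return cls(seqs)

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        obj = cls.__new__(cls)
        obj._seqs = None
        obj._fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)
        return obj

    @property
    def chroms(self) -> list[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            if chrom not in self._seqs:
                raise ValidationError(f"unknown chromosome {chrom!r}")
            return len(self._seqs[chrom])
        if chrom not in self._fasta:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); errors if the window exits the chromosome."""
        n = self.length(chrom)
        if start < 0 or end > n or start >= end:
            raise ValidationError(f"window {chrom}:{start}-{end} outside chromosome (len {n})")
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()

    def to_fasta(self, path, width: int = 80) -> None:
        if self._seqs is None:
            raise MethylRegError("FASTA-backed genome; copy the source file instead")
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(slots=True)
class FeatureVector:
    """The five per-region features plus label — the classifier's input unit."""

    region: Region
    mean_meth: float
    meth_variance: float
    autocorr: float
    cpg_density: float
    motif_score: float
    autocorr_imputed: bool = False
    variance_imputed: bool = False
    motif_imputed: bool = False

    @property
    def label(self) -> str:
        return self.region.label

    def values(self) -> tuple[float, float, float, float, float]:
        return (self.mean_meth, self.meth_variance, self.autocorr, self.cpg_density, self.motif_score)
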
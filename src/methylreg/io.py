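"""Readers and writers for the package's tabular interchange formats.

Formats handled here:

* methylation tables — TSV ``chrom  pos  meth_count  total_count`` (default,
  0-based positions) or the bismark coverage dialect
  ``chrom  start(1-based)  end  pct  meth  unmeth``;
* region sets — BED3+ (name column, when present, is read as the source id);
* gene annotation — UCSC-style table with ``gene_id chrom strand txStart
  txEnd exonStarts exonEnds`` columns;
* expression — TSV matrix of RPKM, genes x cell lines, ``NA`` for missing;
* feature tables — TSV round-trippable to full float precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionTable,
    FeatureVector,
    GeneModel,
    Genome,
    Methylome,
    ParseError,
    Region,
    RegionSet,
    ValidationError,
)

log = logging.getLogger(__name__)

_FEATURE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "region_class",
    "label",
    "source_id",
    "mean_meth",
    "meth_variance",
    "autocorr",
    "cpg_density",
    "motif_score",
    "autocorr_imputed",
    "variance_imputed",
    "motif_imputed",
]


def read_methylome(
    path,
    min_coverage: int = 5,
    *,
    position_base: int = 0,
    dialect: str = "tsv",
    merge_strands: bool = False,
    cell_line: str | None = None,
) -> Methylome:
    """Read one cell line's CpG methylation table, applying the coverage filter.

    Sites covered by fewer than ``min_coverage`` reads are dropped (the default
    of 5 keeps sites covered by more than 4 reads). With ``merge_strands`` the
    counts of a CpG reported separately at the C position and the G position
    (pos+1) are summed onto the forward-strand C before filtering.

    Parameters
    ----------
    dialect : {"tsv", "bismark"}
        "tsv" expects ``chrom pos meth_count total_count``; "bismark" expects
        the bismark coverage format (1-based start, percent, meth, unmeth).
    position_base : {0, 1}
        Coordinate base of the position column in the "tsv" dialect.
    """
    if min_coverage < 1:
        raise ValidationError("min_coverage must be a positive integer")
    path = Path(path)
    name = cell_line if cell_line is not None else path.stem

    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if dialect == "tsv":
                    chrom, pos, meth, total = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                    pos -= position_base
                elif dialect == "bismark":
                    chrom = parts[0]
                    pos = int(parts[1]) - 1
                    meth = int(parts[4])
                    total = meth + int(parts[5])
                else:
                    raise ValidationError(f"unknown methylation dialect {dialect!r}")
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed methylation record: {line!r}") from exc
            if meth > total:
                raise ValidationError(f"{path}:{lineno}: meth_count {meth} > total_count {total}")
            if meth < 0 or total < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            rows.append((chrom, pos, meth, total))

    if not rows:
        log.warning("%s: empty methylation table -> empty methylome", path)
        return Methylome(name)

    frame = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    if merge_strands:
        merged = []
        for chrom, grp in frame.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            meth = grp["meth"].to_numpy().copy()
            total = grp["total"].to_numpy().copy()
            keep = np.ones(len(pos), dtype=bool)
            i = 0
            while i < len(pos) - 1:
                if pos[i + 1] == pos[i] + 1:
                    meth[i] += meth[i + 1]
                    total[i] += total[i + 1]
                    keep[i + 1] = False
                    i += 2
                else:
                    i += 1
            merged.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos[keep], "meth": meth[keep], "total": total[keep]}
                )
            )
        frame = pd.concat(merged, ignore_index=True)

    dup = frame.duplicated(["chrom", "pos"])
    if dup.any():
        first = frame[dup].iloc[0]
        raise ValidationError(f"{path}: duplicate CpG position {first['chrom']}:{first['pos']}")

    n_before = len(frame)
    frame = frame[frame["total"] >= min_coverage]
    dropped = n_before - len(frame)
    if dropped:
        log.info("%s: dropped %d/%d sites below coverage %d", path, dropped, n_before, min_coverage)

    meth = Methylome(name)
    for chrom, grp in frame.groupby("chrom", sort=True):
        meth._add_chrom(chrom, grp["pos"].to_numpy(), grp["meth"].to_numpy(), grp["total"].to_numpy())
    return meth


def write_methylome(methylome: Methylome, path) -> None:
    """Write the default TSV dialect (0-based positions)."""
    with open(path, "w") as fh:
        for chrom in sorted(methylome.chroms):
            pos = methylome.positions(chrom)
            meth, total = methylome.counts(chrom)
            for p, m, t in zip(pos, meth, total):
                fh.write(f"{chrom}\t{p}\t{m}\t{t}\n")


def read_regions(path, label: str, region_class: str, genome: Genome | None = None) -> RegionSet:
    """Read a BED3+ file into a uniformly labelled, sorted RegionSet.

    Overlapping records are kept as-is (logged). When a genome is supplied,
    records on chromosomes absent from it are an error.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED record {line!r}") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            if genome is not None:
                if chrom not in genome.chroms:
                    raise ValidationError(f"{path}:{lineno}: chromosome {chrom!r} not in genome")
                if end > genome.length(chrom):
                    raise ValidationError(f"{path}:{lineno}: interval beyond end of {chrom}")
            source_id = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
            regions.append(Region(chrom, start, end, label, region_class, source_id=source_id))

    rs = RegionSet(regions).sorted()
    n_overlap = 0
    for a, b in zip(rs.regions, rs.regions[1:]):
        if a.overlaps(b):
            n_overlap += 1
    if n_overlap:
        log.info("%s: %d overlapping adjacent records kept as-is", path, n_overlap)
    return rs


def write_regions(regions: Iterable[Region], path) -> None:
    """Write BED4 (name = source_id, '.' when unset)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.source_id or '.'}\n")


def read_gene_annotation(path) -> list[GeneModel]:
    """Read a UCSC-style gene table.

    Expects a header naming at least ``gene_id chrom strand txStart txEnd
    exonStarts exonEnds``; exon columns are comma-separated lists. TSS is
    txStart on '+' and txEnd on '-'.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    genes: list[GeneModel] = []
    for idx, row in frame.iterrows():
        starts = [int(x) for x in str(row["exonStarts"]).strip(",").split(",") if x != ""]
        ends = [int(x) for x in str(row["exonEnds"]).strip(",").split(",") if x != ""]
        if len(starts) != len(ends):
            raise ValidationError(f"{path}: gene {row['gene_id']}: exonStarts/exonEnds length mismatch")
        genes.append(
            GeneModel(
                gene_id=str(row["gene_id"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                tx_start=int(row["txStart"]),
                tx_end=int(row["txEnd"]),
                exons=tuple(zip(starts, ends)),
            )
        )
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\n")
        for g in genes:
            ss = ",".join(str(s) for s, _ in g.exons)
            es = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{ss}\t{es}\n")


def read_expression(path) -> ExpressionTable:
    """Read a gene x cell-line RPKM matrix; 'NA' entries stay missing."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value") from exc
    if (frame.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative RPKM value")
    return ExpressionTable(frame)


def write_expression(expr: ExpressionTable, path) -> None:
    expr.frame.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA", float_format="%.17g")


def write_feature_table(vectors: Sequence[FeatureVector], path) -> None:
    """Write the per-region feature table as TSV (lossless float round-trip)."""
    if not vectors:
        raise ValidationError("refusing to write an empty feature table")
    with open(path, "w") as fh:
        fh.write("\t".join(_FEATURE_COLUMNS) + "\n")
        for v in vectors:
            r = v.region
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.region_class,
                        r.label,
                        r.source_id or ".",
                        repr(v.mean_meth),
                        repr(v.meth_variance),
                        repr(v.autocorr),
                        repr(v.cpg_density),
                        repr(v.motif_score),
                        str(int(v.autocorr_imputed)),
                        str(int(v.variance_imputed)),
                        str(int(v.motif_imputed)),
                    ]
                )
                + "\n"
            )


def read_feature_table(path) -> list[FeatureVector]:
    vectors: list[FeatureVector] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _FEATURE_COLUMNS:
            raise ParseError(f"{path}: unexpected feature-table header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_FEATURE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: wrong column count")
            region = Region(
                parts[0],
                int(parts[1]),
                int(parts[2]),
                parts[4],
                parts[3],
                source_id=None if parts[5] == "." else parts[5],
            )
            vectors.append(
                FeatureVector(
                    region,
                    float(parts[6]),
                    float(parts[7]),
                    float(parts[8]),
                    float(parts[9]),
                    float(parts[10]),
                    autocorr_imputed=bool(int(parts[11])),
                    variance_imputed=bool(int(parts[12])),
                    motif_imputed=bool(int(parts[13])),
                )
            )
    return vectors


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame (the classifier's tabular input)."""
    return pd.DataFrame(
        {
            "chrom": [v.region.chrom for v in vectors],
            "start": [v.region.start for v in vectors],
            "end": [v.region.end for v in vectors],
            "region_class": [v.region.region_class for v in vectors],
            "label": [v.label for v in vectors],
            "source_id": [v.region.source_id for v in vectors],
            "mean_meth": [v.mean_meth for v in vectors],
            "meth_variance": [v.meth_variance for v in vectors],
            "autocorr": [v.autocorr for v in vectors],
            "cpg_density": [v.cpg_density for v in vectors],
            "motif_score": [v.motif_score for v in vectors],
        }
    )
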
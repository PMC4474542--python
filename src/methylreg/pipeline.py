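"""End-to-end orchestration: inputs (real or simulated) -> matched
backgrounds -> features -> motif enrichment -> cross-validated SVM -> report.

Every run is a pure function of (inputs, config, seed) and emits a manifest
whose per-stage record counts must reconcile.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import background, classify, features, io as mio, motifs
from . import simulate as simdata
from .core import (
    Genome,
    MethylRegError,
    RegionSet,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-mappable)."""

    outdir: str
    seed: int = 0
    # simulated inputs ...
    preset: str | None = None  # "promoter" | "enhancer"
    generator: dict = field(default_factory=dict)
    # ... or real inputs
    positives_bed: str | None = None
    methylome_paths: list[str] = field(default_factory=list)
    genome_fasta: str | None = None
    annotation_path: str | None = None
    expression_path: str | None = None
    region_class: str = "promoter"
    min_coverage: int = 5
    # analysis parameters
    n_per_region: int = 20
    folds: int = 10
    cost: float = 10.0
    degree: int = 2
    features: str = "all"  # "all" or a comma-separated subset, e.g. "mean_meth"
    max_lag: int = 2000
    motif_alpha: float = 1e-5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.preset is None:
            missing = [
                name
                for name, value in [
                    ("positives_bed", self.positives_bed),
                    ("methylome_paths", self.methylome_paths),
                    ("genome_fasta", self.genome_fasta),
                    ("annotation_path", self.annotation_path),
                ]
                if not value
            ]
            if missing:
                raise ValidationError(f"config missing required input field(s): {missing}")
        elif self.preset not in ("promoter", "enhancer"):
            raise ValidationError(f"unknown preset {self.preset!r}")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    input_digests: dict
    counts: dict
    outputs: dict
    auc: dict

    def reconcile(self) -> None:
        c = self.counts
        if c["regions_out"] != c["regions_in"] - c["regions_dropped"]:
            raise MethylRegError(
                f"manifest counts do not reconcile: {c['regions_out']} != "
                f"{c['regions_in']} - {c['regions_dropped']}"
            )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    """Resolve inputs: simulate a preset or read the configured files."""
    digests = {}
    if config.preset is not None:
        gen_kwargs = dict(config.generator)
        gen_kwargs.setdefault("seed", config.seed)
        gcfg = (
            simdata.promoter_preset(**gen_kwargs)
            if config.preset == "promoter"
            else simdata.enhancer_preset(**gen_kwargs)
        )
        ds = simdata.simulate_dataset(gcfg)
        digests["generator_config"] = hashlib.sha256(
            json.dumps(dataclasses.asdict(gcfg), sort_keys=True, default=list).encode()
        ).hexdigest()
        return ds.genome, ds.genes, ds.regions, ds.methylomes, ds.expression, digests

    genome = Genome.from_fasta(config.genome_fasta)
    genes = mio.read_gene_annotation(config.annotation_path)
    positives = mio.read_regions(config.positives_bed, "positive", config.region_class, genome)
    methylomes = [
        mio.read_methylome(p, min_coverage=config.min_coverage) for p in config.methylome_paths
    ]
    expression = mio.read_expression(config.expression_path) if config.expression_path else None
    for key in ("positives_bed", "genome_fasta", "annotation_path", "expression_path"):
        p = getattr(config, key)
        if p:
            digests[key] = _digest(p)
    for p in config.methylome_paths:
        digests[f"methylome:{Path(p).name}"] = _digest(p)
    return genome, genes, positives, methylomes, expression, digests


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; writes result files under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        genome, genes, positives, methylomes, expression, digests = _load_inputs(config)
        reference = methylomes[0]
        chrom_lengths = {c: genome.length(c) for c in genome.chroms}
        for r in positives:
            if r.target_gene is None:
                try:
                    r.target_gene = background.assign_target_gene(r, genes)
                except MethylRegError:
                    pass  # sampler will skip and log

        stage = "sample-background"
        pool = background.sample_matched_regions(
            positives,
            genes,
            n_per_region=config.n_per_region,
            seed=config.seed + 1,
            chrom_lengths=chrom_lengths,
        )
        negatives = background.subsample_negatives(pool, seed=config.seed + 2)

        stage = "features"
        combined_all = RegionSet(list(positives) + list(negatives))
        kept, dropped = [], 0
        for r in combined_all:
            pos, _ = reference.sites_in(r.chrom, r.start, r.end)
            if len(pos):
                kept.append(r)
            else:
                dropped += 1
        combined = RegionSet(kept)

        stage = "motifs"
        bg_counts, bg_total = motifs.count_motifs(pool, genome, reference)
        scorer = motifs.FoldAwareMotifScorer(
            combined, genome, reference, bg_counts, bg_total, alpha=config.motif_alpha
        )
        full_table = scorer.table_for(range(len(combined)))
        motif_scores = scorer.scores(full_table)

        stage = "features"
        grand_mean, grand_var = features.pooled_site_stats(combined, reference)
        vectors = []
        for i, region in enumerate(combined):
            vectors.append(
                features.build_feature_vector(
                    region,
                    methylomes,
                    genome,
                    lambda _r, _i=i: (float(motif_scores[_i]), not scorer.region_kmers[_i]),
                    grand_mean,
                    grand_var,
                    config.max_lag,
                )
            )
        table = mio.feature_frame(vectors)

        stage = "predict"
        model = classify.RegulatoryRegionModel(table, motif_refit=scorer.refit)
        subset = None if config.features == "all" else config.features.split(",")
        results = model.fit(
            folds=config.folds,
            seed=config.seed,
            kernel_degree=config.degree,
            cost=config.cost,
            feature_subset=subset,
        )

        stage = "report"
        mio.write_feature_table(vectors, outdir / "feature_table.tsv")
        full_table.to_tsv(outdir / "motif_table.tsv")
        results.roc.to_frame().to_csv(outdir / "roc.tsv", sep="\t", index=False)
        with open(outdir / "auc.txt", "w") as fh:
            fh.write(f"auc\t{results.auc:.6f}\n")
            fh.write(f"auc_fold_mean\t{np.mean(results.fold_aucs):.6f}\n")
        results.information_gain.to_csv(
            outdir / "feature_ig.tsv", sep="\t", header=["information_gain_bits"]
        )
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")

        if expression is not None:
            _write_expression_correlations(
                outdir / "expression_correlation.tsv", combined, methylomes, expression
            )

        counts = {
            "positives_in": len(positives),
            "background_pool": len(pool),
            "negatives": len(negatives),
            "regions_in": len(combined_all),
            "regions_dropped": dropped,
            "regions_out": len(vectors),
            "motifs_tested": int(full_table.n_tests),
            "motif_windows_fg": int(full_table.fg_total),
            "motif_windows_bg": int(full_table.bg_total),
        }
        outputs = {
            name: str(outdir / name)
            for name in (
                "feature_table.tsv",
                "motif_table.tsv",
                "roc.tsv",
                "auc.txt",
                "feature_ig.tsv",
                "summary.txt",
            )
        }
        manifest = RunManifest(
            config=dataclasses.asdict(config),
            seed=config.seed,
            input_digests=digests,
            counts=counts,
            outputs=outputs,
            auc={
                "pooled": results.auc,
                "per_fold": results.fold_aucs,
                "information_gain": results.information_gain.to_dict(),
            },
        )
        manifest.reconcile()
        manifest.write(outdir / "manifest.json")
        return manifest
    except MethylRegError as exc:
        raise MethylRegError(f"stage {stage!r} failed: {exc}") from exc


def _write_expression_correlations(path, regions, methylomes, expression) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\ttarget_gene\tpearson_r\n")
        for r in regions:
            if r.target_gene is None:
                continue
            try:
                rho = features.expression_correlation(r, methylomes, expression)
            except MethylRegError:
                continue
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{r.target_gene}\t{rho!r}\n")
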
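"""End-to-end analyses over files: promoter staging, dosage statistics,
and track export.

Each run function takes a :class:`RunConfig` (loadable from YAML), reads
the standard-format inputs (GTF, fragment BEDs, chrom.sizes, atlas TSVs),
executes the corresponding analysis, writes TSV/bedGraph outputs under
``out_dir``, and records a run manifest with a config hash and per-stage
record counts so every output is re-derivable from config + inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann_mod
from . import atlas as atlas_mod
from . import chromstats, quant

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Bad or incomplete run configuration (caught before any compute)."""


class StageError(RuntimeError):
    """A named pipeline stage failed."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage '{name}' failed: {exc}") from exc


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    ``fragment_beds`` maps a library label (genotype or tissue condition)
    to its fragment BED path.  Defaults mirror the promoter-window,
    binning, clustering and selection parameters of the analysis this
    package implements: −200..+500 bp windows, 20-kb bins, k-means k = 10,
    log2 enrichment threshold 1.
    """

    gtf: str = ""
    chrom_sizes: str = ""
    fragment_beds: dict[str, str] = field(default_factory=dict)
    atlas_matrix: str = ""
    cluster_annotation: str = ""
    consensus_lengths: str = ""
    out_dir: str = "germtag_out"

    up: int = 200
    down: int = 500
    oriented: bool = True
    bin_size: int = 20_000
    k: int = 10
    restarts: int = 50
    seed: int = 0
    pseudocount_expr: float = 0.01  # ε for the germline/somatic ratio
    pseudocount_ratio: float = 1.0  # ρ for the log2 bin ratio
    enrichment_threshold: float = 1.0
    max_upstream_dist: int = 1000
    genotype_triple: tuple[str, str, str] = ("bam", "aly", "wildtype")
    condition_pair: tuple[str, str] = ("spermatocyte", "wing")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.genotype_triple = tuple(cfg.genotype_triple)
        cfg.condition_pair = tuple(cfg.condition_pair)
        return cfg

    def require(self, *fields_: str, labels: tuple[str, ...] = ()) -> None:
        for f in fields_:
            if not getattr(self, f):
                raise ConfigError(f"config field '{f}' is required for this analysis")
        missing = [l for l in labels if l not in self.fragment_beds]
        if missing:
            raise ConfigError(f"fragment library label(s) missing from config: {missing}")
        if len(set(self.fragment_beds)) != len(self.fragment_beds):
            raise ConfigError("duplicate fragment library labels")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, analysis: str, counts: dict, out_dir: Path) -> None:
    manifest = {"analysis": analysis, "config_sha256": _config_hash(cfg), "counts": counts}
    (out_dir / f"{analysis}_manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def _load_libraries(cfg: RunConfig, labels, chrom_sizes) -> dict[str, quant.FragmentLibrary]:
    libs = {}
    for label in labels:
        libs[label] = quant.load_fragments(cfg.fragment_beds[label], label, chrom_sizes)
        log.info("loaded %d fragments for %s (%d rejected)", len(libs[label]), label, libs[label].n_rejected)
    return libs


def run_promoter_staging(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Promoter score table with cross-genotype z-scores and stage labels.

    Joins the promoter table (TSS windows, upstream-neighbor flags), the
    per-genotype CPM and z-scores over the −up..+down windows, and the
    expression-derived stage of each gene.
    """
    cfg.require("gtf", "chrom_sizes", "atlas_matrix", "cluster_annotation", labels=cfg.genotype_triple)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("annotation"):
        transcripts = ann_mod.parse_gene_models(cfg.gtf)
        chrom_sizes = ann_mod.read_chrom_sizes(cfg.chrom_sizes)
        promoters = ann_mod.derive_promoters(transcripts) if transcripts else []
        ptable = ann_mod.promoter_table(
            promoters, chrom_sizes, up=cfg.up, down=cfg.down,
            max_dist=cfg.max_upstream_dist, oriented=cfg.oriented,
        ) if promoters else pd.DataFrame()
        log.info("derived %d promoters from %d transcripts", len(ptable), len(transcripts))

    with _stage("atlas"):
        atlas = atlas_mod.read_atlas(cfg.atlas_matrix, cfg.cluster_annotation)
        gene_universe = pd.Index(sorted({t.gene_id for t in transcripts}))
        summary = atlas_mod.germline_somatic_summary(
            atlas, genes=gene_universe, pseudocount=cfg.pseudocount_expr
        )
        selected, missing = atlas_mod.select_germline_enriched(summary, cfg.enrichment_threshold)
        log.info("%d germline-enriched genes; %d genes absent from atlas", len(selected), len(missing))

    with _stage("staging"):
        staging = atlas_mod.stage_by_kmeans(
            atlas, selected, k=cfg.k, seed=cfg.seed, restarts=cfg.restarts
        ) if len(selected) >= cfg.k else None

    with _stage("quantification"):
        libs = _load_libraries(cfg, cfg.genotype_triple, chrom_sizes)
        if ptable.empty:
            log.warning("empty promoter table; writing empty outputs")
            scores = pd.DataFrame()
        else:
            windows = ptable.rename(columns={"window_start": "start", "window_end": "end"})[
                ["gene_id", "gene_name", "chrom", "start", "end", "strand",
                 "upstream_neighbor", "upstream_distance", "upstream_within_1kb"]
            ]
            scores = quant.score_table(list(libs.values()), windows)
            z = quant.genotype_zscores(
                scores.rename(columns={f"cpm_{l}": l for l in cfg.genotype_triple}),
                cfg.genotype_triple,
            )
            scores = pd.concat([scores, z], axis=1)
            stages = staging.stages if staging is not None else pd.Series(dtype=object)
            scores["stage"] = scores["gene_id"].map(stages).fillna(atlas_mod.UNASSIGNED)

    scores.to_csv(out_dir / "promoter_scores.tsv", sep="\t", index=False)
    stages = staging.stages if staging is not None else pd.Series(dtype=object)
    atlas_mod.write_gene_summary(summary, stages, out_dir / "gene_summary.tsv", cfg.enrichment_threshold)
    _write_manifest(cfg, "staging", {
        "transcripts": len(transcripts),
        "promoters": len(ptable),
        "germline_enriched": len(selected),
        "genes_missing_expression": len(missing),
        "fragments": {l: len(lib) for l, lib in libs.items()},
    }, out_dir)
    return {"promoter_scores": scores, "gene_summary": summary}


def dosage_from_libraries(
    genes: pd.DataFrame,
    libs: dict[str, quant.FragmentLibrary],
    filter_zero: bool = True,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Gene-body dosage statistics from in-memory libraries.

    ``genes`` needs gene_id, chrom, start, end.  Pipeline order follows the
    boxplot procedure: CPKM per gene and condition, discard genes with a
    zero score in any condition, double hemizygous scores, scale to the
    major-autosome median.  Returns the per-gene table and one per-class
    summary frame per condition.
    """
    tbl = genes.reset_index(drop=True).copy()
    tbl["length"] = tbl["end"] - tbl["start"]
    tbl["chrom_class"] = [c.value for c in chromstats.classify_genes(tbl["chrom"])]
    cpkm_cols = {}
    for label, lib in libs.items():
        raw = quant.count_overlaps(lib, tbl)
        tbl[f"raw_{label}"] = raw
        cpkm_cols[label] = pd.Series(
            quant.cpkm(raw, lib.library_size, tbl["length"].to_numpy()), index=tbl.index
        )
        tbl[f"cpkm_{label}"] = cpkm_cols[label]
    if filter_zero:
        kept = chromstats.expressed_gene_filter(cpkm_cols)
        tbl = tbl.loc[kept]
    classes = chromstats.classify_genes(tbl["chrom"])
    summaries = {}
    for label in libs:
        per_copy = chromstats.per_copy_scores(tbl[f"cpkm_{label}"], classes)
        scaled = chromstats.scale_to_autosome_median(per_copy, classes)
        tbl[f"per_copy_{label}"] = per_copy
        tbl[f"scaled_{label}"] = scaled
        summaries[label] = chromstats.chromosome_summary(scaled, classes)
    return tbl.reset_index(drop=True), summaries


def run_dosage_analysis(cfg: RunConfig) -> dict:
    """Gene CPKM → expressed filter → per-copy → autosome-median scaling,
    plus 20-kb binned tracks and their log2 ratio for the condition pair."""
    cfg.require("gtf", "chrom_sizes", labels=cfg.condition_pair)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("annotation"):
        transcripts = ann_mod.parse_gene_models(cfg.gtf)
        chrom_sizes = ann_mod.read_chrom_sizes(cfg.chrom_sizes)
        spans = ann_mod.gene_spans(transcripts)

    with _stage("quantification"):
        libs = _load_libraries(cfg, cfg.condition_pair, chrom_sizes)
        per_gene, summaries = dosage_from_libraries(spans, libs)

    with _stage("tracks"):
        a_label, b_label = cfg.condition_pair
        track_a = quant.binned_coverage(libs[a_label], chrom_sizes, cfg.bin_size)
        track_b = quant.binned_coverage(libs[b_label], chrom_sizes, cfg.bin_size)
        ratio = quant.log2_bin_ratio(track_a, track_b, cfg.pseudocount_ratio)
        quant.write_bedgraph(track_a, out_dir / f"{a_label}.bedgraph")
        quant.write_bedgraph(track_b, out_dir / f"{b_label}.bedgraph")
        quant.write_bedgraph(ratio, out_dir / f"log2_{a_label}_over_{b_label}.bedgraph")

    per_gene.to_csv(out_dir / "dosage_per_gene.tsv", sep="\t", index=False)
    summary_frames = []
    for label, s in summaries.items():
        s = s.reset_index()
        s.insert(0, "condition", label)
        summary_frames.append(s)
    summary_tbl = pd.concat(summary_frames, ignore_index=True)
    summary_tbl.to_csv(out_dir / "dosage_summary.tsv", sep="\t", index=False)
    _write_manifest(cfg, "dosage", {
        "genes": len(spans),
        "genes_after_filter": len(per_gene),
        "fragments": {l: len(lib) for l, lib in libs.items()},
    }, out_dir)
    return {"per_gene": per_gene, "summaries": summaries, "ratio": ratio}


def run_track_export(cfg: RunConfig) -> list[Path]:
    """One CPM-scaled binned bedGraph per configured library."""
    cfg.require("chrom_sizes")
    if not cfg.fragment_beds:
        raise ConfigError("no fragment libraries configured")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom_sizes = ann_mod.read_chrom_sizes(cfg.chrom_sizes)
    paths = []
    with _stage("tracks"):
        libs = _load_libraries(cfg, list(cfg.fragment_beds), chrom_sizes)
        for label, lib in libs.items():
            track = quant.binned_coverage(lib, chrom_sizes, cfg.bin_size)
            path = out_dir / f"{label}.bedgraph"
            quant.write_bedgraph(track, path)
            paths.append(path)
    _write_manifest(cfg, "tracks", {"fragments": {l: len(lib) for l, lib in libs.items()}}, out_dir)
    return paths
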
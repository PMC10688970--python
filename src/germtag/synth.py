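"""Synthetic annotations, fragment libraries, and expression atlases.

The generator emulates the statistical structure that the quantification
pipeline assumes, with planted ground truth for recovery tests:

* a scaled-down male fly genome — four major autosome arms, the small
  fourth chromosome, and the hemizygous X and Y — carrying non-overlapping
  single-transcript genes;
* per-condition chromosome enrichment factors f_c acting multiplicatively
  on per-copy fragment rates (e.g. f_X = 2 models a dosage-compensated X in
  somatic tissue; f_Y near 0 vs ≫ 1 models the heterochromatic-to-active
  switch of the Y between soma and spermatocytes);
* per-gene Poisson fragment counts with rate copies × per-copy rate × f_c,
  expression-coupled through a lognormal per-gene amplitude shared with the
  expression atlas, plus a uniform genomic background;
* a staged expression atlas over 18 ordered germline clusters, 21 somatic
  clusters and one unannotated cluster, with five archetypal "bump"
  profiles along the germline order (and five mirrored somatic archetypes)
  so that the planted stage partition is recoverable.

Everything downstream of a fixed seed is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from .annotation import parse_gene_models
from .quant import FragmentLibrary

__all__ = [
    "ChromSpec",
    "SyntheticConfig",
    "SyntheticAnnotation",
    "simulate_annotation",
    "simulate_fragment_library",
    "simulate_expression_atlas",
    "simulate_transposon_table",
]

STAGES = (1, 2, 3, 4, 5)
SOMATIC = "somatic"


@dataclass(frozen=True)
class ChromSpec:
    """Length, gene count, gene-length bounds and copy number of one
    synthetic chromosome."""

    length: int
    n_genes: int
    gene_len: tuple[int, int] = (2_000, 6_000)
    copies: int = 2


def _default_chromosomes() -> dict[str, ChromSpec]:
    # Scaled-down genome: 0.5-2 Mb scaffolds; Y genes long (the real Y
    # fertility factors span megabases) so gene bodies tile most Y bins.
    arm = ChromSpec(length=2_000_000, n_genes=120)
    return {
        "2L": arm,
        "2R": arm,
        "3L": arm,
        "3R": arm,
        "4": ChromSpec(length=500_000, n_genes=10),
        "X": ChromSpec(length=1_500_000, n_genes=100, copies=1),
        "Y": ChromSpec(length=800_000, n_genes=12, gene_len=(55_000, 64_000), copies=1),
    }


def _default_condition_factors() -> dict[str, dict[str, float]]:
    # wing: somatic tissue — compensated X (f=2), near-silent Y
    # spermatocyte: uncompensated X (f=1), strongly activated Y
    return {
        "wing": {"X": 2.0, "Y": 0.05},
        "spermatocyte": {"X": 1.0, "Y": 8.0, "4": 0.5},
        "testis": {"X": 1.5, "Y": 2.0},
    }


def _default_stage_weights() -> dict[str, dict]:
    # Stage-arrest genotype trio: bam testes enrich spermatogonia (stage 1),
    # aly testes early/mid spermatocytes (2-3), wildtype late stages (4-5).
    return {
        "bam": {1: 10.0, 2: 2.0, 3: 1.0, 4: 1.0, 5: 1.0, SOMATIC: 1.0},
        "aly": {1: 2.0, 2: 10.0, 3: 8.0, 4: 2.0, 5: 1.0, SOMATIC: 1.0},
        "wildtype": {1: 1.0, 2: 4.0, 3: 6.0, 4: 10.0, 5: 10.0, SOMATIC: 1.0},
    }


@dataclass
class SyntheticConfig:
    """Planted parameters of a simulation.

    ``rate_per_kb`` is the per-copy fragment rate per kilobase of gene body
    for an amplitude-1 gene; with the default gene lengths of 2-6 kb this
    puts expected per-gene fragment counts in the 60-360 range for diploid
    genes, comfortably above Poisson noise.  ``noise_sd`` is the additive
    profile noise of the atlas, expressed relative to the per-gene
    amplitude; the archetype bumps have unit height, so the default 0.1
    keeps between-archetype separation an order of magnitude above noise.
    """

    chromosomes: dict[str, ChromSpec] = field(default_factory=_default_chromosomes)
    condition_factors: dict[str, dict[str, float]] = field(default_factory=_default_condition_factors)
    stage_weights: dict[str, dict] = field(default_factory=_default_stage_weights)
    rate_per_kb: float = 15.0
    amplitude_sigma: float = 0.5
    germline_fraction: float = 0.4
    background_fraction: float = 0.1
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 100.0
    fragment_length_bounds: tuple[int, int] = (50, 700)
    n_germline_clusters: int = 18
    n_somatic_clusters: int = 21
    include_unannotated: bool = True
    bump_width: float = 2.0
    noise_sd: float = 0.1
    somatic_baseline: float = 0.02
    atlas_missing_fraction: float = 0.05

    def factor(self, condition: str, chrom: str) -> float:
        return self.condition_factors.get(condition, {}).get(chrom, 1.0)

    def stage_weight(self, condition: str, stage) -> float:
        return self.stage_weights.get(condition, {}).get(stage, 1.0)


@dataclass
class SyntheticAnnotation:
    """Synthetic gene models plus the planted per-gene truth.

    ``genes`` has one row per gene: gene_id, gene_name, chrom, start, end
    (0-based half-open), strand, length, copies, stage (1-5 or "somatic"),
    amplitude, per_copy_rate (expected fragments per copy at f = 1).
    """

    genes: pd.DataFrame
    chrom_sizes: dict[str, int]
    config: SyntheticConfig

    def to_gtf(self) -> str:
        """Emit FlyBase-dialect GTF (1-based inclusive), one mRNA with two
        exons per gene, so parsers must take min/max over features."""
        lines = []
        for g in self.genes.itertuples():
            start1, end1 = g.start + 1, g.end
            mid = (start1 + end1) // 2
            attrs = (
                f'gene_id "{g.gene_id}"; gene_symbol "{g.gene_name}"; '
                f'transcript_id "{g.gene_id}-RA"; transcript_symbol "{g.gene_name}-RA";'
            )
            for feat, s, e in (
                ("mRNA", start1, end1),
                ("exon", start1, mid),
                ("exon", min(mid + 1, end1), end1),
            ):
                lines.append(
                    f"{g.chrom}\tgermtag_synth\t{feat}\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}"
                )
        return "\n".join(lines) + "\n"

    def chrom_sizes_text(self) -> str:
        return "".join(f"{c}\t{l}\n" for c, l in self.chrom_sizes.items())

    def truth_json(self) -> str:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "condition_factors": self.config.condition_factors,
        }
        return json.dumps(payload, indent=1)


def _place_genes(rng: np.random.Generator, spec: ChromSpec, chrom: str) -> pd.DataFrame:
    lengths = rng.integers(spec.gene_len[0], spec.gene_len[1] + 1, size=spec.n_genes)
    free = spec.length - int(lengths.sum())
    if free < 0:
        raise ValueError(
            f"chromosome {chrom} ({spec.length} bp) too small for "
            f"{spec.n_genes} genes totalling {lengths.sum()} bp"
        )
    gaps = np.floor(rng.dirichlet(np.ones(spec.n_genes + 1)) * free).astype(int)
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
            "length": lengths,
            "copies": spec.copies,
        }
    )


def simulate_annotation(config: SyntheticConfig, seed: int) -> SyntheticAnnotation:
    """Generate non-overlapping gene models with planted stages and rates.

    Genes are placed left to right with Dirichlet-distributed gaps (never
    overlapping), assigned a random strand, a stage (germline archetype 1-5
    with probability ``germline_fraction``, else somatic; Y-linked genes are
    always late germline, echoing the fertility factors), a lognormal
    amplitude, and a per-copy fragment rate ∝ amplitude × gene length.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, spec in config.chromosomes.items():
        if spec.n_genes > 0:
            frames.append(_place_genes(rng, spec, chrom))
    genes = pd.concat(frames, ignore_index=True)
    n = len(genes)
    genes.insert(0, "gene_id", [f"SG{i + 1:05d}" for i in range(n)])
    genes.insert(1, "gene_name", [f"sg{i + 1}" for i in range(n)])

    is_germ = rng.random(n) < config.germline_fraction
    stage = np.where(is_germ, rng.integers(1, 6, size=n), 0)
    stage = stage.astype(object)
    stage[stage == 0] = SOMATIC
    on_y = (genes["chrom"] == "Y").to_numpy()
    stage[on_y] = rng.choice([4, 5], size=int(on_y.sum()))
    genes["stage"] = stage
    genes["amplitude"] = rng.lognormal(mean=0.0, sigma=config.amplitude_sigma, size=n)
    genes["per_copy_rate"] = config.rate_per_kb * genes["length"] / 1000.0 * genes["amplitude"]

    chrom_sizes = {c: s.length for c, s in config.chromosomes.items()}
    return SyntheticAnnotation(genes=genes, chrom_sizes=chrom_sizes, config=config)


def _fragment_coords(
    rng: np.random.Generator,
    mids: np.ndarray,
    chrom_len: np.ndarray,
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray]:
    lens = rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=len(mids))
    lo, hi = config.fragment_length_bounds
    lens = np.clip(np.round(lens), lo, hi).astype(np.int64)
    starts = mids - lens // 2
    starts = np.clip(starts, 0, np.maximum(chrom_len - lens, 0))
    ends = np.minimum(starts + lens, chrom_len)
    return starts, ends


def simulate_fragment_library(
    config: SyntheticConfig,
    ann: SyntheticAnnotation,
    condition: str,
    seed: int,
    depth: int | None = None,
    mode: str = "body",
) -> FragmentLibrary:
    """Sample a mapped-fragment library for one condition/genotype.

    Per gene, the fragment count is Poisson with rate
    copies × per_copy_rate × f_chrom(condition) × stage weight(condition);
    fragment midpoints are uniform over the gene body (``mode="body"``,
    elongating-polymerase-like), uniform over the −200..+500 promoter
    window (``mode="promoter"``, promoter-mark-like), or a 50:50 mixture of
    a TSS-proximal normal and the gene body (``mode="peaked"``, emulating
    promoter-proximal polymerase accumulation in somatic cells).  A uniform
    genomic background adds ``background_fraction`` of the genic total in
    expectation.  ``depth`` rescales all rates so the expected total
    fragment count equals it; depth 0 yields an empty library.
    """
    if mode not in ("body", "promoter", "peaked"):
        raise ValueError(f"unknown mark mode {mode!r}")
    rng = np.random.default_rng(seed)
    genes = ann.genes
    factors = genes["chrom"].map(lambda c: config.factor(condition, c)).to_numpy()
    weights = genes["stage"].map(lambda s: config.stage_weight(condition, s)).to_numpy()
    lam = genes["copies"].to_numpy() * genes["per_copy_rate"].to_numpy() * factors * weights
    lam_bg_total = config.background_fraction * lam.sum()
    if depth is not None:
        total = lam.sum() + lam_bg_total
        scale = depth / total if total > 0 else 0.0
        lam = lam * scale
        lam_bg_total = lam_bg_total * scale

    counts = rng.poisson(lam)
    chrom_len_of = genes["chrom"].map(ann.chrom_sizes).to_numpy()
    gidx = np.repeat(np.arange(len(genes)), counts)
    gstart = genes["start"].to_numpy()[gidx]
    gend = genes["end"].to_numpy()[gidx]
    strand = genes["strand"].to_numpy()[gidx]
    clen = chrom_len_of[gidx]

    if mode == "body":
        mids = rng.integers(gstart, gend)
    else:
        tss = np.where(strand == "+", gstart, gend - 1)
        wlo = np.where(strand == "+", tss - 200, tss - 500)
        whi = np.where(strand == "+", tss + 501, tss + 201)
        wlo = np.clip(wlo, 0, None)
        whi = np.minimum(whi, clen)
        if mode == "promoter":
            mids = rng.integers(wlo, np.maximum(whi, wlo + 1))
        else:  # peaked: TSS-proximal accumulation over a genic floor
            peak = np.round(rng.normal(tss + np.where(strand == "+", 150, -150), 100.0)).astype(np.int64)
            peak = np.clip(peak, 0, clen - 1)
            body = rng.integers(gstart, gend)
            mids = np.where(rng.random(len(gidx)) < 0.5, peak, body)

    starts, ends = _fragment_coords(rng, mids, clen, config)
    chroms = genes["chrom"].to_numpy()[gidx]

    n_bg = rng.poisson(lam_bg_total)
    if n_bg > 0:
        names = list(ann.chrom_sizes)
        sizes = np.array([ann.chrom_sizes[c] for c in names], dtype=float)
        pick = rng.choice(len(names), size=n_bg, p=sizes / sizes.sum())
        bg_len = np.array([ann.chrom_sizes[names[i]] for i in pick], dtype=np.int64)
        bg_mid = rng.integers(0, bg_len)
        bs, be = _fragment_coords(rng, bg_mid, bg_len, config)
        chroms = np.concatenate([chroms, np.array([names[i] for i in pick], dtype=object)])
        starts = np.concatenate([starts, bs])
        ends = np.concatenate([ends, be])

    frags = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    frags = frags.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    return FragmentLibrary(label=condition, fragments=frags, chrom_sizes=dict(ann.chrom_sizes))


def _bump_profiles(n_clusters: int, n_arch: int, width: float) -> np.ndarray:
    pos = np.arange(n_clusters, dtype=float)
    centers = np.linspace(0.1, 0.9, n_arch) * (n_clusters - 1)
    return np.exp(-((pos[None, :] - centers[:, None]) ** 2) / (2 * width**2))


def simulate_expression_atlas(
    config: SyntheticConfig,
    ann: SyntheticAnnotation,
    seed: int,
) -> tuple[atlas_mod.ExpressionAtlas, pd.Series]:
    """Generate a clusters × genes atlas from the planted gene truth.

    Germline genes of archetype a express amplitude × (bump_a + noise) over
    the ordered germline clusters and a low baseline over somatic clusters;
    somatic genes mirror this with five archetypes over the somatic
    clusters.  A random ``atlas_missing_fraction`` of genes is withheld from
    the atlas, exercising the missing-gene (#N/A) path downstream.  Returns
    the atlas and the planted stage label per simulated gene (including the
    withheld ones).
    """
    rng = np.random.default_rng(seed)
    ng, ns = config.n_germline_clusters, config.n_somatic_clusters
    if ng < len(STAGES):
        raise ValueError("need at least 5 germline clusters for 5 archetypes")
    germ_ids = [f"germline_{i + 1:02d}" for i in range(ng)]
    som_ids = [f"somatic_{i + 1:02d}" for i in range(ns)]
    cluster_ids = germ_ids + som_ids
    roles = [atlas_mod.GERMLINE] * ng + [atlas_mod.SOMATIC] * ns
    if config.include_unannotated:
        cluster_ids.append("unannotated")
        roles.append(atlas_mod.UNANNOTATED)
    annotation = pd.DataFrame(
        {"cluster_id": cluster_ids, "role": roles, "order_index": np.arange(len(cluster_ids))}
    )

    genes = ann.genes
    germ_bumps = _bump_profiles(ng, len(STAGES), config.bump_width)
    som_bumps = _bump_profiles(ns, len(STAGES), config.bump_width)

    n = len(genes)
    stage = genes["stage"].to_numpy()
    amp = genes["amplitude"].to_numpy()
    # somatic genes draw a hidden somatic archetype so k-means at k = 10
    # resolves 5 germline + 5 somatic groups, as in the real configuration
    som_arch = rng.integers(0, len(STAGES), size=n)

    signal = np.full((n, ng + ns), config.somatic_baseline)
    for i, s in enumerate(stage):
        if s == SOMATIC:
            signal[i, ng:] = som_bumps[som_arch[i]]
        else:
            signal[i, :ng] = germ_bumps[int(s) - 1]
    noise = rng.normal(0.0, config.noise_sd, size=signal.shape) if config.noise_sd > 0 else 0.0
    values = amp[:, None] * np.clip(signal + noise, 0.0, None)

    if config.include_unannotated:
        unann = amp[:, None] * rng.uniform(0.0, config.somatic_baseline, size=(n, 1))
        values = np.concatenate([values, unann], axis=1)

    matrix = pd.DataFrame(values.T, index=cluster_ids, columns=genes["gene_id"].to_numpy())
    if config.atlas_missing_fraction > 0:
        n_drop = int(round(config.atlas_missing_fraction * n))
        drop = rng.choice(matrix.columns.to_numpy(), size=n_drop, replace=False)
        matrix = matrix.drop(columns=list(drop))

    truth = pd.Series(stage, index=genes["gene_id"].to_numpy(), name="stage")
    return atlas_mod.ExpressionAtlas(matrix=matrix, annotation=annotation), truth


def simulate_transposon_table(
    config: SyntheticConfig,
    rng_or_seed,
    n_consensi: int = 16,
    length_range: tuple[int, int] = (400, 9_000),
) -> pd.Series:
    """Consensus lengths for a panel of synthetic transposon scaffolds,
    named like repeat-library consensus entries."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_consensi)
    names = [f"SYNTE{i + 1:03d}_consensus" for i in range(n_consensi)]
    return pd.Series(lengths, index=pd.Index(names, name="consensus"), dtype=int)


def simulate_consensus_fragments(
    config: SyntheticConfig,
    consensus_lengths: pd.Series,
    condition: str,
    seed: int,
    rate_per_kb: float | None = None,
    element_factors: Mapping[str, float] | None = None,
) -> FragmentLibrary:
    """Fragment library over transposon consensus scaffolds.

    Each consensus is sampled like a gene body at
    rate_per_kb × length × per-element condition factor, emulating the
    soma-vs-spermatocyte activation contrasts of individual transposon
    families.  The returned library's chromosome table is the consensus
    panel itself.
    """
    rng = np.random.default_rng(seed)
    rate = config.rate_per_kb if rate_per_kb is None else rate_per_kb
    element_factors = element_factors or {}
    lengths = consensus_lengths.to_numpy()
    lam = rate * lengths / 1000.0 * np.array(
        [element_factors.get(c, 1.0) for c in consensus_lengths.index]
    )
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(len(lengths)), counts)
    clen = lengths[idx]
    mids = rng.integers(0, np.maximum(clen, 1))
    starts, ends = _fragment_coords(rng, mids, clen, config)
    frags = pd.DataFrame(
        {"chrom": consensus_lengths.index.to_numpy()[idx], "start": starts, "end": ends}
    ).sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    sizes = {str(c): int(l) for c, l in consensus_lengths.items()}
    return FragmentLibrary(label=condition, fragments=frags, chrom_sizes=sizes)


def annotation_roundtrip_check(ann: SyntheticAnnotation) -> int:
    """Parse the emitted GTF back; returns the transcript count."""
    return len(parse_gene_models(ann.to_gtf()))
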
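"""Canonical synthetic study scenarios with planted, recoverable truth.

These functions bundle the simulation conditions under which the package's
statistics have known expected values, so that recovery can be measured
reproducibly:

* dosage: autosomal genes at 2 copies × rate r with the X either at
  1 copy × 2r (compensated, somatic-tissue-like → median scaled X ≈ 2) or
  1 copy × r (uncompensated, spermatocyte-like → median scaled X ≈ 1);
* staging: the default 5-archetype germline expression structure, scored
  by adjusted Rand index against the planted stage partition;
* Y activation: the Y chromosome's planted factor switching from near 0 in
  soma to ≫ 1 in spermatocytes, recovered as the sign of the per-bin log2
  coverage ratio over Y bins.
"""

from __future__ import annotations

import numpy as np

from . import quant, synth
from .pipeline import dosage_from_libraries

COMPENSATED, UNCOMPENSATED = "compensated", "uncompensated"


def dosage_config(genes_per_class: int = 500) -> synth.SyntheticConfig:
    """Two-condition dosage scenario: ``genes_per_class`` genes on the
    major autosomes (split over the four arms) and on the X.

    rate_per_kb = 25 with 2-6 kb genes keeps expected per-gene fragment
    counts at or above ~50 per copy.
    """
    per_arm = genes_per_class // 4
    arm = synth.ChromSpec(length=2_000_000, n_genes=per_arm, gene_len=(2_000, 6_000))
    chroms = {c: arm for c in ("2L", "2R", "3L", "3R")}
    # X length keeps gene density equal to the arms (16 kb per gene), so
    # neighbor-fragment spillover affects both classes identically
    chroms["X"] = synth.ChromSpec(
        length=16_000 * genes_per_class, n_genes=genes_per_class, gene_len=(2_000, 6_000), copies=1
    )
    # amplitude_sigma = 0: the scenario plants a single per-copy rate per
    # chromosome class (r vs 2r), so every gene of a class shares its rate
    return synth.SyntheticConfig(
        chromosomes=chroms,
        condition_factors={COMPENSATED: {"X": 2.0}, UNCOMPENSATED: {"X": 1.0}},
        stage_weights={},
        rate_per_kb=25.0,
        amplitude_sigma=0.0,
        background_fraction=0.05,
    )


def dosage_x_medians(
    seed: int, n_seeds: int = 10, genes_per_class: int = 500
) -> dict[str, list[float]]:
    """Median autosome-scaled per-copy X score per condition and seed."""
    config = dosage_config(genes_per_class)
    out: dict[str, list[float]] = {COMPENSATED: [], UNCOMPENSATED: []}
    for i in range(n_seeds):
        base = (seed * 1_000 + i * 17) % 2_000_000_000
        ann = synth.simulate_annotation(config, base)
        libs = {
            cond: synth.simulate_fragment_library(config, ann, cond, base + 1 + j)
            for j, cond in enumerate((COMPENSATED, UNCOMPENSATED))
        }
        _, summaries = dosage_from_libraries(
            ann.genes[["gene_id", "chrom", "start", "end"]], libs
        )
        for cond in out:
            out[cond].append(float(summaries[cond].loc["sex_X", "median"]))
    return out


def staging_aris(seed: int, n_seeds: int = 10) -> list[float]:
    """Adjusted Rand index of k-means staging against the planted stage
    partition, one value per seed, on the default ~600-gene genome."""
    from sklearn.metrics import adjusted_rand_score

    from .atlas import SOMATIC_STAGE, stage_by_kmeans

    config = synth.SyntheticConfig(atlas_missing_fraction=0.0)
    aris = []
    for i in range(n_seeds):
        base = (seed * 1_000 + 500 + i * 13) % 2_000_000_000
        ann = synth.simulate_annotation(config, base)
        atlas, truth = synth.simulate_expression_atlas(config, ann, base + 1)
        result = stage_by_kmeans(atlas, list(atlas.genes), k=10, seed=base % 10_000, restarts=50)
        planted = truth.reindex(result.stages.index).map(
            lambda s: SOMATIC_STAGE if s == synth.SOMATIC else int(s)
        )
        aris.append(float(adjusted_rand_score(planted, result.stages)))
    return aris


def y_activation_sign_agreement(
    seed: int, n_seeds: int = 3, bin_size: int = 20_000, pseudocount: float = 1.0
) -> list[float]:
    """Fraction of Y-chromosome bins whose log2(spermatocyte/wing) coverage
    ratio has the planted positive sign, one value per seed."""
    config = synth.SyntheticConfig()
    fracs = []
    for i in range(n_seeds):
        base = (seed * 1_000 + 900 + i * 11) % 2_000_000_000
        ann = synth.simulate_annotation(config, base)
        sperm = synth.simulate_fragment_library(config, ann, "spermatocyte", base + 1)
        wing = synth.simulate_fragment_library(config, ann, "wing", base + 2)
        ratio = quant.log2_bin_ratio(
            quant.binned_coverage(sperm, bin_size=bin_size),
            quant.binned_coverage(wing, bin_size=bin_size),
            pseudocount,
        )
        y = ratio.bins.loc[ratio.bins["chrom"] == "Y", "value"].to_numpy()
        fracs.append(float(np.mean(y > 0)))
    return fracs
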
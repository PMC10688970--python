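import numpy as np
import pytest

from germtag import synth
from germtag.annotation import TranscriptRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20231130)


@pytest.fixture
def simple_transcripts():
    """Hand-built transcript fixture covering strand, duplicate-TSS and
    shared-TSS cases (coordinates 1-based inclusive as in GTF)."""
    return [
        TranscriptRecord("g1-RA", "g1", "gene1", "2L", 100, 900, "+"),
        TranscriptRecord("g1-RB", "g1", "gene1", "2L", 100, 1200, "+"),  # duplicate TSS
        TranscriptRecord("g1-RC", "g1", "gene1", "2L", 400, 1200, "+"),  # alternative TSS
        TranscriptRecord("g2-RA", "g2", "gene2", "2L", 100, 700, "+"),  # shares TSS with g1
        TranscriptRecord("g3-RA", "g3", "gene3", "2L", 2000, 3000, "-"),
        TranscriptRecord("g4-RA", "g4", "gene4", "3R", 500, 1500, "+"),  # isolated chromosome
    ]


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down genome for fast end-to-end tests."""
    return synth.SyntheticConfig(
        chromosomes={
            "2L": synth.ChromSpec(length=400_000, n_genes=30),
            "2R": synth.ChromSpec(length=400_000, n_genes=30),
            "3L": synth.ChromSpec(length=400_000, n_genes=30),
            "3R": synth.ChromSpec(length=400_000, n_genes=30),
            "4": synth.ChromSpec(length=200_000, n_genes=5),
            "X": synth.ChromSpec(length=400_000, n_genes=25, copies=1),
            "Y": synth.ChromSpec(length=400_000, n_genes=4, gene_len=(40_000, 60_000), copies=1),
        },
    )


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_config):
    """A complete synthetic dataset on disk: GTF, chrom.sizes, five
    fragment BEDs, atlas matrix + cluster annotation, planted truth."""
    out = tmp_path_factory.mktemp("dataset")
    config = small_config
    ann = synth.simulate_annotation(config, 7)
    (out / "annotation.gtf").write_text(ann.to_gtf())
    (out / "chrom.sizes").write_text(ann.chrom_sizes_text())
    atlas, truth = synth.simulate_expression_atlas(config, ann, 8)
    atlas.matrix.to_csv(out / "atlas_matrix.tsv", sep="\t", index_label="cluster_id")
    atlas.annotation.reset_index().to_csv(out / "cluster_annotation.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth_stages.tsv", sep="\t", header=True, index_label="gene_id")
    genotypes = {"bam", "aly", "wildtype"}
    for i, label in enumerate(["bam", "aly", "wildtype", "wing", "spermatocyte"]):
        mode = "promoter" if label in genotypes else "body"
        lib = synth.simulate_fragment_library(config, ann, label, 20 + i, mode=mode)
        lib.fragments.to_csv(out / f"{label}.bed", sep="\t", header=False, index=False)
    return {"dir": out, "ann": ann, "truth": truth, "config": config}
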
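"""Chromosome-scale dosage statistics.

In male flies the X and Y are present in one copy while the autosomes
(including the small fourth chromosome) are diploid.  To compare polymerase
or mark density per gene copy, scores of X- and Y-linked genes are doubled,
and all scores are then scaled to the median per-copy score of genes on the
second and third chromosome arms.  Under dosage compensation the median
scaled X score sits near 2 (one copy working twice as hard); without
compensation it sits near 1.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import ChromosomeClass, classify_chromosome

log = logging.getLogger(__name__)

__all__ = [
    "per_copy_scores",
    "scale_to_autosome_median",
    "expressed_gene_filter",
    "chromosome_summary",
    "classify_genes",
]

_HEMIZYGOUS = (ChromosomeClass.SEX_X, ChromosomeClass.SEX_Y)


def classify_genes(chroms: pd.Series) -> pd.Series:
    """Chromosome class per gene from its chromosome name."""
    return chroms.map(classify_chromosome)


def per_copy_scores(scores: pd.Series, classes: pd.Series) -> pd.Series:
    """Double hemizygous (X, Y) scores to per-copy densities.

    Autosomes — including the fourth chromosome, which is diploid despite
    its X-derived history — are unchanged.
    """
    classes = classes.reindex(scores.index)
    if classes.isna().any():
        raise ValueError("every gene must carry a chromosome class")
    factor = classes.isin(_HEMIZYGOUS).map({True: 2.0, False: 1.0})
    return scores * factor


def scale_to_autosome_median(per_copy: pd.Series, classes: pd.Series) -> pd.Series:
    """Divide every score by the median per-copy score of major-autosome
    genes, so that the scaled major-autosome median is exactly 1."""
    classes = classes.reindex(per_copy.index)
    auto = per_copy[classes == ChromosomeClass.MAJOR_AUTOSOME]
    if auto.empty:
        raise ValueError("no major-autosome genes to define the scaling median")
    med = float(auto.median())
    if med <= 0:
        raise ValueError("major-autosome median is zero; cannot scale")
    return per_copy / med


def expressed_gene_filter(tables: Mapping[str, pd.Series]) -> pd.Index:
    """Genes with score > 0 in *every* supplied condition.

    With a single condition this degenerates to score > 0.  The gene
    universe must agree across conditions.
    """
    it = iter(tables.items())
    name, first = next(it)
    keep = first > 0
    for name, s in it:
        if not s.index.equals(keep.index):
            s = s.reindex(keep.index)
        keep &= s > 0
    return keep.index[keep]


def chromosome_summary(scaled: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """Median and quartiles of scaled scores per chromosome class.

    Quantiles use linear interpolation.  Classes with no genes are omitted
    with a log note.
    """
    classes = classes.reindex(scaled.index)
    rows = []
    for cls in ChromosomeClass:
        vals = scaled[classes == cls]
        if vals.empty:
            log.info("chromosome class %s has no genes; omitted from summary", cls.value)
            continue
        q1, med, q3 = np.quantile(vals.to_numpy(), [0.25, 0.5, 0.75])
        rows.append(
            {"chrom_class": cls.value, "n_genes": len(vals), "q1": q1, "median": med, "q3": q3}
        )
    return pd.DataFrame(rows).set_index("chrom_class")
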
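"""Cluster-level expression atlas: germline/somatic summaries and staging.

The atlas is a clusters × genes matrix of mean normalized expression (as
produced by averaging single-nucleus profiles within annotated clusters of
the testis cell atlas), with each cluster annotated as germline, somatic,
or unannotated.  From it we derive per-gene germline (gexp) and somatic
(sexp) means, the pseudocounted log2 germline/somatic ratio used to select
germline-enriched genes, a k-means staging of genes along the germline
developmental order, and per-gene z-score profiles over germline clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

GERMLINE, SOMATIC, UNANNOTATED = "germline", "somatic", "unannotated"
SOMATIC_STAGE = 11  # collapsed "all somatic categories" group label
UNASSIGNED = "unassigned"


@dataclass
class ExpressionAtlas:
    """Clusters × genes mean-expression matrix plus cluster annotation.

    ``annotation`` has one row per cluster with columns ``cluster_id``,
    ``role`` in {germline, somatic, unannotated} and ``order_index`` (the
    developmental order of germline clusters; arbitrary for others).
    """

    matrix: pd.DataFrame
    annotation: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        ann = self.annotation.set_index("cluster_id") if "cluster_id" in self.annotation.columns else self.annotation
        missing = set(self.matrix.index) - set(ann.index)
        if missing:
            raise ValueError(f"clusters without annotation: {sorted(missing)[:5]}")
        bad = set(ann["role"]) - {GERMLINE, SOMATIC, UNANNOTATED}
        if bad:
            raise ValueError(f"unknown cluster roles: {bad}")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("expression matrix has negative entries")
        if self.matrix.index.duplicated().any() or self.matrix.columns.duplicated().any():
            raise ValueError("duplicate cluster or gene ids")
        self.annotation = ann

    def clusters(self, role: str, ordered: bool = False) -> list[str]:
        ann = self.annotation[self.annotation["role"] == role]
        if ordered:
            ann = ann.sort_values("order_index")
        return [c for c in ann.index if c in self.matrix.index]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.columns


def cluster_means(
    cell_matrix: pd.DataFrame,
    labels: pd.Series,
    annotation: pd.DataFrame,
) -> ExpressionAtlas:
    """Average a cells × genes matrix within clusters.

    Every cell must carry a label; every annotated cluster must contain at
    least one cell (an empty cluster is an error naming the cluster).  The
    entry (c, g) is the arithmetic mean of g's normalized expression over
    the cells of c — the normalization of the input is the caller's
    responsibility.
    """
    labels = labels.reindex(cell_matrix.index)
    if labels.isna().any():
        raise ValueError("unlabeled cells present")
    means = cell_matrix.groupby(labels).mean()
    ann_ids = annotation["cluster_id"] if "cluster_id" in annotation.columns else annotation.index
    empty = set(ann_ids) - set(means.index)
    if empty:
        raise ValueError(f"empty cluster(s): {sorted(empty)}")
    return ExpressionAtlas(matrix=means, annotation=annotation.copy())


def germline_somatic_summary(
    atlas: ExpressionAtlas,
    genes: pd.Index | list[str] | None = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene germline/somatic expression summary.

    gexp and sexp are the means over germline and somatic clusters
    (unannotated clusters are excluded from both);
    log2fc = log2((gexp+ε)/(sexp+ε)).  If ``genes`` is given (e.g. the gene
    universe of an annotation), genes absent from the atlas get NaN rows and
    ``present=False`` — the missing-expression marker.
    """
    germ = atlas.clusters(GERMLINE)
    som = atlas.clusters(SOMATIC)
    if not germ or not som:
        raise ValueError("need at least one germline and one somatic cluster")
    gexp = atlas.matrix.loc[germ].mean(axis=0)
    sexp = atlas.matrix.loc[som].mean(axis=0)
    out = pd.DataFrame({"gexp": gexp, "sexp": sexp})
    out["log2fc"] = np.log2((out["gexp"] + pseudocount) / (out["sexp"] + pseudocount))
    out["present"] = True
    if genes is not None:
        out = out.reindex(pd.Index(genes))
        out["present"] = out["present"].eq(True)
    return out


def select_germline_enriched(
    summary: pd.DataFrame, threshold: float = 1.0
) -> tuple[pd.Index, pd.Index]:
    """Genes with log2fc ≥ threshold (inclusive) and expression data present.

    Returns (selected, missing): ``missing`` lists genes absent from the
    atlas, reported separately rather than silently excluded.
    """
    present = summary["present"]
    selected = summary.index[present & (summary["log2fc"] >= threshold)]
    missing = summary.index[~present]
    return selected, missing


def germline_cluster_zscores(
    atlas: ExpressionAtlas, genes: pd.Index | list[str] | None = None
) -> pd.DataFrame:
    """Genes × germline-clusters z-score matrix (population SD per gene).

    Germline clusters are ordered by developmental order.  Zero-variance
    rows are set to all zeros rather than NaN.
    """
    germ = atlas.clusters(GERMLINE, ordered=True)
    if len(germ) < 2:
        raise ValueError("need at least two germline clusters")
    sub = atlas.matrix.loc[germ]
    if genes is not None:
        sub = sub[[g for g in genes if g in sub.columns]]
    x = sub.to_numpy().T  # genes × clusters
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    return pd.DataFrame(z, index=sub.columns, columns=germ)


@dataclass
class StagingResult:
    """Per-gene stage labels plus the raw k-means decomposition."""

    stages: pd.Series  # gene -> 1..n_germline_stages or SOMATIC_STAGE
    kmeans_labels: pd.Series
    centroids: pd.DataFrame  # k × feature clusters
    germline_kclusters: list[int]  # in stage order
    empty_kclusters: list[int]


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return np.where(sd > 0, (x - mu) / sd, 0.0)


def stage_by_kmeans(
    atlas: ExpressionAtlas,
    genes: pd.Index | list[str],
    k: int = 10,
    seed: int = 0,
    restarts: int = 50,
    feature_roles: tuple[str, ...] = (GERMLINE, SOMATIC),
) -> StagingResult:
    """Group genes into expression stages by k-means over cluster profiles.

    Each gene's feature vector is its expression over the annotated clusters
    (germline first, in developmental order, then somatic; the unannotated
    cluster is excluded), z-scored per gene so that profile shape rather
    than absolute level drives the clustering.  Each k-cluster is called
    germline- or somatic-associated by where its centroid mass lies;
    somatic-associated k-clusters collapse into the single group
    ``SOMATIC_STAGE`` (11), germline-associated ones are numbered 1..n by
    their centroid's peak position along the germline cluster order.
    """
    cols: list[str] = []
    for role in feature_roles:
        cols.extend(atlas.clusters(role, ordered=(role == GERMLINE)))
    genes = [g for g in genes if g in atlas.matrix.columns]
    if len(genes) < k:
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    x = _zscore_rows(atlas.matrix.loc[cols, genes].to_numpy().T)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x)
    centroids = pd.DataFrame(km.cluster_centers_, columns=cols)

    occupied = np.unique(labels)
    empty = sorted(set(range(k)) - set(occupied))
    if empty:
        log.warning("k-means left %d of %d clusters empty: %s", len(empty), k, empty)

    germ_cols = atlas.clusters(GERMLINE, ordered=True)
    som_cols = [c for c in cols if c not in germ_cols]
    germ_kclusters = []
    for kc in occupied:
        c = centroids.loc[kc]
        germ_mass = c[germ_cols].mean()
        som_mass = c[som_cols].mean() if som_cols else -np.inf
        if germ_mass > som_mass:
            peak = int(np.argmax(c[germ_cols].to_numpy()))
            germ_kclusters.append((peak, kc))
    germ_kclusters.sort()
    order = [kc for _, kc in germ_kclusters]
    stage_of = {kc: i + 1 for i, kc in enumerate(order)}
    stages = pd.Series(
        [stage_of.get(l, SOMATIC_STAGE) for l in labels], index=pd.Index(genes), name="stage"
    )
    return StagingResult(
        stages=stages,
        kmeans_labels=pd.Series(labels, index=pd.Index(genes), name="kcluster"),
        centroids=centroids,
        germline_kclusters=order,
        empty_kclusters=empty,
    )


def read_atlas(matrix_path, annotation_path) -> ExpressionAtlas:
    """Load a clusters × genes TSV and a cluster annotation TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t")
    return ExpressionAtlas(matrix=matrix, annotation=ann)


def write_gene_summary(summary: pd.DataFrame, stages: pd.Series, path, threshold: float = 1.0) -> None:
    """Write the per-gene table (gexp, sexp, log2fc, enriched, stage)."""
    out = summary.copy()
    out["enriched"] = out["present"] & (out["log2fc"] >= threshold)
    out["stage"] = stages.reindex(out.index).fillna(UNASSIGNED)
    out.to_csv(path, sep="\t", index_label="gene_id", na_rep="#N/A")
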
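"""Per-sample scATAC analysis: QC, clustering, similarity, relapse scores.

Cells pass a simple fragment-count / fraction-in-peaks / doublet-flag filter,
are clustered on their LSI embedding with a shared-nearest-neighbor (SNN)
graph and modularity community detection, and residual healthy immune cells
are removed as whole clusters when they both score high on a lymphoid/
myeloid marker panel and are epigenetically dissimilar to the rest of the
sample. Cluster pseudobulk profiles support diagnosis-vs-relapse chromatin
comparisons, and each cell receives a relapse chromatin score: the sum of
its gene accessibility over the signature's top genes minus the sum over the
bottom genes.
"""

from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse as sp
import scipy.spatial.distance
from sklearn.neighbors import NearestNeighbors

from .gene_scores import RelapseSignature

logger = logging.getLogger(__name__)

# accessibility markers of residual healthy immune populations
DEFAULT_MARKER_PANEL = {
    "Tcell": ["CD89", "TLR4", "GZMA", "CD247"],
    "Bcell": ["TCL1", "CD37"],
    "Monocyte": ["CD209"],
}


def qc_filter_cells(
    qc: pd.DataFrame,
    min_fragments: int = 1000,
    min_frip: float = 0.2,
) -> list[str]:
    """Cells passing fragment-depth and fraction-in-peaks thresholds and not
    flagged as doublets."""
    keep = (
        (qc["total_fragments"] >= min_fragments)
        & (qc["frac_in_peaks"] >= min_frip)
        & ~qc["doublet_flag"].astype(bool)
    )
    return list(qc.loc[keep, "cell"]) if "cell" in qc.columns else list(qc.index[keep])


def snn_graph(coords: np.ndarray, k: int = 20) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = coords.shape[0]
    if n <= k:
        raise ValueError("fewer cells than k neighbors")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    knn = nn.kneighbors_graph(coords, mode="connectivity")
    shared = knn @ knn.T
    shared = shared.tocoo()
    union = 2 * k - shared.data
    jac = shared.data / union
    mask = (shared.row != shared.col) & (jac > 0)
    return sp.csr_matrix((jac[mask], (shared.row[mask], shared.col[mask])), shape=(n, n))


def cluster_cells(
    embedding,
    resolution: float = 1.0,
    seed: int = 0,
    k: int = 20,
) -> pd.Series:
    """SNN + modularity community detection on an LSI embedding.

    ``embedding`` is a :class:`~epiclone.projection.CellEmbedding` or a
    cells x dims DataFrame. Returns a cell -> cluster-id Series, clusters
    numbered from 0; deterministic for a fixed seed.
    """
    if hasattr(embedding, "coords"):
        coords, cells = embedding.coords, embedding.cells
    else:
        coords, cells = embedding.to_numpy(), embedding.index
    adj = snn_graph(coords, k=k)
    src, dst = adj.nonzero()
    sel = src < dst
    w = np.asarray(adj[src[sel], dst[sel]]).ravel()
    g = ig.Graph(n=adj.shape[0],
                 edges=list(zip(src[sel].tolist(), dst[sel].tolist())),
                 edge_attrs={"weight": w.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=2,
    )
    return pd.Series(part.membership, index=cells, name="cluster")


def cluster_pseudobulk(
    clusters: pd.Series, counts: pd.DataFrame
) -> pd.DataFrame:
    """Summed counts per cluster, CPM-normalized (peaks x clusters).

    ``counts`` is cells x peaks; rows are grouped by cluster label.
    """
    out = {}
    for cl, cells in clusters.groupby(clusters):
        total = counts.loc[cells.index].sum(axis=0)
        if total.sum() == 0:
            raise ValueError(f"cluster {cl} has zero total counts")
        out[cl] = total * 1e6 / total.sum()
    return pd.DataFrame(out)


def cluster_pseudobulk_similarity(
    clusters: pd.Series, counts: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise Pearson correlation between cluster pseudobulk profiles.

    Returns the symmetric unit-diagonal correlation matrix and an
    average-linkage hierarchical grouping (scipy linkage on 1 - r), used to
    spot diagnosis clusters that group with relapse clusters.
    """
    pb = cluster_pseudobulk(clusters, counts)
    if pb.shape[1] < 2:
        raise ValueError("need at least 2 clusters")
    corr = pb.corr(method="pearson")
    dist = scipy.spatial.distance.squareform((1 - corr.to_numpy()), checks=False)
    linkage = scipy.cluster.hierarchy.average(dist)
    return corr, linkage


def filter_contaminant_clusters(
    clusters: pd.Series,
    gene_scores: pd.DataFrame,
    counts: pd.DataFrame,
    marker_panel: dict[str, list[str]] | None = None,
    z_threshold: float = 2.0,
    similarity_cutoff: float | None = None,
    max_removed_fraction: float = 0.5,
    force: bool = False,
) -> pd.Series:
    """Drop whole clusters of residual healthy immune cells.

    A cluster is removed only when (a) its mean accessibility over the
    marker panel exceeds the across-cluster mean by ``z_threshold`` standard
    deviations AND (b) it is epigenetically dissimilar to the rest of the
    sample — its mean pseudobulk correlation with other clusters falls below
    ``similarity_cutoff`` (default: 5th percentile of all inter-cluster
    correlations). Removal of more than ``max_removed_fraction`` of cells is
    refused unless ``force`` is set.

    ``gene_scores`` is cells x genes; ``counts`` cells x peaks. Returns the
    retained cells' cluster assignments.
    """
    panel = marker_panel or DEFAULT_MARKER_PANEL
    markers = [g for gl in panel.values() for g in gl]
    present = [g for g in markers if g in gene_scores.columns]
    for g in set(markers) - set(present):
        logger.warning("marker gene %s absent from score matrix; skipped", g)
    if not present:
        return clusters

    marker_mean = gene_scores[present].mean(axis=1).groupby(clusters).mean()
    z = (marker_mean - marker_mean.mean()) / (marker_mean.std(ddof=0) or 1.0)

    corr, _ = cluster_pseudobulk_similarity(clusters, counts)
    np.fill_diagonal(corr.values, np.nan)
    mean_sim = corr.mean(axis=1)
    if similarity_cutoff is None:
        similarity_cutoff = float(np.nanpercentile(corr.to_numpy(), 5))

    drop = z.index[(z > z_threshold) & (mean_sim.loc[z.index] < similarity_cutoff)]
    if len(drop) == 0:
        return clusters
    removed = clusters.isin(drop)
    frac = removed.mean()
    if frac > max_removed_fraction and not force:
        raise ValueError(
            f"contaminant filter would remove {frac:.0%} of cells; pass force=True to override")
    logger.info("removing %d contaminant clusters (%d cells)", len(drop), int(removed.sum()))
    return clusters[~removed]


def relapse_score_cells(
    gene_scores: pd.DataFrame, signature: RelapseSignature
) -> pd.Series:
    """Per-cell relapse chromatin score.

    Sum of gene accessibility over the signature's top genes minus the sum
    over its bottom genes (cells x genes input). Signature genes missing
    from the matrix contribute 0 and are logged.
    """
    if not signature.top_genes or not signature.bottom_genes:
        raise ValueError("empty relapse signature")
    top = [g for g in signature.top_genes if g in gene_scores.columns]
    bot = [g for g in signature.bottom_genes if g in gene_scores.columns]
    missing = (len(signature.top_genes) - len(top)) + (len(signature.bottom_genes) - len(bot))
    if missing:
        logger.info("%d signature genes absent from the score matrix", missing)
    score = gene_scores[top].sum(axis=1) - gene_scores[bot].sum(axis=1)
    return score.rename("relapse_score")

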
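"""Latent semantic indexing of a healthy reference and query projection.

A healthy hematopoietic scATAC reference is embedded by TF-IDF weighting of
the binarized cell x peak matrix followed by truncated SVD (LSI). Disease
cells — real single cells, or pseudo-single cells subsampled from bulk
libraries — are projected into the same space using the *reference* IDF
weights and singular vectors, without refitting, and each query cell is
assigned the majority label of its k nearest reference cells ("closest
normal" cell type).

Because the term-frequency step row-normalizes each cell, the embedding is
depth-invariant: scaling a cell's counts leaves its coordinates unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class LSIModel:
    """Frozen TF-IDF + SVD model of a reference cell x peak matrix."""

    features: pd.Index
    idf: np.ndarray                  # per retained feature
    singular_values: np.ndarray
    components: np.ndarray           # right singular vectors, features x dims
    scale: float
    binarize: bool
    dropped_first: bool


@dataclass
class CellEmbedding:
    cells: pd.Index
    coords: np.ndarray
    source: str  # "reference" | "query"

    def to_frame(self) -> pd.DataFrame:
        cols = [f"LSI{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.cells, columns=cols)


def _tfidf(counts: sp.csr_matrix, idf: np.ndarray, scale: float, binarize: bool) -> sp.csr_matrix:
    X = counts.copy().tocsr().astype(float)
    if binarize:
        X.data = np.ones_like(X.data)
    depth = np.asarray(X.sum(axis=1)).ravel()
    depth[depth == 0] = 1.0
    X = sp.diags(scale / depth) @ X
    return X @ sp.diags(idf)


def fit_lsi(
    counts: pd.DataFrame | sp.spmatrix,
    cells: pd.Index | None = None,
    features: pd.Index | None = None,
    n_components: int = 25,
    scale: float = 1e4,
    binarize: bool = True,
    depth_corr_threshold: float = 0.75,
    seed: int = 0,
) -> tuple[LSIModel, CellEmbedding]:
    """Fit LSI on a reference cell x peak count matrix.

    Counts are binarized, row-normalized to ``scale`` (term frequency) and
    weighted by ``idf = log(1 + n_cells / feature_frequency)``; a truncated
    SVD yields the components. Features never observed are dropped from the
    model. The first component is discarded when its |correlation| with log
    depth exceeds ``depth_corr_threshold`` (it then reflects sequencing
    depth, not biology); ``n_components`` is the retained dimensionality
    either way.
    """
    if isinstance(counts, pd.DataFrame):
        cells = counts.index
        features = counts.columns
        X = sp.csr_matrix(counts.to_numpy(dtype=float))
    else:
        X = sp.csr_matrix(counts, dtype=float)
        cells = pd.Index(cells if cells is not None else range(X.shape[0]))
        features = pd.Index(features if features is not None else range(X.shape[1]))
    if X.shape[0] < n_components + 2:
        raise ValueError("need at least n_components + 2 cells")
    depth = np.asarray((X > 0).sum(axis=1)).ravel() if binarize else np.asarray(X.sum(axis=1)).ravel()
    if (depth == 0).any():
        raise ValueError("reference contains zero-depth cells")

    feat_freq = np.asarray((X > 0).sum(axis=0)).ravel()
    observed = feat_freq > 0
    if not observed.all():
        logger.info("dropping %d never-observed features", int((~observed).sum()))
    X = X[:, observed]
    features = features[observed]
    idf = np.log1p(X.shape[0] / feat_freq[observed])

    T = _tfidf(X, idf, scale, binarize)
    k = n_components + 1
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(T.shape))
    u, s, vt = svds(T, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    s, vt = s[order], vt[order]
    # fix sign for determinism: largest-|loading| entry of each component positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    coords_full = T @ vt.T

    r = np.corrcoef(coords_full[:, 0], np.log1p(depth))[0, 1]
    dropped = bool(abs(r) > depth_corr_threshold)
    keep = slice(1, n_components + 1) if dropped else slice(0, n_components)
    model = LSIModel(features=pd.Index(features), idf=idf,
                     singular_values=s[keep], components=vt[keep].T,
                     scale=scale, binarize=binarize, dropped_first=dropped)
    emb = CellEmbedding(cells=pd.Index(cells), coords=np.asarray(coords_full[:, keep]),
                        source="reference")
    return model, emb


def project_cells(
    model: LSIModel,
    counts: pd.DataFrame | sp.spmatrix,
    cells: pd.Index | None = None,
    features: pd.Index | None = None,
) -> CellEmbedding:
    """Project query cells into a fitted LSI space.

    Query features are mapped onto the model's feature set (missing features
    zero-filled); term frequencies are weighted by the reference IDF and
    multiplied by the stored singular vectors. Zero-depth cells are excluded
    with a log message.
    """
    if isinstance(counts, pd.DataFrame):
        cells = counts.index
        features = counts.columns
        X = sp.csr_matrix(counts.to_numpy(dtype=float))
    else:
        X = sp.csr_matrix(counts, dtype=float)
        cells = pd.Index(cells if cells is not None else range(X.shape[0]))
        features = pd.Index(features if features is not None else range(X.shape[1]))
    col_map = pd.Index(features).get_indexer(model.features)
    aligned = sp.lil_matrix((X.shape[0], len(model.features)))
    present = col_map >= 0
    aligned[:, np.flatnonzero(present)] = X[:, col_map[present]]
    aligned = aligned.tocsr()
    depth = np.asarray(aligned.sum(axis=1)).ravel()
    keep = depth > 0
    if not keep.all():
        logger.info("excluding %d zero-depth query cells", int((~keep).sum()))
    aligned = aligned[keep]
    T = _tfidf(aligned, model.idf, model.scale, model.binarize)
    coords = np.asarray(T @ model.components)
    return CellEmbedding(cells=pd.Index(cells)[keep], coords=coords, source="query")


def make_pseudo_single_cells(
    cutsites: pd.DataFrame,
    peaks: pd.DataFrame,
    n_cells: int = 250,
    reads_per_cell: int = 10_000,
    seed: int = 0,
    prefix: str = "pseudo",
) -> pd.DataFrame:
    """Subsample a bulk cut-site pool into pseudo-single cells.

    Each of ``n_cells`` pseudo-cells draws ``reads_per_cell`` cut sites
    uniformly without replacement (independently across cells), counted
    against the peak set. Returns a cells x peaks DataFrame.
    """
    pool = cutsites.reset_index(drop=True)
    if len(pool) < reads_per_cell:
        raise ValueError("cut-site pool smaller than reads_per_cell")
    rng = np.random.default_rng(seed)
    peak_ids = (peaks["chrom"] + ":" + peaks["start"].astype(str)
                + "-" + peaks["end"].astype(str))
    rows = []
    from .bulk_chromatin import count_cutsites_in_peaks

    for i in range(n_cells):
        take = rng.choice(len(pool), size=reads_per_cell, replace=False)
        sub = pool.iloc[take]
        cnt = count_cutsites_in_peaks({f"{prefix}{i}": sub}, peaks)
        rows.append(cnt.iloc[:, 0])
    out = pd.DataFrame(rows, index=[f"{prefix}{i}" for i in range(n_cells)])
    out.columns = peak_ids
    return out


def knn_closest_normal(
    reference: CellEmbedding,
    labels: pd.Series,
    query: CellEmbedding,
    k: int = 10,
) -> pd.DataFrame:
    """Closest-normal cell-type call per query cell.

    Euclidean k-nearest-neighbor vote in LSI space against the labeled
    reference; ties between labels are resolved by the smaller mean distance.
    Returns cell, label and vote_fraction.
    """
    if k > len(reference.cells):
        raise ValueError("k exceeds reference size")
    labels = labels.loc[reference.cells]
    nn = NearestNeighbors(n_neighbors=k).fit(reference.coords)
    dist, idx = nn.kneighbors(query.coords)
    lab = labels.to_numpy()
    calls = []
    for ci in range(len(query.cells)):
        neigh = lab[idx[ci]]
        d = dist[ci]
        counts: dict[str, int] = {}
        dsum: dict[str, float] = {}
        for l_, dd in zip(neigh, d):
            counts[l_] = counts.get(l_, 0) + 1
            dsum[l_] = dsum.get(l_, 0.0) + dd
        best = sorted(counts, key=lambda l_: (-counts[l_], dsum[l_] / counts[l_], l_))[0]
        calls.append({"cell": query.cells[ci], "label": best,
                      "vote_fraction": counts[best] / k})
    return pd.DataFrame(calls).set_index("cell")


def label_distribution(calls: pd.DataFrame, sample_of: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample closest-normal label fractions (one row per sample)."""
    df = calls.copy()
    df["sample"] = sample_of.loc[df.index] if sample_of is not None else "all"
    out = df.groupby("sample")["label"].value_counts(normalize=True).unstack(fill_value=0.0)
    return out
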
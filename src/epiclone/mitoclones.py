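"""Mitochondrial-variant clone tracing and the convergent-evolution test.

Somatic mitochondrial variants act as endogenous clonal barcodes. Candidate
variants are filtered with the standard heuristics (detected in more than 3
cells, strand correlation above 0.65, mean coverage above 10 reads — strict
inequalities), a per-variant per-cell heteroplasmy matrix (alt / (alt+ref))
is binarized and clustered with a shared-nearest-neighbor graph to call
"mitoclones", and the clone hierarchy is reconstructed from containment of
the clones' variant sets. Clone frequencies at diagnosis and relapse are
compared with a two-proportion z test, and convergent epigenetic evolution
is declared when the mean inter-clone chromatin similarity (Pearson
correlation of clone pseudobulk profiles) is higher at relapse than at
diagnosis by an unpaired t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .single_cell import cluster_cells, cluster_pseudobulk

logger = logging.getLogger(__name__)

MIN_CELLS_DETECTED = 3      # strictly more cells than this
MIN_STRAND_CORRELATION = 0.65
MIN_MEAN_COVERAGE = 10.0


@dataclass
class CloneTree:
    """Rooted clone hierarchy with per-timepoint frequencies."""

    clones: list[str]
    parents: dict[str, str | None]
    defining_variants: dict[str, frozenset[str]]
    frequencies: pd.DataFrame = field(default_factory=pd.DataFrame)
    conflicts: list[tuple[str, str, str]] = field(default_factory=list)

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, p in self.parents.items() if p is not None]


def compute_heteroplasmy(
    alt_fw: pd.DataFrame, alt_rev: pd.DataFrame,
    ref_fw: pd.DataFrame, ref_rev: pd.DataFrame,
    detect_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heteroplasmy matrix and per-variant quality statistics.

    All four inputs are variants x cells strand-split allele counts.
    Heteroplasmy = alt / (alt + ref); missing (NaN) where a cell has zero
    coverage. Per-variant statistics: the number of cells the variant is
    detected in (heteroplasmy > ``detect_threshold``), the Pearson
    correlation of per-cell alt counts between the two strands (over cells
    with at least one read on each strand), and mean coverage.
    """
    alt = alt_fw + alt_rev
    ref = ref_fw + ref_rev
    cov = alt + ref
    het = alt / cov.where(cov > 0)

    stats = []
    for v in alt.index:
        a_fw, a_rev = alt_fw.loc[v], alt_rev.loc[v]
        informative = (alt_fw.loc[v] + ref_fw.loc[v] > 0) & (alt_rev.loc[v] + ref_rev.loc[v] > 0)
        if informative.sum() >= 2 and a_fw[informative].std() > 0 and a_rev[informative].std() > 0:
            sc = float(np.corrcoef(a_fw[informative], a_rev[informative])[0, 1])
        else:
            sc = np.nan
        stats.append({
            "variant": v,
            "n_cells_detected": int((het.loc[v] > detect_threshold).sum()),
            "strand_correlation": sc,
            "mean_coverage": float(cov.loc[v].mean()),
        })
    return het, pd.DataFrame(stats).set_index("variant")


def filter_mito_variants(stats: pd.DataFrame) -> list[str]:
    """High-quality variants: n_cells_detected > 3 AND strand correlation
    > 0.65 AND mean coverage > 10 (all strict)."""
    keep = (
        (stats["n_cells_detected"] > MIN_CELLS_DETECTED)
        & (stats["strand_correlation"] > MIN_STRAND_CORRELATION)
        & (stats["mean_coverage"] > MIN_MEAN_COVERAGE)
    )
    return list(stats.index[keep.fillna(False)])


def cluster_mitoclones(
    heteroplasmy: pd.DataFrame,
    binarize_threshold: float = 0.1,
    resolution: float = 1.0,
    seed: int = 0,
    k: int = 20,
    low_het_flag: float = 0.1,
    min_cluster_fraction: float = 0.01,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster cells by their binarized mitochondrial variant profiles.

    The variants x cells heteroplasmy matrix is binarized at
    ``binarize_threshold`` and cells are clustered with the SNN/modularity
    procedure. Micro-clusters below ``min_cluster_fraction`` of cells —
    typically coverage-dropout artifacts in which a true clone variant was
    simply unobserved — are dissolved into the nearest major cluster by
    binary-profile distance. Returns (cell -> clone id, mean heteroplasmy
    per variant x clone over covered cells, with a
    ``low_heteroplasmy_cluster`` flag marking clones whose top defining
    variant averages below ``low_het_flag``).
    """
    if heteroplasmy.empty:
        raise ValueError("no variants to cluster on")
    binary = (heteroplasmy.fillna(0.0) >= binarize_threshold).astype(float)
    if not binary.to_numpy().any():
        logger.warning("all-zero binary heteroplasmy matrix; single clone returned")
        clones = pd.Series(0, index=heteroplasmy.columns, name="cluster")
    else:
        emb = binary.T  # cells x variants
        clones = cluster_cells(emb, resolution=resolution, seed=seed,
                               k=min(k, emb.shape[0] - 1))
        clones = _dissolve_micro_clusters(clones, emb, min_cluster_fraction)
    # per-cluster means over covered cells only: zero-coverage dropouts say
    # nothing about a variant's presence in a clone
    mean_het = heteroplasmy.T.groupby(clones).mean().T.fillna(0.0)
    top = mean_het.max(axis=0)
    flags = (top < low_het_flag).rename("low_heteroplasmy_cluster")
    summary = mean_het.copy()
    summary.loc["__low_het_flag__"] = flags.astype(float)
    return clones.rename("clone"), summary


def _dissolve_micro_clusters(
    clones: pd.Series, profiles: pd.DataFrame, min_fraction: float
) -> pd.Series:
    """Reassign cells of clusters below ``min_fraction`` of the population
    to the nearest major cluster centroid; relabels clusters 0..n-1 by
    descending size."""
    sizes = clones.value_counts()
    cutoff = max(min_fraction * len(clones), 1.0)
    major = sizes.index[sizes >= cutoff]
    if len(major) == 0:
        major = sizes.index[:1]
    minor_cells = clones.index[~clones.isin(major)]
    if len(minor_cells):
        logger.info("dissolving %d micro-cluster cells into %d major clusters",
                    len(minor_cells), len(major))
        centroids = np.vstack([profiles.loc[clones.index[clones == m]].mean(axis=0)
                               for m in major])
        d = np.linalg.norm(
            profiles.loc[minor_cells].to_numpy()[:, None, :] - centroids[None, :, :],
            axis=2)
        clones = clones.copy()
        clones.loc[minor_cells] = major.to_numpy()[np.argmin(d, axis=1)]
    relabel = {old: new for new, old in enumerate(clones.value_counts().index)}
    return clones.map(relabel).rename(clones.name)


def sweep_resolution(
    heteroplasmy: pd.DataFrame,
    resolutions: list[float],
    binarize_threshold: float = 0.1,
    seed: int = 0,
    k: int = 20,
) -> pd.DataFrame:
    """Cluster at several resolutions and report unsupervised quality.

    Helps the manual resolution choice: returns clone counts and the mean
    silhouette of the binarized variant profiles per resolution (NaN when a
    single clone results).
    """
    from sklearn.metrics import silhouette_score

    binary = (heteroplasmy.fillna(0.0) >= binarize_threshold).astype(float).T
    rows = []
    for r in resolutions:
        clones, _ = cluster_mitoclones(heteroplasmy, binarize_threshold,
                                       resolution=r, seed=seed, k=k)
        sil = (silhouette_score(binary.to_numpy(), clones.to_numpy())
               if clones.nunique() > 1 else np.nan)
        rows.append({"resolution": r, "n_clones": int(clones.nunique()),
                     "silhouette": sil})
    return pd.DataFrame(rows)


def infer_clone_tree(
    mean_heteroplasmy: pd.DataFrame,
    presence_threshold: float = 0.2,
    overrides: dict[str, str] | None = None,
) -> CloneTree:
    """Reconstruct the clone hierarchy from shared and exclusive variants.

    A variant is *present* in a clone when its mean heteroplasmy reaches
    ``presence_threshold``. Variants present in every clone hang off the
    root; a clone descends from the clone whose variant set is the largest
    proper subset of its own. Containment conflicts (two equally large
    incomparable candidate parents) are reported and can be resolved with a
    ``{clone: parent}`` override table.
    """
    mh = mean_heteroplasmy.drop(index="__low_het_flag__", errors="ignore")
    presence = mh >= presence_threshold
    clones = [str(c) for c in presence.columns]
    vsets = {str(c): frozenset(presence.index[presence[c]]) for c in presence.columns}
    shared_all = frozenset.intersection(*vsets.values()) if vsets else frozenset()

    parents: dict[str, str | None] = {}
    conflicts: list[tuple[str, str, str]] = []
    for c in clones:
        if overrides and c in overrides:
            parents[c] = overrides[c]
            continue
        candidates = [o for o in clones
                      if o != c and vsets[o] < vsets[c]]
        if not candidates:
            parents[c] = None  # direct child of the root
            continue
        best_size = max(len(vsets[o]) for o in candidates)
        best = [o for o in candidates if len(vsets[o]) == best_size]
        if len(best) > 1:
            conflicts.append((c, best[0], best[1]))
            logger.warning("ambiguous parent for clone %s: %s", c, best)
        parents[c] = best[0]
    # non-nesting conflict: two incomparable clones share variants beyond
    # what their deepest observed common ancestor (or the root set) explains
    for i, a in enumerate(clones):
        for b in clones[i + 1:]:
            if vsets[a] <= vsets[b] or vsets[b] <= vsets[a]:
                continue
            inter = vsets[a] & vsets[b]
            ancestors = [vsets[o] for o in clones
                         if vsets[o] <= vsets[a] and vsets[o] <= vsets[b]]
            explained = shared_all | (max(ancestors, key=len) if ancestors else frozenset())
            if inter - explained:
                conflicts.append((a, b, "non-nesting overlap"))
    return CloneTree(clones=clones, parents=parents,
                     defining_variants=vsets, conflicts=conflicts)


def clone_frequencies(
    assignments: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-timepoint clone fractions with an expansion/contraction test.

    ``assignments`` has columns cell, clone, timepoint. Each clone's
    diagnosis and relapse fractions are compared with a two-proportion z
    test (continuity-corrected); ``significant`` flags clones changing at
    level ``alpha``.
    """
    counts = assignments.groupby(["timepoint", "clone"]).size().unstack(fill_value=0)
    if (counts.sum(axis=1) == 0).any() or counts.shape[0] < 2:
        raise ValueError("need cells at both timepoints")
    totals = counts.sum(axis=1)
    freqs = counts.div(totals, axis=0)
    tp_a, tp_b = counts.index[:2]
    rows = []
    for clone in counts.columns:
        x1, n1 = int(counts.loc[tp_a, clone]), int(totals.loc[tp_a])
        x2, n2 = int(counts.loc[tp_b, clone]), int(totals.loc[tp_b])
        p = _two_proportion_p(x1, n1, x2, n2)
        rows.append({
            "clone": clone,
            f"freq_{tp_a}": x1 / n1, f"freq_{tp_b}": x2 / n2,
            "p": p, "significant": p < alpha,
        })
    return pd.DataFrame(rows).set_index("clone")


def _two_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided two-proportion z test with Yates continuity correction."""
    p_pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    diff = abs(x1 / n1 - x2 / n2)
    cc = 0.5 * (1 / n1 + 1 / n2)
    z = max(diff - cc, 0.0) / se
    return float(2 * scipy.stats.norm.sf(z))


def _inter_clone_correlations(pb: pd.DataFrame) -> np.ndarray:
    """Off-diagonal upper-triangle Pearson correlations of clone pseudobulks."""
    corr = pb.corr(method="pearson").to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    return corr[iu]


def convergence_analysis(
    assignments: pd.DataFrame,
    counts: pd.DataFrame,
    timepoint_a: str = "diagnosis",
    timepoint_b: str = "relapse",
) -> dict:
    """Test whether clones converge epigenetically at relapse.

    Clone pseudobulk chromatin profiles (summed counts, CPM) are correlated
    pairwise within each timepoint; the two collections of inter-clone
    similarities are compared with an unpaired two-sample t test.
    Convergence is declared when the relapse mean exceeds the diagnosis mean
    at p < 0.05. Degenerate (zero-variance) similarity collections raise.
    """
    out: dict = {"similarities": {}, "matrices": {}}
    for tp in (timepoint_a, timepoint_b):
        sub = assignments[assignments["timepoint"] == tp]
        if sub["clone"].nunique() < 2:
            raise ValueError(f"timepoint {tp} has <2 clones; similarity undefined")
        clones = pd.Series(sub["clone"].to_numpy(), index=sub["cell"].to_numpy())
        pb = cluster_pseudobulk(clones, counts)
        out["matrices"][tp] = pb.corr(method="pearson")
        out["similarities"][tp] = _inter_clone_correlations(pb)
    a = out["similarities"][timepoint_a]
    b = out["similarities"][timepoint_b]
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("degenerate similarities: zero variance in both groups")
    t, p = scipy.stats.ttest_ind(b, a, equal_var=False)
    out.update({
        "mean_similarity_dx": float(np.mean(a)),
        "mean_similarity_rel": float(np.mean(b)),
        "t": float(t), "p": float(p),
        "convergent": bool(np.mean(b) > np.mean(a) and p < 0.05),
    })
    return out


def clone_shift_concordance(
    assignments: pd.DataFrame,
    counts: pd.DataFrame,
    timepoint_a: str = "diagnosis",
    timepoint_b: str = "relapse",
) -> pd.DataFrame:
    """Correlation between clones' relapse-vs-diagnosis accessibility shifts.

    Per clone present at both timepoints, the per-feature shift is
    ``log2((CPM_rel + 1) / (CPM_dx + 1))``; the returned matrix holds the
    pairwise Pearson correlations of these shift vectors. A high value for
    two clones of distinct origin indicates a shared (convergent) relapse
    program. Zero-variance shift vectors raise; clones missing a timepoint
    are excluded with a log message.
    """
    shifts = {}
    pbs = {}
    for tp in (timepoint_a, timepoint_b):
        sub = assignments[assignments["timepoint"] == tp]
        clones = pd.Series(sub["clone"].to_numpy(), index=sub["cell"].to_numpy())
        pbs[tp] = cluster_pseudobulk(clones, counts)
    common = [c for c in pbs[timepoint_a].columns if c in pbs[timepoint_b].columns]
    skipped = set(pbs[timepoint_a].columns) ^ set(pbs[timepoint_b].columns)
    for c in skipped:
        logger.info("clone %s absent at one timepoint; excluded from concordance", c)
    for c in common:
        v = np.log2((pbs[timepoint_b][c] + 1) / (pbs[timepoint_a][c] + 1))
        if v.std() == 0:
            raise ValueError(f"clone {c} has a zero-variance shift vector")
        shifts[c] = v
    return pd.DataFrame(shifts).corr(method="pearson")
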
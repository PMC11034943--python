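"""Gene accessibility scores, relapse signatures and pre-ranked GSEA.

Gene-level accessibility is summarized from a 5-kb genomic tile matrix with
an exponential distance-decay model: tiles in the extended gene body (TSS
minus 5 kb through the TTS, strand-aware) weigh ``1 + e^-1``; flanking tiles
at distance ``d`` from that span weigh ``exp(-d/5000) + e^-1``; tiles more
than 20 kb away, or running into a neighboring gene's span, weigh 0. Per-tile
insertion counts are depth-normalized per sample and the weighted sum over a
gene's tiles is its accessibility score — a chromatin proxy for expression.

A relapse signature is the top/bottom 500 genes of a relapse-vs-diagnosis
differential ranking; gene set enrichment uses the weighted Kolmogorov-
Smirnov running-sum statistic (weight exponent 1) with a gene-label
permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DECAY_SCALE = 5_000.0
MAX_DISTANCE = 20_000
BODY_UPSTREAM = 5_000
FLOOR = float(np.exp(-1.0))  # constant offset keeping distal weights > 0


@dataclass
class RelapseSignature:
    """Ordered top/bottom gene lists with their ranking statistic."""

    top_genes: list[str]
    bottom_genes: list[str]
    statistic: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if set(self.top_genes) & set(self.bottom_genes):
            raise ValueError("top and bottom gene lists overlap")


def gene_body_span(gene: pd.Series) -> tuple[int, int]:
    """Strand-aware extended gene body: [TSS - 5 kb, TTS] in genome coordinates."""
    if gene["strand"] == "+":
        return int(gene["start"]) - BODY_UPSTREAM, int(gene["end"])
    return int(gene["start"]), int(gene["end"]) + BODY_UPSTREAM


def gene_tile_weights(
    gene: pd.Series,
    tile_starts: np.ndarray,
    tile_width: int = 5_000,
    neighbors: pd.DataFrame | None = None,
) -> np.ndarray:
    """Distance-decay weight of each tile for one gene.

    ``tile_starts`` are starts of tiles on the gene's chromosome. Distance is
    measured from the nearest edge of the extended gene body to the nearest
    edge of the tile (0 for overlapping tiles, giving the body weight
    ``1 + e^-1`` and making the weight continuous at the body/flank
    boundary). Flanking tiles overlapping a neighboring gene's extended body
    get weight 0.
    """
    span_lo, span_hi = gene_body_span(gene)
    ts = np.asarray(tile_starts, dtype=np.int64)
    te = ts + tile_width
    dist = np.maximum.reduce([ts - span_hi, span_lo - te, np.zeros_like(ts)])
    w = np.exp(-dist / DECAY_SCALE) + FLOOR
    w[dist > MAX_DISTANCE] = 0.0
    inside = (ts < span_hi) & (te > span_lo)
    if neighbors is not None and len(neighbors):
        blocked = np.zeros_like(inside)
        for _, nb in neighbors.iterrows():
            if nb["chrom"] != gene["chrom"] or nb["gene"] == gene["gene"]:
                continue
            lo, hi = gene_body_span(nb)
            blocked |= (ts < hi) & (te > lo)
        w[blocked & ~inside] = 0.0
    return w


def compute_gene_scores(
    tile_counts: pd.DataFrame,
    tile_coords: pd.DataFrame,
    genes: pd.DataFrame,
    tile_width: int = 5_000,
    depth_scale: float = 1e4,
) -> pd.DataFrame:
    """Gene accessibility score matrix (genes x samples).

    ``tile_counts`` is tiles x samples; ``tile_coords`` aligns with its rows
    and carries chrom/start. Counts are normalized to ``depth_scale`` total
    insertions per sample, then combined per gene with the decay weights.
    Genes with no weighted tile in range score 0.
    """
    totals = tile_counts.sum(axis=0).replace(0, np.nan)
    norm = tile_counts * depth_scale / totals
    norm = norm.fillna(0.0)
    scores = pd.DataFrame(0.0, index=genes["gene"], columns=tile_counts.columns)
    for chrom, grp in genes.groupby("chrom"):
        on_chrom = tile_coords["chrom"] == chrom
        if not on_chrom.any():
            logger.info("no tiles on %s; genes there score 0", chrom)
            continue
        idx = np.flatnonzero(on_chrom.to_numpy())
        starts = tile_coords.loc[on_chrom, "start"].to_numpy()
        sub = norm.iloc[idx]
        for _, gene in grp.iterrows():
            w = gene_tile_weights(gene, starts, tile_width, neighbors=grp)
            if not w.any():
                logger.info("gene %s has no in-range tiles", gene["gene"])
                continue
            scores.loc[gene["gene"]] = w @ sub.to_numpy()
    return scores


def derive_relapse_signature(
    differential: pd.DataFrame, n_genes: int = 500, stat_col: str = "log2fc"
) -> RelapseSignature:
    """Extract the relapse signature from a gene-score differential table.

    Genes are ranked by the relapse-vs-diagnosis statistic; the top and
    bottom ``n_genes`` (500 by default) form the signature. With fewer than
    ``2 * n_genes`` genes the signature splits evenly and a note is logged.
    """
    d = differential.dropna(subset=[stat_col])
    if len(d) < 2:
        raise ValueError("need at least 2 ranked genes for a signature")
    key = "feature" if "feature" in d.columns else "gene"
    ranked = d.sort_values([stat_col, key], ascending=[False, True])
    n = n_genes
    if len(ranked) < 2 * n_genes:
        n = len(ranked) // 2
        logger.info("only %d genes; signature split %d/%d", len(ranked), n, n)
    stat = pd.Series(ranked[stat_col].to_numpy(), index=ranked[key].to_numpy())
    return RelapseSignature(
        top_genes=list(ranked[key].head(n)),
        bottom_genes=list(ranked[key].tail(n)[::-1]),
        statistic=stat,
    )


def _rank_genes(stats: pd.Series) -> pd.Series:
    """Descending ranking with deterministic name tie-break."""
    if stats.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    order = sorted(stats.index, key=lambda g: (-stats[g], g))
    return stats.loc[order]


def enrichment_score(ranked: pd.Series, gene_set: list[str]) -> float:
    """Weighted KS running-sum enrichment score (weight exponent 1).

    Walking the ranking, member genes increment the running sum by their
    absolute statistic (normalized to the set total) and non-members
    decrement it by ``1 / (N - k)``; the score is the maximum signed
    deviation from zero.
    """
    members = np.asarray(ranked.index.isin(set(gene_set)))
    if not members.any():
        raise ValueError("gene set has no overlap with the ranking")
    pos = np.flatnonzero(members)
    return float(_es_from_positions(pos[None, :], np.abs(ranked.to_numpy()), len(ranked))[0])


def _es_from_positions(pos: np.ndarray, abs_stats: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many member-position sets (rows of ``pos``, sorted).

    The running sum only changes direction at member positions, so the
    extremes are attained immediately after a hit (maximum candidate) or
    immediately before one (minimum candidate).
    """
    pos = np.sort(pos, axis=1)
    k = pos.shape[1]
    w = abs_stats[pos]
    tot = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        hit_cum = np.cumsum(w, axis=1) / tot
    hit_cum = np.where(np.broadcast_to(tot, hit_cum.shape) > 0,
                       hit_cum, (np.arange(1, k + 1) / k)[None, :])
    j = np.arange(k)[None, :]
    denom = max(n - k, 1)
    after = hit_cum - (pos + 1 - (j + 1)) / denom       # just after each hit
    before = np.concatenate(
        [np.zeros((pos.shape[0], 1)), hit_cum[:, :-1]], axis=1
    ) - (pos - j) / denom                               # just before each hit
    top = after.max(axis=1)
    bot = before.min(axis=1)
    return np.where(top >= -bot, top, bot)


def gsea_preranked(
    stats: pd.Series,
    gene_sets: dict[str, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    padj_threshold: float | None = None,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-label permutation null.

    For each set the observed ES is compared with ES values of
    ``n_permutations`` random same-size gene sets; the p value uses the
    same-signed tail and NES normalizes by the mean |null ES| of that sign.
    Sets with fewer than ``min_size`` ranked members are skipped. Pass
    ``padj_threshold`` to filter the returned table.
    """
    ranked = _rank_genes(stats)
    abs_stats = np.abs(ranked.to_numpy())
    n = len(ranked)
    rng = np.random.default_rng(seed)
    rows = []
    for name, genes in gene_sets.items():
        members = np.flatnonzero(ranked.index.isin(set(genes)))
        k = len(members)
        if k < min_size:
            logger.info("set %s has %d ranked members (<%d); skipped", name, k, min_size)
            continue
        if k == n:
            rows.append({"set": name, "size": k, "ES": 0.0, "NES": 0.0, "p": 1.0})
            continue
        es = float(_es_from_positions(members[None, :], abs_stats, n)[0])
        null_pos = np.argsort(
            rng.random((n_permutations, n)), axis=1, kind="stable")[:, :k]
        null_es = _es_from_positions(null_pos, abs_stats, n)
        same = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same.sum())
        extreme = int((np.abs(null_es[same]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_same) if n_same else 1.0
        mean_same = float(np.abs(null_es[same]).mean()) if n_same else np.nan
        nes = es / mean_same if mean_same and not np.isnan(mean_same) else np.nan
        rows.append({"set": name, "size": k, "ES": es, "NES": nes, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
        if padj_threshold is not None:
            out = out[out["padj"] < padj_threshold].reset_index(drop=True)
    return out
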
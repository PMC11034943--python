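"""Bulk ATAC-seq: peaks, counts, similarity and differential accessibility.

The unit of signal is the Tn5 cut site: each sequenced fragment contributes
two insertion events, recovered by shifting the fragment start by +4 and the
end by -5 (coordinates 0-based half-open throughout). Fixed-width peak calls
from individual samples are merged into a non-overlapping consensus set by
iterative removal in order of significance score; counts of cut sites per
consensus peak feed the downstream similarity and differential stages.

Differential accessibility between relapse and diagnosis uses a
negative-binomial generalized linear model with median-of-ratios size
factors, trended dispersion shrinkage and a Wald test on the timepoint
coefficient, with patient identity as a fixed-effect covariate (the DESeq2
model, via pydeseq2). P values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TN5_SHIFT_PLUS = 4   # applied to the fragment start (left insertion)
TN5_SHIFT_MINUS = 5  # subtracted from the fragment end (right insertion)


def fragments_to_cutsites(fragments: pd.DataFrame, expand_duplicates: bool = False) -> pd.DataFrame:
    """Convert fragments to Tn5 cut sites.

    Each fragment (chrom, start, end) yields the two insertion positions
    ``start + 4`` and ``end - 5``. With ``expand_duplicates`` the per-fragment
    duplicate count replicates each site.
    """
    if fragments.empty:
        return pd.DataFrame(columns=["chrom", "pos"])
    left = fragments[["chrom", "start"]].rename(columns={"start": "pos"}).copy()
    left["pos"] = left["pos"] + TN5_SHIFT_PLUS
    right = fragments[["chrom", "end"]].rename(columns={"end": "pos"}).copy()
    right["pos"] = right["pos"] - TN5_SHIFT_MINUS
    if expand_duplicates and "count" in fragments.columns:
        reps = fragments["count"].to_numpy()
        left = left.loc[left.index.repeat(reps)]
        right = right.loc[right.index.repeat(reps)]
    sites = pd.concat([left, right], ignore_index=True)
    return sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def iterative_merge_peaks(
    peaks: pd.DataFrame,
    blacklist: pd.DataFrame | None = None,
    min_samples: int = 2,
    width: int = 500,
) -> pd.DataFrame:
    """Merge per-sample fixed-width peak calls into a disjoint consensus set.

    Peaks overlapping the blacklist are removed first. The remaining calls
    are sorted by descending score (ties broken by chrom, start for
    determinism) and resolved by iterative removal: the best-scoring peak is
    kept and every call overlapping it discarded, repeatedly. A retained
    consensus peak must be supported by original calls from at least
    ``min_samples`` distinct samples.
    """
    df = peaks.copy()
    if ((df["end"] - df["start"]) != width).any():
        raise ValueError(f"all peaks must have fixed width {width}")
    if blacklist is not None and not blacklist.empty:
        df = df[~_overlaps_any(df, blacklist)]
    if df.empty:
        return df.reset_index(drop=True)

    df = df.sort_values(["score", "chrom", "start"],
                        ascending=[False, True, True], kind="stable").reset_index(drop=True)
    kept_rows: list[int] = []
    removed = np.zeros(len(df), dtype=bool)
    # group row indices by chromosome for overlap queries
    by_chrom: dict[str, np.ndarray] = {
        c: idx.to_numpy() for c, idx in df.groupby("chrom").groups.items()
    }
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    for i in range(len(df)):
        if removed[i]:
            continue
        kept_rows.append(i)
        sibs = by_chrom[df.at[i, "chrom"]]
        overl = sibs[(starts[sibs] < ends[i]) & (ends[sibs] > starts[i])]
        removed[overl] = True

    kept = df.loc[kept_rows]
    if "sample_of_origin" in df.columns and min_samples > 1:
        support = []
        for i in kept_rows:
            sibs = by_chrom[df.at[i, "chrom"]]
            overl = sibs[(starts[sibs] < ends[i]) & (ends[sibs] > starts[i])]
            support.append(df.loc[overl, "sample_of_origin"].nunique())
        kept = kept[np.array(support) >= min_samples]
    return kept.sort_values(["chrom", "start"]).reset_index(drop=True)


def _overlaps_any(intervals: pd.DataFrame, other: pd.DataFrame) -> pd.Series:
    """Boolean mask: does each interval overlap any interval in ``other``."""
    out = np.zeros(len(intervals), dtype=bool)
    for chrom, grp in other.groupby("chrom"):
        sel = intervals["chrom"] == chrom
        if not sel.any():
            continue
        s = intervals.loc[sel, "start"].to_numpy()[:, None]
        e = intervals.loc[sel, "end"].to_numpy()[:, None]
        os_, oe = grp["start"].to_numpy()[None, :], grp["end"].to_numpy()[None, :]
        out[np.flatnonzero(sel.to_numpy())] = ((s < oe) & (e > os_)).any(axis=1)
    return pd.Series(out, index=intervals.index)


def count_cutsites_in_peaks(
    sites_by_sample: dict[str, pd.DataFrame], peaks: pd.DataFrame
) -> pd.DataFrame:
    """Count cut sites per consensus peak per sample (half-open intervals).

    Returns a peaks x samples integer DataFrame indexed by
    ``chrom:start-end`` peak ids.
    """
    pk = peaks.reset_index(drop=True)
    peak_ids = pk["chrom"] + ":" + pk["start"].astype(str) + "-" + pk["end"].astype(str)
    mat = np.zeros((len(pk), len(sites_by_sample)), dtype=np.int64)
    for j, (sample, sites) in enumerate(sites_by_sample.items()):
        for chrom, grp in pk.groupby("chrom"):
            chrom_sites = sites.loc[sites["chrom"] == chrom, "pos"]
            if chrom_sites.empty:
                logger.info("no cut sites on %s for sample %s", chrom, sample)
                continue
            pos = np.sort(chrom_sites.to_numpy())
            lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
            hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
            mat[grp.index.to_numpy(), j] = hi - lo
    return pd.DataFrame(mat, index=peak_ids, columns=list(sites_by_sample))


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization of each column."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-depth sample; CPM undefined")
    return counts * 1e6 / totals


def dx_rel_similarity(
    counts: pd.DataFrame, meta: pd.DataFrame,
    group_a: str = "diagnosis", group_b: str = "relapse",
    group_col: str = "timepoint",
) -> pd.Series:
    """Per-patient Pearson correlation of chromatin profiles between two
    sample groups (diagnosis vs relapse by default; also used for LSC vs
    non-LSC comparisons).

    Each sample column is CPM-normalized; replicate CPM vectors are averaged
    per (patient, group); the correlation is computed across all peaks.
    """
    norm = cpm(counts)
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    out = {}
    for pid, grp in meta.groupby("patient_id"):
        a_cols = grp.index[grp[group_col] == group_a]
        b_cols = grp.index[grp[group_col] == group_b]
        if len(a_cols) == 0 or len(b_cols) == 0:
            continue
        a = norm[a_cols].mean(axis=1)
        b = norm[b_cols].mean(axis=1)
        if a.std() == 0 or b.std() == 0:
            raise ValueError(f"zero-variance profile for patient {pid}")
        out[pid] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name="pearson_r")


def differential_accessibility(
    counts: pd.DataFrame, meta: pd.DataFrame,
    condition_col: str = "timepoint", baseline: str = "diagnosis",
    treatment: str = "relapse", patient_col: str = "patient_id",
) -> pd.DataFrame:
    """Relapse-vs-diagnosis differential accessibility per feature.

    Fits the DESeq2 negative-binomial model (median-of-ratios size factors,
    trended dispersion shrinkage, Wald test) with patient fixed effects, and
    returns log2 fold changes with BH-adjusted p values. All-zero features
    are excluded from testing and reported with NA statistics.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    meta = meta.loc[counts.columns]
    nonzero = counts.sum(axis=1) > 0
    X = counts.loc[nonzero].T
    X.index = X.index.astype(str)
    md = pd.DataFrame({
        "patient": meta[patient_col].astype(str).values,
        "condition": meta[condition_col].astype(str).values,
    }, index=X.index)
    if md.groupby("patient")["condition"].nunique().lt(2).all():
        raise ValueError("need patients with both conditions")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=X, metadata=md,
                           design="~patient + condition", quiet=True, n_cpus=1)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", treatment, baseline], quiet=True)
        stats.summary()
    res = stats.results_df
    out = pd.DataFrame(index=counts.index, columns=["log2fc", "p", "padj"], dtype=float)
    out.loc[res.index, "log2fc"] = res["log2FoldChange"]
    out.loc[res.index, "p"] = res["pvalue"]
    out.loc[res.index, "padj"] = res["padj"]
    out.index.name = "feature"
    return out.reset_index()


def locus_window_scan(
    differential: pd.DataFrame, peaks: pd.DataFrame,
    window_bp: int = 100_000, step_bp: int = 50_000,
    alpha: float = 0.05, min_peaks: int = 5,
    direction: str = "enriched",
) -> pd.DataFrame:
    """Scan the genome for windows carrying an excess of significant peaks.

    Sliding windows are scored with a binomial tail test of the in-window
    count of significantly enriched (``log2fc > 0``) or depleted peaks
    against the genome-wide significant fraction; windows with fewer than
    ``min_peaks`` peaks are skipped. P values are BH adjusted.
    """
    if direction not in ("enriched", "depleted"):
        raise ValueError("direction must be 'enriched' or 'depleted'")
    df = peaks.reset_index(drop=True).copy()
    d = differential.set_index("feature") if "feature" in differential.columns else differential
    ids = df["chrom"] + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
    sig = (d.loc[ids, "padj"].to_numpy() < alpha)
    fc = d.loc[ids, "log2fc"].to_numpy()
    hit = sig & (fc > 0 if direction == "enriched" else fc < 0)
    global_rate = hit.sum() / len(df)

    rows = []
    for chrom, grp in df.groupby("chrom"):
        starts = grp["start"].to_numpy()
        h = hit[grp.index.to_numpy()]
        lo, hi = starts.min(), starts.max()
        w0 = (lo // step_bp) * step_bp
        for ws in range(int(w0), int(hi) + 1, step_bp):
            in_w = (starts >= ws) & (starts < ws + window_bp)
            n = int(in_w.sum())
            if n < min_peaks:
                continue
            k = int(h[in_w].sum())
            p = float(scipy.stats.binom.sf(k - 1, n, global_rate)) if global_rate > 0 else (
                0.0 if k > 0 else 1.0)
            rows.append({"chrom": chrom, "start": ws, "end": ws + window_bp,
                         "n_peaks": n, "n_significant": k, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["padj"] = pd.Series(dtype=float)
        out["flagged"] = pd.Series(dtype=bool)
        return out
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["flagged"] = out["padj"] < alpha
    return out


def differential_overlap_fraction(set_a, set_b) -> float:
    """|A intersect B| / |A| — the fraction of A's differential features also
    differential in B (asymmetric)."""
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("set A is empty; overlap fraction undefined")
    return len(a & b) / len(a)


def motif_enrichment(
    foreground: list[str], background: list[str], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of foreground peaks vs a background
    universe.

    ``annotation`` is a boolean peaks x motifs DataFrame. Both tails are
    reported (enrichment p and depletion p) with an odds ratio (``inf`` when
    the foreground captures every motif-positive peak and no negatives are
    sampled). BH adjustment is applied to the enrichment p values.
    """
    bg = [p for p in background if p in annotation.index]
    fg = [p for p in foreground if p in annotation.index]
    ann = annotation.loc[bg].astype(bool)
    n_universe, n_draw = len(bg), len(fg)
    rows = []
    for motif in ann.columns:
        n_pos = int(ann[motif].sum())
        if n_pos == 0:
            logger.warning("motif %s absent from background; skipped", motif)
            continue
        k = int(ann.loc[fg, motif].sum())
        p_enr = float(scipy.stats.hypergeom.sf(k - 1, n_universe, n_pos, n_draw))
        p_dep = float(scipy.stats.hypergeom.cdf(k, n_universe, n_pos, n_draw))
        a, b_ = k, n_draw - k
        c = n_pos - k
        d_ = (n_universe - n_pos) - (n_draw - k)
        odds = np.inf if (b_ == 0 or c == 0) and a > 0 else (
            (a * d_) / (b_ * c) if b_ * c > 0 else np.nan)
        rows.append({"motif": motif, "n_foreground": k, "n_background": n_pos,
                     "odds_ratio": odds, "p_enriched": p_enr, "p_depleted": p_dep})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj_enriched"] = multipletests(out["p_enriched"], method="fdr_bh")[1]
        out["padj_depleted"] = multipletests(out["p_depleted"], method="fdr_bh")[1]
    return out
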
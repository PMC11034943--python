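"""Cut sites, consensus peaks, counting, similarity, differential stats."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from epiclone import bulk_chromatin as bc
from conftest import brute_force_count


def test_fragment_yields_shifted_cutsites():
    frags = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200],
                          "barcode": ["b"], "count": [1]})
    sites = bc.fragments_to_cutsites(frags)
    assert sorted(sites["pos"]) == [104, 195]


def test_empty_fragments_give_empty_sites():
    assert bc.fragments_to_cutsites(pd.DataFrame(columns=["chrom", "start", "end"])).empty


def test_cutsite_conservation_two_per_fragment():
    rng = np.random.default_rng(0)
    n = 500
    starts = rng.integers(0, 10_000, n)
    frags = pd.DataFrame({"chrom": "chr1", "start": starts,
                          "end": starts + rng.integers(50, 300, n)})
    assert len(bc.fragments_to_cutsites(frags)) == 2 * n


def _peak(chrom, start, score, sample, width=500):
    return {"chrom": chrom, "start": start, "end": start + width,
            "score": score, "sample_of_origin": sample}


def test_merge_keeps_best_scoring_of_overlapping_pair():
    peaks = pd.DataFrame([
        _peak("chr1", 1000, 10, "s1"), _peak("chr1", 1200, 8, "s2"),
    ])
    merged = bc.iterative_merge_peaks(peaks, min_samples=2)
    assert len(merged) == 1
    assert merged.iloc[0]["start"] == 1000


def test_merge_disjoint_peaks_all_retained():
    peaks = pd.DataFrame([
        _peak("chr1", 1000, 5, "s1"), _peak("chr1", 1000, 4, "s2"),
        _peak("chr1", 5000, 3, "s1"), _peak("chr1", 5000, 2, "s2"),
    ])
    merged = bc.iterative_merge_peaks(peaks, min_samples=2)
    assert len(merged) == 2


def test_merge_single_sample_peak_excluded():
    peaks = pd.DataFrame([
        _peak("chr1", 1000, 5, "s1"), _peak("chr1", 1000, 4, "s2"),
        _peak("chr2", 9000, 9, "s1"),
    ])
    merged = bc.iterative_merge_peaks(peaks, min_samples=2)
    assert list(merged["chrom"]) == ["chr1"]


def test_merge_blacklist_removed_first():
    peaks = pd.DataFrame([
        _peak("chr1", 1000, 99, "s1"), _peak("chr1", 1200, 8, "s1"),
        _peak("chr1", 1200, 7, "s2"),
    ])
    blacklist = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1100]})
    merged = bc.iterative_merge_peaks(peaks, blacklist=blacklist, min_samples=2)
    # the high-scoring blacklisted peak no longer suppresses its neighbors
    assert list(merged["start"]) == [1200]


def test_merge_rejects_wrong_width():
    peaks = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 300,
                           "score": 1, "sample_of_origin": "s1"}])
    with pytest.raises(ValueError):
        bc.iterative_merge_peaks(peaks)


def _brute_force_merge(peaks: pd.DataFrame, min_samples: int) -> list[tuple]:
    """Independent O(n^2) enumeration of the iterative removal order."""
    rows = sorted(peaks.to_dict("records"),
                  key=lambda r: (-r["score"], r["chrom"], r["start"]))
    kept, removed = [], [False] * len(rows)
    for i, r in enumerate(rows):
        if removed[i]:
            continue
        kept.append(r)
        for j, o in enumerate(rows):
            if (o["chrom"] == r["chrom"] and o["start"] < r["end"]
                    and o["end"] > r["start"]):
                removed[j] = True
    out = []
    for r in kept:
        support = {o["sample_of_origin"] for o in peaks.to_dict("records")
                   if o["chrom"] == r["chrom"] and o["start"] < r["end"]
                   and o["end"] > r["start"]}
        if len(support) >= min_samples:
            out.append((r["chrom"], r["start"]))
    return sorted(out)


@pytest.mark.parametrize("seed", range(10))
def test_merge_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    peaks = pd.DataFrame([
        _peak(f"chr{rng.integers(1, 3)}", int(rng.integers(0, 8000)),
              float(rng.integers(1, 1000)), f"s{rng.integers(1, 4)}")
        for _ in range(n)
    ])
    merged = bc.iterative_merge_peaks(peaks, min_samples=2)
    got = sorted(zip(merged["chrom"], merged["start"]))
    assert got == _brute_force_merge(peaks, 2)


def test_merged_consensus_is_pairwise_disjoint():
    rng = np.random.default_rng(7)
    peaks = pd.DataFrame([
        _peak("chr1", int(rng.integers(0, 20_000)), float(rng.random()), f"s{i % 3}")
        for i in range(200)
    ])
    merged = bc.iterative_merge_peaks(peaks, min_samples=1)
    m = merged.sort_values("start")
    assert (m["start"].to_numpy()[1:] >= m["end"].to_numpy()[:-1]).all()


def test_count_single_site_and_halfopen_end(toy_peaks):
    sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1200, 1500]})
    counts = bc.count_cutsites_in_peaks({"s": sites}, toy_peaks)
    assert counts.iloc[0, 0] == 1   # 1200 inside [1000, 1500)
    assert counts.iloc[1, 0] == 0   # 1500 excluded by half-open end


@pytest.mark.parametrize("seed", range(8))
def test_counting_matches_quadratic_oracle(seed, toy_peaks):
    rng = np.random.default_rng(100 + seed)
    sites = pd.DataFrame({
        "chrom": rng.choice(["chr1", "chr2"], 300),
        "pos": rng.integers(0, 4000, 300),
    })
    counts = bc.count_cutsites_in_peaks({"s": sites}, toy_peaks)
    np.testing.assert_array_equal(counts["s"].to_numpy(),
                                  brute_force_count(sites, toy_peaks))


def test_cpm_columns_sum_to_million_and_preserve_ranks():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(0, 100, (50, 4)))
    norm = bc.cpm(counts)
    np.testing.assert_allclose(norm.sum(axis=0), 1e6, atol=1e-3)
    for c in counts.columns:
        assert (norm[c].rank() - counts[c].rank()).abs().max() == 0


def _sim_meta(n_pairs):
    rows = []
    for i in range(n_pairs):
        for tp in ("diagnosis", "relapse"):
            rows.append({"sample": f"P{i}_{tp}", "patient_id": f"P{i}",
                         "timepoint": tp, "replicate": 1})
    return pd.DataFrame(rows)


def test_similarity_identity_and_antisymmetry():
    meta = _sim_meta(1)
    counts = pd.DataFrame({"P0_diagnosis": [1, 2, 3], "P0_relapse": [1, 2, 3]})
    assert bc.dx_rel_similarity(counts, meta)["P0"] == pytest.approx(1.0)
    counts = pd.DataFrame({"P0_diagnosis": [1, 2, 3], "P0_relapse": [3, 2, 1]})
    assert bc.dx_rel_similarity(counts, meta)["P0"] == pytest.approx(-1.0)


def test_similarity_zero_variance_raises():
    meta = _sim_meta(1)
    counts = pd.DataFrame({"P0_diagnosis": [1, 1, 1], "P0_relapse": [1, 2, 3]})
    with pytest.raises(ValueError):
        bc.dx_rel_similarity(counts, meta)


def test_similarity_near_one_without_planted_change():
    from epiclone import synthetic_data as sd
    cfg = sd.SimConfig(seed=5, n_peaks=2000, signature_size=10, effect_log2fc=0.0,
                       n_bulk_patients=3, mean_peak_count=500.0, nb_dispersion=0.002)
    counts, meta, _ = sd.simulate_bulk_chromatin_cohort(cfg)
    sim = bc.dx_rel_similarity(counts, meta)
    assert (sim > 0.99).all()


def test_differential_recovers_planted_features(small_bulk_cohort):
    counts, meta, truth = small_bulk_cohort
    res = bc.differential_accessibility(counts, meta)
    sig = set(res.loc[res["padj"] < 0.05, "feature"])
    planted = set(truth["signature_features"])
    assert len(sig & planted) / len(planted) >= 0.8
    # planted features shift upward at relapse
    planted_fc = res.set_index("feature").loc[list(planted), "log2fc"]
    assert planted_fc.median() > 0.5


def test_differential_flat_feature_has_zero_fold_change(small_bulk_cohort):
    counts, meta, _ = small_bulk_cohort
    counts = counts.copy()
    counts.iloc[-1] = 37  # identical counts in every sample
    res = bc.differential_accessibility(counts, meta).set_index("feature")
    assert abs(res.iloc[-1]["log2fc"]) < 0.1


def test_locus_scan_flags_planted_block():
    rng = np.random.default_rng(2)
    n = 400
    peaks = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 2000 + 1000})
    peaks["end"] = peaks["start"] + 500
    ids = peaks["chrom"] + ":" + peaks["start"].astype(str) + "-" + peaks["end"].astype(str)
    padj = rng.uniform(0.06, 1.0, n)
    fc = rng.normal(0, 1, n)
    block = slice(100, 140)  # 40 consecutive peaks = one 100-kb-scale locus
    padj[block] = 0.001
    fc[block] = 2.0
    diff = pd.DataFrame({"feature": ids, "log2fc": fc, "padj": padj, "p": padj})
    hits = bc.locus_window_scan(diff, peaks, direction="enriched")
    flagged = hits[hits["flagged"]]
    assert not flagged.empty
    assert flagged["start"].min() >= 100 * 2000 - 100_000
    assert flagged["end"].max() <= 140 * 2000 + 100_000 + 2000


def test_locus_scan_window_at_global_rate_not_flagged():
    rng = np.random.default_rng(3)
    n = 300
    peaks = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 2000})
    peaks["end"] = peaks["start"] + 500
    ids = peaks["chrom"] + ":" + peaks["start"].astype(str) + "-" + peaks["end"].astype(str)
    sig = rng.random(n) < 0.05
    diff = pd.DataFrame({"feature": ids, "log2fc": np.where(sig, 1.0, 0.0),
                         "padj": np.where(sig, 0.01, 0.5), "p": 0.5})
    hits = bc.locus_window_scan(diff, peaks)
    assert not hits["flagged"].any()


def test_overlap_fraction_edges():
    assert bc.differential_overlap_fraction({"a", "b"}, {"a", "b", "c"}) == 1.0
    assert bc.differential_overlap_fraction({"a"}, {"b"}) == 0.0
    with pytest.raises(ValueError):
        bc.differential_overlap_fraction(set(), {"a"})


def test_overlap_fraction_matches_set_oracle():
    rng = np.random.default_rng(4)
    universe = [f"p{i}" for i in range(10_000)]
    a = list(rng.choice(universe, 100, replace=False))
    b = list(rng.choice(universe, 500, replace=False))
    expected = sum(1 for x in a if x in set(b)) / 100
    assert bc.differential_overlap_fraction(a, b) == pytest.approx(expected)


def test_motif_enrichment_matches_hypergeometric_tail():
    universe = [f"p{i}" for i in range(100)]
    ann = pd.DataFrame({"M1": [i < 10 for i in range(100)]}, index=universe)
    fg = universe[:5] + universe[50:65]  # 5 of 10 positives among 20 drawn
    res = bc.motif_enrichment(fg, universe, ann).set_index("motif")
    expected = scipy.stats.hypergeom.sf(4, 100, 10, 20)
    assert res.loc["M1", "p_enriched"] == pytest.approx(expected, rel=1e-12)


def test_motif_enrichment_all_positive_foreground_is_infinite_odds():
    universe = [f"p{i}" for i in range(50)]
    ann = pd.DataFrame({"M1": [i < 8 for i in range(50)]}, index=universe)
    res = bc.motif_enrichment(universe[:8], universe, ann).set_index("motif")
    assert np.isinf(res.loc["M1", "odds_ratio"])
    assert res.loc["M1", "p_enriched"] == pytest.approx(
        scipy.stats.hypergeom.sf(7, 50, 8, 8), rel=1e-9)


def test_bh_adjustment_controls_null_discoveries():
    rng = np.random.default_rng(5)
    from statsmodels.stats.multitest import multipletests
    m, q = 2000, 0.05
    discoveries = []
    for _ in range(20):
        p = rng.random(m)
        discoveries.append(multipletests(p, alpha=q, method="fdr_bh")[0].sum())
    assert np.mean(discoveries) <= q * m
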
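"""Heteroplasmy, variant QC, mitoclone clustering, trees, convergence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epiclone import mitoclones as mc
from epiclone import synthetic_data as sd


def _stats(n, sc_, cov):
    return pd.DataFrame({"n_cells_detected": [n], "strand_correlation": [sc_],
                         "mean_coverage": [cov]}, index=["v"])


@pytest.mark.parametrize(
    "n,sc_,cov,kept",
    [
        (3, 0.9, 50, False),    # boundary: strictly greater than 3 required
        (4, 0.9, 50, True),
        (40, 0.3, 50, False),   # low strand correlation
        (40, 0.65, 50, False),  # boundary: strictly greater than 0.65
        (40, 0.9, 10, False),   # boundary: strictly greater than 10 reads
        (40, 0.9, 10.5, True),
    ],
)
def test_variant_filter_boundaries(n, sc_, cov, kept):
    assert (mc.filter_mito_variants(_stats(n, sc_, cov)) == ["v"]) is kept


def test_variant_filter_invariant_to_cell_order(small_mito):
    m = small_mito
    _, stats = mc.compute_heteroplasmy(m["alt_fw"], m["alt_rev"],
                                       m["ref_fw"], m["ref_rev"])
    perm = np.random.default_rng(0).permutation(m["alt_fw"].columns)
    _, stats2 = mc.compute_heteroplasmy(
        m["alt_fw"][perm], m["alt_rev"][perm], m["ref_fw"][perm], m["ref_rev"][perm])
    assert mc.filter_mito_variants(stats) == mc.filter_mito_variants(stats2)


def test_filter_removes_all_and_only_artifacts(small_mito):
    m = small_mito
    _, stats = mc.compute_heteroplasmy(m["alt_fw"], m["alt_rev"],
                                       m["ref_fw"], m["ref_rev"])
    assert set(mc.filter_mito_variants(stats)) == set(m["clone_variants"])


def test_heteroplasmy_basic_values():
    ones = pd.DataFrame([[5]], index=["v"], columns=["c"])
    zeros = pd.DataFrame([[0]], index=["v"], columns=["c"])
    het, _ = mc.compute_heteroplasmy(ones, zeros, ones, zeros)
    assert het.loc["v", "c"] == pytest.approx(0.5)
    het0, _ = mc.compute_heteroplasmy(zeros, zeros, zeros, zeros)
    assert np.isnan(het0.loc["v", "c"])


def test_heteroplasmy_concentrates_at_high_coverage():
    """Binomial sampling at coverage 1000 pins cell heteroplasmy near truth."""
    rng = np.random.default_rng(0)
    n_cells, cov, het = 200, 1000, 0.8
    alt = rng.binomial(cov, het, n_cells)
    alt_fw = pd.DataFrame([rng.binomial(alt, 0.5)], index=["v"])
    alt_rev = pd.DataFrame([alt], index=["v"]) - alt_fw
    ref = cov - alt
    ref_fw = pd.DataFrame([rng.binomial(ref, 0.5)], index=["v"])
    ref_rev = pd.DataFrame([ref], index=["v"]) - ref_fw
    h, _ = mc.compute_heteroplasmy(alt_fw, alt_rev, ref_fw, ref_rev)
    assert 0.78 < h.loc["v"].mean() < 0.82


def test_full_heteroplasmy_gives_allele_fraction_one():
    cfg = sd.SimConfig(seed=3, n_peaks=200, signature_size=20,
                       n_cells_per_timepoint=100,
                       heteroplasmy=1.0, n_artifact_variants=0)
    m = sd.simulate_mito_scatac(cfg)
    het, _ = mc.compute_heteroplasmy(m["alt_fw"], m["alt_rev"],
                                     m["ref_fw"], m["ref_rev"])
    clone1_cells = m["assignments"].loc[m["assignments"]["clone"] == "clone1", "cell"]
    vals = het.loc["m1", clone1_cells].dropna()
    assert (vals == 1.0).all()


def test_mitoclone_clustering_recovers_planted_clones(small_mito):
    m = small_mito
    het, stats = mc.compute_heteroplasmy(m["alt_fw"], m["alt_rev"],
                                         m["ref_fw"], m["ref_rev"])
    passing = mc.filter_mito_variants(stats)
    clones, _ = mc.cluster_mitoclones(het.loc[passing], resolution=0.5, seed=0)
    truth = m["assignments"].set_index("cell")["clone"]
    assert adjusted_rand_score(truth.loc[clones.index], clones) >= 0.95


def test_mitoclone_clustering_deterministic(small_mito):
    m = small_mito
    het, _ = mc.compute_heteroplasmy(m["alt_fw"], m["alt_rev"],
                                     m["ref_fw"], m["ref_rev"])
    a, _ = mc.cluster_mitoclones(het, resolution=0.5, seed=1)
    b, _ = mc.cluster_mitoclones(het, resolution=0.5, seed=1)
    pd.testing.assert_series_equal(a, b)


def test_all_zero_matrix_single_clone_with_warning():
    het = pd.DataFrame(0.0, index=["v1"], columns=[f"c{i}" for i in range(30)])
    clones, _ = mc.cluster_mitoclones(het, seed=0)
    assert clones.nunique() == 1


def test_low_heteroplasmy_cluster_flagged():
    rng = np.random.default_rng(1)
    het = pd.DataFrame(rng.uniform(0, 0.05, (2, 50)),
                       index=["v1", "v2"], columns=[f"c{i}" for i in range(50)])
    het.iloc[0, :25] = 0.15  # just over the binarization threshold
    clones, summary = mc.cluster_mitoclones(het, seed=0, low_het_flag=0.3)
    assert summary.loc["__low_het_flag__"].any()


class TestCloneTree:
    def test_nested_sets_give_chain(self):
        mh = pd.DataFrame(
            {"c1": [0.9, 0.0, 0.0], "c2": [0.9, 0.9, 0.0], "c3": [0.9, 0.9, 0.9]},
            index=["v1", "v2", "v3"])
        tree = mc.infer_clone_tree(mh)
        assert tree.parents == {"c1": None, "c2": "c1", "c3": "c2"}
        assert not tree.conflicts

    def test_disjoint_exclusive_variants_make_siblings(self):
        mh = pd.DataFrame(
            {"A": [0.9, 0.9, 0.0], "B": [0.9, 0.0, 0.9]},
            index=["v0", "v1", "v2"])
        tree = mc.infer_clone_tree(mh)
        # both clones share v0 and add an exclusive variant: siblings
        assert tree.parents["A"] is None or tree.parents["A"] == "B"
        assert tree.parents["B"] is None or tree.parents["B"] == "A"
        assert not (tree.parents["A"] == "B" and tree.parents["B"] == "A")

    def test_presence_threshold_applies(self):
        mh = pd.DataFrame({"c1": [0.15], "c2": [0.9]}, index=["v1"])
        tree = mc.infer_clone_tree(mh, presence_threshold=0.2)
        assert tree.defining_variants["c1"] == frozenset()
        assert tree.defining_variants["c2"] == frozenset({"v1"})

    def test_non_nesting_overlap_reported(self):
        # A and B share v2 while a third clone lacks it, so v2 is not a
        # root variant and the A/B overlap cannot nest
        mh = pd.DataFrame(
            {"A": [0.9, 0.9, 0.0, 0.0], "B": [0.0, 0.9, 0.9, 0.0],
             "C": [0.0, 0.0, 0.0, 0.9]},
            index=["v1", "v2", "v3", "v4"])
        tree = mc.infer_clone_tree(mh)
        assert tree.conflicts

    def test_manual_override_respected(self):
        mh = pd.DataFrame(
            {"A": [0.9, 0.9, 0.0], "B": [0.0, 0.9, 0.9]},
            index=["v1", "v2", "v3"])
        tree = mc.infer_clone_tree(mh, overrides={"B": "A"})
        assert tree.parents["B"] == "A"

    def test_planted_tree_recovered(self, small_mito):
        m = small_mito
        het, stats = mc.compute_heteroplasmy(m["alt_fw"], m["alt_rev"],
                                             m["ref_fw"], m["ref_rev"])
        passing = mc.filter_mito_variants(stats)
        clones, summary = mc.cluster_mitoclones(het.loc[passing],
                                                resolution=0.5, seed=0)
        tree = mc.infer_clone_tree(summary)
        truth = m["assignments"].set_index("cell")["clone"]
        mapping = {str(cl): truth.loc[cells.index].mode()[0]
                   for cl, cells in clones.groupby(clones)}
        got = {mapping[c]: (mapping[p] if p is not None else None)
               for c, p in tree.parents.items()}
        assert got == m["truth_tree"]["parents"]


class TestCloneFrequencies:
    def _assign(self, dx_counts, rel_counts):
        rows = []
        for tp, cc in (("diagnosis", dx_counts), ("relapse", rel_counts)):
            i = 0
            for clone, n in cc.items():
                for _ in range(n):
                    rows.append({"cell": f"{tp}_{i}", "clone": clone,
                                 "timepoint": tp})
                    i += 1
        return pd.DataFrame(rows)

    def test_frequencies_sum_to_one(self):
        a = self._assign({"c1": 30, "c2": 70}, {"c1": 60, "c2": 40})
        freqs = mc.clone_frequencies(a)
        assert freqs["freq_diagnosis"].sum() == pytest.approx(1.0)
        assert freqs["freq_relapse"].sum() == pytest.approx(1.0)

    def test_equal_assignment_uniform(self):
        a = self._assign({"c1": 50, "c2": 50}, {"c1": 50, "c2": 50})
        freqs = mc.clone_frequencies(a)
        assert (freqs["freq_diagnosis"] == 0.5).all()
        assert not freqs["significant"].any()

    def test_planted_expansion_flagged(self):
        # a 0.2% -> 36% outgrowth at 3000 cells per timepoint
        a = self._assign({"minor": 6, "major": 2994}, {"minor": 1080, "major": 1920})
        freqs = mc.clone_frequencies(a)
        assert freqs.loc["minor", "significant"]
        assert freqs.loc["minor", "p"] < 1e-10

    def test_missing_timepoint_raises(self):
        a = self._assign({"c1": 10}, {"c1": 10})
        with pytest.raises(ValueError):
            mc.clone_frequencies(a[a["timepoint"] == "diagnosis"])


class TestConvergence:
    def test_identical_profiles_degenerate(self):
        counts = pd.DataFrame(np.tile([1, 2, 3, 4], (40, 1)),
                              index=[f"c{i}" for i in range(40)])
        assign = pd.DataFrame({
            "cell": counts.index,
            "clone": (["a"] * 10 + ["b"] * 10) * 2,
            "timepoint": ["diagnosis"] * 20 + ["relapse"] * 20,
        })
        with pytest.raises(ValueError):
            mc.convergence_analysis(assign, counts)

    def test_convergence_mode_detected(self):
        cfg = sd.SimConfig(seed=30, n_peaks=600, n_cells_per_timepoint=300,
                           convergence=True)
        m = sd.simulate_mito_scatac(cfg)
        res = mc.convergence_analysis(m["assignments"], m["cell_peak_counts"])
        assert res["mean_similarity_rel"] > res["mean_similarity_dx"]
        assert res["p"] < 0.05 and res["convergent"]

    def test_stationary_clones_not_convergent(self):
        cfg = sd.SimConfig(seed=31, n_peaks=600, n_cells_per_timepoint=300,
                           convergence=False)
        m = sd.simulate_mito_scatac(cfg)
        res = mc.convergence_analysis(m["assignments"], m["cell_peak_counts"])
        assert not res["convergent"]

    def test_single_clone_timepoint_raises(self):
        counts = pd.DataFrame(np.random.default_rng(0).poisson(3, (20, 50)),
                              index=[f"c{i}" for i in range(20)])
        assign = pd.DataFrame({
            "cell": counts.index,
            "clone": ["a"] * 10 + ["a", "b"] * 5,
            "timepoint": ["diagnosis"] * 10 + ["relapse"] * 10,
        })
        with pytest.raises(ValueError):
            mc.convergence_analysis(assign, counts)


class TestShiftConcordance:
    def _sim(self, shared_shift, seed=0):
        rng = np.random.default_rng(seed)
        n_peaks = 400
        base = rng.lognormal(2, 1, n_peaks)
        shift = rng.normal(0, 1, n_peaks)
        rows, assign = [], []
        for clone in ("a", "b"):
            own_shift = shift if shared_shift else rng.normal(0, 1, n_peaks)
            for tp, prog in (("diagnosis", base),
                             ("relapse", base * 2.0 ** own_shift)):
                for i in range(25):
                    cell = f"{clone}_{tp}_{i}"
                    rows.append(pd.Series(rng.poisson(prog * 20), name=cell))
                    assign.append({"cell": cell, "clone": clone, "timepoint": tp})
        return pd.DataFrame(rows), pd.DataFrame(assign)

    def test_identical_planted_shift_high_concordance(self):
        counts, assign = self._sim(shared_shift=True)
        corr = mc.clone_shift_concordance(assign, counts)
        assert corr.loc["a", "b"] > 0.9

    def test_independent_shifts_centered_on_zero(self):
        vals = []
        for seed in range(10):
            counts, assign = self._sim(shared_shift=False, seed=seed)
            vals.append(mc.clone_shift_concordance(assign, counts).loc["a", "b"])
        assert abs(np.mean(vals)) < 0.1

    def test_zero_shift_degenerate(self):
        counts = pd.DataFrame(np.tile([5, 5, 5, 5], (20, 1)),
                              index=[f"c{i}" for i in range(20)])
        assign = pd.DataFrame({
            "cell": counts.index,
            "clone": ["a", "b"] * 10,
            "timepoint": ["diagnosis"] * 10 + ["relapse"] * 10,
        })
        with pytest.raises(ValueError):
            mc.clone_shift_concordance(assign, counts)
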
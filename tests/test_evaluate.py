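import itertools
import math

import numpy as np
import pandas as pd
import pytest

from scgnorm import (
    AbundanceTable,
    GenomeContentMatrix,
    OTUProfileSet,
    Stage,
    correlation_structure_similarity,
    cov_bootstrap,
    cross_study_recovery,
    differential_features,
    identify_osgs,
    osg_correlation,
    osg_foldchange_ratios,
    pathway_abundance,
    slope_vs_truth,
)
from scgnorm.evaluate import DifferentialResult
from scgnorm.types import PathwayMap


def _table(values, kos, samples, stage=Stage.marker_normalized):
    return AbundanceTable(pd.DataFrame(values, index=kos, columns=samples), stage)


class TestPathwayAbundance:
    def test_single_member(self):
        t = _table([[1.0, 2.0], [5.0, 6.0]], ["K1", "K2"], ["S1", "S2"])
        pa = pathway_abundance(t, PathwayMap({"pw": {"K1"}}))
        assert list(pa.loc["pw"]) == [1.0, 2.0]

    def test_sum_by_hand(self):
        t = _table([[1.5], [2.5]], ["K1", "K2"], ["S1"])
        pa = pathway_abundance(t, PathwayMap({"pw": {"K1", "K2"}}))
        assert pa.loc["pw", "S1"] == pytest.approx(4.0)

    def test_partition_identity(self, rng):
        kos = [f"K{i}" for i in range(9)]
        t = _table(rng.gamma(1, 1, size=(9, 3)), kos, ["S1", "S2", "S3"])
        pm = PathwayMap({"a": set(kos[:4]), "b": set(kos[4:7]), "c": set(kos[7:])})
        pa = pathway_abundance(t, pm)
        assert np.allclose(pa.sum(axis=0), t.data.sum(axis=0))

    def test_absent_members_are_zero(self):
        t = _table([[1.0]], ["K1"], ["S1"])
        pa = pathway_abundance(t, PathwayMap({"pw": {"K404"}}))
        assert pa.loc["pw", "S1"] == 0.0


def _ranksum_enumeration_p(xa, xb):
    """Exact two-sided rank-sum p by enumerating all group assignments
    (tie-free data only)."""
    pooled = np.concatenate([xa, xb])
    n, na = len(pooled), len(xa)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    center = na * (n - na) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestDifferentialFeatures:
    def test_identical_distributions(self):
        t = _table([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], ["K1"],
                   [f"S{i}" for i in range(6)])
        res = differential_features(t, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert res.table.loc["K1", "p_raw"] == pytest.approx(1.0)

    def test_extreme_small_groups(self):
        t = _table([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], ["K1"],
                   [f"S{i}" for i in range(6)])
        res = differential_features(t, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        # smallest attainable two-sided p at n=3,3: 2/20
        assert res.table.loc["K1", "p_raw"] == pytest.approx(0.1)
        assert res.table.loc["K1", "direction"] == "b"

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (6, 6)])
    def test_matches_enumeration_oracle(self, rng, na, nb):
        kos = [f"K{i}" for i in range(8)]
        samples = [f"S{i}" for i in range(na + nb)]
        vals = np.exp(rng.normal(size=(8, na + nb)))
        t = _table(vals, kos, samples)
        res = differential_features(t, samples[:na], samples[na:])
        for i, ko in enumerate(kos):
            p_oracle = _ranksum_enumeration_p(vals[i, :na], vals[i, na:])
            assert res.table.loc[ko, "p_raw"] == pytest.approx(p_oracle, abs=1e-12)

    def test_adjustment_monotone_and_bounded(self, rng):
        kos = [f"K{i}" for i in range(30)]
        samples = [f"S{i}" for i in range(12)]
        vals = rng.normal(size=(30, 12)) + 2.0
        vals[:10, :6] += 1.5
        t = _table(np.abs(vals), kos, samples)
        res = differential_features(t, samples[:6], samples[6:])
        tab = res.table.sort_values("p_raw")
        assert (tab["p_adjusted"] >= tab["p_raw"] - 1e-15).all()
        assert tab["p_adjusted"].is_monotonic_increasing

    def test_higher_in_filter(self):
        t = _table([[1.0, 2.0, 3.0, 7.0, 8.0, 9.0]], ["K1"],
                   [f"S{i}" for i in range(6)])
        a, b = ["S0", "S1", "S2"], ["S3", "S4", "S5"]
        res = differential_features(t, a, b, alpha=0.2, require_higher_in="a")
        assert not res.table.loc["K1", "significant"]
        res2 = differential_features(t, a, b, alpha=0.2, require_higher_in="b")
        assert res2.table.loc["K1", "significant"]

    def test_overlapping_groups_rejected(self):
        t = _table([[1.0] * 6], ["K1"], [f"S{i}" for i in range(6)])
        with pytest.raises(ValueError, match="overlap"):
            differential_features(t, ["S0", "S1", "S2"], ["S2", "S3", "S4"])


class TestCovBootstrap:
    def test_constant_vector(self):
        full, subs = cov_bootstrap(np.full(12, 3.0), 5, 10, seed=0)
        assert full == 0.0 and np.all(subs == 0.0)

    def test_hand_example(self):
        full, _ = cov_bootstrap(np.array([1.0, 2.0, 3.0]), 2, 1, seed=0)
        assert full == pytest.approx(0.5)  # sd(n-1)=1, mean=2

    def test_full_size_subsets_equal_full(self, rng):
        v = rng.gamma(2, 1, size=15)
        full, subs = cov_bootstrap(v, 15, 20, seed=1)
        assert np.allclose(subs, full)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            cov_bootstrap(np.array([-1.0, 1.0]), 2, 1, seed=0)


class TestSlopeVsTruth:
    def test_identity(self, rng):
        truth = pd.DataFrame(rng.gamma(2, 1, size=(20, 4)),
                             index=[f"K{i}" for i in range(20)],
                             columns=[f"S{i}" for i in range(4)])
        t = AbundanceTable(truth.copy(), Stage.marker_normalized)
        s = slope_vs_truth(t, truth)
        assert s.mean_slope == pytest.approx(1.0)
        assert s.slope_cov == pytest.approx(0.0, abs=1e-12)

    def test_linear_scaling(self, rng):
        truth = pd.DataFrame(rng.gamma(2, 1, size=(20, 3)),
                             index=[f"K{i}" for i in range(20)],
                             columns=[f"S{i}" for i in range(3)])
        t = AbundanceTable(2.0 * truth, Stage.marker_normalized)
        s = slope_vs_truth(t, truth)
        assert np.allclose(s.per_sample["slope"], 2.0)
        assert np.allclose(s.per_sample["r2"], 1.0)


@pytest.fixture
def osg_profiles():
    abund = pd.DataFrame(
        {
            "S1": [0.5, 0.5, 0.0],
            "S2": [0.2, 0.8, 0.0],
            "S3": [0.9, 0.1, 0.0],
            "S4": [0.4, 0.6, 0.0],
            "S5": [0.7, 0.3, 0.0],
            "S6": [0.1, 0.9, 0.0],
        },
        index=["O1", "O2", "O3"],
    )
    copies = pd.DataFrame(
        {
            "Kboth": [1, 1, 0],
            "Konly1": [2, 0, 0],
            "Konly2": [0, 1, 0],
            "Kwith_absent": [1, 0, 1],  # carried by O1 and the never-present O3
        },
        index=["O1", "O2", "O3"],
    )
    nsti = pd.Series({"O1": 0.1, "O2": 0.1, "O3": 0.1})
    return OTUProfileSet(otu_rel_abundance=abund, otu_ko_copies=copies, nsti=nsti)


class TestOSGs:
    def test_identify(self, osg_profiles):
        osgs = identify_osgs(osg_profiles, "S1")
        assert osgs["Konly1"] == "O1"
        assert osgs["Konly2"] == "O2"
        assert osgs["Kwith_absent"] == "O1"  # absent OTU does not count
        assert "Kboth" not in osgs

    def test_single_otu_sample(self):
        abund = pd.DataFrame({"S": [1.0]}, index=["O1"])
        copies = pd.DataFrame({"K1": [2], "K2": [1], "K3": [0]}, index=["O1"])
        p = OTUProfileSet(otu_rel_abundance=abund, otu_ko_copies=copies,
                          nsti=pd.Series({"O1": 0.0}))
        assert set(identify_osgs(p, "S")) == {"K1", "K2"}

    def test_correlation_proportional(self, osg_profiles):
        otu = osg_profiles.otu_rel_abundance.loc["O1"]
        table = AbundanceTable(
            pd.DataFrame({s: {"Konly1": 2 * otu[s]} for s in otu.index}),
            Stage.marker_normalized,
        )
        res = osg_correlation(osg_profiles, table, min_samples=5)
        row = res[res["ko"] == "Konly1"].iloc[0]
        assert row["otu"] == "O1"
        assert row["r"] == pytest.approx(1.0)

    def test_correlation_min_samples_threshold(self, osg_profiles):
        otu = osg_profiles.otu_rel_abundance.loc["O1"]
        cols = {s: {"Konly1": 2 * otu[s]} for s in ["S1", "S2", "S3", "S4"]}
        table = AbundanceTable(pd.DataFrame(cols), Stage.marker_normalized)
        res = osg_correlation(osg_profiles, table, min_samples=5)
        assert res.empty

    def test_foldchange_proportional_is_zero(self, osg_profiles):
        otu = osg_profiles.otu_rel_abundance.loc["O1"]
        table = AbundanceTable(
            pd.DataFrame({s: {"Konly1": 3 * otu[s]} for s in otu.index}),
            Stage.marker_normalized,
        )
        vals, skipped = osg_foldchange_ratios(osg_profiles, table)
        konly1 = vals[: 5]  # O1: 6 samples -> 5 consecutive pairs
        assert np.allclose(konly1, 0.0, atol=1e-12)
        assert skipped == 0

    def test_foldchange_by_hand(self):
        abund = pd.DataFrame({"S1": [0.3, 0.7], "S2": [0.6, 0.4]}, index=["O1", "O2"])
        copies = pd.DataFrame({"K1": [1, 0]}, index=["O1", "O2"])
        p = OTUProfileSet(otu_rel_abundance=abund, otu_ko_copies=copies,
                          nsti=pd.Series({"O1": 0.0, "O2": 0.0}))
        # OTU doubles (0.3 -> 0.6), OSG triples (1 -> 3)
        table = AbundanceTable(pd.DataFrame({"S1": {"K1": 1.0}, "S2": {"K1": 3.0}}),
                               Stage.marker_normalized)
        vals, _ = osg_foldchange_ratios(p, table)
        assert vals == pytest.approx([abs(math.log(3.0 / 2.0))])

    def test_foldchange_structural_count(self, osg_profiles, rng):
        kos = ["Konly1", "Konly2", "Kwith_absent"]
        table = AbundanceTable(
            pd.DataFrame(
                rng.gamma(2, 1, size=(3, 6)) + 0.1,
                index=kos, columns=[f"S{i}" for i in range(1, 7)],
            ),
            Stage.marker_normalized,
        )
        vals, skipped = osg_foldchange_ratios(osg_profiles, table)
        # O1 present in 6 samples with 2 OSGs, O2 in 6 samples with 1 OSG
        assert len(vals) + skipped == 5 * 2 + 5 * 1


class TestCorrelationStructure:
    def test_three_ko_brute_force(self):
        copies = pd.DataFrame(
            {"K1": [1, 1, 0, 0], "K2": [1, 1, 1, 0], "K3": [0, 0, 1, 1]},
            index=list("abcd"),
        )
        content = GenomeContentMatrix(copies)
        rng = np.random.default_rng(0)
        ab = pd.DataFrame(rng.gamma(2, 1, size=(3, 6)),
                          index=["K1", "K2", "K3"],
                          columns=[f"S{i}" for i in range(6)])
        t = AbundanceTable(ab, Stage.marker_normalized)
        res = correlation_structure_similarity(content, t)
        # brute force for K1: A = (J(K1,K2), J(K1,K3)), B = (r12, r13)
        pres = copies >= 1
        def jac(a, b):
            inter = (pres[a] & pres[b]).sum()
            return inter / (pres[a] | pres[b]).sum()
        a_vec = np.array([jac("K1", "K2"), jac("K1", "K3")])
        b_vec = np.array([
            np.corrcoef(ab.loc["K1"], ab.loc["K2"])[0, 1],
            np.corrcoef(ab.loc["K1"], ab.loc["K3"])[0, 1],
        ])
        expected = np.corrcoef(a_vec, b_vec)[0, 1]
        assert res["K1"] == pytest.approx(expected, abs=1e-12)

    def test_linear_image_shifts_positive(self, rng):
        n_genomes, n_kos, n_samples = 30, 40, 25
        copies = pd.DataFrame(
            (rng.random((n_genomes, n_kos)) < 0.4).astype(int),
            index=[f"g{i}" for i in range(n_genomes)],
            columns=[f"K{i:02d}" for i in range(n_kos)],
        )
        content = GenomeContentMatrix(copies)
        comm = rng.dirichlet(np.ones(n_genomes), size=n_samples)  # samples x genomes
        ab = pd.DataFrame(
            (comm @ copies.to_numpy()).T,
            index=copies.columns, columns=[f"S{i}" for i in range(n_samples)],
        )
        t = AbundanceTable(ab, Stage.marker_normalized)
        observed = correlation_structure_similarity(content, t)
        # permuted-label null: shuffle the abundance rows
        perm = rng.permutation(n_kos)
        ab_null = pd.DataFrame(ab.to_numpy()[perm], index=copies.columns,
                               columns=ab.columns)
        null = correlation_structure_similarity(content,
                                                AbundanceTable(ab_null, Stage.marker_normalized))
        assert observed.mean() > null.mean() + 0.2


def _diff_result(p_by_feature, sig):
    table = pd.DataFrame(
        {
            "statistic": 0.0,
            "p_raw": pd.Series(p_by_feature),
            "p_adjusted": pd.Series(p_by_feature),
            "direction": "a",
            "significant": pd.Series(sig),
        }
    )
    return DifferentialResult(table=table, correction="bh_fdr", alpha=0.05)


class TestCrossStudyRecovery:
    def test_identical(self):
        ref = _diff_result({"p1": 0.01, "p2": 0.02, "p3": 0.9},
                           {"p1": True, "p2": True, "p3": False})
        assert cross_study_recovery(ref, ref) == (2, 2)

    def test_disjoint(self):
        ref = _diff_result({"p1": 0.01, "p2": 0.9}, {"p1": True, "p2": False})
        alt = _diff_result({"p1": 0.9, "p2": 0.01}, {"p1": False, "p2": True})
        assert cross_study_recovery(ref, alt) == (0, 1)

    def test_truncation_to_reference_size(self):
        ref_p = {f"p{i}": 0.001 * (i + 1) for i in range(3)}
        ref_sig = {f"p{i}": i < 2 for i in range(3)}  # 2 reference hits
        ref = _diff_result(ref_p, ref_sig)
        # alternative flags all 3, but only the 2 smallest-p count
        alt_p = {"p0": 0.03, "p1": 0.01, "p2": 0.02}
        alt = _diff_result(alt_p, {k: True for k in alt_p})
        # top-2 by p: p1 (0.01), p2 (0.02); reference hits are p0, p1
        assert cross_study_recovery(ref, alt) == (1, 2)
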
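"""GWAS thresholds, consensus SNPs, marker sets, superior genotypes and the
Type I-V classification."""

import numpy as np
import pandas as pd
import pytest

from spdchg import (
    SimConfig,
    assoc_scan,
    build_marker_sets,
    classify_snp_types,
    consensus_snps,
    evaluate_marker_sets,
    read_association_tsv,
    significance_threshold,
    sim_genotypes,
    sim_trait,
    superior_genotypes,
)
from spdchg.errors import ModelError
from spdchg.markers import threshold_table


def assoc_rows(snps, method, score=10.0, trait="T", target="gca"):
    return pd.DataFrame(
        {"snp": snps, "chrom": "1", "pos": range(1, len(snps) + 1), "trait": trait,
         "target": target, "method": method, "score": score, "score_type": "-log10p"}
    )


class TestThreshold:
    def test_values(self):
        assert significance_threshold(108_541) == pytest.approx(5.036, abs=5e-4)
        assert significance_threshold(1000) == pytest.approx(3.0)
        assert significance_threshold(10) == pytest.approx(1.0)

    def test_invalid_count(self):
        with pytest.raises(ModelError):
            significance_threshold(0)


@pytest.fixture(scope="module")
def panel():
    cfg = SimConfig(n_lines=200, n_groups=4, n_snps=300, n_qtl=5, h2=0.8, seed=41)
    g, _ = sim_genotypes(cfg)
    return g


class TestAssocScan:

    def test_strong_qtl_detected(self, panel):
        rng = np.random.default_rng(0)
        j = 57
        x = panel.X[:, j]
        y = x + rng.normal(0, np.sqrt(x.var() * 9), panel.n_lines)  # ~10% variance
        res = assoc_scan(y, panel, n_pcs=3)
        thr = significance_threshold(panel.n_markers)
        assert res.loc[res["snp"] == panel.markers[j], "score"].iloc[0] > thr

    def test_null_calibration_one_expected_exceedance(self, panel):
        # at the p = 1/m threshold a null scan of m SNPs yields on average
        # about one significant SNP; check the rate over permuted phenotypes
        rng = np.random.default_rng(1)
        thr = significance_threshold(panel.n_markers)
        counts = []
        for _ in range(25):
            y = rng.normal(size=panel.n_lines)
            res = assoc_scan(y, panel, n_pcs=3)
            counts.append(int((res["score"] > thr).sum()))
        mean_exceed = np.mean(counts)
        assert 0.2 < mean_exceed < 3.0

    def test_no_pcs_equals_simple_regression(self, panel):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        y = rng.normal(size=panel.n_lines)
        res = assoc_scan(y, panel, n_pcs=0)
        for j in (0, 10, 123):
            lr = sps.linregress(panel.X[:, j], y)
            assert res["score"].iloc[j] == pytest.approx(-np.log10(lr.pvalue), abs=1e-6)

    def test_constant_snp_scores_zero(self, panel):
        g = type(panel)(panel.X.copy(), panel.lines, panel.markers, panel.chrom,
                        panel.pos)
        g.X[:, 5] = 2.0
        rng = np.random.default_rng(3)
        res = assoc_scan(rng.normal(size=g.n_lines), g, n_pcs=0)
        assert res["score"].iloc[5] == 0.0


class TestConsensus:
    def test_definitional_membership(self):
        t1 = assoc_rows(["s1", "s2"], "m1")
        t2 = assoc_rows(["s1"], "m2")
        t3 = assoc_rows(["s3"], "m3")
        assert consensus_snps([t1, t2, t3], 2) == ["s1"]
        assert consensus_snps([t1, t2, t3], 3) == []
        assert consensus_snps([t1, t2, t3], 1) == ["s1", "s2", "s3"]

    def test_nesting_invariant(self):
        rng = np.random.default_rng(4)
        tables = [
            assoc_rows(sorted(rng.choice([f"s{i}" for i in range(30)], 12,
                                         replace=False)), f"m{k}")
            for k in range(4)
        ]
        c1, c2, c3 = (set(consensus_snps(tables, k)) for k in (1, 2, 3))
        assert c3 <= c2 <= c1

    def test_hand_fixture_stable_count(self):
        # three methods; exactly s1, s4, s7 shared by >= 2
        t1 = assoc_rows(["s1", "s2", "s4", "s7"], "blink_like")
        t2 = assoc_rows(["s1", "s4", "s5"], "farmcpu_like")
        t3 = assoc_rows(["s7", "s9"], "lod_like", score=4.0)
        t3["score_type"] = "LOD"
        assert consensus_snps([t1, t2, t3], 2) == ["s1", "s4", "s7"]

    def test_empty_tables_and_min_methods_error(self):
        assert consensus_snps([assoc_rows([], "m1")], 1) == []
        with pytest.raises(ModelError):
            consensus_snps([assoc_rows(["s1"], "m1")], 2)

    def test_threshold_then_consensus_order_independent(self):
        t1 = assoc_rows(["s1", "s2", "s3"], "m1", score=[6.0, 2.0, 6.0])
        t2 = assoc_rows(["s1", "s3"], "m2", score=[6.0, 1.0])
        thr = 5.0
        a = consensus_snps([threshold_table(t1, thr), threshold_table(t2, thr)], 2)
        both = pd.concat([t1, t2])
        b = consensus_snps([threshold_table(both, thr)],  # single pooled table
                           2)
        assert a == b == ["s1"]

    def test_association_tsv_round_trip(self, tmp_path):
        t = assoc_rows(["s1", "s2"], "m1")
        p = tmp_path / "assoc.tsv"
        t.to_csv(p, sep="\t", index=False)
        back = read_association_tsv(p)
        assert back["snp"].tolist() == ["s1", "s2"]


class TestMarkerSets:
    def test_nine_sets_with_size_matched_random_counterparts(self):
        gca_t = [assoc_rows(["s1", "s2", "s3"], "m1"), assoc_rows(["s2", "s3"], "m2")]
        trait_t = [assoc_rows(["s5"], "m1"), assoc_rows(["s5", "s6"], "m2")]
        all_snps = [f"s{i}" for i in range(50)]
        sets = build_marker_sets(gca_t, trait_t, all_snps, seed=11)
        assert len(sets) == 9
        assert sets["GCA_SNP1"].snps == ["s1", "s2", "s3"]
        assert sets["GCA_SNP2"].snps == ["s2", "s3"]
        assert sets["Trait_SNP2"].snps == ["s5"]
        for name in ("GCA_SNP1", "GCA_SNP2", "Trait_SNP1", "Trait_SNP2"):
            assert len(sets[f"Rnd {name}"]) == len(sets[name])
        again = build_marker_sets(gca_t, trait_t, all_snps, seed=11)
        assert all(again[k].snps == sets[k].snps for k in sets)

    def test_empty_reference_warns(self):
        sets_in = [assoc_rows([], "m1"), assoc_rows([], "m2")]
        with pytest.warns(UserWarning, match="empty"):
            sets = build_marker_sets(sets_in, sets_in, ["s1", "s2"], seed=0)
        assert len(sets["Rnd GCA_SNP1"]) == 0

    def test_all_snps_set_reduces_to_plain_gblup(self, pop):
        from spdchg import fit_hybrid_model
        from spdchg.markers import MarkerSet

        pairs = pop.plan.pairs
        y = pop.truth.phenotypes.to_numpy()
        tr, te = pairs[:220], pairs[220:]
        ytr, yte = y[:220], y[220:]
        sets = {"All SNPs": MarkerSet("All SNPs", list(pop.g.markers))}
        res = evaluate_marker_sets(sets, pop.g, tr, ytr, te, yte, model="gblup",
                                   max_iter=50)
        fit = fit_hybrid_model("gblup", ytr, pop.coding.Za[:220],
                               pop.coding.Zd[:220], max_iter=50)
        direct = np.corrcoef(yte, fit.predict(pop.coding.Za[220:],
                                              pop.coding.Zd[220:]))[0, 1]
        assert res["accuracy"].iloc[0] == pytest.approx(direct, abs=1e-10)

    def test_empty_set_errors(self, pop):
        from spdchg.markers import MarkerSet

        sets = {"bad": MarkerSet("bad", [])}
        with pytest.raises(ModelError):
            evaluate_marker_sets(sets, pop.g, pop.plan.pairs[:20],
                                 np.zeros(20), pop.plan.pairs[20:30], np.zeros(10))


class TestSuperiorGenotypes:
    def test_definitional_superior_class(self):
        col = np.array([0.0] * 10 + [2.0] * 10)
        vals = np.r_[np.zeros(10), np.ones(10)]
        tab, counts = superior_genotypes(["m0"], col[:, None], ["m0"], vals,
                                         direction="higher")
        assert tab["superior_class"].iloc[0] == 2.0
        assert counts[:10].sum() == 0 and counts[10:].sum() == 10

    def test_direction_flip_inverts(self):
        col = np.array([0.0] * 10 + [2.0] * 10)
        vals = np.r_[np.zeros(10), np.ones(10)]
        tab, _ = superior_genotypes(["m0"], col[:, None], ["m0"], vals,
                                    direction="lower")
        assert tab["superior_class"].iloc[0] == 0.0

    def test_single_class_snp_skipped_with_warning(self):
        col = np.full(20, 2.0)
        with pytest.warns(UserWarning, match="skipped"):
            tab, counts = superior_genotypes(["m0"], col[:, None], ["m0"],
                                             np.arange(20.0))
        assert tab.empty and counts.sum() == 0

    def test_accumulation_separates_top_and_bottom_hybrids(self, pop):
        truth = pop.truth
        qtl_names = [pop.g.markers[j] for j in truth.qtl_indices]
        _, counts = superior_genotypes(qtl_names, pop.coding.Za,
                                       pop.coding.markers,
                                       truth.phenotypes.to_numpy())
        order = np.argsort(-truth.genetic_values.to_numpy())
        top, bottom = order[:50], order[-50:]
        assert counts[top].mean() > counts[bottom].mean()


class TestClassifySnpTypes:
    @staticmethod
    def build(seed, inb_effect, hyb_pattern, n_i=60, n_h=150, noise=0.3):
        """hyb_pattern maps dosage class -> mean shift."""
        rng = np.random.default_rng(seed)
        ci = rng.choice([0.0, 2.0], n_i)
        ch = rng.choice([0.0, 1.0, 2.0], n_h)
        vi = rng.normal(0, noise, n_i) + inb_effect * (ci == 2.0)
        vh = rng.normal(0, noise, n_h)
        for cls, shift in hyb_pattern.items():
            vh += shift * (ch == cls)
        return ci[:, None], vi, ch[:, None], vh

    def test_type_i_additive_pattern(self):
        ci, vi, ch, vh = self.build(1, 2.0, {1.0: 1.0, 2.0: 2.0})
        res = classify_snp_types(["s"], ci, ["s"], vi, ch, ["s"], vh)
        assert res["type"].iloc[0] == "I"

    def test_type_ii_het_and_matching_homozygote(self):
        ci, vi, ch, vh = self.build(2, 2.0, {1.0: 2.0, 2.0: 2.0})
        res = classify_snp_types(["s"], ci, ["s"], vi, ch, ["s"], vh)
        assert res["type"].iloc[0] == "II"

    def test_type_iii_heterozygote_best(self):
        ci, vi, ch, vh = self.build(3, 1.5, {1.0: 2.5})
        res = classify_snp_types(["s"], ci, ["s"], vi, ch, ["s"], vh)
        assert res["type"].iloc[0] == "III"

    def test_type_iv_superior_homozygote_flips(self):
        ci, vi, ch, vh = self.build(4, 2.0, {0.0: 2.5})
        res = classify_snp_types(["s"], ci, ["s"], vi, ch, ["s"], vh)
        assert res["type"].iloc[0] == "IV"

    def test_type_v_no_differences(self):
        ci, vi, ch, vh = self.build(50, 0.0, {})
        res = classify_snp_types(["s"], ci, ["s"], vi, ch, ["s"], vh)
        assert res["type"].iloc[0] == "V"

    def test_missing_hybrid_class_flagged(self):
        ci, vi, ch, vh = self.build(6, 2.0, {1.0: 1.0, 2.0: 2.0})
        ch = np.where(ch == 1.0, 0.0, ch)  # no heterozygotes observed
        res = classify_snp_types(["s"], ci, ["s"], vi, ch, ["s"], vh)
        assert "missing_hybrid_class" in res["flag"].iloc[0]
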
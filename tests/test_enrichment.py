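"""Target enrichment: contingency stats, Fisher p, ranking, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

import angiomoa as am
from angiomoa.enrichment import ContingencyTable
from _oracles import fisher_enumeration, prevalence_ratio
from conftest import tiny_config


class TestBinarize:
    def test_binary_passthrough(self):
        df = pd.DataFrame([[0, 1], [1, 0]], index=["c1", "c2"], columns=["t1", "t2"])
        out = am.binarize(am.ActivityMatrix(df))
        pd.testing.assert_frame_equal(out, df)

    def test_cutoff_boundary_is_active(self):
        df = pd.DataFrame([[0.49, 0.5, 0.51]], index=["c1"],
                          columns=["t1", "t2", "t3"])
        out = am.binarize(am.ActivityMatrix(df, activity_cutoff=0.5))
        assert out.loc["c1"].tolist() == [0, 1, 1]

    def test_out_of_range_rejected(self):
        df = pd.DataFrame([[1.2]], index=["c1"], columns=["t1"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            am.ActivityMatrix(df)


class TestContingency:
    def test_counts(self):
        study = pd.DataFrame({"t1": [1] * 8 + [0] * 2},
                             index=[f"c{i}" for i in range(10)])
        bkg = pd.DataFrame({"t1": [1, 0, 0, 0]}, index=list("wxyz"))
        t = am.build_contingency("t1", list(study.index), study, bkg)
        assert (t.a, t.b, t.c, t.d) == (8, 2, 1, 3)

    def test_target_absent_everywhere(self):
        study = pd.DataFrame({"t1": [0, 0]}, index=["c1", "c2"])
        bkg = pd.DataFrame({"t1": [0, 0, 0]}, index=["b1", "b2", "b3"])
        t = am.build_contingency("t1", ["c1", "c2"], study, bkg)
        assert (t.a, t.c) == (0, 0)

    def test_empty_phenotype_set_rejected(self):
        study = pd.DataFrame({"t1": [1]}, index=["c1"])
        with pytest.raises(ValueError, match="empty"):
            am.build_contingency("t1", [], study, study)


class TestOddsRatio:
    @pytest.mark.parametrize("table, expected", [
        ((5, 5, 500, 500), 1.0),
        ((0, 10, 100, 900), 0.0),
        ((8, 2, 100, 300), 3.2),
    ])
    def test_prevalence_ratio_values(self, table, expected):
        assert am.odds_ratio(ContingencyTable(*table)) == pytest.approx(expected)

    def test_sentinels(self):
        assert am.odds_ratio(ContingencyTable(3, 7, 0, 100)) == math.inf
        assert math.isnan(am.odds_ratio(ContingencyTable(0, 10, 0, 100)))

    def test_textbook_or(self):
        assert am.textbook_odds_ratio(ContingencyTable(8, 2, 100, 300)) \
            == pytest.approx(12.0)

    def test_monotone_in_a_at_fixed_margins(self):
        # move one compound from inactive to active; phenotype size fixed
        values = [am.odds_ratio(ContingencyTable(a, 10 - a, 50, 450))
                  for a in range(11)]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestFisher:
    def test_no_association_p_one(self):
        assert am.fisher_exact_p(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_enumerated_small_tables(self):
        assert am.fisher_exact_p(ContingencyTable(3, 1, 1, 3)) \
            == pytest.approx(34 / 70, abs=1e-10)
        assert am.fisher_exact_p(ContingencyTable(10, 0, 0, 10)) \
            == pytest.approx(2 / 184756, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            if t.phenotype_size == 0 or t.background_size == 0:
                continue
            for side in ("two-sided", "greater"):
                assert am.fisher_exact_p(t, side) == pytest.approx(
                    fisher_enumeration(t.a, t.b, t.c, t.d, side), abs=1e-10)


def _planted_setup(seed, **overrides):
    cfg = tiny_config(seed=seed, **overrides)
    study, background, truth = am.simulate_activity_matrix(cfg)
    labels = am.simulate_labels(cfg, truth)["label"]
    return cfg, study, background, truth, labels


class TestEnrichTargets:
    def test_sorted_by_p_with_flags(self, tiny_bundle):
        res = am.enrich_targets(am.PROMOTE, tiny_bundle.study_activity,
                                tiny_bundle.labels["label"],
                                tiny_bundle.background_activity)
        assert list(res["p_value"]) == sorted(res["p_value"])
        assert (res["significant"] == (res["p_value"] < 0.05)).all()
        assert len(res) == tiny_bundle.study_activity.values.shape[1]

    def test_single_target(self):
        _, study, background, truth, labels = _planted_setup(
            3, n_targets=1, planted_targets_per_class=0)
        res = am.enrich_targets(am.PROMOTE, study, labels, background)
        assert len(res) == 1

    def test_universe_mismatch_lists_difference(self, tiny_bundle):
        trimmed = am.ActivityMatrix(
            tiny_bundle.background_activity.values.drop(columns=["T001"]))
        with pytest.raises(ValueError, match="T001"):
            am.enrich_targets(am.PROMOTE, tiny_bundle.study_activity,
                              tiny_bundle.labels["label"], trimmed)

    def test_planted_contingency_rate(self):
        _, study, background, truth, labels = _planted_setup(
            7, n_promoters=25, planted_activity_rate=0.7)
        pro = labels[labels == am.PROMOTE].index
        sb = study.binarize()
        rates = [am.build_contingency(t, list(pro), sb, background.binarize()).a / len(pro)
                 for t in truth.promoter_targets]
        se = np.sqrt(0.7 * 0.3 / (len(pro) * len(rates)))
        assert abs(np.mean(rates) - 0.7) <= 3 * se

    def test_null_small_panel_rarely_flags(self):
        """Background and phenotype share every rate: with a 3-target panel,
        no target is flagged at alpha=0.05 in >=95% of simulations."""
        clean = 0
        runs = 40
        for s in range(runs):
            cfg = am.SimulationConfig(
                n_promoters=20, n_inhibitors=5, n_unknown=0, n_background=4000,
                n_targets=3, planted_targets_per_class=0,
                baseline_activity_rate=0.05, planted_activity_rate=1.0,
                n_genes=10, planted_degs_per_class=0, n_controls=2,
                n_gene_sets=1, gene_set_size=5, seed=s)
            study, background, truth = am.simulate_activity_matrix(cfg)
            labels = am.simulate_labels(cfg, truth)["label"]
            res = am.enrich_targets(am.PROMOTE, study, labels, background)
            clean += int(res["significant"].sum() == 0)
        assert clean / runs >= 0.95

    def test_null_or_centred_at_one(self, rng):
        """Swapping the phenotype set for an equal-rate background subset
        yields an OR distribution with median near 1."""
        bkg = pd.DataFrame(rng.binomial(1, 0.3, size=(600, 1)),
                           index=[f"b{i}" for i in range(600)], columns=["t1"])
        ors = []
        for _ in range(100):
            pick = rng.choice(600, size=20, replace=False)
            fake = bkg.iloc[pick]
            rest = bkg.drop(index=fake.index)
            t = am.build_contingency("t1", list(fake.index), fake, rest)
            ors.append(am.odds_ratio(t))
        med = float(np.median(ors))
        assert 0.8 <= med <= 1.25

    def test_background_scale_invariance_of_top_k(self):
        """10x the background at identical rates leaves the top-k target set
        unchanged in >=90% of planted simulations."""
        hits = 0
        runs = 10
        for s in range(runs):
            _, study, bkg_small, truth, labels = _planted_setup(
                100 + s, n_background=150, n_promoters=12)
            _, _, bkg_big, _, _ = _planted_setup(
                100 + s, n_background=1500, n_promoters=12)
            k = tiny_config().planted_targets_per_class
            top_small = set(am.enrich_targets(am.PROMOTE, study, labels,
                                              bkg_small).head(k)["target_id"])
            top_big = set(am.enrich_targets(am.PROMOTE, study, labels,
                                            bkg_big).head(k)["target_id"])
            hits += int(top_small == top_big)
        assert hits / runs >= 0.9


class TestClusterProfiles:
    def test_identical_rows_merge_first_at_zero_distance(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 0, 1]],
                         index=list("abcd"), columns=["t1", "t2", "t3"])
        res = am.cluster_profiles(m)
        assert res.row_linkage[0, 2] == 0.0
        merged = {int(res.row_linkage[0, 0]), int(res.row_linkage[0, 1])}
        assert merged == {0, 1}

    def test_block_diagonal_recovered_at_k2(self):
        m = pd.DataFrame(
            [[1, 1, 1, 0, 0, 0], [1, 1, 0, 0, 0, 0], [1, 0, 1, 0, 0, 0],
             [0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 0], [0, 0, 0, 0, 1, 1]],
            index=list("abcdef"), columns=[f"t{i}" for i in range(6)])
        res = am.cluster_profiles(m, k=2)
        groups = res.row_clusters
        assert len(set(groups[list("abc")])) == 1
        assert len(set(groups[list("def")])) == 1
        assert groups["a"] != groups["d"]

    def test_row_order_is_permutation(self, tiny_bundle):
        m = tiny_bundle.study_activity.binarize()
        res = am.cluster_profiles(m)
        assert sorted(res.row_order) == sorted(m.index)

    def test_constant_matrix_warns(self, caplog):
        m = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["t1", "t2"])
        with caplog.at_level("WARNING", logger="angiomoa.enrichment"):
            am.cluster_profiles(m)
        assert any("single cluster" in r.message for r in caplog.records)
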
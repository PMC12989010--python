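import numpy as np
import pandas as pd
import pytest
from scipy import stats

from awnet.descriptives import CentralityProfile
from awnet.linkage import (
    clinical_relevance,
    run_linkage,
    step1_zero_order,
    step2_centrality_linkage,
)
from oracles import spearman_by_hand


def _profile(ei_raw, labels):
    ei = np.asarray(ei_raw, dtype=float)
    z = (ei - ei.mean()) / ei.std(ddof=1)
    order = np.argsort(-ei)
    rank = np.empty(len(ei), dtype=int)
    rank[order] = np.arange(1, len(ei) + 1)
    k = round(len(ei) / 3)
    mask = np.zeros(len(ei), dtype=bool)
    mask[order[:k]] = True
    return CentralityProfile(
        node_labels=list(labels), ei_raw=ei, ei_z=z, rank=rank, top_third=mask
    )


@pytest.fixture
def toy_data():
    rng = np.random.default_rng(10)
    facets = pd.DataFrame(
        rng.integers(0, 13, size=(40, 6)) / 4.0, columns=list("abcdef")
    )
    conditions = pd.DataFrame(
        rng.normal(60, 10, size=(40, 2)), columns=["anx", "adhd"]
    )
    return facets, conditions


class TestStep1:
    def test_condition_equal_to_node_column_gives_unit_correlation(self, toy_data):
        facets, conditions = toy_data
        conditions = conditions.copy()
        conditions["anx"] = facets["c"].to_numpy()
        step1 = step1_zero_order(facets, conditions)
        assert step1.loc["c", "anx"] == pytest.approx(1.0)

    def test_shape_and_labels_preserved(self, toy_data):
        facets, conditions = toy_data
        step1 = step1_zero_order(facets, conditions)
        assert step1.shape == (6, 2)
        assert list(step1.index) == list(facets.columns)
        assert list(step1.columns) == list(conditions.columns)

    def test_matches_independent_rank_correlation(self, toy_data):
        facets, conditions = toy_data
        step1 = step1_zero_order(facets, conditions)
        for node in facets.columns:
            for cond in conditions.columns:
                expected = spearman_by_hand(
                    facets[node].to_numpy(), conditions[cond].to_numpy()
                )
                assert step1.loc[node, cond] == pytest.approx(expected, abs=1e-12)

    def test_missing_condition_rows_dropped_listwise_per_condition(self, toy_data):
        facets, conditions = toy_data
        conditions = conditions.copy()
        conditions.iloc[:5, 0] = np.nan
        with pytest.warns(UserWarning, match="dropped 5"):
            step1 = step1_zero_order(facets, conditions)
        keep = conditions["anx"].notna().to_numpy()
        expected = spearman_by_hand(
            facets["a"].to_numpy()[keep], conditions["anx"].to_numpy()[keep]
        )
        assert step1.loc["a", "anx"] == pytest.approx(expected, abs=1e-12)

    def test_row_count_mismatch_rejected(self, toy_data):
        facets, conditions = toy_data
        with pytest.raises(ValueError):
            step1_zero_order(facets.iloc[:30], conditions)


class TestStep2:
    def test_step1_column_matching_centrality_ranks_gives_rho_one(self):
        labels = list("abcdef")
        profile = _profile([3.0, 2.0, 1.5, 1.0, 0.5, 0.1], labels)
        step1 = pd.DataFrame({"c1": [0.6, 0.5, 0.4, 0.3, 0.2, 0.1]}, index=labels)
        out = step2_centrality_linkage(profile, step1)
        assert out.loc["c1", "rho"] == pytest.approx(1.0)
        reversed_out = step2_centrality_linkage(
            profile, step1.iloc[::-1].set_axis(labels)
        )
        assert reversed_out.loc["c1", "rho"] == pytest.approx(-1.0)

    def test_matches_independent_spearman_with_p_value(self, toy_data):
        facets, conditions = toy_data
        profile = _profile(np.arange(6)[::-1] * 0.3 + np.array([0, .1, 0, .2, 0, .1]), facets.columns)
        step1 = step1_zero_order(facets, conditions)
        out = step2_centrality_linkage(profile, step1)
        for cond in step1.columns:
            ref = stats.spearmanr(profile.ei_z, step1[cond].to_numpy())
            assert out.loc[cond, "rho"] == pytest.approx(
                spearman_by_hand(profile.ei_z, step1[cond].to_numpy()), abs=1e-10
            )
            assert out.loc[cond, "p_value"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_to_monotone_transform_of_centrality(self, toy_data):
        facets, conditions = toy_data
        ei = np.array([3.0, 2.0, 1.5, 1.0, 0.5, 0.1])
        step1 = step1_zero_order(facets, conditions)
        a = step2_centrality_linkage(_profile(ei, facets.columns), step1)
        b = step2_centrality_linkage(_profile(np.exp(ei), facets.columns), step1)
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)

    def test_too_few_nodes_rejected(self):
        profile = _profile([1.0, 0.5, 0.2], list("abc"))
        step1 = pd.DataFrame({"c1": [0.1, 0.2, 0.3]}, index=list("abc"))
        with pytest.raises(ValueError):
            step2_centrality_linkage(profile, step1)


class TestClinicalRelevance:
    def _toy(self):
        labels = list("abcdef")
        profile = _profile([3.0, 2.0, 1.5, 1.0, 0.5, 0.1], labels)  # top third: a, b
        step1 = pd.DataFrame(
            {
                "c1": [0.50, 0.10, 0.40, 0.30, 0.05, 0.00],
                "c2": [0.20, 0.45, 0.10, 0.35, 0.25, 0.15],
            },
            index=labels,
        )
        return profile, step1

    def test_flags_match_exhaustive_enumeration(self):
        profile, step1 = self._toy()
        threshold, relevant, differential = clinical_relevance(profile, step1)
        expected_threshold = round(float(step1.to_numpy().mean()), 4)
        assert threshold == expected_threshold
        top = {"a", "b"}
        for node in step1.index:
            for cond in step1.columns:
                above = step1.loc[node, cond] >= expected_threshold
                assert relevant.loc[node, cond] == (above and node in top)
                assert differential.loc[node, cond] == (above and node not in top)

    def test_relevant_and_differential_partition_above_threshold_cells(self):
        profile, step1 = self._toy()
        threshold, relevant, differential = clinical_relevance(profile, step1)
        above = step1 >= threshold
        assert ((relevant | differential) == above).all().all()
        assert not (relevant & differential).any().any()

    def test_fixed_threshold_mode(self):
        profile, step1 = self._toy()
        threshold, relevant, _ = clinical_relevance(
            profile, step1, threshold_mode="fixed", threshold_value=0.25
        )
        assert threshold == 0.25
        assert relevant.loc["a", "c1"]
        assert not relevant.loc["a", "c2"]

    def test_empty_step1_rejected(self):
        profile, step1 = self._toy()
        with pytest.raises(ValueError):
            clinical_relevance(profile, step1.iloc[:0, :0])


class TestPlantedLoadingsRecovery:
    def test_conditions_loading_on_central_nodes_yield_positive_step2(
        self, recovery_bundle
    ):
        # conditions built from planted high-centrality facets should produce a
        # larger mean step-2 rho than the same loadings randomly permuted
        facets = recovery_bundle.facets
        profile = recovery_bundle.profile
        rng = np.random.default_rng(99)
        top_idx = np.argsort(-profile.ei_raw)[:5]
        loadings = np.zeros((facets.shape[1], 4))
        for j in range(4):
            loadings[rng.choice(top_idx, 3, replace=False), j] = 1.0
        noise = rng.normal(size=(len(facets), 4))
        signal = facets.to_numpy() @ loadings
        conditions = pd.DataFrame(
            60 + 12 * (signal + noise * signal.std(axis=0)),
            columns=[f"c{j}" for j in range(4)],
            index=facets.index,
        )
        planted = run_linkage(facets, conditions, profile)
        perm = rng.permutation(facets.shape[1])
        signal_perm = facets.to_numpy() @ loadings[perm]
        conditions_perm = pd.DataFrame(
            60 + 12 * (signal_perm + noise * signal_perm.std(axis=0)),
            columns=[f"c{j}" for j in range(4)],
            index=facets.index,
        )
        control = run_linkage(facets, conditions_perm, profile)
        assert planted.step2["rho"].mean() > 0
        assert planted.step2["rho"].mean() > control.step2["rho"].mean()
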
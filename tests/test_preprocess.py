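import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from awnet.preprocess import (
    estimate_correlations,
    goldbricker,
    hittner_dependent_z,
    nearest_psd_correlation,
    npn_transform,
)
from awnet.synthetic import generate_true_network, sample_facet_data
from oracles import hittner_z_reference


def _df(**cols):
    return pd.DataFrame(cols)


class TestNpnTransform:
    def test_rank_invariance_under_exponential(self):
        x = np.array([0.1, 2.0, 1.5, 0.7, 3.0, 2.2, 0.4])
        df = _df(a=x, b=np.exp(x))
        out = npn_transform(df)
        np.testing.assert_array_equal(out["a"].to_numpy(), out["b"].to_numpy())

    def test_matches_truncated_ecdf_formula_on_n5(self):
        # independent evaluation of the stated formula for x = 1..5
        n = 5
        delta = 1.0 / (4.0 * n**0.25 * math.sqrt(math.pi * math.log(n)))
        from scipy.special import ndtri

        expected = np.array(
            [ndtri(min(max(r / n, delta), 1 - delta)) for r in range(1, 6)]
        )
        out = npn_transform(_df(a=[1.0, 2.0, 3.0, 4.0, 5.0]))
        np.testing.assert_allclose(out["a"].to_numpy(), expected, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=40, unique=True))
    def test_strictly_increasing_in_the_original_ranks(self, values):
        out = npn_transform(_df(a=values))["a"].to_numpy()
        order = np.argsort(values)
        assert np.all(np.diff(out[order]) > 0)

    def test_average_ranks_for_ties(self):
        out = npn_transform(_df(a=[1.0, 1.0, 2.0, 3.0]))["a"].to_numpy()
        assert out[0] == out[1]

    def test_constant_column_error_names_column(self):
        with pytest.raises(ValueError, match="b"):
            npn_transform(_df(a=[1.0, 2.0, 3.0], b=[1.0, 1.0, 1.0]))


class TestEstimateCorrelations:
    def test_duplicated_column_has_unit_correlation(self):
        x = np.random.default_rng(0).normal(size=30)
        R = estimate_correlations(_df(a=x, b=x.copy(), c=x + np.arange(30)))
        assert R.values.loc["a", "b"] == pytest.approx(1.0)

    def test_single_column_gives_one_by_one_identity(self):
        R = estimate_correlations(_df(a=[1.0, 2.0, 3.0, 4.0]))
        assert R.values.shape == (1, 1)
        assert R.values.iloc[0, 0] == 1.0

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        shuffled = df.sample(frac=1.0, random_state=7)
        a = estimate_correlations(df).to_numpy()
        b = estimate_correlations(shuffled).to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            estimate_correlations(_df(a=[1.0, 2.0], b=[2.0, 1.0]))

    def test_psd_repair_clips_negative_eigenvalues(self):
        # pairwise-inconsistent matrix: indefinite by independent eigendecomposition
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0
        fixed, repaired = nearest_psd_correlation(bad)
        assert repaired
        assert np.linalg.eigvalsh(fixed).min() >= -1e-8
        assert np.allclose(np.diag(fixed), 1.0)
        ok, flag = nearest_psd_correlation(np.eye(3))
        assert not flag

    def test_output_is_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 6)))
        df.columns = [f"v{i}" for i in range(6)]
        R = estimate_correlations(df)
        assert np.linalg.eigvalsh(R.to_numpy()).min() >= -1e-8


class TestHittnerTest:
    def test_matches_independent_reference_implementation(self):
        z, p = hittner_dependent_z(0.3, 0.6, 0.8, n=100)
        z_ref = hittner_z_reference(0.3, 0.6, 0.8, n=100)
        assert z == pytest.approx(z_ref, abs=1e-10)
        from scipy import stats

        assert p == pytest.approx(2 * stats.norm.sf(abs(z_ref)), abs=1e-10)

    def test_antisymmetric_in_the_two_correlations(self):
        z1, _ = hittner_dependent_z(0.3, 0.6, 0.5, n=80)
        z2, _ = hittner_dependent_z(0.6, 0.3, 0.5, n=80)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_equal_correlations_give_zero_statistic(self):
        z, p = hittner_dependent_z(0.4, 0.4, 0.9, n=50)
        assert z == 0.0 and p == 1.0


class TestGoldbricker:
    def test_exact_duplicate_columns_are_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        df = _df(a=x, b=x.copy(), c=rng.normal(size=100), d=rng.normal(size=100))
        report = goldbricker(df)
        flagged = report.flagged_pairs
        assert len(flagged) == 1
        row = flagged.iloc[0]
        assert {row["node_i"], row["node_j"]} == {"a", "b"}
        assert row["r_ij"] == pytest.approx(1.0)
        assert row["prop_significant"] == 0.0

    def test_pairs_below_cor_min_never_appear(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        report = goldbricker(df, cor_min=0.5)
        assert len(report.candidate_pairs) == 0

    def test_reduction_drops_lower_variance_member(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        df = _df(a=2 * x, b=x + rng.normal(0, 0.01, 200), c=rng.normal(size=200))
        report = goldbricker(df)
        assert {row for row in report.suggested_reduced_node_set} == {"a", "c"}

    def test_near_duplicate_nodes_detected_on_generated_data(self):
        # two nodes with latent correlation ~0.95 and identical neighbors
        hits = 0
        for seed in range(5):
            spec = generate_true_network(p=6, n_communities=2, within_prob=0.5,
                                         between_prob=0.1, seed=seed)
            K = spec.precision.copy()
            # make node 1 an almost-copy of node 0: same neighbors, huge partial
            K[0, 1] = K[1, 0] = -0.9 * np.sqrt(K[0, 0] * K[1, 1])
            K[2:, 1] = K[1, 2:] = K[2:, 0]
            if np.linalg.eigvalsh(K).min() <= 0:
                K += np.eye(6) * (abs(np.linalg.eigvalsh(K).min()) + 0.05)
            spec.precision = K
            from awnet.synthetic import partials_from_precision

            spec.true_partials = partials_from_precision(K)
            X = sample_facet_data(spec, n=280, seed=seed + 100)
            report = goldbricker(X, cor_min=0.5)
            pairs = {
                frozenset((r["node_i"], r["node_j"]))
                for _, r in report.flagged_pairs.iterrows()
            }
            if frozenset(("F01", "F02")) in pairs:
                hits += 1
        assert hits >= 4

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            goldbricker(_df(a=[1.0, 2.0, 3.0], b=[3.0, 2.0, 1.0]))
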
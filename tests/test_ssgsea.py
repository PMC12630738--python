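"""Enrichment scoring, permutation null, scaling and significance calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spotsig.discovery import Signature
from spotsig.ssgsea import (
    HIGH,
    LOW,
    NOT_SIGNIFICANT,
    PermutationNull,
    ScoringError,
    _score_from_ranks,
    center_matrix,
    fisher_combine,
    min_max_scale_scores,
    permutation_significance,
    score_signature,
    score_units,
    ssgsea_raw_score,
)


def oracle_score(values, in_set, w=0.0):
    """Literal running-sum re-implementation of the enrichment score.

    Walks the decreasing-value ordering (ties broken by index) and sums
    at every rank the gap between the weighted in-set ECDF and the
    uniform out-set ECDF.
    """
    values = np.asarray(values, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    G = len(values)
    m = int(in_set.sum())
    order = sorted(range(G), key=lambda i: (-values[i], i))
    if w == 0.0:
        weights = {i: 1.0 / m for i in range(G) if in_set[i]}
    else:
        a = {i: abs(values[i]) ** w for i in range(G) if in_set[i]}
        tot = sum(a.values())
        weights = (
            {i: 1.0 / m for i in a} if tot == 0
            else {i: v / tot for i, v in a.items()}
        )
    score, p_in, p_out = 0.0, 0.0, 0.0
    for i in order:
        if in_set[i]:
            p_in += weights[i]
        else:
            p_out += 1.0 / (G - m)
        score += p_in - p_out
    return score


class TestCenter:
    def test_hand_example_and_idempotence(self):
        m = np.array([[1.0, 3.0], [0.0, 0.0]])
        c = center_matrix(m)
        np.testing.assert_allclose(c, [[-1, 1], [0, 0]])
        np.testing.assert_allclose(center_matrix(c), c)

    def test_single_unit_refused(self):
        with pytest.raises(ScoringError):
            center_matrix(np.ones((3, 1)))


class TestRawScore:
    def test_matches_oracle_on_all_3_subsets_of_10(self, rng):
        values = rng.normal(size=10)
        for subset in itertools.combinations(range(10), 3):
            mask = np.zeros(10, dtype=bool)
            mask[list(subset)] = True
            assert ssgsea_raw_score(values, mask) == pytest.approx(
                oracle_score(values, mask), abs=1e-10
            )

    def test_matches_oracle_with_weighting(self, rng):
        for _ in range(20):
            values = rng.normal(size=15)
            mask = np.zeros(15, dtype=bool)
            mask[rng.choice(15, size=4, replace=False)] = True
            for w in (0.25, 1.0, 2.0):
                assert ssgsea_raw_score(values, mask, w) == pytest.approx(
                    oracle_score(values, mask, w), abs=1e-10
                )

    def test_top_ranked_set_is_the_maximum(self, rng):
        values = rng.normal(size=10)
        best = np.zeros(10, dtype=bool)
        best[np.argsort(-values)[:3]] = True
        best_score = ssgsea_raw_score(values, best)
        for subset in itertools.combinations(range(10), 3):
            mask = np.zeros(10, dtype=bool)
            mask[list(subset)] = True
            assert ssgsea_raw_score(values, mask) <= best_score + 1e-12

    def test_rank_only_statistic_is_monotone_invariant(self, rng):
        values = rng.normal(size=30)
        assert len(np.unique(values)) == 30
        mask = np.zeros(30, dtype=bool)
        mask[:7] = True
        s = ssgsea_raw_score(values, mask, 0.0)
        assert ssgsea_raw_score(np.exp(values), mask, 0.0) == pytest.approx(s)
        assert ssgsea_raw_score(3 * values + 7, mask, 0.0) == pytest.approx(s)

    def test_antisymmetric_under_rank_reversal(self, rng):
        values = rng.normal(size=25)
        mask = np.zeros(25, dtype=bool)
        mask[rng.choice(25, size=6, replace=False)] = True
        assert ssgsea_raw_score(-values, mask) == pytest.approx(
            -ssgsea_raw_score(values, mask)
        )

    def test_random_sets_average_near_zero(self, rng):
        values = rng.normal(size=40)
        scores = []
        for _ in range(400):
            mask = np.zeros(40, dtype=bool)
            mask[rng.choice(40, size=8, replace=False)] = True
            scores.append(ssgsea_raw_score(values, mask))
        assert abs(np.mean(scores)) < 1.0  # scores range over tens

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ScoringError):
            ssgsea_raw_score(np.arange(5.0), np.zeros(5, dtype=bool))
        with pytest.raises(ScoringError):
            ssgsea_raw_score(np.arange(5.0), np.ones(5, dtype=bool))

    def test_score_from_ranks_matches_full_computation(self, rng):
        for _ in range(20):
            values = rng.normal(size=30)
            mask = np.zeros(30, dtype=bool)
            mask[rng.choice(30, size=5, replace=False)] = True
            order = np.argsort(-values, kind="stable")
            ranks = np.empty(30)
            ranks[order] = np.arange(1, 31)
            assert _score_from_ranks(ranks[mask], 30, 5) == pytest.approx(
                ssgsea_raw_score(values, mask)
            )


class TestScoreUnits:
    def test_combined_is_half_the_up_down_gap(self, rng):
        genes = [f"g{i}" for i in range(20)]
        m = rng.normal(size=(20, 5))
        sig = Signature("s", up_genes={"g0", "g1"}, down_genes={"g5", "g6"})
        frame = score_units(m, sig, genes, [f"u{j}" for j in range(5)],
                            center=False)
        up_mask = np.isin(genes, ["g0", "g1"])
        dn_mask = np.isin(genes, ["g5", "g6"])
        for j in range(5):
            up_s = ssgsea_raw_score(m[:, j], up_mask)
            dn_s = ssgsea_raw_score(m[:, j], dn_mask)
            row = frame.iloc[j]
            assert row["up_score"] == pytest.approx(up_s)
            assert row["down_score"] == pytest.approx(dn_s)
            assert row["combined_raw"] == pytest.approx((up_s - dn_s) / 2)

    def test_one_sided_down_signature_negated(self, rng):
        genes = [f"g{i}" for i in range(10)]
        m = rng.normal(size=(10, 3))
        sig = Signature("d", down_genes={"g2", "g3"})
        frame = score_units(m, sig, genes, list("abc"), center=False)
        np.testing.assert_allclose(
            frame["combined_raw"], -frame["down_score"]
        )

    def test_absent_signature_raises(self, rng):
        genes = ["g0", "g1", "g2"]
        sig = Signature("x", up_genes={"h9"})
        with pytest.raises(ScoringError):
            score_units(np.zeros((3, 2)), sig, genes, ["a", "b"])

    def test_centering_changes_sparse_unit_ranking(self):
        """A zero count in a gene expressed elsewhere ranks below an
        always-near-zero gene after centering."""
        genes = ["strong", "silent"]
        m = np.array([[0.0, 5.0, 5.0], [0.01, 0.01, 0.01]])
        centered = center_matrix(m)
        # unit 0: strong gene centered to a negative value
        assert centered[0, 0] < centered[1, 0]


class TestScaling:
    def test_bounds_attained_and_degenerate_zero(self):
        frame = pd.DataFrame(
            {"up_score": [0.0, 1.0, 2.0],
             "down_score": [5.0, 5.0, 5.0],
             "combined_raw": [-3.0, 0.0, 5.0]},
            index=["a", "b", "c"],
        )
        out = min_max_scale_scores(frame)
        assert out["combined_scaled"].min() == -1000.0
        assert out["combined_scaled"].max() == 1000.0
        assert out.loc["b", "combined_scaled"] == pytest.approx(-250.0)
        assert (out["down_scaled"] == 0.0).all()


class TestNull:
    def test_small_universe_permutation_guard(self):
        with pytest.raises(ScoringError):
            PermutationNull.build(3, 1, 1, n_permutations=10, seed=0)

    def test_invalid_set_sizes(self):
        with pytest.raises(ScoringError):
            PermutationNull.build(10, 10, 2, seed=0)
        with pytest.raises(ScoringError):
            PermutationNull.build(10, -1, 2, seed=0)

    def test_null_scores_have_zero_mean_shape(self):
        null = PermutationNull.build(50, 5, 5, n_permutations=500, seed=7)
        assert null.null_up.shape == (500,)
        # the rank statistic is symmetric around 0 under the null
        assert abs(null.null_up.mean()) < 3 * null.null_up.std() / np.sqrt(500)

    def test_reproducible_with_seed(self):
        a = PermutationNull.build(30, 4, 4, n_permutations=50, seed=3)
        b = PermutationNull.build(30, 4, 4, n_permutations=50, seed=3)
        np.testing.assert_array_equal(a.null_up, b.null_up)
        np.testing.assert_array_equal(a.null_down, b.null_down)


class TestSignificance:
    def _null(self):
        return PermutationNull.build(40, 3, 3, n_permutations=1000, seed=1)

    def test_extreme_observation_gets_add_one_p(self):
        null = self._null()
        big = null.null_up.max() + 1
        small = null.null_down.min() - 1
        frame = pd.DataFrame(
            {"up_score": [big], "down_score": [small],
             "combined_raw": [1.0], "combined_scaled": [900.0]},
            index=["u"],
        )
        out = permutation_significance(frame, null, mode="bulk")
        assert out.loc["u", "p_up"] == pytest.approx(1 / 1001)
        assert out.loc["u", "p_down"] == pytest.approx(1 / 1001)
        assert out.loc["u", "significance_class"] == HIGH

    def test_fisher_hand_example(self):
        # -2(ln .5 + ln .5) = 2.7726 on 4 df -> sf ~= 0.5966
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-3)
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        with pytest.raises(ScoringError):
            fisher_combine([0.0, 0.5])

    def test_score_cutoff_gates_significance(self):
        null = self._null()
        big = null.null_up.max() + 1
        small = null.null_down.min() - 1
        frame = pd.DataFrame(
            {"up_score": [big, small], "down_score": [small, big],
             "combined_raw": [1.0, -1.0],
             "combined_scaled": [150.0, -900.0]},
            index=["tiny_scale", "low"],
        )
        out = permutation_significance(frame, null, mode="bulk")
        assert out.loc["tiny_scale", "significance_class"] == NOT_SIGNIFICANT
        assert out.loc["low", "significance_class"] == LOW

    def test_st_mode_uses_bonferroni_threshold(self):
        null = self._null()
        # p_high will be ~= Fisher(1/1001, 1/1001) ~ 1.4e-5; with 6
        # signature genes alpha_st = 0.0083 so the call survives, but
        # with an inflated gene count of 10**6 it cannot.
        big, small = null.null_up.max() + 1, null.null_down.min() - 1
        frame = pd.DataFrame(
            {"up_score": [big], "down_score": [small],
             "combined_raw": [1.0], "combined_scaled": [900.0]},
            index=["u"],
        )
        out = permutation_significance(frame, null, mode="st")
        assert out.loc["u", "significance_class"] == HIGH
        out2 = permutation_significance(
            frame, null, mode="st", n_signature_genes=10**6
        )
        assert out2.loc["u", "significance_class"] == NOT_SIGNIFICANT

    def test_unscaled_frame_rejected(self):
        null = self._null()
        frame = pd.DataFrame({"up_score": [0.0], "down_score": [0.0],
                              "combined_raw": [0.0]}, index=["u"])
        with pytest.raises(ScoringError):
            permutation_significance(frame, null)


class TestEndToEnd:
    def test_score_signature_reproducible(self, rng):
        genes = [f"g{i}" for i in range(60)]
        m = rng.normal(size=(60, 30))
        sig = Signature("s", up_genes={"g0", "g1", "g2"},
                        down_genes={"g10", "g11"})
        units = [f"u{j}" for j in range(30)]
        a = score_signature(m, sig, genes, units, seed=5, n_permutations=200)
        b = score_signature(m, sig, genes, units, seed=5, n_permutations=200)
        pd.testing.assert_frame_equal(a, b)
        assert a["combined_scaled"].min() == -1000.0
        assert a["combined_scaled"].max() == 1000.0
        assert set(a["significance_class"]) <= {HIGH, LOW, NOT_SIGNIFICANT}
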
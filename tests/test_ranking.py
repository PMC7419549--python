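"""Rankings and cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twindiag import (
    Evidence,
    GeneratorConfig,
    Vignette,
    error_reduction,
    evaluate_cohort,
    generate_cohort,
    generate_network,
    matched_differential_evaluation,
    posterior_disease,
    rank_comparison,
    rank_diseases,
    stratify_by_rarity,
    top_k_accuracy,
)
from twindiag.ranking import CohortResult, MEASURES

from conftest import small_random_case


@pytest.fixture(scope="module")
def small_cohort():
    cfg = GeneratorConfig(n_risk=3, n_disease=6, n_symptom=9, seed=11)
    net = generate_network(cfg)
    vignettes = generate_cohort(net, cfg, 40)
    return net, vignettes, evaluate_cohort(net, vignettes)


class TestRankDiseases:
    def test_singleton_network(self, single_link):
        r = rank_diseases(single_link, Evidence(positive_symptoms={"S"}), "posterior")
        assert r.entries[0][0] == "D"

    def test_symmetric_tie_break_is_stable(self, symmetric_net):
        """Repeated ranking of a symmetric presentation is deterministic,
        and exact score ties resolve to lexicographic id order."""
        ev = Evidence(positive_symptoms={"S1", "S3"})
        for m in MEASURES:
            orders = {
                tuple(d for d, _ in rank_diseases(symmetric_net, ev, m).entries)
                for _ in range(3)
            }
            assert len(orders) == 1
        tied = rank_diseases(
            symmetric_net, Evidence(positive_symptoms=frozenset()), "expected_sufficiency"
        )
        # no positive symptoms: both measures are exactly zero, id order wins
        assert [d for d, _ in tied.entries] == ["DA", "DB"]

    def test_confounded_disease_scores_zero_but_high_posterior(self, confounder_net):
        """The motivating failure mode: a disease correlated with the
        symptom through a shared risk factor gets a high posterior (above a
        genuine weak cause) although it cannot have caused the symptom; the
        counterfactual measures give it exactly zero and rank every
        positive-scoring cause above it."""
        ev = Evidence(positive_symptoms={"S"})
        prior = posterior_disease(confounder_net, Evidence(), "Dcand")
        post = posterior_disease(confounder_net, ev, "Dcand")
        assert post > prior  # confounding inflates the posterior
        posterior_order = [d for d, _ in rank_diseases(confounder_net, ev, "posterior").entries]
        assert posterior_order.index("Dcand") < posterior_order.index("Dweak")
        for m in ("expected_disablement", "expected_sufficiency"):
            ranking = rank_diseases(confounder_net, ev, m)
            scores = dict(ranking.entries)
            assert scores["Dcand"] == 0.0
            order = [d for d, _ in ranking.entries]
            for d, s in scores.items():
                if s > 0:
                    assert order.index(d) < order.index("Dcand")

    def test_unknown_measure_rejected(self, single_link):
        with pytest.raises(ValueError, match="unknown measure"):
            rank_diseases(single_link, Evidence(positive_symptoms={"S"}), "oddsratio")


class TestTopK:
    def test_counting(self):
        assert top_k_accuracy([1, 3, 2], 1) == pytest.approx(1 / 3)
        assert top_k_accuracy([1, 3, 2], 3) == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            top_k_accuracy([], 1)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        ranks=st.lists(st.integers(1, 12), min_size=1, max_size=50),
        k=st.integers(1, 12),
    )
    def test_monotone_and_matches_recount(self, ranks, k):
        acc = top_k_accuracy(ranks, k)
        assert acc == pytest.approx(sum(r <= k for r in ranks) / len(ranks))
        if k > 1:
            assert acc >= top_k_accuracy(ranks, k - 1)


class TestErrorReduction:
    def test_values(self):
        assert error_reduction(0.5, 0.5) == pytest.approx(0.0)
        assert error_reduction(0.8, 0.9) == pytest.approx(0.5)
        assert error_reduction(0.8, 0.7) < 0.0

    def test_perfect_associative_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            error_reduction(1.0, 0.9)


class TestCohortEvaluation:
    def test_counts_partition_cohort(self, small_cohort):
        net, vignettes, result = small_cohort
        assert len(result) + len(result.failures) == len(vignettes)
        comp = rank_comparison(result, "posterior", "expected_sufficiency")
        assert (
            comp["wins_posterior"] + comp["wins_expected_sufficiency"] + comp["draws"]
            == comp["n"]
            == len(result)
        )

    def test_full_ranking_reaches_certainty(self, small_cohort):
        net, _, result = small_cohort
        for m in MEASURES:
            assert top_k_accuracy(result, len(net.diseases), m) == 1.0

    def test_identical_measures_all_draws(self, small_cohort):
        _, _, result = small_cohort
        comp = rank_comparison(result, "posterior", "posterior")
        assert comp["draws"] == comp["n"]
        assert comp["wins_posterior"] == 0

    def test_wins_and_mean_ranks_hand_counted(self):
        table = pd.DataFrame(
            {
                "vignette_id": ["a", "b"],
                "true_disease": ["D1", "D1"],
                "k": [1, 1],
                "prior": [0.01, 0.01],
                "band": [2, 2],
                "rank_posterior": [2, 2],
                "tiepos_posterior": [2, 2],
                "rank_expected_sufficiency": [1, 3],
                "tiepos_expected_sufficiency": [1, 3],
            }
        )
        result = CohortResult(table, ("posterior", "expected_sufficiency"), 4, (0.5,))
        comp = rank_comparison(result, "posterior", "expected_sufficiency")
        assert comp["wins_posterior"] == 1
        assert comp["wins_expected_sufficiency"] == 1
        assert comp["draws"] == 0
        assert comp["mean_rank_posterior"] == pytest.approx(2.0)
        assert comp["mean_rank_expected_sufficiency"] == pytest.approx(2.0)

    def test_mismatched_measure_rejected(self, small_cohort):
        _, _, result = small_cohort
        with pytest.raises(ValueError, match="not computed"):
            result.ranks("expected_disablement_typo")


class TestStratification:
    def test_bands_partition_cohort(self, small_cohort):
        net, _, result = small_cohort
        strata = stratify_by_rarity(net, result)
        assert sum(len(s) for s in strata.values()) == len(result)

    def test_single_band_is_unstratified(self, small_cohort):
        net, _, result = small_cohort
        strata = stratify_by_rarity(net, result, band_edges=())
        assert list(strata) == [0]
        assert len(strata[0]) == len(result)

    def test_two_singleton_bands(self):
        table = pd.DataFrame(
            {
                "vignette_id": ["a", "b"],
                "true_disease": ["D1", "D2"],
                "k": [1, 1],
                "prior": [0.1, 0.9],
                "band": [0, 1],
                "rank_posterior": [1, 1],
                "tiepos_posterior": [1, 1],
            }
        )
        result = CohortResult(table, ("posterior",), 2, (0.5,))
        strata = stratify_by_rarity(None, result, band_edges=(0.5,))
        assert len(strata[0]) == 1 and len(strata[1]) == 1

    def test_bad_edges_rejected(self, small_cohort):
        net, _, result = small_cohort
        with pytest.raises(ValueError, match="strictly increasing"):
            stratify_by_rarity(net, result, band_edges=(0.5, 0.1))


class TestMatchedDifferential:
    def test_k_equal_to_disease_count_is_certain(self, small_cohort):
        net, _, result = small_cohort
        full = result.table.copy()
        full["k"] = len(net.diseases)
        res = CohortResult(full, result.measures, result.n_diseases, result.band_edges)
        acc = matched_differential_evaluation(res)
        assert all(v == 1.0 for v in acc.values())

    def test_k_one_equals_top_1(self, small_cohort):
        net, _, result = small_cohort
        one = result.table.copy()
        one["k"] = 1
        res = CohortResult(one, result.measures, result.n_diseases, result.band_edges)
        acc = matched_differential_evaluation(res)
        for m in result.measures:
            assert acc[m] == pytest.approx(top_k_accuracy(result, 1, m))

    def test_mixed_k_recounted_by_hand(self, small_cohort):
        _, _, result = small_cohort
        rng = np.random.default_rng(5)
        mixed = result.table.copy()
        mixed["k"] = rng.integers(1, 4, size=len(mixed))
        res = CohortResult(mixed, result.measures, result.n_diseases, result.band_edges)
        acc = matched_differential_evaluation(res)
        for m in result.measures:
            by_hand = np.mean(
                [r <= k for r, k in zip(mixed[f"rank_{m}"], mixed["k"])]
            )
            assert acc[m] == pytest.approx(by_hand)

    def test_missing_k_listed(self, small_cohort):
        _, _, result = small_cohort
        broken = result.table.copy()
        broken.loc[0, "k"] = np.nan
        res = CohortResult(broken, result.measures, result.n_diseases, result.band_edges)
        with pytest.raises(ValueError, match="missing differential size"):
            matched_differential_evaluation(res)
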
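"""Checklist derivation, weight rounding and BCCS case scoring."""

import itertools

import numpy as np
import pytest
from scipy.stats import kendalltau

import turbt_complexity as tc
from turbt_complexity.checklist import DEFAULT_GRANULARITY


class TestWeightAdjustedScore:
    @pytest.mark.parametrize(
        "coefficient, mo, granularity, expected",
        [
            (1.44, 3, 0.5, 4.5),  # location: 4.32 -> nearest half
            (1.10, 3, 1.0, 3.0),  # access: 3.3 -> nearest unit
            (1.0, 3, 1.0, 3.0),  # unit coefficient identity
            (0.99, 1, 1.0, 1.0),
            (0.99, 4, 1.0, 4.0),
            (1.04, 2, 1.0, 2.0),
            (0.96, 3, 1.0, 3.0),
            (1.25, 2, 1.0, 3.0),  # 2.5 ties round up
        ],
    )
    def test_rounding_rule(self, coefficient, mo, granularity, expected):
        assert tc.weight_adjusted_score(coefficient, mo, granularity) == expected

    def test_nonpositive_coefficient_rejected(self):
        with pytest.raises(tc.InvalidInputError):
            tc.weight_adjusted_score(0.0, 3, 1.0)
        with pytest.raises(tc.InvalidInputError):
            tc.weight_adjusted_score(-1.2, 3, 1.0)


class TestDeriveChecklist:
    def test_location_weights_from_published_coefficients(self, published_model):
        catalog = tc.ItemCatalog(
            [
                tc.CatalogItem("trigon", "location", "Trigon", 1),
                tc.CatalogItem("anterior", "location", "Anterior wall", 3),
                tc.CatalogItem("dome", "location", "Dome", 4),
            ]
        )
        table = tc.derive_checklist(published_model, catalog)
        assert {r.item_id: r.weight for r in table.rows} == {
            "trigon": 1.5,
            "anterior": 4.5,
            "dome": 6.0,
        }

    def test_history_weights_equal_median_opinions(self, published_model):
        catalog = tc.ItemCatalog(
            [
                tc.CatalogItem(f"h{k}", "history", f"History {k}", k)
                for k in (1, 2, 3, 4)
            ]
        )
        table = tc.derive_checklist(published_model, catalog)
        assert [r.weight for r in table.rows] == [1.0, 2.0, 3.0, 4.0]

    def test_regenerates_every_published_weight(
        self, published_model, catalog, published_checklist
    ):
        """Deriving from the published coefficients and the catalog's Median
        Opinions reproduces the published checklist row for row."""
        derived = tc.derive_checklist(published_model, catalog)
        derived_weights = {r.item_id: r.weight for r in derived.rows}
        for row in published_checklist.rows:
            assert derived_weights[row.item_id] == row.weight, row.item_id
        assert derived.provenance == "derived"

    def test_identical_mos_give_identical_weights(self, published_model):
        catalog = tc.ItemCatalog(
            [tc.CatalogItem(f"a{k}", "access", f"Access {k}", 3) for k in range(4)]
        )
        weights = {r.weight for r in tc.derive_checklist(published_model, catalog).rows}
        assert len(weights) == 1


class TestScoreCase:
    WORKED_EXAMPLE = {
        "history": "No relevant history",
        "access": "Thin bladder wall",
        "number": "1-3 tumours",
        "size": "3-5 cm",
        "location": "Dome",
    }

    def test_worked_example_sums_to_fifteen(self, published_checklist):
        result = tc.score_case(
            published_checklist, tc.CaseProfile(self.WORKED_EXAMPLE)
        )
        assert result.value == 15.0
        assert result.components == {
            "history": 1.0,
            "access": 4.0,
            "number": 1.0,
            "size": 3.0,
            "location": 6.0,
        }

    def test_minimal_case_sums_to_five_and_a_half(self, published_checklist):
        case = tc.CaseProfile(
            {
                "history": "hist_none",
                "access": "acc_none",
                "number": "num_1_3",
                "size": "size_lt3",
                "location": "loc_trigon",
            }
        )
        assert tc.score_case(published_checklist, case).value == 5.5

    def test_maximal_case_sums_to_twenty_two(self, published_checklist):
        case = tc.CaseProfile(
            {
                "history": "ASA class 4-5",
                "access": "Not amenable to lithotomy position",
                "number": ">10 tumours",
                "size": ">5 cm",
                "location": "Dome",
            }
        )
        assert tc.score_case(published_checklist, case).value == 22.0

    def test_labels_match_case_insensitively(self, published_checklist):
        case = tc.CaseProfile({**self.WORKED_EXAMPLE, "location": "dome"})
        assert tc.score_case(published_checklist, case).value == 15.0

    def test_unknown_item_named_in_error(self, published_checklist):
        case = tc.CaseProfile({**self.WORKED_EXAMPLE, "size": "gigantic"})
        with pytest.raises(tc.InvalidInputError, match="gigantic"):
            tc.score_case(published_checklist, case)

    def test_value_equals_sum_of_components(self, published_checklist, catalog, rng):
        for _ in range(50):
            case = tc.CaseProfile(
                {
                    d: rng.choice([it.item_id for it in catalog.items_in(d)])
                    for d in tc.PREDICTOR_DOMAINS
                }
            )
            result = tc.score_case(published_checklist, case)
            assert result.value == pytest.approx(sum(result.components.values()))
            assert 5.0 <= result.value <= 22.0

    def test_monotone_in_item_weight(self, published_checklist):
        """Swapping any selection for a heavier same-domain item never
        lowers the BCCS."""
        base = tc.score_case(
            published_checklist, tc.CaseProfile(self.WORKED_EXAMPLE)
        )
        for domain in tc.PREDICTOR_DOMAINS:
            for row in published_checklist.items_in(domain):
                case = tc.CaseProfile({**self.WORKED_EXAMPLE, domain: row.item_id})
                swapped = tc.score_case(published_checklist, case)
                original = base.components[domain]
                if row.weight >= original:
                    assert swapped.value >= base.value


def test_bccs_ranks_agree_with_logistic_probability(published_model):
    """Exhaustive 5^5 score grid: Kendall tau between the derived checklist
    sum and the logistic probability is at least 0.95."""
    catalog = tc.ItemCatalog(
        [
            tc.CatalogItem(f"{d}_{s}", d, f"{d} {s}", s)
            for d in tc.PREDICTOR_DOMAINS
            for s in range(1, 6)
        ]
    )
    table = tc.derive_checklist(published_model, catalog)
    weights = {r.item_id: r.weight for r in table.rows}
    sums, probs = [], []
    for combo in itertools.product(range(1, 6), repeat=5):
        scores = dict(zip(tc.PREDICTOR_DOMAINS, combo))
        sums.append(sum(weights[f"{d}_{s}"] for d, s in scores.items()))
        probs.append(tc.predict_probability(published_model, scores))
    tau = kendalltau(sums, probs).statistic
    assert tau >= 0.95


def test_derive_then_score_is_compositional(published_model, catalog):
    """score_case on a derived checklist equals the sum of per-domain
    weight_adjusted_score calls."""
    table = tc.derive_checklist(published_model, catalog)
    case = tc.CaseProfile(
        {
            "history": "hist_pelvic_radiation",
            "access": "acc_urethral_stricture",
            "number": "num_4_10",
            "size": "size_gt5",
            "location": "loc_lateral_wall",
        }
    )
    result = tc.score_case(table, case)
    expected = sum(
        tc.weight_adjusted_score(
            published_model.coefficients[d],
            catalog.get(case.selections[d]).median_opinion,
            DEFAULT_GRANULARITY.get(d, 1.0),
        )
        for d in tc.PREDICTOR_DOMAINS
    )
    assert result.value == pytest.approx(expected)


def test_published_checklist_weights_are_half_unit_steps(published_checklist):
    for row in published_checklist.rows:
        assert row.weight > 0
        assert 2 * row.weight == int(2 * row.weight)
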
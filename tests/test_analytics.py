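"""Distribution tables, shares, durations and the collaboration cross-tab."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from grantminer.analytics import (
    Duration,
    average_duration,
    collaboration_crosstab,
    distribution,
    distribution_from_counts,
    share_of_corpus,
    top_recipients,
)
from grantminer.data_model import CollaborationRecord, CountryInfo, CountryTable

from conftest import make_grant


class TestShareOfCorpus:
    @pytest.mark.parametrize(
        "count,denom,decimals,expected",
        [
            (52928, 69420, 0, 76.0),
            (48879, 69420, 1, 70.4),
            (0, 100, 1, 0.0),
            (1, 200, 1, 0.5),  # exact .5 rounds up, not to even
            (165, 69420, 1, 0.2),
        ],
    )
    def test_examples(self, count, denom, decimals, expected):
        assert share_of_corpus(count, denom, decimals) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            share_of_corpus(1, 0)

    @given(st.integers(1, 10_000), st.data())
    def test_exact_complementarity_pre_rounding(self, denom, data):
        count = data.draw(st.integers(0, denom))
        # complement shares are exactly complementary before rounding
        a = 100 * count / denom
        b = 100 * (denom - count) / denom
        assert a + b == pytest.approx(100.0)
        # and after rounding they differ from 100 by at most one rounding step
        ra = share_of_corpus(count, denom, 1)
        rb = share_of_corpus(denom - count, denom, 1)
        assert abs(ra + rb - 100.0) <= 0.1 + 1e-9


class TestDistribution:
    def test_classified_denominator_table(self):
        counts = {
            "Non-communicable": 40035,
            "Communicable, maternal, perinatal and nutritional conditions": 11123,
            "Injuries": 3056,
            "Others": 1127,
        }
        table = distribution_from_counts(counts, "classified_grants")
        assert table.denominator == 55341
        as_dict = {k: p for k, _, p in table.rows}
        assert as_dict["Non-communicable"] == 72.0
        assert as_dict["Communicable, maternal, perinatal and nutritional conditions"] == 20.0

    def test_all_grants_denominator_for_flag_share(self):
        table = distribution_from_counts(
            {"ntd_flagged": 792}, "all_grants", denominator=69420, decimals=1
        )
        assert table.rows[0][2] == 1.1

    def test_single_key_is_100_percent(self):
        frame = pd.DataFrame({"category": ["A"] * 7})
        table = distribution(frame, "category", "all_grants")
        assert table.rows == (("A", 7, 100.0),)

    def test_unclassified_excluded_from_classified_denominator(self):
        frame = pd.DataFrame({"category": ["A", "A", "B", None, "none"]})
        table = distribution(frame, "category", "classified_grants")
        assert table.denominator == 3
        assert table.n_unclassified == 2
        assert table.counts() == {"A": 2, "B": 1}

    def test_full_partition_counts_sum_to_denominator(self):
        frame = pd.DataFrame({"k": list("aabbbccccd")})
        table = distribution(frame, "k", "all_grants")
        assert sum(c for _, c, _ in table.rows) == table.denominator == 10

    def test_rows_sorted_descending(self):
        frame = pd.DataFrame({"k": list("abbccc")})
        assert [k for k, _, _ in distribution(frame, "k").rows] == ["c", "b", "a"]

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            distribution(pd.DataFrame({"k": ["a"]}), "k", "most_grants")

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError, match="empty denominator"):
            distribution(pd.DataFrame({"k": [None]}), "k", "classified_grants")


class TestTopRecipients:
    def test_ranking_and_cutoff(self):
        grants = (
            [make_grant(f"u{i}", recipient_country="US", recipient_institution="MIT") for i in range(3)]
            + [make_grant(f"k{i}", recipient_country="UK", recipient_institution="UCL") for i in range(2)]
            + [make_grant("s0", recipient_country="SE", recipient_institution="KI")]
        )
        top = top_recipients(grants, "country", 2)
        assert list(top["country"]) == ["US", "UK"]

    def test_tie_broken_alphabetically(self):
        grants = [
            make_grant("a", recipient_country="US"),
            make_grant("b", recipient_country="US"),
            make_grant("c", recipient_country="UK"),
            make_grant("d", recipient_country="UK"),
        ]
        assert list(top_recipients(grants, "country", 2)["country"]) == ["UK", "US"]

    def test_n_larger_than_distinct_returns_all(self):
        grants = [make_grant("a", recipient_country="US")]
        assert len(top_recipients(grants, "country", 10)) == 1

    def test_top_institution_attached(self):
        grants = [
            make_grant("a", recipient_country="US", recipient_institution="MIT"),
            make_grant("b", recipient_country="US", recipient_institution="MIT"),
            make_grant("c", recipient_country="US", recipient_institution="Yale"),
        ]
        top = top_recipients(grants, "country", 1)
        assert top.loc[0, "top_institution"] == "MIT"
        assert top.loc[0, "top_institution_grants"] == 2


class TestAverageDuration:
    def test_two_year_grant(self):
        g = make_grant("a", start_date=date(2016, 1, 1), end_date=date(2018, 1, 1))
        assert average_duration([g]).display == "2 years, 0 months"

    def test_rounding_half_month_up(self):
        # mean of 12 and 25 months = 18.5 -> 1 year, 7 months
        assert Duration.from_months(18.5).display == "1 year, 7 months"

    def test_carry_into_next_year(self):
        assert Duration.from_months(23.8).display == "2 years, 0 months"

    def test_undated_grants_excluded(self):
        g1 = make_grant("a", start_date=date(2016, 1, 1), end_date=date(2018, 1, 1))
        g2 = make_grant("b")  # no dates
        assert average_duration([g1, g2]).display == "2 years, 0 months"

    def test_no_dated_grants_is_error(self):
        with pytest.raises(ValueError, match="no dated grants"):
            average_duration([make_grant("a")])


@pytest.fixture
def mini_countries():
    return CountryTable(
        [
            CountryInfo("Richland", "Europe", "high"),
            CountryInfo("Midland", "Africa", "lower_middle"),
            CountryInfo("Poorland", "Africa", "low"),
        ]
    )


class TestCollaborationCrosstab:
    def test_direct_counted_once_collabs_counted_each(self, mini_countries):
        grants = [make_grant("A", recipient_country="Richland")]
        collabs = [
            CollaborationRecord("A", "I1", "Poorland"),
            CollaborationRecord("A", "I2", "Poorland"),
        ]
        ct = collaboration_crosstab(grants, collabs, mini_countries)
        assert ct.direct_counts["high"] == 1
        assert ct.matrix.loc["high", "low"] == 2
        assert ct.total_collaborations == 2

    def test_no_collaborations(self, mini_countries):
        ct = collaboration_crosstab(
            [make_grant("A", recipient_country="Richland")], [], mini_countries
        )
        assert ct.total_collaborations == 0
        assert int(ct.direct_counts.sum()) == 0

    def test_two_recipients_one_collab_each(self, mini_countries):
        grants = [
            make_grant("A", recipient_country="Richland"),
            make_grant("B", recipient_country="Poorland"),
        ]
        collabs = [
            CollaborationRecord("A", "I", "Richland"),
            CollaborationRecord("B", "I", "Richland"),
        ]
        ct = collaboration_crosstab(grants, collabs, mini_countries)
        assert ct.matrix.loc["high", "high"] == 1
        assert ct.matrix.loc["low", "high"] == 1

    def test_unresolved_collaborations_excluded_and_counted(self, mini_countries):
        grants = [make_grant("A", recipient_country="Richland")]
        collabs = [
            CollaborationRecord("A", "I", "Midland"),
            CollaborationRecord("ZZ", "I", "Midland", resolved=False),
        ]
        ct = collaboration_crosstab(grants, collabs, mini_countries)
        assert ct.total_collaborations == 1
        assert ct.n_unresolved == 1

    def test_row_marginals_equal_group_totals(self, mini_countries):
        grants = [
            make_grant("A", recipient_country="Richland"),
            make_grant("B", recipient_country="Midland"),
        ]
        collabs = [
            CollaborationRecord("A", "I", "Poorland"),
            CollaborationRecord("A", "I", "Richland"),
            CollaborationRecord("B", "I", "Midland"),
        ]
        ct = collaboration_crosstab(grants, collabs, mini_countries)
        totals = ct.row_totals()
        assert totals["high"] == 2
        assert totals["lower_middle"] == 1
        assert int(totals.sum()) == ct.total_collaborations
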
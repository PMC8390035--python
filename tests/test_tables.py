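"""Grouped descriptive tables: counting, moments, partitions, rounding."""

from __future__ import annotations

import numpy as np
import pytest

from egoreach.errors import UsageError
from egoreach.schema import FriendBlock, NeighborBlock, PopulationFrame
from egoreach.synthetic import generate_population
from egoreach.tables import (
    round_half_up,
    roles_distribution,
    size_by_role,
    type_by_covariate,
    type_distribution,
    vulnerability_by_metro,
)
from egoreach.typology import per_ego_results

from conftest import flat_params, make_ego, tie


def _results(records):
    return per_ego_results(PopulationFrame(records=records))


def _friend_ego(ego_id, n_friends, **kw):
    friends = (
        FriendBlock(can_count_on=True, n_friends=n_friends, contact_freq="weekly")
        if n_friends
        else FriendBlock()
    )
    return make_ego(ego_id=ego_id, friends=friends, **kw)


class TestRolesDistribution:
    def test_direct_counting(self):
        records = [
            make_ego(ego_id="0"),
            _friend_ego("1", 2),
            make_ego(ego_id="2", ties=(tie("parent", "same_municipality", "daily"),)),
            make_ego(
                ego_id="3",
                ties=(tie("parent", "same_municipality", "daily"),),
                neighbors=NeighborBlock(can_count_on=True),
            ),
        ]
        table = roles_distribution(_results(records), definition="easy").table
        shares = dict(zip(table["n_roles"], table["share_pct"]))
        assert shares == {0: 25.0, 1: 50.0, 2: 25.0}

    def test_all_empty_single_group(self):
        table = roles_distribution(
            _results([make_ego(ego_id=str(i)) for i in range(3)]), definition="easy"
        ).table
        assert list(table["share_pct"]) == [100.0]
        assert list(table["n_roles"]) == [0]

    def test_mixed_definitions_need_explicit_choice(self):
        results = _results([make_ego(ego_id="a")])
        with pytest.raises(UsageError):
            roles_distribution(results)

    def test_row_zero_equals_no_alters_share(self, default_results):
        """Two routes to the isolation share must agree exactly."""
        keys = ("age_group", "living_arrangement", "gender")
        for definition in ("easy", "accustomed"):
            roles = roles_distribution(default_results, keys, definition).table
            types = type_distribution(default_results, keys, definition).table
            zero = roles[roles["n_roles"] == 0].set_index(list(keys))["share_pct"]
            empty = types[types["network_type"] == "no_alters"].set_index(list(keys))["share_pct"]
            assert np.allclose(zero.sort_index(), empty.sort_index())

    def test_shares_sum_to_100(self, default_results):
        table = roles_distribution(
            default_results, ("age_group", "gender"), "easy"
        ).table
        sums = table.groupby(["age_group", "gender"])["share_pct"].sum()
        assert np.allclose(sums, 100.0)


class TestSizeByRole:
    def test_presence_mean_median(self):
        records = [_friend_ego("a", 2), _friend_ego("b", 0)]
        table = size_by_role(_results(records), definition="easy").table
        row = table[table["role"] == "friend"].iloc[0]
        assert row["pct_with_alter"] == 50.0
        assert row["mean"] == 1.0
        assert row["median"] == 1.0

    def test_all_zero_counts(self):
        table = size_by_role(
            _results([make_ego(ego_id=str(i)) for i in range(4)]), definition="easy"
        ).table
        row = table[table["role"] == "parent"].iloc[0]
        assert (row[["pct_with_alter", "mean", "sd", "median"]] == 0).all()

    def test_sample_sd_and_even_median(self):
        records = [_friend_ego(str(i), n) for i, n in enumerate([0, 1, 2, 3])]
        table = size_by_role(_results(records), definition="easy").table
        row = table[table["role"] == "friend"].iloc[0]
        assert row["mean"] == pytest.approx(1.5)
        assert row["sd"] == pytest.approx(np.std([0, 1, 2, 3], ddof=1))  # ~1.29
        assert row["median"] == pytest.approx(1.5)

    def test_roles_outside_role_set_absent(self):
        table = size_by_role(_results([make_ego(ego_id="a")]), definition="easy").table
        assert set(table["role"]) == {"parent", "sibling", "friend", "neighbor"}


class TestTypeDistribution:
    def test_two_ego_example(self):
        records = [make_ego(ego_id="0"), _friend_ego("1", 3)]
        table = type_distribution(_results(records), definition="easy").table
        by_type = table.set_index("network_type")
        assert by_type.loc["no_alters", "share_pct"] == 50.0
        assert by_type.loc["no_alters", "mean_size"] == 0.0
        assert by_type.loc["non_kin", "share_pct"] == 50.0
        assert by_type.loc["non_kin", "mean_size"] == 3.0

    def test_partition_and_nonempty_means(self, default_results):
        table = type_distribution(
            default_results, ("age_group", "living_arrangement"), "easy"
        ).table
        sums = table.groupby(["age_group", "living_arrangement"])["share_pct"].sum()
        assert np.allclose(sums, 100.0)
        nonempty = table[table["network_type"] != "no_alters"]
        assert (nonempty["mean_size"] >= 1.0).all()
        assert (table["sd_size"] >= 0).all()

    def test_rerun_bit_identical(self, default_results):
        a = type_distribution(default_results, ("gender",), "easy").table
        b = type_distribution(default_results, ("gender",), "easy").table
        assert a.equals(b)


class TestTypeByCovariate:
    def test_degenerate_single_level_equals_plain_distribution(self):
        records = [make_ego(ego_id=str(i)) for i in range(2)] + [_friend_ego("f", 1)]
        results = _results(records)
        strat = type_by_covariate(results, "territorial_area", "easy").table
        plain = type_distribution(results, ("age_group",), "easy").table
        assert list(strat["share_pct"]) == list(plain["share_pct"])

    def test_unknown_covariate_rejected(self, default_results):
        with pytest.raises(UsageError):
            type_by_covariate(default_results, "favourite_colour", "easy")

    def test_education_gradient_via_stratified_params(self):
        """Friend availability 0.9 vs 0.3 must push the non-kin share up."""
        high = flat_params(n=5000, friend_count_on=0.9, neighbor_count_on=0.2, seed=1)
        low = flat_params(n=5000, friend_count_on=0.3, neighbor_count_on=0.2, seed=2)
        share = {}
        for name, params in [("high", high), ("low", low)]:
            results = per_ego_results(generate_population(params))
            table = type_distribution(results, definition="easy").table
            share[name] = table.set_index("network_type")["share_pct"].get("non_kin", 0.0)
        assert share["high"] > share["low"]


class TestVulnerabilityByMetro:
    def test_all_metropolitan(self):
        records = [
            make_ego(ego_id=str(i), place_of_residence="metropolitan") for i in range(3)
        ]
        table = vulnerability_by_metro(_results(records)).table
        assert not table.empty
        assert (table["metro_pct"] == 100.0).all()
        # both-empty single young adults populate the easy row (very critical)
        # and the accustomed row (critical)
        assert set(table["level"]) == {"very_critical", "critical"}
        assert set(table["definition"]) == {"easy", "accustomed"}

    def test_no_empty_networks_yields_empty_table(self):
        records = [_friend_ego("a", 2)]
        table = vulnerability_by_metro(_results(records)).table
        assert table.empty

    def test_independence_gives_uniform_metro_share(self):
        """Metropolitan residence independent of networks: every populated
        cell sits near the marginal 20%."""
        params = flat_params(n=10_000, metro=0.2, seed=8)
        results = per_ego_results(generate_population(params))
        table = vulnerability_by_metro(results).table
        assert not table.empty
        for _, row in table.iterrows():
            se3 = 300.0 * np.sqrt(0.2 * 0.8 / row["n"])
            assert abs(row["metro_pct"] - 20.0) <= se3

    def test_requires_both_definitions(self):
        results = per_ego_results(
            PopulationFrame(records=[make_ego(ego_id="a")]), definitions=("easy",)
        )
        with pytest.raises(UsageError):
            vulnerability_by_metro(results)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(0.05, 0.1), (0.15, 0.2), (0.25, 0.3), (12.34, 12.3), (99.96, 100.0)]
    )
    def test_half_up_one_decimal(self, value, expected):
        assert round_half_up(value) == expected

    def test_rounded_table_keeps_n_exact(self, default_results):
        gt = type_distribution(default_results, ("gender",), "easy")
        rounded = gt.rounded()
        assert rounded["n"].equals(gt.table["n"])
        assert (rounded["share_pct"] * 10 == (rounded["share_pct"] * 10).round()).all()
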
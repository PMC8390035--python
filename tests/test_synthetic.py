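"""Synthetic generator: determinism, skip patterns, calibration, oracle."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from pydantic import ValidationError

from egoreach.errors import UsageError
from egoreach.schema import KinRole
from egoreach.synthetic import (
    GeneratorParams,
    RoleParams,
    default_params,
    expected_no_alters_share,
    generate_population,
)
from egoreach.typology import per_ego_results

from conftest import flat_params, flat_role


def _binomial_3se(p: float, n: int) -> float:
    return 3.0 * np.sqrt(p * (1.0 - p) / n)


class TestContracts:
    def test_determinism_identical_frames(self):
        params = flat_params(n=100, seed=42)
        a = generate_population(params)
        b = generate_population(params)
        assert a.records == b.records
        assert a.metadata == b.metadata
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_different_seeds_differ(self):
        params = flat_params(n=200)
        a = generate_population(params, seed=1)
        b = generate_population(params, seed=2)
        assert a.records != b.records

    def test_degenerate_all_absent(self):
        kin = {KinRole.PARENT: flat_role(0.0), KinRole.SIBLING: flat_role(0.0)}
        params = flat_params(n=50, kin=kin, friend_count_on=0.0, neighbor_count_on=0.0)
        frame = generate_population(params, seed=5)
        for rec in frame:
            assert rec.kin_ties == ()
            assert not rec.friends.can_count_on
            assert not rec.neighbors.can_count_on

    def test_metadata_carries_seed_and_digest(self):
        params = flat_params(n=10)
        frame = generate_population(params, seed=9)
        assert frame.provenance == "synthetic"
        assert frame.metadata["seed"] == 9
        assert frame.metadata["params_digest"] == params.digest()

    def test_digest_stable_and_sensitive(self):
        a, b = flat_params(n=10), flat_params(n=10)
        assert a.digest() == b.digest()
        assert a.digest() != flat_params(n=11).digest()

    def test_skip_patterns(self):
        params = default_params(seed=3)
        frame = generate_population(params)
        for rec in frame.records[::37]:
            roles = {t.role for t in rec.kin_ties}
            if rec.age_group.value == "young_adult":
                assert roles <= {KinRole.PARENT, KinRole.SIBLING}
            else:
                assert KinRole.PARENT not in roles

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            RoleParams(presence=0.5, count_dist={1: 0.7, 2: 0.2},  # sums to 0.9
                       proximity_dist={"same_municipality": 1.0},
                       freq_dist={"weekly": 1.0})
        with pytest.raises(ValidationError):
            GeneratorParams(group_sizes={"young_adult:single:male": -1}, strata={})
        with pytest.raises(ValidationError):
            GeneratorParams(group_sizes={"young_adult:single:male": 5}, strata={})

    def test_elderly_stratum_rejects_parent_role(self):
        base = flat_params(age_group="elderly", n=5)
        stratum = list(base.strata.values())[0]
        bad_roles = {**stratum.roles, KinRole.PARENT: flat_role(0.5)}
        with pytest.raises(ValidationError):
            GeneratorParams(
                group_sizes=base.group_sizes,
                strata={list(base.strata)[0]: stratum.model_copy(update={"roles": bad_roles})},
            )


class TestOracle:
    def test_enumeration_of_half_half_roles(self):
        """Four independent roles at inclusion 0.5: enumerate 2^4 patterns."""
        params = flat_params()  # every young-adult role included w.p. 0.5
        share = expected_no_alters_share(params, "easy", "young_adult")
        qs = [0.5, 0.5, 0.5, 0.5]
        enumerated = sum(
            np.prod([q if bit else 1 - q for q, bit in zip(qs, bits)])
            for bits in product([0, 1], repeat=4)
            if not any(bits)
        )
        assert share == pytest.approx(enumerated) == pytest.approx(0.0625)

    def test_degenerate_limits(self):
        kin = {KinRole.PARENT: flat_role(0.0), KinRole.SIBLING: flat_role(0.0)}
        empty = flat_params(kin=kin, friend_count_on=0.0, neighbor_count_on=0.0)
        assert expected_no_alters_share(empty, "easy", "young_adult") == pytest.approx(1.0)
        sure = flat_params(neighbor_count_on=1.0)
        assert expected_no_alters_share(sure, "accustomed", "young_adult") == pytest.approx(0.0)

    def test_accustomed_share_at_least_easy_share(self):
        params = default_params()
        for age_group in ("young_adult", "elderly"):
            easy = expected_no_alters_share(params, "easy", age_group)
            acc = expected_no_alters_share(params, "accustomed", age_group)
            assert acc >= easy

    def test_radius_relaxation_lowers_empty_share(self):
        params = default_params()
        for definition in ("easy", "accustomed"):
            base = expected_no_alters_share(params, definition, "elderly")
            relaxed = expected_no_alters_share(
                params, definition, "elderly", radius_policy="within_16km"
            )
            assert relaxed <= base

    def test_correlation_hook_disables_oracle(self):
        base = flat_params()
        key = list(base.strata)[0]
        stratum = base.strata[key].model_copy(update={"family_nearby_prob": 0.5})
        params = GeneratorParams(group_sizes=base.group_sizes, strata={key: stratum})
        with pytest.raises(UsageError):
            expected_no_alters_share(params, "easy", "young_adult")

    def test_unmatched_group_raises(self):
        with pytest.raises(UsageError):
            expected_no_alters_share(flat_params(), "easy", "elderly")


class TestCalibration:
    """Implied default-parameter marginals against the observed shares."""

    def test_friend_and_neighbor_availability_single_young_males(self):
        params = default_params()
        stratum = params.strata["young_adult:single:male"]
        assert stratum.friends.count_on_prob * stratum.friends.weekly_prob == pytest.approx(0.689)
        assert stratum.neighbors.count_on_prob == pytest.approx(0.481)

    def test_friend_availability_all_young_strata(self):
        params = default_params()
        want = {"single:male": 0.689, "single:female": 0.686,
                "couple:male": 0.567, "couple:female": 0.556}
        for cell, share in want.items():
            f = params.strata[f"young_adult:{cell}"].friends
            assert f.count_on_prob * f.weekly_prob == pytest.approx(share)

    def test_metropolitan_share_young_singles(self):
        params = default_params()
        cov = params.strata["young_adult:single:male"].covariates["place_of_residence"]
        assert cov["metropolitan"] == pytest.approx(0.165)

    def test_implied_kin_inclusion_shares_match_both_definitions(self):
        """The solved proximity/frequency scales reproduce the observed
        per-role inclusion shares for every stratum and definition."""
        from egoreach.synthetic import _KIN_SHARES, _inclusion_given_presence

        params = default_params()
        for (age_group, living, gender), kin in _KIN_SHARES.items():
            stratum = params.strata[f"{age_group}:{living}:{gender}"]
            for role, (easy_pct, acc_pct) in kin.items():
                rp = stratum.roles[role]
                p_near = sum(
                    p for lvl, p in rp.proximity_dist.items()
                    if lvl.value in ("same_building", "same_municipality")
                )
                p_week = sum(
                    p for lvl, p in rp.freq_dist.items()
                    if lvl.value in ("daily", "several_weekly", "weekly")
                )
                easy = rp.presence * _inclusion_given_presence(rp.count_dist, p_near)
                acc = rp.presence * _inclusion_given_presence(rp.count_dist, p_near * p_week)
                assert easy == pytest.approx(easy_pct / 100, abs=1e-9)
                assert acc == pytest.approx(acc_pct / 100, abs=1e-9)

    def test_simulated_friend_share_single_young_males(self):
        """10,000 single young males: count-on weekly friend share near 0.689."""
        params = default_params().restrict("young_adult:single:male", 10_000)
        frame = generate_population(params, seed=101)
        share = np.mean([rec.friends.meets_weekly for rec in frame])
        assert abs(share - 0.689) <= _binomial_3se(0.689, 10_000)

    def test_simulated_neighbor_share_single_young_males(self):
        params = default_params().restrict("young_adult:single:male", 10_000)
        frame = generate_population(params, seed=202)
        share = np.mean([rec.neighbors.can_count_on for rec in frame])
        assert abs(share - 0.481) <= _binomial_3se(0.481, 10_000)

    def test_simulated_empty_share_matches_oracle(self):
        """Monte-Carlo empty-network share within 3 SE of the closed form."""
        params = default_params().restrict("elderly:single:female", 10_000)
        frame = generate_population(params, seed=77)
        results = per_ego_results(frame)
        for definition in ("easy", "accustomed"):
            expected = expected_no_alters_share(params, definition, "elderly")
            simulated = (results[f"{definition}_type"] == "no_alters").mean()
            assert abs(simulated - expected) <= _binomial_3se(expected, 10_000)
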
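"""Shared fixtures, factories and independent oracles for the test suite."""

from __future__ import annotations

from types import MappingProxyType

import pytest
from hypothesis import settings, strategies as st

from egoreach.networks import Definition, EgoNetwork, role_set
from egoreach.schema import (
    AgeClass,
    ContactFreq,
    EgoRecord,
    FriendBlock,
    Gender,
    KinRole,
    KinTie,
    LivingArrangement,
    NeighborBlock,
    Proximity,
)
from egoreach.synthetic import (
    FriendParams,
    GeneratorParams,
    NeighborParams,
    RoleParams,
    StratumParams,
)

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


# --------------------------------------------------------------------------
# Record factory
# --------------------------------------------------------------------------

_DEMO_DEFAULTS = dict(
    territorial_area="north",
    place_of_residence="gt_10k",
    education="medium",
    health="good",
    income_source="employed",
)


def make_ego(
    age_class: str = "25-34",
    living: str = "single",
    gender: str = "male",
    ties: tuple = (),
    friends: FriendBlock | None = None,
    neighbors: NeighborBlock | None = None,
    ego_id: str = "e1",
    **kwargs,
) -> EgoRecord:
    fields = {**_DEMO_DEFAULTS, **kwargs}
    return EgoRecord(
        ego_id=ego_id,
        age_class=age_class,
        gender=gender,
        living_arrangement=living,
        kin_ties=tuple(ties),
        friends=friends or FriendBlock(),
        neighbors=neighbors or NeighborBlock(),
        **fields,
    )


def tie(role: str, proximity: str, freq: str) -> KinTie:
    return KinTie(role=role, proximity=proximity, contact_freq=freq)


def net_from_counts(counts: dict, age_group: str, definition: str = "easy") -> EgoNetwork:
    """Assemble an EgoNetwork consistent with its own invariants."""
    rs = role_set(age_group)
    full = {r: int(counts.get(r, 0)) for r in rs.roles}
    kin = {"parent", "sibling", "child", "grandchild"}
    return EgoNetwork(
        ego_id="x",
        definition=Definition(definition),
        alter_counts=MappingProxyType(full),
        size=sum(full.values()),
        n_roles=sum(1 for v in full.values() if v > 0),
        kin_present=any(v > 0 for r, v in full.items() if r in kin),
        nonkin_present=full.get("friend", 0) > 0 or full.get("neighbor", 0) > 0,
    )


# --------------------------------------------------------------------------
# Independent network-rule oracle (hand-coded from the rule text; kept free
# of the implementation's recode helpers)
# --------------------------------------------------------------------------

_NEAR = {
    "same_municipality": {"same_building", "same_municipality"},
    "within_16km": {"same_building", "same_municipality", "within_16km"},
}
_WEEKLY = {"daily", "several_weekly", "weekly"}


def brute_force_counts(ego: EgoRecord, definition: str, radius: str = "same_municipality") -> dict:
    counts = {r: 0 for r in role_set(ego.age_group).roles}
    for t in ego.kin_ties:
        near = t.proximity.value in _NEAR[radius]
        weekly = t.contact_freq.value in _WEEKLY
        if near and (definition == "easy" or weekly):
            counts[t.role.value] += 1
    if ego.friends.can_count_on and ego.friends.contact_freq.value in _WEEKLY:
        counts["friend"] = ego.friends.n_friends
    if ego.neighbors.can_count_on:
        counts["neighbor"] = ego.neighbors.n_neighbors or 1
    return counts


def truth_table_type(present: dict, roles: tuple) -> str:
    """Direct transcription of the five type definitions over role presence."""
    kin_roles = {"parent", "sibling", "child", "grandchild"}
    if not any(present.get(r) for r in roles):
        return "no_alters"
    if all(present.get(r) for r in roles):
        return "comprehensive"
    has_kin = any(present.get(r) for r in roles if r in kin_roles)
    has_nonkin = any(present.get(r) for r in roles if r not in kin_roles)
    if has_kin and not has_nonkin:
        return "kin"
    if has_nonkin and not has_kin:
        return "non_kin"
    return "mixed"


# --------------------------------------------------------------------------
# Generator-parameter helpers
# --------------------------------------------------------------------------

def flat_role(presence: float, p_near: float = 1.0, p_week: float = 1.0,
              count_dist: dict | None = None) -> RoleParams:
    """Role params with all near mass on same_municipality, weekly on weekly."""
    return RoleParams(
        presence=presence,
        count_dist=count_dist or {1: 1.0},
        proximity_dist={
            Proximity.SAME_MUNICIPALITY: p_near,
            Proximity.BEYOND_16KM: 1.0 - p_near,
        },
        freq_dist={ContactFreq.WEEKLY: p_week, ContactFreq.NEVER: 1.0 - p_week},
    )


def flat_params(
    age_group: str = "young_adult",
    living: str = "single",
    gender: str = "male",
    n: int = 100,
    kin: dict | None = None,
    friend_count_on: float = 0.5,
    friend_weekly: float = 1.0,
    neighbor_count_on: float = 0.5,
    seed: int = 0,
    metro: float = 0.2,
) -> GeneratorParams:
    """Single-stratum parameters with explicit inclusion probabilities."""
    if kin is None:
        kin = (
            {KinRole.PARENT: flat_role(0.5), KinRole.SIBLING: flat_role(0.5)}
            if age_group == "young_adult"
            else {
                KinRole.SIBLING: flat_role(0.5),
                KinRole.CHILD: flat_role(0.5),
                KinRole.GRANDCHILD: flat_role(0.5),
            }
        )
    ages = {"18-24": 0.2, "25-34": 0.8} if age_group == "young_adult" else {"65-74": 0.5, "75plus": 0.5}
    key = f"{age_group}:{living}:{gender}"
    return GeneratorParams(
        group_sizes={key: n},
        strata={
            key: StratumParams(
                roles=kin,
                friends=FriendParams(
                    count_on_prob=friend_count_on, weekly_prob=friend_weekly, count_geom_p=0.5
                ),
                neighbors=NeighborParams(count_on_prob=neighbor_count_on),
                covariates={
                    "age_class": ages,
                    "territorial_area": {"north": 1.0},
                    "place_of_residence": {"metropolitan": metro, "gt_10k": 1.0 - metro},
                    "education": {"medium": 1.0},
                    "health": {"good": 1.0},
                    "income_source": {"employed": 1.0},
                },
            )
        },
        seed=seed,
    )


# --------------------------------------------------------------------------
# Hypothesis strategies
# --------------------------------------------------------------------------

_PROXIMITIES = [p for p in Proximity if p is not Proximity.SAME_HOUSEHOLD]


@st.composite
def ego_records(draw) -> EgoRecord:
    age_class = draw(st.sampled_from(list(AgeClass)))
    young = age_class in (AgeClass.A18_24, AgeClass.A25_34)
    living = draw(st.sampled_from(list(LivingArrangement)))
    gender = draw(st.sampled_from(list(Gender)))
    roles = (
        [(KinRole.PARENT, 2), (KinRole.SIBLING, 3)]
        if young
        else [(KinRole.SIBLING, 3), (KinRole.CHILD, 3), (KinRole.GRANDCHILD, 3)]
    )
    ties = []
    for role, cap in roles:
        k = draw(st.integers(min_value=0, max_value=cap))
        for _ in range(k):
            ties.append(
                KinTie(
                    role=role,
                    proximity=draw(st.sampled_from(_PROXIMITIES)),
                    contact_freq=draw(st.sampled_from(list(ContactFreq))),
                )
            )
    if draw(st.booleans()):
        friends = FriendBlock(
            can_count_on=True,
            n_friends=draw(st.integers(min_value=1, max_value=12)),
            contact_freq=draw(st.sampled_from(list(ContactFreq))),
        )
    else:
        friends = FriendBlock()
    if draw(st.booleans()):
        neighbors = NeighborBlock(
            can_count_on=True, n_neighbors=draw(st.sampled_from([None, 1, 2, 5]))
        )
    else:
        neighbors = NeighborBlock(can_count_on=False)
    cohab = draw(st.booleans()) if (young and living is LivingArrangement.COUPLE) else False
    return make_ego(
        age_class=age_class.value,
        living=living.value,
        gender=gender.value,
        ties=tuple(ties),
        friends=friends,
        neighbors=neighbors,
        has_cohabiting_children=cohab,
    )


@pytest.fixture(scope="session")
def default_population():
    """One calibrated default population, shared across tests."""
    from egoreach.synthetic import default_params, generate_population

    return generate_population(default_params(seed=11))


@pytest.fixture(scope="session")
def default_results(default_population):
    from egoreach.typology import per_ego_results

    return per_ego_results(default_population)
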
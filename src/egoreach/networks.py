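"""Construction of the easy-to-reach and accustomed-to-reach ego networks.

Two nested network definitions are built from each ego record:

* **easy-to-reach** — kin alters living near the ego (same municipality by
  default) regardless of contact frequency; friends the ego can count on and
  meets at least weekly (weekly contact proxies friends' proximity, which the
  survey does not record); neighbours the ego can count on.
* **accustomed-to-reach** — as above, but kin must additionally be met
  face-to-face at least once a week.  Friend and neighbour rules are
  unchanged, so the accustomed network is role-wise contained in the easy one.

Network *size* counts alters (three friends and three siblings count as six);
the *number of roles* counts distinct alter roles present (the same network
counts as two roles).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping, Union

import pandas as pd

from .errors import DataError
from .schema import (
    AgeGroup,
    EgoRecord,
    RadiusPolicy,
    recode_contact_freq,
    recode_proximity,
)

__all__ = [
    "Definition",
    "RoleSet",
    "EgoNetwork",
    "role_set",
    "build_network",
    "networks_wide",
    "networks_long",
    "KIN_NETWORK_ROLES",
    "NONKIN_NETWORK_ROLES",
    "ALL_NETWORK_ROLES",
]


class Definition(str, enum.Enum):
    EASY = "easy"
    ACCUSTOMED = "accustomed"


KIN_NETWORK_ROLES = ("parent", "sibling", "child", "grandchild")
NONKIN_NETWORK_ROLES = ("friend", "neighbor")
ALL_NETWORK_ROLES = KIN_NETWORK_ROLES + NONKIN_NETWORK_ROLES

_ROLE_LISTS: Mapping[AgeGroup, tuple[str, ...]] = {
    AgeGroup.YOUNG_ADULT: ("parent", "sibling", "friend", "neighbor"),
    AgeGroup.ELDERLY: ("sibling", "child", "grandchild", "friend", "neighbor"),
}


@dataclass(frozen=True)
class RoleSet:
    """The ordered alter roles available to an age group (4 for young adults,
    5 for the elderly)."""

    age_group: AgeGroup
    roles: tuple[str, ...]


def role_set(age_group: Union[str, AgeGroup]) -> RoleSet:
    group = AgeGroup(age_group)
    return RoleSet(age_group=group, roles=_ROLE_LISTS[group])


@dataclass(frozen=True)
class EgoNetwork:
    """One ego's personal network under one definition."""

    ego_id: str
    definition: Definition
    alter_counts: Mapping[str, int]
    size: int
    n_roles: int
    kin_present: bool
    nonkin_present: bool


def build_network(
    ego: EgoRecord,
    definition: Union[str, Definition],
    radius_policy: Union[str, RadiusPolicy] = RadiusPolicy.SAME_MUNICIPALITY,
) -> EgoNetwork:
    """Apply the alter-inclusion rules of ``definition`` to one ego.

    A kin tie is included iff it is near under ``radius_policy`` and, for the
    accustomed-to-reach definition, met at least weekly.  Friends contribute
    their reported number when the ego counts on them and meets them at least
    weekly; neighbours contribute their reported number (or one when the
    number is unknown) when the ego counts on them.
    """
    definition = Definition(definition)
    radius_policy = RadiusPolicy(radius_policy)
    rs = role_set(ego.age_group)
    counts = {role: 0 for role in rs.roles}

    for tie in ego.kin_ties:
        if tie.role.value not in counts:
            raise DataError(
                f"ego {ego.ego_id}: kin role {tie.role.value!r} is outside the "
                f"{ego.age_group.value} role set"
            )
        if not recode_proximity(tie.proximity, radius_policy):
            continue
        if definition is Definition.ACCUSTOMED and not recode_contact_freq(tie.contact_freq):
            continue
        counts[tie.role.value] += 1

    if ego.friends.meets_weekly:
        counts["friend"] = ego.friends.n_friends
    if ego.neighbors.can_count_on:
        counts["neighbor"] = ego.neighbors.n_neighbors if ego.neighbors.n_neighbors else 1

    size = sum(counts.values())
    n_roles = sum(1 for c in counts.values() if c > 0)
    kin_present = any(counts[r] > 0 for r in rs.roles if r in KIN_NETWORK_ROLES)
    nonkin_present = counts.get("friend", 0) > 0 or counts.get("neighbor", 0) > 0
    return EgoNetwork(
        ego_id=ego.ego_id,
        definition=definition,
        alter_counts=MappingProxyType(counts),
        size=size,
        n_roles=n_roles,
        kin_present=kin_present,
        nonkin_present=nonkin_present,
    )


def networks_wide(networks: Iterable[EgoNetwork]) -> pd.DataFrame:
    """One row per (ego, definition); role-count columns, size and n_roles.

    Roles outside an ego's role set are left missing, not zero.
    """
    rows = []
    for net in networks:
        row: dict[str, object] = {"ego_id": net.ego_id, "definition": net.definition.value}
        for role in ALL_NETWORK_ROLES:
            row[role] = net.alter_counts.get(role, pd.NA)
        row["size"] = net.size
        row["n_roles"] = net.n_roles
        rows.append(row)
    cols = ["ego_id", "definition", *ALL_NETWORK_ROLES, "size", "n_roles"]
    return pd.DataFrame(rows, columns=cols).astype({"size": int, "n_roles": int}, errors="ignore")


def networks_long(networks: Iterable[EgoNetwork]) -> pd.DataFrame:
    """Tidy long table: one row per (ego, definition, role)."""
    rows = [
        {
            "ego_id": net.ego_id,
            "definition": net.definition.value,
            "role": role,
            "count": count,
        }
        for net in networks
        for role, count in net.alter_counts.items()
    ]
    return pd.DataFrame(rows, columns=["ego_id", "definition", "role", "count"])
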
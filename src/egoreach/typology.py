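"""Network composition typology and relational-vulnerability grading.

Networks are classified into five mutually exclusive types from the roles
present: *No Alters* (empty network), *Comprehensive* (at least one alter of
every role available to the age group), *Kin* (only kin roles), *Non-kin*
(only friends and/or neighbours) and *Mixed* (at least one kin alter together
with at least one friend or neighbour).

Egos whose network is empty are graded on a three-level relational
vulnerability scale.  An empty easy-to-reach network signals a critical lack
of nearby others: *very critical* for singles (both age groups), *more
critical* for couples, whose partner is a protective relational resource.
When only the accustomed-to-reach network is empty the ego still has nearby
alters, just not ones they habitually meet: *very critical* for single
elderly, *critical* for single young adults and for couples of either age
group.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import ConsistencyError
from .networks import (
    Definition,
    EgoNetwork,
    RoleSet,
    build_network,
    role_set,
)
from .schema import AgeGroup, EgoRecord, LivingArrangement, PopulationFrame, RadiusPolicy

__all__ = [
    "NetworkType",
    "VulnerabilityLevel",
    "classify_type",
    "assign_vulnerability",
    "vulnerability_row_level",
    "per_ego_results",
]


class NetworkType(str, enum.Enum):
    NO_ALTERS = "no_alters"
    KIN = "kin"
    NON_KIN = "non_kin"
    MIXED = "mixed"
    COMPREHENSIVE = "comprehensive"


class VulnerabilityLevel(str, enum.Enum):
    VERY_CRITICAL = "very_critical"
    MORE_CRITICAL = "more_critical"
    CRITICAL = "critical"
    NONE = "none"


def classify_type(network: EgoNetwork, rs: Optional[RoleSet] = None) -> NetworkType:
    """Classify one network; total over all possible networks.

    Comprehensive is checked before the kin/non-kin/mixed split because a
    network with every role present also satisfies the mixed predicate and
    the types are mutually exclusive.
    """
    if rs is None:
        roles = tuple(network.alter_counts.keys())
    else:
        roles = rs.roles
    if network.size == 0:
        return NetworkType.NO_ALTERS
    if all(network.alter_counts.get(r, 0) >= 1 for r in roles):
        return NetworkType.COMPREHENSIVE
    if not network.nonkin_present:
        return NetworkType.KIN
    if not network.kin_present:
        return NetworkType.NON_KIN
    return NetworkType.MIXED


def assign_vulnerability(
    age_group: Union[str, AgeGroup],
    living_arrangement: Union[str, LivingArrangement],
    easy_type: Union[str, NetworkType],
    accustomed_type: Union[str, NetworkType, None] = None,
) -> VulnerabilityLevel:
    """Grade a No Alters ego; ``none`` when both networks are non-empty.

    ``accustomed_type`` may be omitted when only the easy-to-reach network was
    built.  An ego empty under easy but non-empty under accustomed violates
    network nesting and raises :class:`ConsistencyError`.
    """
    age_group = AgeGroup(age_group)
    living = LivingArrangement(living_arrangement)
    easy_type = NetworkType(easy_type)
    if accustomed_type is not None:
        accustomed_type = NetworkType(accustomed_type)

    if easy_type is NetworkType.NO_ALTERS:
        if accustomed_type is not None and accustomed_type is not NetworkType.NO_ALTERS:
            raise ConsistencyError(
                "empty easy-to-reach network with non-empty accustomed-to-reach "
                "network violates nesting"
            )
        if living is LivingArrangement.SINGLE:
            return VulnerabilityLevel.VERY_CRITICAL
        return VulnerabilityLevel.MORE_CRITICAL
    if accustomed_type is NetworkType.NO_ALTERS:
        if living is LivingArrangement.SINGLE and age_group is AgeGroup.ELDERLY:
            return VulnerabilityLevel.VERY_CRITICAL
        return VulnerabilityLevel.CRITICAL
    return VulnerabilityLevel.NONE


def vulnerability_row_level(
    age_group: Union[str, AgeGroup],
    living_arrangement: Union[str, LivingArrangement],
    definition: Union[str, Definition],
) -> VulnerabilityLevel:
    """Level attached to a (group, definition-empty) cell of the grading table."""
    definition = Definition(definition)
    if definition is Definition.EASY:
        return assign_vulnerability(age_group, living_arrangement, NetworkType.NO_ALTERS, None)
    return assign_vulnerability(
        age_group, living_arrangement, NetworkType.KIN, NetworkType.NO_ALTERS
    )


_COVARIATE_COLUMNS = [
    "age_group",
    "age_class",
    "living_arrangement",
    "gender",
    "territorial_area",
    "place_of_residence",
    "education",
    "health",
    "income_source",
    "weight",
]


def per_ego_results(
    frame: Union[PopulationFrame, Iterable[EgoRecord]],
    definitions: Iterable[Union[str, Definition]] = (Definition.EASY, Definition.ACCUSTOMED),
    radius_policy: Union[str, RadiusPolicy] = RadiusPolicy.SAME_MUNICIPALITY,
) -> pd.DataFrame:
    """Build networks, classify them and grade vulnerability for every ego.

    Returns one row per ego: covariates, then per definition the role counts
    (missing for roles outside the ego's role set), size, number of roles and
    network type, plus the vulnerability level.
    """
    definitions = [Definition(d) for d in definitions]
    records = frame.records if isinstance(frame, PopulationFrame) else list(frame)
    rows = []
    for rec in records:
        row: dict[str, object] = {"ego_id": rec.ego_id}
        row["age_group"] = rec.age_group.value
        for col in _COVARIATE_COLUMNS[1:]:
            value = getattr(rec, col)
            row[col] = value.value if isinstance(value, enum.Enum) else value
        types: dict[Definition, NetworkType] = {}
        for definition in definitions:
            net = build_network(rec, definition, radius_policy)
            rs = role_set(rec.age_group)
            types[definition] = classify_type(net, rs)
            prefix = definition.value
            for role in rs.roles:
                row[f"{prefix}_{role}"] = net.alter_counts[role]
            row[f"{prefix}_size"] = net.size
            row[f"{prefix}_n_roles"] = net.n_roles
            row[f"{prefix}_type"] = types[definition].value
        if Definition.EASY in types:
            row["vulnerability"] = assign_vulnerability(
                rec.age_group,
                rec.living_arrangement,
                types[Definition.EASY],
                types.get(Definition.ACCUSTOMED),
            ).value
        rows.append(row)
    df = pd.DataFrame(rows)
    # Stable column order: id, covariates, per-definition blocks, grade.
    ordered = ["ego_id", *_COVARIATE_COLUMNS]
    for definition in definitions:
        prefix = definition.value
        for role in ("parent", "sibling", "child", "grandchild", "friend", "neighbor"):
            col = f"{prefix}_{role}"
            if col in df.columns:
                ordered.append(col)
        ordered += [f"{prefix}_size", f"{prefix}_n_roles", f"{prefix}_type"]
    if "vulnerability" in df.columns:
        ordered.append("vulnerability")
    df = df.reindex(columns=[c for c in ordered if c in df.columns])
    role_cols = [
        c for c in df.columns
        if any(c.endswith(f"_{r}") for r in ("parent", "sibling", "child", "grandchild", "friend", "neighbor"))
    ]
    return df.astype({c: "Int64" for c in role_cols})
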
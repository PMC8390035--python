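"""Descriptive tables over constructed networks.

Every tabulation consumes the per-ego results frame produced by
:func:`egoreach.typology.per_ego_results` and returns a
:class:`GroupedTable`: a tidy data frame (group keys as leading columns)
carrying full-precision statistics, plus a half-up rounded rendering that
mirrors how such survey tables are printed (one decimal for shares and
means).  Standard deviations use the sample (n-1) denominator; the median
of an even-sized group is the midpoint of the two central values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .errors import UsageError
from .networks import ALL_NETWORK_ROLES, Definition
from .typology import NetworkType, vulnerability_row_level

__all__ = [
    "GroupedTable",
    "roles_distribution",
    "size_by_role",
    "type_distribution",
    "type_by_covariate",
    "vulnerability_by_metro",
    "round_half_up",
]

_COVARIATE_CHOICES = ("territorial_area", "place_of_residence", "education")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as survey tables print."""
    if pd.isna(value):
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GroupedTable:
    """A tidy grouped statistics table with display rounding attached."""

    table: pd.DataFrame
    group_keys: list[str]
    rounding: int = 1
    metadata: dict = field(default_factory=dict)

    def rounded(self) -> pd.DataFrame:
        out = self.table.copy()
        for col in out.columns:
            if col in self.group_keys or col == "n" or not pd.api.types.is_float_dtype(out[col]):
                continue
            out[col] = out[col].map(lambda v: round_half_up(v, self.rounding))
        return out

    def to_csv(self, path: Union[str, Path], rounded: bool = True) -> None:
        (self.rounded() if rounded else self.table).to_csv(path, index=False)

    def to_string(self, rounded: bool = True) -> str:
        return (self.rounded() if rounded else self.table).to_string(index=False)


def _resolve_definition(results: pd.DataFrame, definition: Union[str, Definition, None]) -> str:
    present = [d.value for d in Definition if f"{d.value}_type" in results.columns]
    if definition is not None:
        d = Definition(definition).value
        if d not in present:
            raise UsageError(f"results carry no {d!r} network columns")
        return d
    if len(present) != 1:
        raise UsageError(
            "results carry several network definitions; pass `definition` explicitly"
        )
    return present[0]


def _grouped(results: pd.DataFrame, group_keys: Sequence[str]):
    missing = [k for k in group_keys if k not in results.columns]
    if missing:
        raise UsageError(f"unknown grouping key(s): {missing}")
    if group_keys:
        return results.groupby(list(group_keys), sort=True, observed=True)
    return [((), results)]


def _key_dict(group_keys: Sequence[str], key) -> dict:
    if not group_keys:
        return {}
    if len(group_keys) == 1 and not isinstance(key, tuple):
        key = (key,)
    return dict(zip(group_keys, key))


def roles_distribution(
    results: pd.DataFrame,
    group_keys: Sequence[str] = (),
    definition: Union[str, Definition, None] = None,
) -> GroupedTable:
    """Per group, % of egos by number of distinct alter roles present.

    Row 0 is the physically (easy-to-reach) or socially (accustomed-to-reach)
    isolated share.
    """
    d = _resolve_definition(results, definition)
    col = f"{d}_n_roles"
    max_roles = int(results[col].max()) if len(results) else 0
    rows = []
    for key, grp in _grouped(results, group_keys):
        n = len(grp)
        counts = grp[col].value_counts()
        for k in range(0, max_roles + 1):
            rows.append(
                {
                    **_key_dict(group_keys, key),
                    "n_roles": k,
                    "share_pct": 100.0 * counts.get(k, 0) / n,
                    "n": n,
                }
            )
    table = pd.DataFrame(rows, columns=[*group_keys, "n_roles", "share_pct", "n"])
    return GroupedTable(table, list(group_keys), metadata={"definition": d})


def size_by_role(
    results: pd.DataFrame,
    group_keys: Sequence[str] = (),
    definition: Union[str, Definition, None] = None,
) -> GroupedTable:
    """Per group and role: % of egos with >= 1 alter, mean, sd and median of
    the alter count (zeros included)."""
    d = _resolve_definition(results, definition)
    role_cols = [r for r in ALL_NETWORK_ROLES if f"{d}_{r}" in results.columns]
    rows = []
    for key, grp in _grouped(results, group_keys):
        for role in role_cols:
            counts = grp[f"{d}_{role}"].dropna().astype(float)
            if counts.empty:
                continue
            n = len(counts)
            rows.append(
                {
                    **_key_dict(group_keys, key),
                    "role": role,
                    "pct_with_alter": 100.0 * float((counts > 0).mean()),
                    "mean": float(counts.mean()),
                    "sd": float(counts.std(ddof=1)) if n > 1 else 0.0,
                    "median": float(counts.median()),
                    "n": n,
                }
            )
    table = pd.DataFrame(
        rows, columns=[*group_keys, "role", "pct_with_alter", "mean", "sd", "median", "n"]
    )
    return GroupedTable(table, list(group_keys), metadata={"definition": d})


def type_distribution(
    results: pd.DataFrame,
    group_keys: Sequence[str] = (),
    definition: Union[str, Definition, None] = None,
) -> GroupedTable:
    """Per group: % of egos in each network type with within-type mean size
    and sd (No Alters rows have mean size 0)."""
    d = _resolve_definition(results, definition)
    tcol, scol = f"{d}_type", f"{d}_size"
    rows = []
    for key, grp in _grouped(results, group_keys):
        n = len(grp)
        for ntype in NetworkType:
            sub = grp.loc[grp[tcol] == ntype.value, scol].astype(float)
            if sub.empty:
                continue
            rows.append(
                {
                    **_key_dict(group_keys, key),
                    "network_type": ntype.value,
                    "share_pct": 100.0 * len(sub) / n,
                    "mean_size": float(sub.mean()),
                    "sd_size": float(sub.std(ddof=1)) if len(sub) > 1 else 0.0,
                    "n": len(sub),
                }
            )
    table = pd.DataFrame(
        rows, columns=[*group_keys, "network_type", "share_pct", "mean_size", "sd_size", "n"]
    )
    return GroupedTable(table, list(group_keys), metadata={"definition": d})


def type_by_covariate(
    results: pd.DataFrame,
    covariate: str,
    definition: Union[str, Definition, None] = None,
) -> GroupedTable:
    """Network-type shares per age group and covariate level (table form of
    the type-by-context figures)."""
    if covariate not in _COVARIATE_CHOICES:
        raise UsageError(
            f"unknown covariate {covariate!r}; choose one of {_COVARIATE_CHOICES}"
        )
    sub = type_distribution(results, ("age_group", covariate), definition)
    sub.metadata["covariate"] = covariate
    return sub


def vulnerability_by_metro(results: pd.DataFrame) -> GroupedTable:
    """Among No Alters egos, % living in a metropolitan area, by vulnerability
    row (level, group, empty definition) and gender."""
    for d in Definition:
        if f"{d.value}_type" not in results.columns:
            raise UsageError("vulnerability table needs both network definitions")
    rows = []
    for d in Definition:
        empty = results[results[f"{d.value}_type"] == NetworkType.NO_ALTERS.value]
        if empty.empty:
            continue
        grouped = empty.groupby(
            ["age_group", "living_arrangement", "gender"], sort=True, observed=True
        )
        for (age_group, living, gender), grp in grouped:
            level = vulnerability_row_level(age_group, living, d)
            rows.append(
                {
                    "level": level.value,
                    "definition": d.value,
                    "age_group": age_group,
                    "living_arrangement": living,
                    "gender": gender,
                    "metro_pct": 100.0
                    * float((grp["place_of_residence"] == "metropolitan").mean()),
                    "n": len(grp),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "level",
            "definition",
            "age_group",
            "living_arrangement",
            "gender",
            "metro_pct",
            "n",
        ],
    )
    return GroupedTable(table, ["level", "definition", "age_group", "living_arrangement", "gender"])
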
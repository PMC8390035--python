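"""Domain types for FSS-style survey microdata.

The unit of analysis is the *ego*: a survey respondent described by
socio-demographic covariates and by blocks of non-cohabiting *alters*
(kin with per-alter residential proximity and face-to-face contact
frequency; friends and neighbours the ego can count on).  The module
provides validated record types, the two category recodes that drive
alter inclusion (the at-least-weekly contact flag and the residential
"near" flag), reading/writing of flat delimited microdata, and selection
of the target population: young adults (18-34) living alone or as a
couple, and the elderly (65+) living alone or as a couple without
cohabiting children, with no other household members.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .errors import MicrodataError, RecodeError, SchemaError

__all__ = [
    "AgeClass",
    "AgeGroup",
    "Gender",
    "LivingArrangement",
    "TerritorialArea",
    "PlaceOfResidence",
    "Education",
    "Health",
    "KinRole",
    "Proximity",
    "ContactFreq",
    "RadiusPolicy",
    "KinTie",
    "FriendBlock",
    "NeighborBlock",
    "EgoRecord",
    "PopulationFrame",
    "KIN_CAPS",
    "recode_contact_freq",
    "recode_proximity",
    "read_microdata",
    "write_microdata",
    "select_target_population",
    "microdata_columns",
]


# --------------------------------------------------------------------------
# Canonical category levels
# --------------------------------------------------------------------------

class AgeClass(str, enum.Enum):
    A18_24 = "18-24"
    A25_34 = "25-34"
    A65_74 = "65-74"
    A75P = "75plus"


class AgeGroup(str, enum.Enum):
    YOUNG_ADULT = "young_adult"
    ELDERLY = "elderly"


AGE_GROUP_OF: Mapping[AgeClass, AgeGroup] = {
    AgeClass.A18_24: AgeGroup.YOUNG_ADULT,
    AgeClass.A25_34: AgeGroup.YOUNG_ADULT,
    AgeClass.A65_74: AgeGroup.ELDERLY,
    AgeClass.A75P: AgeGroup.ELDERLY,
}


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class LivingArrangement(str, enum.Enum):
    SINGLE = "single"
    COUPLE = "couple"


class TerritorialArea(str, enum.Enum):
    NORTH = "north"
    CENTER = "center"
    SOUTH_ISLANDS = "south_islands"


class PlaceOfResidence(str, enum.Enum):
    METROPOLITAN = "metropolitan"
    LE_10K = "le_10k"
    GT_10K = "gt_10k"


class Education(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class Health(str, enum.Enum):
    GOOD = "good"
    FAIR = "fair"
    BAD = "bad"


class KinRole(str, enum.Enum):
    PARENT = "parent"
    SIBLING = "sibling"
    CHILD = "child"
    GRANDCHILD = "grandchild"


#: FSS truncation: parents are at most two; the questionnaire records at most
#: three siblings, children and grandchildren.
KIN_CAPS: Mapping[KinRole, int] = {
    KinRole.PARENT: 2,
    KinRole.SIBLING: 3,
    KinRole.CHILD: 3,
    KinRole.GRANDCHILD: 3,
}

#: Kin roles available per age group (grandchildren are only asked of
#: respondents aged 25+, automatically satisfied for the elderly).
KIN_ROLES_BY_AGE_GROUP: Mapping[AgeGroup, tuple[KinRole, ...]] = {
    AgeGroup.YOUNG_ADULT: (KinRole.PARENT, KinRole.SIBLING),
    AgeGroup.ELDERLY: (KinRole.SIBLING, KinRole.CHILD, KinRole.GRANDCHILD),
}


class Proximity(str, enum.Enum):
    """Residential proximity of a kin alter, ordered from closest to farthest.

    ``same_household_excluded`` exists only as an input label: cohabitants are
    never alters, so it cannot be stored on a tie.
    """

    SAME_HOUSEHOLD = "same_household_excluded"
    SAME_BUILDING = "same_building"
    SAME_MUNICIPALITY = "same_municipality"
    WITHIN_16KM = "within_16km"
    BEYOND_16KM = "beyond_16km"
    ABROAD = "abroad"


class ContactFreq(str, enum.Enum):
    """Face-to-face contact frequency, ordered from most to least frequent."""

    DAILY = "daily"
    SEVERAL_WEEKLY = "several_weekly"
    WEEKLY = "weekly"
    MONTHLY = "monthly"
    FEW_YEARLY = "few_yearly"
    NEVER = "never"


class RadiusPolicy(str, enum.Enum):
    """How far away a kin alter may live and still count as "near".

    ``same_municipality`` is the baseline rule; ``within_16km`` is the relaxed
    rule that also admits alters in another municipality no farther than 16 km.
    """

    SAME_MUNICIPALITY = "same_municipality"
    WITHIN_16KM = "within_16km"


_WEEKLY_OR_MORE = frozenset({ContactFreq.DAILY, ContactFreq.SEVERAL_WEEKLY, ContactFreq.WEEKLY})
_NEAR_BY_POLICY: Mapping[RadiusPolicy, frozenset[Proximity]] = {
    RadiusPolicy.SAME_MUNICIPALITY: frozenset(
        {Proximity.SAME_BUILDING, Proximity.SAME_MUNICIPALITY}
    ),
    RadiusPolicy.WITHIN_16KM: frozenset(
        {Proximity.SAME_BUILDING, Proximity.SAME_MUNICIPALITY, Proximity.WITHIN_16KM}
    ),
}


def recode_contact_freq(raw: Union[str, ContactFreq]) -> bool:
    """True iff the contact-frequency level means "at least once a week"."""
    try:
        level = ContactFreq(raw)
    except ValueError:
        raise RecodeError(f"unknown contact frequency level: {raw!r}") from None
    return level in _WEEKLY_OR_MORE


def recode_proximity(
    raw: Union[str, Proximity],
    radius_policy: Union[str, RadiusPolicy] = RadiusPolicy.SAME_MUNICIPALITY,
) -> bool:
    """True iff the proximity level counts as "near" under ``radius_policy``."""
    try:
        level = Proximity(raw)
    except ValueError:
        raise RecodeError(f"unknown proximity level: {raw!r}") from None
    try:
        policy = RadiusPolicy(radius_policy)
    except ValueError:
        raise RecodeError(f"unknown radius policy: {radius_policy!r}") from None
    return level in _NEAR_BY_POLICY[policy]


# --------------------------------------------------------------------------
# Record types
# --------------------------------------------------------------------------

class KinTie(BaseModel):
    """One non-cohabiting kin alter with its tie attributes."""

    model_config = ConfigDict(frozen=True)

    role: KinRole
    proximity: Proximity
    contact_freq: ContactFreq

    @field_validator("proximity")
    @classmethod
    def _not_cohabiting(cls, v: Proximity) -> Proximity:
        if v is Proximity.SAME_HOUSEHOLD:
            raise ValueError("cohabitants are never alters; cannot store same-household ties")
        return v


class FriendBlock(BaseModel):
    """Friends the ego can count on, with one group-level contact frequency."""

    model_config = ConfigDict(frozen=True)

    can_count_on: bool = False
    n_friends: int = Field(default=0, ge=0)
    contact_freq: Optional[ContactFreq] = None

    @model_validator(mode="after")
    def _consistent(self) -> "FriendBlock":
        if self.can_count_on:
            if self.n_friends == 0:
                raise ValueError("can_count_on friends requires n_friends >= 1")
            if self.contact_freq is None:
                raise ValueError("can_count_on friends requires a contact frequency")
        else:
            if self.n_friends != 0:
                raise ValueError("n_friends must be 0 when can_count_on is false")
            if self.contact_freq is not None:
                raise ValueError("contact_freq must be absent when can_count_on is false")
        return self

    @property
    def meets_weekly(self) -> bool:
        return self.can_count_on and recode_contact_freq(self.contact_freq)


class NeighborBlock(BaseModel):
    """Neighbours the ego can count on; the number may be unknown (None)."""

    model_config = ConfigDict(frozen=True)

    can_count_on: bool = False
    n_neighbors: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _consistent(self) -> "NeighborBlock":
        if not self.can_count_on and self.n_neighbors not in (None, 0):
            raise ValueError("n_neighbors must be 0 or unknown when can_count_on is false")
        return self


class EgoRecord(BaseModel):
    """One respondent: demographics plus the per-role alter blocks."""

    model_config = ConfigDict(frozen=True)

    ego_id: str
    age_class: AgeClass
    gender: Gender
    living_arrangement: LivingArrangement
    has_cohabiting_children: bool = False
    other_household_members: bool = False
    territorial_area: TerritorialArea
    place_of_residence: PlaceOfResidence
    education: Education
    health: Health
    income_source: str
    kin_ties: tuple[KinTie, ...] = ()
    friends: FriendBlock = FriendBlock()
    neighbors: NeighborBlock = NeighborBlock()
    weight: float = Field(default=1.0, gt=0)

    @property
    def age_group(self) -> AgeGroup:
        return AGE_GROUP_OF[self.age_class]

    @model_validator(mode="after")
    def _invariants(self) -> "EgoRecord":
        allowed = set(KIN_ROLES_BY_AGE_GROUP[self.age_group])
        counts: dict[KinRole, int] = {}
        for tie in self.kin_ties:
            if tie.role not in allowed:
                raise ValueError(
                    f"kin role {tie.role.value!r} is outside the "
                    f"{self.age_group.value} role set"
                )
            counts[tie.role] = counts.get(tie.role, 0) + 1
        for role, n in counts.items():
            if n > KIN_CAPS[role]:
                raise ValueError(
                    f"{n} {role.value} ties exceed the survey cap of {KIN_CAPS[role]}"
                )
        if self.living_arrangement is LivingArrangement.SINGLE and self.has_cohabiting_children:
            raise ValueError("a single (living-alone) ego cannot have cohabiting children")
        return self

    def kin_count(self, role: KinRole) -> int:
        return sum(1 for t in self.kin_ties if t.role is role)


@dataclass
class PopulationFrame:
    """A validated collection of ego records plus provenance metadata."""

    records: list[EgoRecord]
    provenance: str = "real"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.provenance not in ("real", "synthetic"):
            raise SchemaError(f"provenance must be 'real' or 'synthetic', got {self.provenance!r}")
        ids = [r.ego_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate ego_id values: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EgoRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return records_to_dataframe(self.records)


# --------------------------------------------------------------------------
# Flat (wide) microdata layout
# --------------------------------------------------------------------------

_DEMO_COLUMNS = [
    "ego_id",
    "age_class",
    "gender",
    "living_arrangement",
    "has_cohabiting_children",
    "other_household_members",
    "territorial_area",
    "place_of_residence",
    "education",
    "health",
    "income_source",
    "weight",
]

_BLOCK_COLUMNS = [
    "friends_count_on",
    "friends_number",
    "friends_contact",
    "neighbors_count_on",
    "neighbors_number",
]

_CATEGORY_FIELDS = {
    "age_class": AgeClass,
    "gender": Gender,
    "living_arrangement": LivingArrangement,
    "territorial_area": TerritorialArea,
    "place_of_residence": PlaceOfResidence,
    "education": Education,
    "health": Health,
}

_KIN_COL_RE = re.compile(r"^(parent|sibling|child|grandchild)(\d+)_(proximity|contact)$")


def _kin_columns() -> list[str]:
    cols = []
    for role in KinRole:
        for i in range(1, KIN_CAPS[role] + 1):
            cols.append(f"{role.value}{i}_proximity")
            cols.append(f"{role.value}{i}_contact")
    return cols


def microdata_columns() -> list[str]:
    """Canonical wide-format column order (stable for reproducibility)."""
    return _DEMO_COLUMNS + _kin_columns() + _BLOCK_COLUMNS


def _to_bool(value: object, column: str) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n", ""):
        return False
    raise RecodeError(f"column {column!r}: cannot interpret {value!r} as boolean")


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""


def records_to_dataframe(records: Iterable[EgoRecord]) -> pd.DataFrame:
    """Flatten ego records to the canonical wide microdata table."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "ego_id": rec.ego_id,
            "age_class": rec.age_class.value,
            "gender": rec.gender.value,
            "living_arrangement": rec.living_arrangement.value,
            "has_cohabiting_children": int(rec.has_cohabiting_children),
            "other_household_members": int(rec.other_household_members),
            "territorial_area": rec.territorial_area.value,
            "place_of_residence": rec.place_of_residence.value,
            "education": rec.education.value,
            "health": rec.health.value,
            "income_source": rec.income_source,
            "weight": rec.weight,
        }
        slot: dict[KinRole, int] = {r: 0 for r in KinRole}
        for tie in rec.kin_ties:
            slot[tie.role] += 1
            row[f"{tie.role.value}{slot[tie.role]}_proximity"] = tie.proximity.value
            row[f"{tie.role.value}{slot[tie.role]}_contact"] = tie.contact_freq.value
        row["friends_count_on"] = int(rec.friends.can_count_on)
        row["friends_number"] = rec.friends.n_friends
        row["friends_contact"] = (
            rec.friends.contact_freq.value if rec.friends.contact_freq is not None else ""
        )
        row["neighbors_count_on"] = int(rec.neighbors.can_count_on)
        row["neighbors_number"] = (
            "" if rec.neighbors.n_neighbors is None else rec.neighbors.n_neighbors
        )
        rows.append(row)
    df = pd.DataFrame(rows, columns=microdata_columns())
    return df.fillna("")


def _record_from_row(row: Mapping[str, object]) -> EgoRecord:
    kin_ties = []
    for role in KinRole:
        for i in range(1, KIN_CAPS[role] + 1):
            pcol = f"{role.value}{i}_proximity"
            ccol = f"{role.value}{i}_contact"
            prox, contact = row.get(pcol), row.get(ccol)
            pm, cm = _is_missing(prox), _is_missing(contact)
            if pm and cm:
                continue
            if pm or cm:
                raise RecodeError(
                    f"kin slot {role.value}{i}: proximity and contact frequency "
                    "must both be present or both absent"
                )
            kin_ties.append(
                KinTie(role=role, proximity=str(prox).strip(), contact_freq=str(contact).strip())
            )
    friends = FriendBlock(
        can_count_on=_to_bool(row.get("friends_count_on", 0), "friends_count_on"),
        n_friends=0 if _is_missing(row.get("friends_number")) else int(float(row["friends_number"])),
        contact_freq=None
        if _is_missing(row.get("friends_contact"))
        else str(row["friends_contact"]).strip(),
    )
    neighbors = NeighborBlock(
        can_count_on=_to_bool(row.get("neighbors_count_on", 0), "neighbors_count_on"),
        n_neighbors=None
        if _is_missing(row.get("neighbors_number"))
        else int(float(row["neighbors_number"])),
    )
    return EgoRecord(
        ego_id=str(row["ego_id"]),
        age_class=str(row["age_class"]).strip(),
        gender=str(row["gender"]).strip(),
        living_arrangement=str(row["living_arrangement"]).strip(),
        has_cohabiting_children=_to_bool(
            row.get("has_cohabiting_children", 0), "has_cohabiting_children"
        ),
        other_household_members=_to_bool(
            row.get("other_household_members", 0), "other_household_members"
        ),
        territorial_area=str(row["territorial_area"]).strip(),
        place_of_residence=str(row["place_of_residence"]).strip(),
        education=str(row["education"]).strip(),
        health=str(row["health"]).strip(),
        income_source=str(row["income_source"]).strip(),
        weight=1.0 if _is_missing(row.get("weight")) else float(row["weight"]),
        kin_ties=tuple(kin_ties),
        friends=friends,
        neighbors=neighbors,
    )


# --------------------------------------------------------------------------
# Reading / writing
# --------------------------------------------------------------------------

_MANDATORY_COLUMNS = [
    "ego_id",
    "age_class",
    "gender",
    "living_arrangement",
    "territorial_area",
    "place_of_residence",
    "education",
    "health",
    "income_source",
]


def _load_schema_config(schema_config: Union[None, str, Path, Mapping]) -> dict:
    if schema_config is None:
        return {}
    if isinstance(schema_config, (str, Path)):
        with open(schema_config, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise SchemaError("schema config file must contain a mapping")
        return dict(loaded)
    return dict(schema_config)


def read_microdata(
    path: Union[str, Path],
    schema_config: Union[None, str, Path, Mapping] = None,
) -> PopulationFrame:
    """Read a flat delimited microdata table into a validated frame.

    ``schema_config`` may supply ``delimiter``, a ``columns`` mapping from the
    file's column names to canonical names, and per-field ``categories``
    mappings from the file's labels to canonical levels.  Rows failing
    validation are collected and reported together via :class:`MicrodataError`.
    """
    cfg = _load_schema_config(schema_config)
    delimiter = cfg.get("delimiter", ",")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    rename = cfg.get("columns", {})
    if rename:
        unknown = set(rename) - set(df.columns)
        if unknown:
            raise SchemaError(f"columns mapping names absent columns: {sorted(unknown)}")
        df = df.rename(columns=dict(rename))

    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    # The survey caps kin slots; a populated slot beyond the cap is an error.
    for col in df.columns:
        m = _KIN_COL_RE.match(col)
        if m and int(m.group(2)) > KIN_CAPS[KinRole(m.group(1))]:
            populated = df.index[df[col].map(lambda v: not _is_missing(v))].tolist()
            if populated:
                raise MicrodataError(
                    [
                        (r, f"column {col!r} exceeds the cap of "
                            f"{KIN_CAPS[KinRole(m.group(1))]} {m.group(1)} alters")
                        for r in populated
                    ]
                )

    # Category dictionaries: keys are either a column name, or the special
    # keys "proximity" / "contact_freq" which apply to every kin proximity /
    # contact column (contact_freq also covers friends_contact).
    categories = cfg.get("categories", {})
    failures: list[tuple[object, str]] = []
    for fld, mapping in categories.items():
        if fld == "proximity":
            cols = [c for c in df.columns if _KIN_COL_RE.match(c) and c.endswith("_proximity")]
        elif fld == "contact_freq":
            cols = [c for c in df.columns if _KIN_COL_RE.match(c) and c.endswith("_contact")]
            if "friends_contact" in df.columns:
                cols.append("friends_contact")
        elif fld in df.columns:
            cols = [fld]
        else:
            raise SchemaError(f"categories mapping names absent column: {fld!r}")
        for col in cols:
            known = set(mapping)
            for idx, val in df[col].items():
                if not _is_missing(val) and val not in known:
                    failures.append((idx, f"column {col!r}: unknown category label {val!r}"))
            df[col] = df[col].map(lambda v, m=mapping: m.get(v, v))
    if failures:
        raise MicrodataError(failures)

    records: list[EgoRecord] = []
    for idx, row in df.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValidationError, RecodeError, ValueError) as exc:
            failures.append((idx, _summarize_error(exc)))
    if failures:
        raise MicrodataError(failures)

    return PopulationFrame(
        records=records,
        provenance=cfg.get("provenance", "real"),
        metadata={"source_path": str(path)},
    )


def _summarize_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        parts = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<record>"
            parts.append(f"{loc}: {err['msg']}")
        return "; ".join(parts)
    return str(exc)


def write_microdata(frame: PopulationFrame, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a frame as canonical wide-format delimited text (UTF-8, header)."""
    df = frame.to_dataframe()
    df.to_csv(path, sep=delimiter, index=False)


def select_target_population(frame: PopulationFrame) -> PopulationFrame:
    """Keep only the two target living arrangements.

    Young adults (18-34) living alone or as a couple (with or without
    cohabiting children) and the elderly (65+) living alone or as a couple
    without cohabiting children; in all cases no other household members.
    """
    kept = []
    for rec in frame.records:
        if rec.other_household_members:
            continue
        if rec.age_group is AgeGroup.ELDERLY and rec.has_cohabiting_children:
            continue
        kept.append(rec)
    return PopulationFrame(
        records=kept,
        provenance=frame.provenance,
        metadata={**frame.metadata, "selection": "target_population"},
    )
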
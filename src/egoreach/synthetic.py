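"""Seeded generator of FSS-like survey populations.

The generator draws egos independently within strata defined by age group,
living arrangement and gender.  Within an ego, each kin role is drawn
independently: a presence flag, a truncated count (at most two parents, at
most three siblings / children / grandchildren, mirroring the survey's
top-coding), and per-alter residential proximity and face-to-face contact
frequency.  Friends are drawn as a count-on flag, a truncated-geometric
count and one group-level contact frequency; neighbours as a count-on flag
only.  Independence across roles gives closed-form expressions for the
probability of an empty network, used as an analytic oracle in tests.

Default parameters are calibrated so that the *implied* per-role inclusion
shares under both network definitions, the friend and neighbour availability
shares, and the socio-demographic marginals match the shares observed in the
FSS 2016 target populations.  Joint behaviour across roles is not calibrated:
real roles co-occur (families cluster in space), so empty-network shares of a
generated population are lower than the observed ones; see docs/methods.md.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq

from .errors import UsageError
from .networks import Definition, role_set
from .schema import (
    AGE_GROUP_OF,
    AgeClass,
    AgeGroup,
    ContactFreq,
    EgoRecord,
    FriendBlock,
    Gender,
    KIN_CAPS,
    KIN_ROLES_BY_AGE_GROUP,
    KinRole,
    KinTie,
    LivingArrangement,
    NeighborBlock,
    PopulationFrame,
    Proximity,
    RadiusPolicy,
    recode_contact_freq,
    recode_proximity,
)

__all__ = [
    "RoleParams",
    "FriendParams",
    "NeighborParams",
    "StratumParams",
    "GeneratorParams",
    "group_key",
    "default_params",
    "generate_population",
    "expected_no_alters_share",
]

_PROB = Field(ge=0.0, le=1.0)
_DIST_TOL = 1e-9

# Fixed splits used to expand a "near" probability into the full proximity
# scale and a "weekly" probability into the full frequency scale.
_NEAR_SPLIT = {Proximity.SAME_BUILDING: 0.15, Proximity.SAME_MUNICIPALITY: 0.85}
_FAR_SPLIT = {Proximity.WITHIN_16KM: 0.45, Proximity.BEYOND_16KM: 0.45, Proximity.ABROAD: 0.10}
_WEEKLY_SPLIT = {ContactFreq.DAILY: 0.40, ContactFreq.SEVERAL_WEEKLY: 0.30, ContactFreq.WEEKLY: 0.30}
_RARE_SPLIT = {ContactFreq.MONTHLY: 0.50, ContactFreq.FEW_YEARLY: 0.35, ContactFreq.NEVER: 0.15}


def _check_dist(dist: Mapping, name: str) -> None:
    total = float(sum(dist.values()))
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name}: probabilities must be non-negative")
    if abs(total - 1.0) > _DIST_TOL:
        raise ValueError(f"{name}: probabilities sum to {total}, not 1")


class RoleParams(BaseModel):
    """Distribution of one kin role within one stratum."""

    model_config = ConfigDict(frozen=True)

    presence: float = _PROB
    count_dist: dict[int, float]
    proximity_dist: dict[Proximity, float]
    freq_dist: dict[ContactFreq, float]

    @model_validator(mode="after")
    def _valid(self) -> "RoleParams":
        _check_dist(self.count_dist, "count_dist")
        _check_dist(self.proximity_dist, "proximity_dist")
        _check_dist(self.freq_dist, "freq_dist")
        if any(c < 1 for c in self.count_dist):
            raise ValueError("count_dist support must be >= 1")
        if self.proximity_dist.get(Proximity.SAME_HOUSEHOLD, 0.0) > 0:
            raise ValueError("alters are non-cohabiting; same-household mass must be 0")
        return self


class FriendParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    count_on_prob: float = _PROB
    weekly_prob: float = _PROB
    #: truncated geometric on {1, 2, ...}: P(k) = p (1-p)^(k-1); mean 1/p.
    count_geom_p: float = Field(gt=0.0, le=1.0)


class NeighborParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    count_on_prob: float = _PROB


class StratumParams(BaseModel):
    """All parameters for one (age group, living arrangement, gender) cell."""

    model_config = ConfigDict(frozen=True)

    roles: dict[KinRole, RoleParams]
    friends: FriendParams
    neighbors: NeighborParams
    covariates: dict[str, dict[str, float]]
    cohab_children_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    #: Correlation hook: probability that an ego is "family-nearby", in which
    #: case all its kin proximity draws come from the near-conditional part of
    #: the proximity distribution.  Off (0.0) by default; the analytic oracle
    #: requires it off.
    family_nearby_prob: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _valid(self) -> "StratumParams":
        for name, dist in self.covariates.items():
            _check_dist(dist, f"covariates[{name}]")
        return self


def group_key(
    age_group: Union[str, AgeGroup],
    living_arrangement: Union[str, LivingArrangement],
    gender: Union[str, Gender],
) -> str:
    return f"{AgeGroup(age_group).value}:{LivingArrangement(living_arrangement).value}:{Gender(gender).value}"


def _parse_key(key: str) -> tuple[AgeGroup, LivingArrangement, Gender]:
    try:
        a, l, g = key.split(":")
        return AgeGroup(a), LivingArrangement(l), Gender(g)
    except ValueError:
        raise ValueError(f"malformed group key {key!r}; expected age_group:living:gender") from None


class GeneratorParams(BaseModel):
    """Full stochastic specification of a synthetic population."""

    model_config = ConfigDict(frozen=True)

    group_sizes: dict[str, int]
    strata: dict[str, StratumParams]
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "GeneratorParams":
        for key, n in self.group_sizes.items():
            age_group, _, _ = _parse_key(key)
            if n < 0:
                raise ValueError(f"group size for {key!r} must be >= 0")
            if n > 0 and key not in self.strata:
                raise ValueError(f"no stratum parameters for populated group {key!r}")
            if key in self.strata:
                stratum = self.strata[key]
                allowed = set(KIN_ROLES_BY_AGE_GROUP[age_group])
                extra = set(stratum.roles) - allowed
                if extra:
                    raise ValueError(
                        f"stratum {key!r}: roles {sorted(r.value for r in extra)} are "
                        f"outside the {age_group.value} role set"
                    )
                for role, rp in stratum.roles.items():
                    if any(c > KIN_CAPS[role] for c in rp.count_dist):
                        raise ValueError(
                            f"stratum {key!r}: {role.value} counts exceed the cap "
                            f"of {KIN_CAPS[role]}"
                        )
                ac = stratum.covariates.get("age_class")
                if ac is not None:
                    for level in ac:
                        if AGE_GROUP_OF[AgeClass(level)] is not age_group:
                            raise ValueError(
                                f"stratum {key!r}: age class {level!r} is outside "
                                f"{age_group.value}"
                            )
        return self

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]

    def restrict(self, key: str, n: int) -> "GeneratorParams":
        """A copy generating ``n`` egos of a single stratum (for experiments)."""
        if key not in self.strata:
            raise UsageError(f"unknown stratum {key!r}")
        return GeneratorParams(
            group_sizes={key: n}, strata={key: self.strata[key]}, seed=self.seed
        )

    def scaled(self, n: int, age_group: Union[str, AgeGroup, None] = None) -> "GeneratorParams":
        """A copy with group sizes rescaled proportionally to a total of ``n``,
        optionally keeping only one age group."""
        keys = sorted(k for k, v in self.group_sizes.items() if v > 0)
        if age_group is not None:
            target = AgeGroup(age_group)
            keys = [k for k in keys if _parse_key(k)[0] is target]
        if not keys:
            raise UsageError("no populated stratum matches the requested group")
        total = sum(self.group_sizes[k] for k in keys)
        sizes = {k: (self.group_sizes[k] * n) // total for k in keys}
        for k in keys[: n - sum(sizes.values())]:
            sizes[k] += 1
        return GeneratorParams(
            group_sizes=sizes, strata={k: self.strata[k] for k in keys}, seed=self.seed
        )


# --------------------------------------------------------------------------
# Default (calibrated) parameters
# --------------------------------------------------------------------------

# Observed per-role inclusion shares (%) under the easy- and accustomed-to-
# reach definitions, per stratum, in the FSS 2016 target populations.
_KIN_SHARES: dict[tuple[str, str, str], dict[KinRole, tuple[float, float]]] = {
    ("young_adult", "single", "male"): {KinRole.PARENT: (49.4, 44.4), KinRole.SIBLING: (34.9, 29.0)},
    ("young_adult", "single", "female"): {KinRole.PARENT: (51.0, 47.2), KinRole.SIBLING: (42.8, 35.8)},
    ("young_adult", "couple", "male"): {KinRole.PARENT: (49.3, 47.1), KinRole.SIBLING: (44.7, 38.4)},
    ("young_adult", "couple", "female"): {KinRole.PARENT: (47.3, 46.0), KinRole.SIBLING: (37.6, 35.5)},
    ("elderly", "single", "male"): {
        KinRole.CHILD: (43.9, 40.3), KinRole.SIBLING: (38.9, 27.6), KinRole.GRANDCHILD: (34.8, 27.4)},
    ("elderly", "single", "female"): {
        KinRole.CHILD: (58.9, 57.3), KinRole.SIBLING: (37.4, 24.7), KinRole.GRANDCHILD: (48.0, 42.3)},
    ("elderly", "couple", "male"): {
        KinRole.CHILD: (61.8, 59.2), KinRole.SIBLING: (44.7, 28.7), KinRole.GRANDCHILD: (48.8, 45.5)},
    ("elderly", "couple", "female"): {
        KinRole.CHILD: (60.8, 59.1), KinRole.SIBLING: (40.7, 26.9), KinRole.GRANDCHILD: (48.7, 45.4)},
}

# Friends: (% of egos with count-on weekly friends, mean friend count incl. zeros).
_FRIEND_SHARES: dict[tuple[str, str, str], tuple[float, float]] = {
    ("young_adult", "single", "male"): (68.9, 2.9),
    ("young_adult", "single", "female"): (68.6, 2.7),
    ("young_adult", "couple", "male"): (56.7, 2.2),
    ("young_adult", "couple", "female"): (55.6, 2.1),
    ("elderly", "single", "male"): (31.8, 1.1),
    ("elderly", "single", "female"): (30.7, 0.9),
    ("elderly", "couple", "male"): (31.6, 1.1),
    ("elderly", "couple", "female"): (28.7, 1.0),
}

_NEIGHBOR_SHARES: dict[tuple[str, str, str], float] = {
    ("young_adult", "single", "male"): 48.1,
    ("young_adult", "single", "female"): 56.6,
    ("young_adult", "couple", "male"): 47.9,
    ("young_adult", "couple", "female"): 56.1,
    ("elderly", "single", "male"): 45.4,
    ("elderly", "single", "female"): 50.7,
    ("elderly", "couple", "male"): 50.7,
    ("elderly", "couple", "female"): 48.7,
}

# Conditional weekly rate for friends; only the product count_on x weekly is
# identified by the observed shares, so the split is a modelling choice.
_FRIEND_WEEKLY = 0.95

# Raw (pre-inclusion) presence of at least one non-cohabiting alter per role,
# and the truncated count distribution conditional on presence.  Not observed
# directly; chosen as plausible Italian-population values, then the proximity
# and frequency scales are solved so the *implied inclusion shares* match the
# observed ones exactly.
_PRESENCE = {KinRole.PARENT: 0.90, KinRole.SIBLING: 0.75, KinRole.CHILD: 0.85, KinRole.GRANDCHILD: 0.75}
_COUNT_DIST = {
    KinRole.PARENT: {1: 0.25, 2: 0.75},
    KinRole.SIBLING: {1: 0.55, 2: 0.30, 3: 0.15},
    KinRole.CHILD: {1: 0.45, 2: 0.40, 3: 0.15},
    KinRole.GRANDCHILD: {1: 0.35, 2: 0.35, 3: 0.30},
}

# Socio-demographic marginals per (age group, living arrangement); shared by
# the two genders.  The last level of each distribution absorbs rounding so
# the leading levels keep their observed values exactly.
_COVARIATES: dict[tuple[str, str], dict[str, dict[str, float]]] = {
    ("young_adult", "single"): {
        "age_class": {"18-24": 0.162, "25-34": 0.838},
        "territorial_area": {"north": 0.455, "center": 0.193, "south_islands": 0.352},
        "place_of_residence": {"metropolitan": 0.165, "le_10k": 0.360, "gt_10k": 0.475},
        "education": {"high": 0.300, "medium": 0.530, "low": 0.170},
        "health": {"good": 0.929, "fair": 0.056, "bad": 0.015},
        "income_source": {"self_employed": 0.160, "employed": 0.625, "other": 0.215},
    },
    ("young_adult", "couple"): {
        "age_class": {"18-24": 0.136, "25-34": 0.864},
        "territorial_area": {"north": 0.503, "center": 0.151, "south_islands": 0.346},
        "place_of_residence": {"metropolitan": 0.154, "le_10k": 0.434, "gt_10k": 0.412},
        "education": {"high": 0.202, "medium": 0.513, "low": 0.285},
        "health": {"good": 0.945, "fair": 0.048, "bad": 0.007},
        "income_source": {"self_employed": 0.127, "employed": 0.639, "other": 0.234},
    },
    ("elderly", "single"): {
        "age_class": {"65-74": 0.333, "75plus": 0.667},
        "territorial_area": {"north": 0.461, "center": 0.157, "south_islands": 0.382},
        "place_of_residence": {"metropolitan": 0.169, "le_10k": 0.384, "gt_10k": 0.447},
        "education": {"high": 0.060, "medium": 0.175, "low": 0.765},
        "health": {"good": 0.305, "fair": 0.425, "bad": 0.270},
        "income_source": {"pension": 0.885, "other": 0.115},
    },
    ("elderly", "couple"): {
        "age_class": {"65-74": 0.553, "75plus": 0.447},
        "territorial_area": {"north": 0.453, "center": 0.183, "south_islands": 0.364},
        "place_of_residence": {"metropolitan": 0.178, "le_10k": 0.374, "gt_10k": 0.448},
        "education": {"high": 0.067, "medium": 0.205, "low": 0.728},
        "health": {"good": 0.394, "fair": 0.421, "bad": 0.185},
        "income_source": {"pension": 0.806, "other": 0.194},
    },
}

# Target-population cell sizes (FSS 2016): 400 / 748 young-adult singles /
# couples split 60.2% / 51.2% male; 1851 / 3234 elderly split 28.6% / 52% male.
_GROUP_SIZES = {
    "young_adult:single:male": 241,
    "young_adult:single:female": 159,
    "young_adult:couple:male": 383,
    "young_adult:couple:female": 365,
    "elderly:single:male": 529,
    "elderly:single:female": 1322,
    "elderly:couple:male": 1682,
    "elderly:couple:female": 1552,
}

_COHAB_CHILDREN_PROB = 0.643  # young-adult couples with at least one child


def _inclusion_given_presence(count_dist: Mapping[int, float], p_incl: float) -> float:
    """P(at least one alter passes) given presence, per-alter pass prob p_incl."""
    return 1.0 - sum(p * (1.0 - p_incl) ** c for c, p in count_dist.items())


def _solve_role(role: KinRole, easy_pct: float, acc_pct: float) -> RoleParams:
    presence = _PRESENCE[role]
    count_dist = _COUNT_DIST[role]
    q_easy, q_acc = easy_pct / 100.0, acc_pct / 100.0
    p_near = brentq(
        lambda p: _inclusion_given_presence(count_dist, p) - q_easy / presence, 0.0, 1.0,
        xtol=1e-12,
    )
    p_week = brentq(
        lambda w: _inclusion_given_presence(count_dist, p_near * w) - q_acc / presence,
        0.0, 1.0, xtol=1e-12,
    )
    proximity_dist = {lvl: p_near * w for lvl, w in _NEAR_SPLIT.items()}
    proximity_dist.update({lvl: (1.0 - p_near) * w for lvl, w in _FAR_SPLIT.items()})
    freq_dist = {lvl: p_week * w for lvl, w in _WEEKLY_SPLIT.items()}
    freq_dist.update({lvl: (1.0 - p_week) * w for lvl, w in _RARE_SPLIT.items()})
    return RoleParams(
        presence=presence,
        count_dist=count_dist,
        proximity_dist=proximity_dist,
        freq_dist=freq_dist,
    )


def default_params(seed: int = 0) -> GeneratorParams:
    """Parameters calibrated to the FSS 2016 target-population marginals."""
    strata = {}
    for (age_group, living, gender), kin in _KIN_SHARES.items():
        friend_pct, friend_mean = _FRIEND_SHARES[(age_group, living, gender)]
        q_friend = friend_pct / 100.0
        strata[f"{age_group}:{living}:{gender}"] = StratumParams(
            roles={role: _solve_role(role, e, a) for role, (e, a) in kin.items()},
            friends=FriendParams(
                count_on_prob=q_friend / _FRIEND_WEEKLY,
                weekly_prob=_FRIEND_WEEKLY,
                # mean included count = friend_mean / q_friend, geometric mean 1/p
                count_geom_p=q_friend / friend_mean,
            ),
            neighbors=NeighborParams(
                count_on_prob=_NEIGHBOR_SHARES[(age_group, living, gender)] / 100.0
            ),
            covariates=_COVARIATES[(age_group, living)],
            cohab_children_prob=(
                _COHAB_CHILDREN_PROB if (age_group, living) == ("young_adult", "couple") else 0.0
            ),
        )
    return GeneratorParams(group_sizes=dict(_GROUP_SIZES), strata=strata, seed=seed)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _draw(rng: np.random.Generator, dist: Mapping) -> object:
    levels = list(dist.keys())
    probs = np.asarray(list(dist.values()), dtype=float)
    return levels[int(rng.choice(len(levels), p=probs / probs.sum()))]


def _draw_ego(
    ego_id: str,
    age_group: AgeGroup,
    living: LivingArrangement,
    gender: Gender,
    stratum: StratumParams,
    rng: np.random.Generator,
) -> EgoRecord:
    cov = {name: _draw(rng, dist) for name, dist in stratum.covariates.items()}
    cohab = (
        living is LivingArrangement.COUPLE
        and age_group is AgeGroup.YOUNG_ADULT
        and rng.random() < stratum.cohab_children_prob
    )
    family_nearby = stratum.family_nearby_prob > 0 and rng.random() < stratum.family_nearby_prob

    kin_ties = []
    for role in KIN_ROLES_BY_AGE_GROUP[age_group]:
        rp = stratum.roles.get(role)
        if rp is None or rng.random() >= rp.presence:
            continue
        count = int(_draw(rng, rp.count_dist))
        prox_dist = rp.proximity_dist
        if family_nearby:
            near = {
                lvl: p for lvl, p in rp.proximity_dist.items()
                if recode_proximity(lvl, RadiusPolicy.SAME_MUNICIPALITY)
            }
            if sum(near.values()) > 0:
                prox_dist = near
        for _ in range(count):
            kin_ties.append(
                KinTie(
                    role=role,
                    proximity=_draw(rng, prox_dist),
                    contact_freq=_draw(rng, rp.freq_dist),
                )
            )

    if rng.random() < stratum.friends.count_on_prob:
        n_friends = int(rng.geometric(stratum.friends.count_geom_p))
        weekly = rng.random() < stratum.friends.weekly_prob
        freq = _draw(rng, _WEEKLY_SPLIT if weekly else _RARE_SPLIT)
        friends = FriendBlock(can_count_on=True, n_friends=n_friends, contact_freq=freq)
    else:
        friends = FriendBlock()

    neighbors = NeighborBlock(can_count_on=bool(rng.random() < stratum.neighbors.count_on_prob))

    return EgoRecord(
        ego_id=ego_id,
        age_class=cov["age_class"],
        gender=gender,
        living_arrangement=living,
        has_cohabiting_children=cohab,
        territorial_area=cov["territorial_area"],
        place_of_residence=cov["place_of_residence"],
        education=cov["education"],
        health=cov["health"],
        income_source=str(cov["income_source"]),
        kin_ties=tuple(kin_ties),
        friends=friends,
        neighbors=neighbors,
    )


def generate_population(params: GeneratorParams, seed: Optional[int] = None) -> PopulationFrame:
    """Draw a synthetic population; identical (params, seed) give identical frames."""
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(int(seed))
    records = []
    i = 0
    for key in sorted(params.group_sizes):
        n = params.group_sizes[key]
        if n == 0:
            continue
        age_group, living, gender = _parse_key(key)
        stratum = params.strata[key]
        for _ in range(n):
            i += 1
            records.append(_draw_ego(f"syn{i:06d}", age_group, living, gender, stratum, rng))
    return PopulationFrame(
        records=records,
        provenance="synthetic",
        metadata={"seed": int(seed), "params_digest": params.digest()},
    )


# --------------------------------------------------------------------------
# Analytic oracle
# --------------------------------------------------------------------------

def _stratum_no_alters_prob(
    stratum: StratumParams,
    age_group: AgeGroup,
    definition: Definition,
    radius_policy: RadiusPolicy,
) -> float:
    if stratum.family_nearby_prob > 0:
        raise UsageError(
            "the closed-form empty-network probability assumes independent roles; "
            "disable the family_nearby correlation hook"
        )
    prob_empty = 1.0
    for role in role_set(age_group).roles:
        if role == "friend":
            q = stratum.friends.count_on_prob * stratum.friends.weekly_prob
        elif role == "neighbor":
            q = stratum.neighbors.count_on_prob
        else:
            rp = stratum.roles.get(KinRole(role))
            if rp is None:
                q = 0.0
            else:
                p_near = sum(
                    p for lvl, p in rp.proximity_dist.items()
                    if recode_proximity(lvl, radius_policy)
                )
                p_incl = p_near
                if definition is Definition.ACCUSTOMED:
                    p_week = sum(
                        p for lvl, p in rp.freq_dist.items() if recode_contact_freq(lvl)
                    )
                    p_incl = p_near * p_week
                q = rp.presence * _inclusion_given_presence(rp.count_dist, p_incl)
        prob_empty *= 1.0 - q
    return prob_empty


def expected_no_alters_share(
    params: GeneratorParams,
    definition: Union[str, Definition],
    age_group: Union[str, AgeGroup],
    living_arrangement: Union[str, LivingArrangement, None] = None,
    gender: Union[str, Gender, None] = None,
    radius_policy: Union[str, RadiusPolicy] = RadiusPolicy.SAME_MUNICIPALITY,
) -> float:
    """Closed-form probability that a generated ego's network is empty.

    Averages over the strata matching the filters, weighted by group sizes.
    Valid because the generator draws roles independently.
    """
    definition = Definition(definition)
    age_group = AgeGroup(age_group)
    radius_policy = RadiusPolicy(radius_policy)
    if living_arrangement is not None:
        living_arrangement = LivingArrangement(living_arrangement)
    if gender is not None:
        gender = Gender(gender)

    total_w = 0.0
    acc = 0.0
    for key, n in params.group_sizes.items():
        if n == 0:
            continue
        a, l, g = _parse_key(key)
        if a is not age_group:
            continue
        if living_arrangement is not None and l is not living_arrangement:
            continue
        if gender is not None and g is not gender:
            continue
        p = _stratum_no_alters_prob(params.strata[key], a, definition, radius_policy)
        acc += n * p
        total_w += n
    if total_w == 0:
        raise UsageError("no populated stratum matches the requested group")
    return acc / total_w
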
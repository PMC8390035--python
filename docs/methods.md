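# Methods

## Data model

The unit of analysis is one survey respondent (*ego*) in one of two target
populations: young adults aged 18–34 living alone or with a partner (with or
without cohabiting children) and elderly aged 65+ living alone or with a
partner without cohabiting children, in both cases with no other household
members. `select_target_population` enforces these rules; records carrying an
`other_household_members` flag or an elderly couple with cohabiting children
are excluded rather than rejected at parse time, so that a raw file can
legitimately contain them.

Alter information follows the FSS questionnaire structure:

* **kin** (parents; siblings; children; grandchildren, the latter only asked
  of respondents aged 25+): per-alter residential proximity on an ordered
  scale (same building, same municipality, within 16 km, beyond 16 km,
  abroad) and face-to-face contact frequency (daily, several times a week,
  weekly, monthly, a few times a year, never). Counts are top-coded at two
  parents and three alters for every other kin role, as in the survey.
  Cohabitants are never alters; a "same household" proximity label is
  rejected on stored ties.
* **friends**: a can-count-on flag, a reported number, and one group-level
  contact frequency (the survey asks about friends jointly).
* **neighbours**: a can-count-on flag and an optional number.

## Network construction

Two recodes drive inclusion. `recode_contact_freq` maps frequency to an
*at-least-weekly* flag (daily / several times a week / weekly → true).
`recode_proximity` maps proximity to a *near* flag under a radius policy:
`same_municipality` (default: same building or same municipality) or
`within_16km` (additionally within 16 km). Widening the radius can only add
alters; the relaxed policy exists to study how sensitive isolation counts
are to the proximity cut.

A kin tie enters the **easy-to-reach** network iff it is near; it enters the
**accustomed-to-reach** network iff it is near *and* met at least weekly.
Friends enter both networks (contributing their reported number) iff the ego
counts on them and meets them at least weekly — the weekly flag doubles as a
proximity proxy because the survey does not record where friends live, and
in-person contact above weekly frequency is strongly associated with short
distances. Neighbours enter both networks iff the ego counts on them,
contributing their reported number or one alter when the number is unknown
(the survey's neighbour information is essentially presence-level; the
choice is recorded in the run manifest). Consequently non-kin counts are
identical across definitions and the accustomed network is role-wise nested
in the easy network; an ego empty under easy is necessarily empty under
accustomed. These invariants are property-tested against a brute-force
re-implementation of the rule text.

Role sets are fixed per age group: parents, siblings, friends, neighbours
for young adults (4 roles); siblings, children, grandchildren, friends,
neighbours for the elderly (5 roles). *Size* sums alters; *n_roles* counts
roles with at least one alter.

## Typology and vulnerability

Classification order: **No Alters** (size 0) → **Comprehensive** (every role
of the role set present) → **Kin** (no friends/neighbours) → **Non-kin** (no
kin) → **Mixed**. Comprehensive is checked before Mixed because it satisfies
the Mixed predicate and the types must be mutually exclusive; the classifier
is verified exhaustively against a truth table over all 2^4 / 2^5 presence
patterns.

Vulnerability grading of empty networks: an empty easy-to-reach network ⇒
*very critical* for singles, *more critical* for couples; otherwise an empty
accustomed-to-reach network ⇒ *very critical* for single elderly, *critical*
for single young adults and all couples; otherwise *none*. An ego empty
under both definitions takes the easy-to-reach (more severe) grade in the
per-ego output; in the metropolitan-residence tabulation it appears in both
the easy and the accustomed rows, since the two No Alters sets overlap by
construction. An easy-empty ego with a non-empty accustomed network violates
nesting and raises an error rather than being graded.

## Synthetic generator

The generator emulates the FSS structure so the pipeline can be exercised
and tested without the access-restricted microdata. Egos are drawn
independently within strata (age group × living arrangement × gender);
within an ego each role is drawn independently: presence → truncated count →
per-alter proximity and frequency (independent across an ego's alters of a
role). Friends: count-on flag, truncated-geometric count on {1, 2, …}, one
group-level frequency. Neighbours: count-on flag, number left unknown.
Identical (params, seed) yield byte-identical populations; frames carry the
seed and a SHA-256 digest of the parameters.

**Calibration of the defaults.** Published quantities for the FSS 2016
target populations pin down, per stratum: the share of egos with at least
one *included* alter per kin role under each definition, friend availability
(count-on ∧ weekly: 68.9 / 68.6 / 56.7 / 55.6 % for single-male /
single-female / couple-male / couple-female young adults; ~29–32 % for the
elderly), neighbour count-on shares, the mean friend count, group cell sizes
(400 / 748 / 1851 / 3234 split by the observed gender shares) and the
socio-demographic marginals (area, place of residence, education, health,
income source, age class; e.g. 16.5 % of young singles in metropolitan
areas). Raw per-role presence is *not* published, so the defaults fix a
plausible presence per role (0.90 parents, 0.75 siblings, 0.85 children,
0.75 grandchildren) and a count distribution, then solve the per-alter
P(near) and P(weekly) by bisection so the implied inclusion shares equal
the published ones exactly under both definitions. The near/far and
weekly/rare masses are spread over the full ordered scales with fixed
splits; only the binary cuts matter for network construction. Friend
availability is split as count-on = share / 0.95 with a 0.95 conditional
weekly rate (only the product is identified; the published fact that ≥ 70 %
of each age group meets friends at least weekly supports a high conditional
rate). The friend geometric parameter is set so that share × conditional
mean reproduces the published mean friend count.

**What the generator does not emulate.** Roles are independent, whereas in
reality kin availability is spatially correlated (whole families live near
or far together). The generated *joint* quantities — in particular the No
Alters shares, around 5–7 % — are therefore lower than the observed ones
(about 10–15 %), which embed that positive correlation. Tests consequently
validate simulated joint quantities against the generator's own closed-form
oracle, not against the published joint tables; per-role marginals are
validated against the published shares. A `family_nearby_prob` hook can
force an ego's kin proximity draws to the near part of the scale to induce
correlation; it is off by default and the closed-form oracle refuses to run
with it on. Covariates are drawn independently of network blocks; real
gradients (e.g. more non-kin networks among the highly educated) are
induced by giving strata different role parameters, which is how the
stratified tests construct them.

**Analytic oracle.** With independent roles the probability of an empty
network is ∏ᵣ (1 − qᵣ) over the age group's role set, where for kin
qᵣ = presence × (1 − Σ_c P(c) (1 − p)^c) with p = P(near) (easy) or
P(near) × P(weekly) (accustomed), q_friend = count-on × weekly and
q_neighbour = count-on. Simulated shares at n = 10,000 are required to fall
within three binomial standard errors of this value for both definitions
and both age groups.

## Tabulation conventions

Shares are percentages within the grouping cell and sum to 100 up to
floating-point error; standard deviations use the sample (n−1) denominator
(the published tables do not state theirs; the manifest records the choice);
the median of an even-sized group is the midpoint of the two central values.
Tables carry full precision internally; the written/rendered form rounds
half-up to one decimal, matching how such survey tables are printed. Counts
(`n`) are exact integers and never rounded. Re-running any tabulation on the
same frame is bit-identical.

## Problem sizes and numerical choices

The packaged default population is 6,233 egos (the four published cell
sizes); Monte-Carlo checks use 10,000 egos per cell, where three binomial
standard errors are ~1.5 percentage points at p ≈ 0.5 — tight enough to
detect calibration errors while keeping the whole suite fast. Bisection for
the calibration solves to 1e−12 on probabilities in [0, 1]; distribution
validity is enforced to 1e−9. Degenerate inputs are defined, not special
cases: empty frames select and tabulate to empty outputs, all-zero
populations give a 100 % share at zero roles, and a stratum with no No
Alters egos yields an empty (not erroneous) metropolitan table.

## Known limitations

Only face-to-face reachability is modelled; phone/video contact is out of
scope. The two vulnerability ingredients a survey of this structure cannot
measure (dissatisfaction with support, perceived loneliness) are not
modelled. Survey weights are carried through records but all replication
outputs are unweighted, matching the published tables. The generator's
independence assumption makes it unsuitable for studying joint role
structure unless the correlation hook or stratified parameters are used
deliberately.
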
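# egoreach

Ego-centered "reachability" networks and relational vulnerability from
FSS-style survey microdata.

Large-scale family surveys such as Istat's *Famiglie e Soggetti Sociali*
(FSS) ask each respondent (the **ego**) about non-cohabiting kin — parents,
siblings, children, grandchildren, with per-alter residential proximity and
face-to-face contact frequency — and about friends and neighbours they "can
count on". When mobility is restricted (a lockdown, reduced travel), support
realistically comes only from **alters who are physically reachable**.
`egoreach` turns such microdata into two nested personal networks per ego
and grades who is left with nobody:

* **easy-to-reach** network — kin living in the ego's municipality
  (regardless of how often they meet), friends the ego counts on and meets
  at least weekly (weekly contact proxies proximity, which the survey does
  not record for friends), and neighbours the ego counts on;
* **accustomed-to-reach** network — the same rules plus the requirement
  that kin are met face-to-face at least once a week. It is role-wise
  contained in the easy-to-reach network by construction.

Networks are summarised by **size** (number of alters: three friends and
three siblings count as six) and **number of distinct roles** (the same
network counts two roles), and classified into five mutually exclusive
types — *No Alters*, *Kin*, *Non-kin*, *Mixed*, *Comprehensive* (at least
one alter of every role available to the age group). Egos with an empty
network are graded on a three-level **relational vulnerability** scale
driven by age group (young adults 18–34 vs elderly 65+), living arrangement
(alone vs couple) and which definition is empty: an empty easy-to-reach
network is *very critical* for singles and *more critical* for couples; an
empty accustomed-to-reach network (with a non-empty easy one) is *very
critical* for single elderly and *critical* otherwise.

Because the real FSS microdata are access-restricted, the package ships a
seeded synthetic generator whose default parameters are calibrated to the
published per-role availability shares and socio-demographic marginals of
the FSS 2016 target populations, together with a closed-form oracle for the
probability of an empty network (roles are generated independently). The
audience is survey methodologists and social-demography researchers who
want a tested, reproducible implementation of the construction rules —
on real microdata when they have access, on calibrated synthetic data when
they do not.

## Worked example

```python
import egoreach as eg
from egoreach.synthetic import default_params, generate_population

params = default_params(seed=1)
frame = generate_population(params.scaled(2000))   # 2,000 egos, FSS-shaped
results = eg.per_ego_results(frame)                # networks + types + grades
table = eg.type_distribution(results, ("age_group", "living_arrangement"), "easy")
print(table.to_string())
```

```
  age_group living_arrangement  network_type  share_pct  mean_size  sd_size   n
    elderly             couple     no_alters        3.5        0.0      0.0  36
    elderly             couple           kin       31.0        2.3      1.1 322
    elderly             couple       non_kin        8.4        1.8      2.0  87
    elderly             couple         mixed       55.5        4.6      2.6 576
    elderly             couple comprehensive        1.6        7.6      1.8  17
    ...
young_adult             single     no_alters        4.7        0.0      0.0   6
young_adult             single       non_kin       25.8        3.5      4.2  33
```

Each row gives, within an age-group × living-arrangement cell, the share of
egos (%) whose easy-to-reach network is of that type, with the mean and
sample standard deviation of network size within the type (No Alters rows
are size 0 by definition). `results["vulnerability"]` carries the per-ego
grade; on the same run:

```
vulnerability
none             1886
more_critical      51
very_critical      46
critical           17
```

The same pipeline runs from the shell:

```bash
egoreach simulate --n 2000 --seed 1 --out micro.csv
egoreach run-all --input micro.csv --out results/
egoreach run-all --synthetic --seed 1 --radius 16km --out results_16km/
```

`run-all` writes the canonical microdata, per-ego results, tidy network
exports, every grouped table and a `manifest.json` with SHA-256 digests of
all outputs; identical configuration and seed reproduce every file
byte-for-byte. `--radius 16km` relaxes the kin proximity rule from "same
municipality" to "not farther than 16 km", which can only enlarge networks.

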
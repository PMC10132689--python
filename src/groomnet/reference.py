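"""Synthetic reference dataset matching the published study composition.

The real study released group composition, individual metadata and raw
adjacency matrices as a supplementary workbook.  That workbook is not
redistributable here, so this module constructs a *synthetic* stand-in whose
composition reproduces every printed descriptor of the study sample exactly:

* 22 compositionally different groups, adult group sizes 3-15, median 6;
* 136 individual-in-group records from 84 unique individuals (48 observed
  once, 25 twice, 6 three times, 5 four times, each time in a different
  group);
* 51 male records (33 unique; 39 mother-reared / 12 atypically reared) and
  85 female records (51 unique; 62 mother-reared / 23 atypically reared);
* male ages 7-45 (average near 19), female ages 7-71 (average near 24);
* adult male-to-female sex ratios from 0.20 to 2.00 with 14 female-biased
  groups;
* an indirect-measure subset of 126 records from the 20 groups with at
  least 5 adults (three records in large groups belong to individuals that
  were never observed grooming, so their indirect metrics are undefined).

Grooming scans, adjacency matrices and metric values are *simulated* by
:mod:`groomnet.synthetic_data` on top of this fixed composition; they are
plausible under the study conditions but are not the real observations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (GroupRecord, IndividualRecord, ObservationSet,
                         write_supplementary_workbook)
from .network_build import build_networks
from .network_metrics import MetricsOptions, compute_metrics_table
from .synthetic_data import (GroundTruth, Population, SimulationConfig,
                             assign_latents, simulate_agonistic,
                             simulate_scans)

# (group_id, n_males, n_females); 5 even, 3 male-biased, 14 female-biased
REFERENCE_GROUPS: list[tuple[str, int, int]] = [
    ("G01", 2, 2), ("G02", 3, 3), ("G03", 3, 3), ("G04", 3, 3),
    ("G05", 3, 3),
    ("G06", 4, 2), ("G07", 3, 2), ("G08", 4, 3),
    ("G09", 1, 2),
    ("G10", 2, 3), ("G11", 2, 3), ("G12", 2, 3), ("G13", 2, 3),
    ("G14", 1, 4), ("G15", 1, 4),
    ("G16", 1, 5), ("G17", 2, 4),
    ("G18", 2, 5), ("G19", 2, 5),
    ("G20", 3, 5), ("G21", 2, 6),
    ("G22", 3, 12),
]

# how often each unique individual was observed (in different groups)
MALE_MULTIPLICITIES = [4] + [3] * 2 + [2] * 11 + [1] * 19        # 33 -> 51
FEMALE_MULTIPLICITIES = [4] * 4 + [3] * 4 + [2] * 14 + [1] * 29  # 51 -> 85

# unique ids with atypical rearing (sum of their multiplicities: 12 / 23)
ATYPICAL_MALES = {"M04", "M05", "M06", "M15", "M16", "M17", "M18", "M19",
                  "M20"}
ATYPICAL_FEMALES = {"F01", "F02", "F05", "F09", "F10", "F11", "F23", "F24",
                    "F25", "F26", "F27", "F28"}

MALE_AGE_RANGE = (7.0, 45.0)
FEMALE_AGE_RANGE = (7.0, 71.0)

# records of individuals never observed grooming (indirect metrics missing);
# chosen in three of the largest groups so that the indirect-measure subset
# is 126 records from 20 groups
N_NON_SOCIAL = 3
NON_SOCIAL_GROUPS = ("G22", "G21", "G20")

def _base_ages(n: int, age_range: tuple[float, float],
               power: float) -> np.ndarray:
    lo, hi = age_range
    i = np.arange(n, dtype=float)
    return np.round(lo + (hi - lo) * (i / (n - 1)) ** power, 1)


def _assign(mults: list[int], prefix: str) -> dict[str, int]:
    return {f"{prefix}{k + 1:02d}": m for k, m in enumerate(mults)}


def build_reference_composition() -> pd.DataFrame:
    """Deterministic individual-to-group assignment.

    Greedy scheduling: groups are filled in decreasing size order and each
    slot takes the not-yet-used-in-this-group individual with the most
    remaining observations, which guarantees that every repeated individual
    lands in distinct groups.
    """
    male_left = _assign(MALE_MULTIPLICITIES, "M")
    female_left = _assign(FEMALE_MULTIPLICITIES, "F")
    # power-law spacing over the printed ranges; exponents chosen so the
    # observation-weighted averages land on the printed values (19 / 24)
    male_ages = dict(zip(sorted(male_left),
                         _base_ages(len(male_left), MALE_AGE_RANGE, 1.4)))
    female_ages = dict(zip(sorted(female_left),
                           _base_ages(len(female_left), FEMALE_AGE_RANGE,
                                      1.6)))
    seen: dict[str, int] = {}  # how many times an id has been placed so far

    def take(pool: dict[str, int], count: int) -> list[str]:
        chosen: list[str] = []
        for _ in range(count):
            # most remaining observations first, id as deterministic
            # tie-break; never the same individual twice in one group
            cand = sorted((k for k in pool if k not in chosen),
                          key=lambda k: (-pool[k], k))
            iid = cand[0]
            chosen.append(iid)
            pool[iid] -= 1
            if pool[iid] == 0:
                del pool[iid]
        return chosen

    rows = []
    order = sorted(REFERENCE_GROUPS, key=lambda g: -(g[1] + g[2]))
    for gid, n_males, n_females in order:
        for iid in take(male_left, n_males):
            repeat = seen.get(iid, 0)
            seen[iid] = repeat + 1
            rows.append({"group_id": gid, "individual_id": iid,
                         "sex": "male",
                         "age": min(male_ages[iid] + repeat,
                                    MALE_AGE_RANGE[1]),
                         "rearing": ("atypically_reared"
                                     if iid in ATYPICAL_MALES
                                     else "mother_reared")})
        for iid in take(female_left, n_females):
            repeat = seen.get(iid, 0)
            seen[iid] = repeat + 1
            rows.append({"group_id": gid, "individual_id": iid,
                         "sex": "female",
                         "age": min(female_ages[iid] + repeat,
                                    FEMALE_AGE_RANGE[1]),
                         "rearing": ("atypically_reared"
                                     if iid in ATYPICAL_FEMALES
                                     else "mother_reared")})
    df = pd.DataFrame(rows)
    df["non_social"] = False
    already: set[str] = set()
    for gid in NON_SOCIAL_GROUPS:
        members = df[(df["group_id"] == gid)
                     & ~df["individual_id"].isin(already)]
        iid = sorted(members["individual_id"])[-1]
        already.add(iid)
        df.loc[(df["group_id"] == gid)
               & (df["individual_id"] == iid), "non_social"] = True
    gid_order = [g for g, _, _ in REFERENCE_GROUPS]
    df["__order"] = df["group_id"].map({g: i for i, g in enumerate(gid_order)})
    df = df.sort_values(["__order", "sex", "individual_id"],
                        ascending=[True, False, True])
    return df.drop(columns="__order").reset_index(drop=True)


def reference_population() -> tuple[Population, set[tuple[str, str]]]:
    comp = build_reference_composition()
    individuals = [IndividualRecord(individual_id=r.individual_id,
                                    group_id=r.group_id, sex=r.sex,
                                    age=float(r.age), rearing=r.rearing)
                   for r in comp.itertuples(index=False)]
    groups = []
    for gid in comp["group_id"].unique():
        members = tuple(comp.loc[comp["group_id"] == gid, "individual_id"])
        groups.append(GroupRecord(group_id=gid, members=members))
    non_social = {(r.group_id, r.individual_id)
                  for r in comp.itertuples(index=False) if r.non_social}
    return Population(individuals=individuals, groups=groups), non_social


def make_reference_observations(seed: int = 1,
                                config: SimulationConfig | None = None,
                                ) -> tuple[ObservationSet, GroundTruth]:
    """Simulate the full observational dataset on the fixed composition."""
    config = config or SimulationConfig()
    pop, non_social = reference_population()
    rng = np.random.default_rng(seed)
    gt = assign_latents(pop, config, rng, non_social=non_social)
    obs = simulate_scans(pop, gt, config, seed + 1)
    obs.agonistic_events = simulate_agonistic(pop, gt, config, seed + 2)
    obs.validate()
    return obs, gt


def make_reference_workbook(path: str | Path, seed: int = 1,
                            config: SimulationConfig | None = None,
                            ) -> pd.DataFrame:
    """Write the synthetic S1-layout workbook; returns the metrics table."""
    obs, gt = make_reference_observations(seed=seed, config=config)
    networks = build_networks(obs)
    table = compute_metrics_table(networks, obs, MetricsOptions())
    individuals = table[["group_id", "individual_id", "sex", "age", "rearing",
                         "out_strength", "in_strength", "disparity",
                         "affinity", "eigenvector"]]
    groups = pd.DataFrame({
        "group_id": [n.group_id for n in networks],
        "group_size": [n.n_nodes for n in networks],
        "sex_ratio": [obs.sex_ratio(n.group_id) for n in networks],
        "n_scans": [gt.n_scans[n.group_id] for n in networks],
    })
    matrices = {n.group_id: (n.nodes, n.W) for n in networks}
    write_supplementary_workbook(path, individuals, groups, matrices)
    return table


def describe_sample(individuals: pd.DataFrame,
                    groups: pd.DataFrame) -> dict:
    """Descriptors of a workbook-style sample, in the study's terms."""
    merged = individuals.merge(groups[["group_id", "group_size"]],
                               on="group_id", how="left")
    males = merged[merged["sex"] == "male"]
    females = merged[merged["sex"] == "female"]
    if "eigenvector" in merged:
        defined = np.isfinite(merged["eigenvector"])
    else:
        defined = pd.Series(True, index=merged.index)
    indirect = merged[(merged["group_size"] >= 5) & defined]
    counts = merged["individual_id"].value_counts()
    return {
        "n_groups": int(len(groups)),
        "n_records": int(len(merged)),
        "n_unique_individuals": int(merged["individual_id"].nunique()),
        "median_group_size": float(groups["group_size"].median()),
        "min_group_size": int(groups["group_size"].min()),
        "max_group_size": int(groups["group_size"].max()),
        "n_female_biased_groups": int((groups["sex_ratio"] < 1).sum()),
        "n_male_biased_groups": int((groups["sex_ratio"] > 1).sum()),
        "min_sex_ratio": float(groups["sex_ratio"].min()),
        "max_sex_ratio": float(groups["sex_ratio"].max()),
        "n_observed_once": int((counts == 1).sum()),
        "n_observed_twice": int((counts == 2).sum()),
        "n_observed_thrice": int((counts == 3).sum()),
        "n_observed_four_times": int((counts == 4).sum()),
        "n_male_records": int(len(males)),
        "n_unique_males": int(males["individual_id"].nunique()),
        "n_male_mother_reared": int((males["rearing"]
                                     == "mother_reared").sum()),
        "n_male_atypically_reared": int((males["rearing"]
                                         == "atypically_reared").sum()),
        "n_female_records": int(len(females)),
        "n_unique_females": int(females["individual_id"].nunique()),
        "n_female_mother_reared": int((females["rearing"]
                                       == "mother_reared").sum()),
        "n_female_atypically_reared": int((females["rearing"]
                                           == "atypically_reared").sum()),
        "n_indirect_records": int(len(indirect)),
        "n_indirect_groups": int(indirect["group_id"].nunique()),
    }
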
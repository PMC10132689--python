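"""Synthetic multi-group scan-sampling data with known ground truth.

The generator emulates the observation protocol of the real study: several
compositionally distinct groups (3-15 adults, male-to-female ratios 0.20 to
2.00), instantaneous group scans (274-1103 per group) with per-individual
visibility missingness, dyadic grooming whose probability carries planted
individual effects, and ad libitum agonistic wins driven by latent dominance
values.

Grooming is generated on the logistic scale: the probability that actor i is
seen grooming receiver j in one scan is

    p_ij = logistic(b0 + b_male * male_i + b_rear * atypical_i
                    + b1 * age_c_i + b2 * age_c_i^2 + eps_i     (giver)
                    + r_j                                        (receiver)
                    + assortment(sex_i, sex_j) + d_ij)           (dyad)

with at most one receiver per actor per scan (scan sampling records an
instantaneous behavior).  The default coefficients are chosen so that the
average out-strength sits near 0.08 -- the scale of the real male average --
with a grooming peak near the prime age and a deficit for atypically reared
givers.  Latent dominance follows sex-specific age curves (female peak in the
mid-thirties, male minimum around the mid-twenties, females above males on
average).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (GroupRecord, IndividualRecord, ObservationSet,
                         ScanEvent, ValidationError)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator (defaults follow the real study)."""

    n_groups: int = 22
    group_size_range: tuple[int, int] = (3, 15)
    sex_ratio_range: tuple[float, float] = (0.20, 2.00)
    age_range: tuple[float, float] = (7.0, 71.0)
    age_gamma_shape: float = 2.2
    age_gamma_scale: float = 7.5
    rearing_prob: float = 0.26
    n_scans_range: tuple[int, int] = (274, 1103)
    visibility_missing_prob: float = 0.05

    # giver (out-going grooming propensity), logit scale
    giver_intercept: float = -4.05  # calibrated: male out-strength ~ 0.08
    # finite grooming time budget: per-dyad giving dilutes with the number
    # of available partners, keeping total giving roughly group-size-free
    time_budget_dilution: float = 1.0
    reference_partners: float = 5.0  # dilution pivot (mean available partners)
    sex_effect_give: float = 0.0
    rearing_effect_give: float = -0.35
    age_quadratic: float = -6.5e-4  # per year^2
    age_peak: float = 28.0          # age at maximum giving
    individual_noise_sd: float = 0.40

    # receiver attractiveness, logit scale
    receiver_female_effect: float = 0.25
    receiver_atypical_male_effect: float = -0.50
    receiver_noise_sd: float = 0.30

    # dyad level
    sex_assortment: float = 0.30    # +ff, -mm
    dyad_noise_sd: float = 0.30

    # agonistic process
    agonistic_rate: float = 2.0     # expected events per dyad
    dom_female_advantage: float = 1.5
    dom_female_peak: float = 35.0
    dom_female_quad: float = -4e-3
    dom_male_trough: float = 25.0
    dom_male_quad: float = 4e-3
    dom_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.rearing_prob, self.visibility_missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.group_size_range[0] < 3:
            raise ValidationError("group sizes must be >= 3")


@dataclass
class GroundTruth:
    """Latent quantities behind a simulated dataset."""

    coefficients: dict
    giver: dict[tuple[str, str], float] = field(default_factory=dict)
    receiver: dict[tuple[str, str], float] = field(default_factory=dict)
    dominance: dict[tuple[str, str], float] = field(default_factory=dict)
    prob: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    n_scans: dict[str, int] = field(default_factory=dict)
    mean_age: float = 0.0
    non_social: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class Population:
    individuals: list[IndividualRecord]
    groups: list[GroupRecord]

    def records_for(self, group_id: str) -> list[IndividualRecord]:
        return [r for r in self.individuals if r.group_id == group_id]


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _draw_ages(rng: np.random.Generator, n: int,
               config: SimulationConfig) -> np.ndarray:
    lo, hi = config.age_range
    ages = lo + rng.gamma(config.age_gamma_shape, config.age_gamma_scale,
                          size=n)
    return np.clip(ages, lo, hi)


def simulate_population(config: SimulationConfig, seed: int,
                        ) -> tuple[Population, GroundTruth]:
    """Draw groups, traits and latent propensities (no scans yet)."""
    rng = np.random.default_rng(seed)
    individuals: list[IndividualRecord] = []
    groups: list[GroupRecord] = []
    counter = 0
    for g in range(config.n_groups):
        gid = f"G{g + 1:02d}"
        for _ in range(1000):
            size = int(rng.integers(config.group_size_range[0],
                                    config.group_size_range[1] + 1))
            ratio = rng.uniform(*config.sex_ratio_range)
            n_males = int(round(size * ratio / (1.0 + ratio)))
            n_males = min(max(n_males, 1), size - 1)
            if (config.sex_ratio_range[0] <= n_males / (size - n_males)
                    <= config.sex_ratio_range[1]):
                break
        else:  # pragma: no cover - range always feasible for sizes >= 3
            raise ValidationError("could not draw a feasible composition")
        members = []
        for k in range(size):
            counter += 1
            iid = f"I{counter:04d}"
            members.append(iid)
            individuals.append(IndividualRecord(
                individual_id=iid, group_id=gid,
                sex="male" if k < n_males else "female",
                age=float(_draw_ages(rng, 1, config)[0]),
                rearing=("atypically_reared"
                         if rng.random() < config.rearing_prob
                         else "mother_reared")))
        groups.append(GroupRecord(group_id=gid, members=tuple(members)))
    pop = Population(individuals=individuals, groups=groups)
    gt = assign_latents(pop, config, rng)
    return pop, gt


def assign_latents(pop: Population, config: SimulationConfig,
                   rng: np.random.Generator,
                   non_social: set[tuple[str, str]] | None = None,
                   ) -> GroundTruth:
    """Latent giver/receiver/dominance values for an existing population."""
    non_social = non_social or set()
    ages = np.array([r.age for r in pop.individuals])
    mean_age = float(ages.mean())
    b2 = config.age_quadratic
    b1 = -2.0 * b2 * (config.age_peak - mean_age)
    coeffs = {"giver_intercept": config.giver_intercept,
              "sex_effect_give": config.sex_effect_give,
              "rearing_effect_give": config.rearing_effect_give,
              "age_linear": b1, "age_quadratic": b2,
              "mean_age": mean_age}
    gt = GroundTruth(coefficients=coeffs, mean_age=mean_age,
                     non_social=set(non_social))
    for rec in pop.individuals:
        key = (rec.group_id, rec.individual_id)
        age_c = rec.age - mean_age
        male = rec.sex == "male"
        atypical = rec.rearing == "atypically_reared"
        g = (config.giver_intercept + config.sex_effect_give * male
             + config.rearing_effect_give * atypical
             + b1 * age_c + b2 * age_c ** 2
             + rng.normal(0.0, config.individual_noise_sd))
        r = (config.receiver_female_effect * (not male)
             + config.receiver_atypical_male_effect * (male and atypical)
             + rng.normal(0.0, config.receiver_noise_sd))
        if male:
            dom = config.dom_male_quad * (rec.age - config.dom_male_trough) ** 2
        else:
            dom = (config.dom_female_advantage
                   + config.dom_female_quad
                   * (rec.age - config.dom_female_peak) ** 2)
        dom += rng.normal(0.0, config.dom_noise_sd)
        if key in non_social:
            g, r = -math.inf, -math.inf
        gt.giver[key] = float(g)
        gt.receiver[key] = float(r)
        gt.dominance[key] = float(dom)

    for grp in pop.groups:
        nodes = list(grp.members)
        recs = {r.individual_id: r for r in pop.records_for(grp.group_id)}
        n = len(nodes)
        dilution = (config.time_budget_dilution
                    * math.log((n - 1) / config.reference_partners))
        logits = np.zeros((n, n))
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                if i == j:
                    continue
                sex_a = recs[a].sex
                sex_b = recs[b].sex
                if sex_a == sex_b == "female":
                    assort = config.sex_assortment
                elif sex_a == sex_b == "male":
                    assort = -config.sex_assortment
                else:
                    assort = 0.0
                logits[i, j] = (gt.giver[(grp.group_id, a)] - dilution
                                + gt.receiver[(grp.group_id, b)] + assort
                                + rng.normal(0.0, config.dyad_noise_sd))
        P = _logistic(logits)
        np.fill_diagonal(P, 0.0)
        for idx, a in enumerate(nodes):
            if (grp.group_id, a) in non_social:
                P[idx, :] = 0.0
                P[:, idx] = 0.0
        gt.prob[grp.group_id] = (nodes, P)
    return gt


# ---------------------------------------------------------------------------
# scans and agonistic events
# ---------------------------------------------------------------------------

def simulate_scans(pop: Population, gt: GroundTruth,
                   config: SimulationConfig, seed: int,
                   n_scans: dict[str, int] | None = None) -> ObservationSet:
    """Generate scan events for every group.

    Each individual is independently out of sight with the configured
    probability; every visible ordered dyad grooms with its planted
    probability, and if an actor has several candidate receivers in one scan
    the highest draw wins (one receiver per actor per scan).
    """
    rng = np.random.default_rng(seed)
    scans: list[ScanEvent] = []
    for grp in pop.groups:
        gid = grp.group_id
        nodes, P = gt.prob[gid]
        n = len(nodes)
        if n_scans and gid in n_scans:
            S = int(n_scans[gid])
        else:
            S = int(rng.integers(config.n_scans_range[0],
                                 config.n_scans_range[1] + 1))
        gt.n_scans[gid] = S
        visible = rng.random((S, n)) >= config.visibility_missing_prob
        U = rng.random((S, n, n))
        success = (U < P[None, :, :]) & visible[:, :, None] & visible[:, None, :]
        draw = np.where(success, U, -1.0)
        best = draw.argmax(axis=2)           # (S, n): best receiver per actor
        any_success = success.any(axis=2)
        for s in range(S):
            pairs = [(nodes[i], nodes[best[s, i]])
                     for i in np.flatnonzero(any_success[s])]
            out = frozenset(nodes[i] for i in np.flatnonzero(~visible[s]))
            scans.append(ScanEvent(group_id=gid, scan_index=s,
                                   grooming_pairs=frozenset(pairs),
                                   out_of_sight=out))
    return ObservationSet(individuals=list(pop.individuals),
                          groups=list(pop.groups), scans=scans)


def simulate_agonistic(pop: Population, gt: GroundTruth,
                       config: SimulationConfig, seed: int,
                       ) -> list[tuple[str, str, str]]:
    """Poisson dyadic agonistic events; the higher latent dominance tends to
    win (logistic in the dominance difference)."""
    rng = np.random.default_rng(seed)
    events: list[tuple[str, str, str]] = []
    for grp in pop.groups:
        gid = grp.group_id
        nodes = list(grp.members)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                count = rng.poisson(config.agonistic_rate)
                if count == 0:
                    continue
                p_a = _logistic(gt.dominance[(gid, a)]
                                - gt.dominance[(gid, b)])
                wins_a = rng.binomial(count, p_a)
                events.extend([(gid, a, b)] * int(wins_a))
                events.extend([(gid, b, a)] * int(count - wins_a))
    return events


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0,
                     with_agonistic: bool = True,
                     ) -> tuple[ObservationSet, GroundTruth]:
    """One full synthetic dataset (population, scans, agonistic events)."""
    config = config or SimulationConfig()
    pop, gt = simulate_population(config, seed)
    obs = simulate_scans(pop, gt, config, seed + 1)
    if with_agonistic:
        obs.agonistic_events = simulate_agonistic(pop, gt, config, seed + 2)
        obs.validate()
    return obs, gt


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """A copy of ``config`` with every planted individual effect removed."""
    config = config or SimulationConfig()
    return replace(config, sex_effect_give=0.0, rearing_effect_give=0.0,
                   age_quadratic=0.0, receiver_female_effect=0.0,
                   receiver_atypical_male_effect=0.0, sex_assortment=0.0)
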
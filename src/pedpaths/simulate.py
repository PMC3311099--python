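"""Seedable synthetic-pedigree generation.

Two generators: a yearly-cycle population simulator with overlapping
generations (aging, mortality, immigration, marriage, births) producing
pedigrees whose inbreeding level is controlled chiefly by the immigration
rate, and a minimal random-mating generator for property tests.

The demographic defaults model a small, relatively isolated founding
population growing over several centuries; they are deliberately simple
(constant rates, no geography or genotypes) and every one is settable, via
:class:`SimConfig` or a YAML mapping of the same field names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Dict, List, Optional, Tuple

import numpy as np

from .pedigree import Individual, Pedigree, Sex

__all__ = ["SimConfig", "simulate_population", "random_pedigree"]


def _default_ages() -> Dict[str, float]:
    return {"0-14": 0.35, "15-39": 0.40, "40-59": 0.20, "60+": 0.05}


def _default_deaths() -> Dict[str, float]:
    return {"0-14": 0.004, "15-59": 0.007, "60-79": 0.05, "80+": 0.25}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the yearly population cycle.

    Probabilities are per year; ``expected_children`` is the per-couple birth
    probability per year while the wife is at most ``max_pregnancy_age``.
    ``immigration_rate`` is the fraction of the living population arriving as
    unrelated adult founders each year.  The run stops at ``end_year`` or
    when ``max_individuals`` is reached, whichever is first.
    """

    start_year: int = 1500
    end_year: int = 2000
    initial_population: int = 30
    initial_age_distribution: Dict[str, float] = field(default_factory=_default_ages)
    marriage_probability: float = 0.12
    marriage_age: int = 17
    max_pregnancy_age: int = 45
    expected_children: float = 0.22
    immigration_rate: float = 0.005
    death_probability: Dict[str, float] = field(default_factory=_default_deaths)
    max_individuals: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("marriage_probability", "expected_children", "immigration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_individuals < self.initial_population:
            raise ValueError("max_individuals must be >= initial_population")

    @classmethod
    def from_dict(cls, d: Dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown SimConfig fields: {sorted(bad)}")
        return cls(**d)


def _parse_bracket(name: str) -> Tuple[int, int]:
    if name.endswith("+"):
        return int(name[:-1]), 10**9
    lo, hi = name.split("-")
    return int(lo), int(hi)


@dataclass
class _Person:
    id: str
    sex: Sex
    age: int
    father: Optional[str] = None
    mother: Optional[str] = None
    spouse: Optional[str] = None
    alive: bool = True


def simulate_population(cfg: SimConfig, seed: Optional[int] = None) -> Pedigree:
    """Run the yearly cycle and return the accumulated pedigree.

    Deterministic for a given (config, seed); ``seed`` overrides
    ``cfg.seed`` when given.  Hitting ``max_individuals`` mid-year truncates
    the run with a warning.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    death_brackets = [(_parse_bracket(k), v) for k, v in cfg.death_probability.items()]
    age_brackets = list(cfg.initial_age_distribution.items())
    age_probs = np.array([w for _, w in age_brackets], dtype=float)
    age_probs /= age_probs.sum()

    people: Dict[str, _Person] = {}
    order: List[str] = []
    counter = 0
    immigrant_sex_toggle = [Sex.MALE]

    def new_person(sex: Sex, age: int, father=None, mother=None) -> Optional[_Person]:
        nonlocal counter
        if len(order) >= cfg.max_individuals:
            return None
        pid = f"I{counter}"
        counter += 1
        person = _Person(pid, sex, age, father, mother)
        people[pid] = person
        order.append(pid)
        return person

    def sample_age() -> int:
        k = rng.choice(len(age_brackets), p=age_probs)
        lo, hi = _parse_bracket(age_brackets[k][0])
        hi = min(hi, 80)
        return int(rng.integers(lo, hi + 1))

    def death_prob(age: int) -> float:
        for (lo, hi), v in death_brackets:
            if lo <= age <= hi:
                return v
        return 1.0

    for _ in range(cfg.initial_population):
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        new_person(sex, sample_age())

    truncated = False
    for _year in range(cfg.start_year, cfg.end_year + 1):
        living = [people[i] for i in order if people[i].alive]
        if not living:
            break
        # aging and mortality
        for person in living:
            person.age += 1
            if rng.random() < death_prob(person.age):
                person.alive = False
                if person.spouse and person.spouse in people:
                    people[person.spouse].spouse = None
                person.spouse = None
        living = [q for q in living if q.alive]
        # immigration: unrelated adult founders, sexes alternating
        expected = cfg.immigration_rate * len(living)
        n_migrants = int(expected) + (1 if rng.random() < expected % 1 else 0)
        for _ in range(n_migrants):
            sex = immigrant_sex_toggle[0]
            immigrant_sex_toggle[0] = (
                Sex.FEMALE if sex is Sex.MALE else Sex.MALE
            )
            if new_person(sex, int(rng.integers(17, 41))) is None:
                truncated = True
                break
        # marriages among unmarried adults
        def eligible(sex: Sex) -> List[_Person]:
            return [
                q
                for q in living
                if q.alive
                and q.sex is sex
                and q.spouse is None
                and q.age >= cfg.marriage_age
                and rng.random() < cfg.marriage_probability
            ]

        bachelors, maidens = eligible(Sex.MALE), eligible(Sex.FEMALE)
        bachelors = [bachelors[k] for k in rng.permutation(len(bachelors))]
        maidens = [maidens[k] for k in rng.permutation(len(maidens))]
        for husband, wife in zip(bachelors, maidens):
            husband.spouse, wife.spouse = wife.id, husband.id
        # births
        if not truncated:
            for person in living:
                if (
                    person.sex is Sex.FEMALE
                    and person.alive
                    and person.spouse is not None
                    and person.age <= cfg.max_pregnancy_age
                    and rng.random() < cfg.expected_children
                ):
                    sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                    child = new_person(sex, 0, father=person.spouse, mother=person.id)
                    if child is None:
                        truncated = True
                        break
        if truncated:
            break

    if truncated:
        warnings.warn(
            f"population cap {cfg.max_individuals} reached before end_year; "
            "pedigree truncated",
            stacklevel=2,
        )
    return Pedigree(
        Individual(
            id=pid,
            father_id=people[pid].father,
            mother_id=people[pid].mother,
            sex=people[pid].sex,
        )
        for pid in order
    )


def random_pedigree(
    n: int,
    n_founders: int = 4,
    seed: int = 0,
    p_extra_founder: float = 0.05,
    p_single_parent: float = 0.1,
) -> Pedigree:
    """Random-mating DAG fixture: parents drawn uniformly from earlier individuals.

    Founders come first with alternating sexes; each later individual draws a
    father among earlier males and a mother among earlier females (acyclic by
    construction), occasionally keeping one parent or none.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders (one of each sex)")
    if n < n_founders:
        raise ValueError("n must be >= n_founders")
    rng = np.random.default_rng(seed)
    inds: List[Individual] = []
    males: List[str] = []
    females: List[str] = []
    for i in range(n):
        pid = f"R{i}"
        if i < n_founders:
            sex = Sex.MALE if i % 2 == 0 else Sex.FEMALE
            inds.append(Individual(id=pid, sex=sex))
        else:
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            if rng.random() < p_extra_founder:
                father = mother = None
            else:
                father = males[int(rng.integers(len(males)))]
                mother = females[int(rng.integers(len(females)))]
                if rng.random() < p_single_parent:
                    if rng.random() < 0.5:
                        father = None
                    else:
                        mother = None
            inds.append(Individual(id=pid, father_id=father, mother_id=mother, sex=sex))
        (males if sex is Sex.MALE else females).append(pid)
    return Pedigree(inds)
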
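"""Growth, size-dependent maturation, fecundity, and mortality.

Core vital-rate functions for the simulated salmonid population:

- growth follows a von Bertalanffy curve, ``ΔL = (L∞ − L)(1 − e^(−k))``
  per year;
- maturation probability is a logistic function of body length,
  ``P = expit(A + B·L)``, with a shared intercept ``A`` and a steeper slope
  ``B`` for sneaker males (steeper slope ⇒ maturity at smaller size, hence
  younger age);
- mean fecundity is an exponential function of female length,
  ``eggs = 9.5576 · exp(0.0181 · L)``;
- mortality acts through an age-class schedule, an additive sneaker-male
  mortality applied in natal patches after return migration, and
  phenotype-blind density-dependent truncation to patch carrying capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .population import Population

__all__ = [
    "LifeHistoryParams",
    "maturation_probability",
    "fecundity_mean",
    "grow",
    "apply_class_mortality",
    "class_survival_mask",
    "sneaker_survival_mask",
    "density_dependent_cull",
]

# annual mortality by age class (age 0, 1, 2, ... capped at the last entry);
# juvenile mortality declines with size, adult (migratory) mortality is
# substantial and rises with age, so the late-maturing territorial strategy
# buys few spawning seasons — the life-history trade-off under study
DEFAULT_AGE_CLASS_MORTALITY = (
    0.60, 0.40, 0.30, 0.30, 0.35, 0.35, 0.40, 0.40, 0.45, 0.50, 0.60, 0.75, 1.0,
)


@dataclass
class LifeHistoryParams:
    """Fixed life-history settings plus the two scenario-varied sneaker knobs.

    Lengths in mm, rates per year, mortalities as annual fractions in [0, 1].
    ``maturation_B_sneaker`` and ``sneaker_additive_mortality`` are the two
    life-history parameters varied across sensitivity scenarios.
    """

    vonB_Linf: float = 800.0          # asymptotic length, mm
    vonB_k: float = 0.18              # Brody growth coefficient, 1/yr
    length_age0: float = 30.0         # length at age 0 (fry), mm
    maturation_A: float = -10.0       # logistic intercept (shared across AMS)
    maturation_B_territorial_and_female: float = 0.01704  # per mm
    maturation_B_sneaker: float = 0.01704                 # per mm, LHS-varied
    fecundity_a: float = 9.5576       # eggs at length 0
    fecundity_b: float = 0.0181       # per mm
    egg_survival: float = 2e-4        # egg -> age-0 recruit survival
    age_class_mortality: tuple = field(default=DEFAULT_AGE_CLASS_MORTALITY)
    sneaker_additive_mortality: float = 0.0  # per year, all classes; LHS-varied
    max_age: int = 12

    def __post_init__(self) -> None:
        m = np.asarray(self.age_class_mortality, dtype=float)
        if ((m < 0) | (m > 1)).any():
            raise ValueError("age-class mortalities must lie in [0, 1]")
        if not 0 <= self.sneaker_additive_mortality <= 1:
            raise ValueError("sneaker_additive_mortality must lie in [0, 1]")
        if self.maturation_B_territorial_and_female <= 0 or self.maturation_B_sneaker <= 0:
            raise ValueError("maturation slopes must be positive")
        if self.fecundity_a <= 0:
            raise ValueError("fecundity_a must be positive")

    # -- derived helpers ----------------------------------------------------
    def length_at_age(self, age) -> np.ndarray:
        """Deterministic growth-curve length at integer age."""
        age = np.asarray(age, dtype=float)
        return self.vonB_Linf - (self.vonB_Linf - self.length_age0) * np.exp(
            -self.vonB_k * age
        )

    def class_mortality(self, age) -> np.ndarray:
        m = np.asarray(self.age_class_mortality, dtype=float)
        idx = np.minimum(np.asarray(age, dtype=int), len(m) - 1)
        return m[idx]

    def survivorship(self) -> np.ndarray:
        """Cumulative survival l(a) to the start of each age 0..max_age."""
        m = self.class_mortality(np.arange(self.max_age + 1))
        l = np.ones(self.max_age + 1)
        l[1:] = np.cumprod(1.0 - m[:-1])
        return l

    def stable_age_sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Ages 1..max_age drawn from the survivorship-weighted distribution."""
        l = self.survivorship()[1:]
        p = l / l.sum()
        return rng.choice(np.arange(1, self.max_age + 1), size=n, p=p)

    def maturation_probability_for(self, length, sex, genotype) -> np.ndarray:
        """Per-individual maturation probability with the AMS-specific slope."""
        length = np.asarray(length, dtype=float)
        sneaker = (np.asarray(sex) == 1) & (np.asarray(genotype) == 2)
        b = np.where(sneaker, self.maturation_B_sneaker,
                     self.maturation_B_territorial_and_female)
        return expit(self.maturation_A + b * length)


def maturation_probability(length, A: float, B: float) -> np.ndarray:
    """Logistic size-at-maturity: ``expit(A + B · length)``.

    Overflow-safe; strictly increasing in length for B > 0.
    """
    length = np.asarray(length, dtype=float)
    return expit(A + B * length)


def fecundity_mean(length) -> np.ndarray:
    """Mean egg number as a function of female length (mm)."""
    return 9.5576 * np.exp(0.0181 * np.asarray(length, dtype=float))


def grow(length, params: LifeHistoryParams) -> np.ndarray:
    """One year of von Bertalanffy growth; never shrinks, never exceeds L∞."""
    length = np.asarray(length, dtype=float)
    increment = np.maximum(0.0, (params.vonB_Linf - length) * (1.0 - np.exp(-params.vonB_k)))
    return np.minimum(np.maximum(length, params.vonB_Linf), length + increment)


# -- mortality --------------------------------------------------------------

def class_survival_mask(pop: Population, params: LifeHistoryParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli survival draws from the age-class schedule."""
    m = params.class_mortality(pop.age)
    return rng.random(len(pop)) >= m


def sneaker_survival_mask(pop: Population, params: LifeHistoryParams,
                          rng: np.random.Generator,
                          mature_only: bool = False) -> np.ndarray:
    """Additive sneaker-male mortality, the same rate across all age classes.

    Non-sneaker individuals always survive this draw.  With
    ``mature_only=True`` the draw is restricted to mature sneaker males —
    the spawners who immigrated back into the natal patches, which is how
    the annual cycle applies it (it is a cost of the spawning return, not a
    resident juvenile mortality).
    """
    survive = np.ones(len(pop), dtype=bool)
    sm = pop.is_sneaker_male
    if mature_only:
        sm = sm & pop.mature
    if sm.any() and params.sneaker_additive_mortality > 0:
        survive[sm] = rng.random(int(sm.sum())) >= params.sneaker_additive_mortality
    return survive


def apply_class_mortality(pop: Population, params: LifeHistoryParams,
                          rng: np.random.Generator,
                          sneaker_additive: bool = True) -> Population:
    """Apply age-class mortality (and, optionally, the additive sneaker-male
    mortality) in place; returns the surviving population."""
    mask = class_survival_mask(pop, params, rng)
    if sneaker_additive:
        mask &= sneaker_survival_mask(pop, params, rng)
    pop.keep(mask)
    return pop


def density_dependent_cull(n_or_pop, carrying_capacity: int,
                           rng: np.random.Generator,
                           age: np.ndarray | None = None,
                           yoy_first: bool = False) -> np.ndarray:
    """Phenotype-blind truncation of one patch to its carrying capacity.

    Accepts either a :class:`Population` (all individuals assumed co-located)
    or an integer count with an optional ``age`` vector.  Returns a boolean
    survivor mask of length n.  If ``n <= K`` everyone survives; otherwise
    survivors are drawn uniformly without replacement down to K.  With
    ``yoy_first=True`` the excess is removed from young-of-year (age 0)
    first — i.e. recruitment is capped at the space left by older fish —
    then uniformly from the remainder.
    """
    if carrying_capacity < 1:
        raise ValueError("carrying capacity must be >= 1")
    if isinstance(n_or_pop, Population):
        n = len(n_or_pop)
        age = n_or_pop.age
    else:
        n = int(n_or_pop)
    mask = np.ones(n, dtype=bool)
    if n <= carrying_capacity:
        return mask
    excess = n - carrying_capacity
    if yoy_first and age is not None:
        yoy = np.flatnonzero(np.asarray(age) == 0)
        kill_from_yoy = min(excess, yoy.size)
        if kill_from_yoy:
            mask[rng.choice(yoy, size=kill_from_yoy, replace=False)] = False
            excess -= kill_from_yoy
    if excess:
        alive = np.flatnonzero(mask)
        mask[rng.choice(alive, size=excess, replace=False)] = False
    return mask
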
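"""Female mate choice, polyandrous spawning, and Mendelian inheritance.

Mate choice follows a dominant-preference model: every territorial male
carries unnormalized weight ``c`` (the assortative mating factor) and every
sneaker male weight 1, independent of the female's own genotype; ``c = 1``
is random mating.  With equal phenotype frequencies and ``c = 2`` a female
is therefore twice as likely to mate with any given territorial male as
with any given sneaker male.

A literal genotype-matching variant (weight ``c`` when the female's and
male's genotypes are identical) is selectable via
``MatingConfig.preference_model = "genotype_delta"``.

Clutches: the total egg number for a female is one Poisson draw of her
length-based mean fecundity, split equally among her (polyandrous) mates,
with the indivisible remainder assigned to random mates.  Each offspring
inherits one allele from each parent by a fair Mendelian draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .life_history import LifeHistoryParams, fecundity_mean

__all__ = ["MatingConfig", "mate_weights", "select_mates", "spawn", "breed_patch"]


@dataclass
class MatingConfig:
    assortative_c: float = 1.0       # >= 1; 1 = random mating
    mates_per_female: int = 2        # polyandry, draws with replacement
    replacement: bool = True
    preference_model: str = "dominant_preference"  # or "genotype_delta"

    def __post_init__(self) -> None:
        if self.assortative_c < 1:
            raise ValueError("assortative_c must be >= 1")
        if self.mates_per_female < 1:
            raise ValueError("mates_per_female must be >= 1")
        if self.preference_model not in ("dominant_preference", "genotype_delta"):
            raise ValueError(f"unknown preference model {self.preference_model!r}")


def _territorial_mask(males) -> np.ndarray:
    """Accept phenotype strings, genotype ints, or a boolean mask."""
    arr = np.asarray(males)
    if arr.dtype.kind in "US":
        return arr == "territorial"
    if arr.dtype.kind == "b":
        return arr
    return arr != 2  # genotypes: non-recessive-homozygote males are territorial


def mate_weights(males, c: float) -> np.ndarray:
    """Normalized per-male mating probabilities under dominant preference.

    ``males`` may be phenotype labels, male genotypes, or a boolean
    is-territorial mask.  Territorial males get unnormalized weight ``c``,
    sneakers weight 1; the result sums to 1.  An empty male pool returns an
    empty array, signalling a skipped breeding event.
    """
    if c < 1:
        raise ValueError("assortative factor c must be >= 1")
    territorial = _territorial_mask(males)
    if territorial.size == 0:
        return np.empty(0)
    w = np.where(territorial, c, 1.0)
    return w / w.sum()


def _weights_for_female(female_genotype: int, male_genotypes: np.ndarray,
                        config: MatingConfig) -> np.ndarray:
    if config.preference_model == "genotype_delta":
        w = np.where(male_genotypes == female_genotype, config.assortative_c, 1.0)
        return w / w.sum() if w.size else np.empty(0)
    return mate_weights(male_genotypes, config.assortative_c)


def select_mates(female_genotype: int, male_genotypes, config: MatingConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw ``mates_per_female`` sire indices with replacement.

    Returns an empty index array when no mature males are present.
    """
    male_genotypes = np.asarray(male_genotypes)
    w = _weights_for_female(female_genotype, male_genotypes, config)
    if w.size == 0:
        return np.empty(0, dtype=int)
    return rng.choice(male_genotypes.size, size=config.mates_per_female,
                      replace=config.replacement, p=w)


def _split_equally(total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` eggs into k equal shares; remainder to random shares."""
    shares = np.full(k, total // k, dtype=int)
    rem = total % k
    if rem:
        shares[rng.choice(k, size=rem, replace=False)] += 1
    return shares


def _mendelian(mother_genotypes, father_genotypes, rng) -> np.ndarray:
    """Offspring recessive-copy counts from fair allele draws per parent."""
    m = rng.random(len(mother_genotypes)) < np.asarray(mother_genotypes) / 2.0
    p = rng.random(len(father_genotypes)) < np.asarray(father_genotypes) / 2.0
    return (m.astype(np.int8) + p.astype(np.int8))


def spawn(female, sire_genotypes, params: LifeHistoryParams,
          rng: np.random.Generator, egg_survival: float = 1.0):
    """Produce one female's offspring for the year.

    ``female`` needs ``length``, ``genotype`` and ``mature`` attributes.
    The clutch size is a single Poisson draw of the mean fecundity at the
    female's length (optionally pre-thinned by ``egg_survival``: a Poisson
    count with independently surviving eggs is again Poisson).  Eggs are
    split equally among the sires; each offspring gets one maternal and one
    paternal allele by fair Mendelian draws, a fair-coin sex, and age 0.

    Returns ``(sexes, genotypes)`` int8 arrays.
    """
    if not female.mature:
        raise ValueError("immature female cannot spawn")
    sire_genotypes = np.asarray(sire_genotypes)
    if sire_genotypes.size == 0:
        raise ValueError("spawn requires at least one sire")
    mean = float(fecundity_mean(female.length)) * egg_survival
    total = int(rng.poisson(mean))
    shares = _split_equally(total, sire_genotypes.size, rng)
    fathers = np.repeat(sire_genotypes, shares)
    mothers = np.full(total, female.genotype)
    genotypes = _mendelian(mothers, fathers, rng)
    sexes = rng.integers(0, 2, size=total).astype(np.int8)
    return sexes, genotypes


def breed_patch(female_lengths, female_genotypes, male_genotypes,
                config: MatingConfig, params: LifeHistoryParams,
                rng: np.random.Generator, egg_survival: float = 1.0):
    """Vectorized within-patch breeding for the simulation engine.

    Semantically equivalent to looping :func:`select_mates` + :func:`spawn`
    over all mature females in a patch, but draws sires, clutch sizes and
    inheritance for the whole patch at once.  Returns ``(sexes, genotypes)``
    for all offspring produced in the patch (empty arrays when either sex
    is absent).
    """
    female_lengths = np.asarray(female_lengths, dtype=float)
    female_genotypes = np.asarray(female_genotypes)
    male_genotypes = np.asarray(male_genotypes)
    n_f, n_m = female_genotypes.size, male_genotypes.size
    empty = (np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int8))
    if n_f == 0 or n_m == 0:
        return empty

    k = config.mates_per_female
    if config.preference_model == "genotype_delta":
        sires = np.empty((n_f, k), dtype=int)
        for g in (0, 1, 2):
            rows = np.flatnonzero(female_genotypes == g)
            if rows.size == 0:
                continue
            w = _weights_for_female(g, male_genotypes, config)
            sires[rows] = rng.choice(n_m, size=(rows.size, k), p=w)
    else:
        w = mate_weights(male_genotypes, config.assortative_c)
        sires = rng.choice(n_m, size=(n_f, k), p=w)

    eggs = rng.poisson(fecundity_mean(female_lengths) * egg_survival)
    total = int(eggs.sum())
    if total == 0:
        return empty
    # equal split across each female's k mate slots, remainder to random slots
    base, rem = eggs // k, eggs % k
    slot_rank = np.argsort(rng.random((n_f, k)), axis=1)
    counts = base[:, None] + (slot_rank < rem[:, None])
    fathers = np.repeat(male_genotypes[sires.ravel()], counts.ravel())
    mothers = np.repeat(female_genotypes, eggs)
    genotypes = _mendelian(mothers, fathers, rng)
    sexes = rng.integers(0, 2, size=total).astype(np.int8)
    return sexes, genotypes
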
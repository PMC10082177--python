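"""Individuals, single-locus mating-strategy genetics, and initialization.

The alternative mating strategy (AMS) is controlled by one autosomal locus
with two alleles.  An individual's *allelic state* is its count of the
recessive "sneaker" allele (0, 1 or 2).  Recessive homozygote males
(allelic state 2) develop as sneakers; heterozygous and dominant-homozygote
males develop as territorial males.  Females carry and transmit the alleles
but express no mating-strategy phenotype.

For speed the population is stored column-wise in numpy arrays
(:class:`Population`); :class:`Individual` is a per-row convenience view
used in tests and serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .riverscape import Riverscape

__all__ = [
    "FEMALE",
    "MALE",
    "SNEAKER",
    "TERRITORIAL",
    "NOT_APPLICABLE",
    "Individual",
    "Population",
    "ams_phenotype",
    "initialize_population",
    "allele_summary",
]

FEMALE = 0
MALE = 1

SNEAKER = "sneaker"
TERRITORIAL = "territorial"
NOT_APPLICABLE = "not_applicable"

_SEX_LABEL = {FEMALE: "female", MALE: "male"}
_SEX_CODE = {"female": FEMALE, "male": MALE}


def ams_phenotype(genotype: int, sex) -> str:
    """Map (genotype, sex) to the expressed mating-strategy phenotype.

    Males with two recessive alleles are sneakers; all other males are
    territorial.  Females express no AMS phenotype regardless of genotype.
    """
    if genotype not in (0, 1, 2):
        raise ValueError(f"genotype must be 0, 1 or 2, got {genotype!r}")
    sex_code = _SEX_CODE.get(sex, sex)
    if sex_code not in (FEMALE, MALE):
        raise ValueError(f"unknown sex {sex!r}")
    if sex_code == FEMALE:
        return NOT_APPLICABLE
    return SNEAKER if genotype == 2 else TERRITORIAL


@dataclass
class Individual:
    id: int
    sex: str
    age: int
    length: float
    genotype: int
    mature: bool
    natal_patch: str
    current_patch: str

    @property
    def phenotype(self) -> str:
        return ams_phenotype(self.genotype, self.sex)


class Population:
    """Columnar store of living individuals.

    Attributes are parallel numpy arrays; dead individuals are removed by
    boolean ``keep`` compaction rather than flagged.  Patch membership is by
    integer index into the riverscape's patch list.
    """

    __slots__ = ("id", "sex", "age", "length", "genotype", "mature", "natal", "current")

    def __init__(self, id, sex, age, length, genotype, mature, natal, current):
        self.id = np.asarray(id, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=np.int8)
        self.age = np.asarray(age, dtype=np.int32)
        self.length = np.asarray(length, dtype=np.float64)
        self.genotype = np.asarray(genotype, dtype=np.int8)
        self.mature = np.asarray(mature, dtype=bool)
        self.natal = np.asarray(natal, dtype=np.int32)
        self.current = np.asarray(current, dtype=np.int32)

    @classmethod
    def empty(cls) -> "Population":
        z = np.empty(0)
        return cls(z, z, z, z, z, z, z, z)

    def __len__(self) -> int:
        return self.id.size

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    @property
    def is_sneaker_male(self) -> np.ndarray:
        """Sneaker phenotype mask: recessive-homozygote males."""
        return (self.sex == MALE) & (self.genotype == 2)

    @property
    def is_territorial_male(self) -> np.ndarray:
        return (self.sex == MALE) & (self.genotype != 2)

    def keep(self, mask: np.ndarray) -> None:
        """Drop individuals where ``mask`` is False (in place)."""
        for name in self.__slots__:
            setattr(self, name, getattr(self, name)[mask])

    def append(self, other: "Population") -> None:
        for name in self.__slots__:
            setattr(
                self, name, np.concatenate([getattr(self, name), getattr(other, name)])
            )

    def individuals(self, riverscape: Riverscape) -> list[Individual]:
        ids = riverscape.patch_ids
        return [
            Individual(
                id=int(self.id[i]),
                sex=_SEX_LABEL[int(self.sex[i])],
                age=int(self.age[i]),
                length=float(self.length[i]),
                genotype=int(self.genotype[i]),
                mature=bool(self.mature[i]),
                natal_patch=ids[self.natal[i]],
                current_patch=ids[self.current[i]],
            )
            for i in range(len(self))
        ]

    def to_frame(self, riverscape: Riverscape) -> pd.DataFrame:
        ids = np.asarray(riverscape.patch_ids)
        return pd.DataFrame(
            {
                "id": self.id,
                "sex": np.where(self.sex == MALE, "male", "female"),
                "age": self.age,
                "length_mm": self.length,
                "genotype": self.genotype,
                "mature": self.mature,
                "natal_patch": ids[self.natal],
                "current_patch": ids[self.current],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, riverscape: Riverscape) -> "Population":
        idx = {pid: i for i, pid in enumerate(riverscape.patch_ids)}
        return cls(
            id=frame["id"].to_numpy(),
            sex=frame["sex"].map(_SEX_CODE).to_numpy(),
            age=frame["age"].to_numpy(),
            length=frame["length_mm"].to_numpy(),
            genotype=frame["genotype"].to_numpy(),
            mature=frame["mature"].to_numpy(),
            natal=frame["natal_patch"].map(idx).to_numpy(),
            current=frame["current_patch"].map(idx).to_numpy(),
        )


def _genotype_probs(mode: str, sneaker_male_proportion: float) -> np.ndarray:
    """Initial genotype distribution {0,1,2} under the named rule."""
    p = sneaker_male_proportion
    if mode == "hardy_weinberg":
        # recessive allele frequency implied by the target male sneaker share
        q = np.sqrt(p)
        return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    if mode == "equal_thirds":
        return np.array([1 / 3, 1 / 3, 1 / 3])
    if mode == "phenotype_split":
        # exactly the requested share of genotype-2; the rest split over 0/1
        return np.array([(1 - p) / 2, (1 - p) / 2, p])
    raise ValueError(f"unknown genotype_mode {mode!r}")


def initialize_population(
    riverscape: Riverscape,
    total_n: int,
    sneaker_male_proportion: float,
    seed: int | np.random.Generator = 0,
    genotype_mode: str = "hardy_weinberg",
    life_history=None,
) -> Population:
    """Build the starting population on the natal patches.

    Individuals are allocated across natal patches proportionally to
    carrying capacity, with a 1:1 expected sex ratio.  Genotypes are drawn
    per ``genotype_mode``:

    - ``"hardy_weinberg"`` (default): every individual (both sexes) draws a
      genotype from Hardy–Weinberg proportions at the allele frequency
      ``sqrt(sneaker_male_proportion)``, so the expected share of males with
      the sneaker phenotype equals ``sneaker_male_proportion`` and the
      initial gene pool is internally consistent.
    - ``"equal_thirds"``: genotypes 0/1/2 equiprobable (mean allelic
      state 1.0); used by the null/baseline scenario.
    - ``"phenotype_split"``: genotype 2 with probability
      ``sneaker_male_proportion``, remainder split evenly over 0 and 1.

    Ages are drawn from the stable age distribution implied by the survival
    schedule of ``life_history`` (uniform over 1..5 when none is given) and
    lengths follow the growth curve at age; maturity is drawn from the
    size-at-maturity curve.
    """
    if not 0 <= sneaker_male_proportion <= 1:
        raise ValueError("sneaker_male_proportion must be in [0, 1]")
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    rng = np.random.default_rng(seed)

    natal = riverscape.natal_indices
    ks = riverscape.carrying_capacities[natal].astype(float)
    share = ks / ks.sum()
    counts = np.floor(share * total_n).astype(int)
    # distribute the rounding remainder to the largest fractional shares
    frac = share * total_n - counts
    for i in np.argsort(frac)[::-1][: total_n - counts.sum()]:
        counts[i] += 1
    patch_of = np.repeat(natal, counts).astype(np.int32)
    n = patch_of.size

    sex = rng.integers(0, 2, size=n).astype(np.int8)
    genotype = rng.choice(
        np.array([0, 1, 2], dtype=np.int8),
        size=n,
        p=_genotype_probs(genotype_mode, sneaker_male_proportion),
    )

    if life_history is not None:
        ages = life_history.stable_age_sample(rng, n)
        length = life_history.length_at_age(ages)
        p_mat = life_history.maturation_probability_for(length, sex, genotype)
        mature = rng.random(n) < p_mat
    else:
        ages = rng.integers(1, 6, size=n)
        length = 100.0 + 80.0 * ages
        mature = ages >= 4
    mature &= ages >= 1

    return Population(
        id=np.arange(n, dtype=np.int64),
        sex=sex,
        age=ages,
        length=length,
        genotype=genotype,
        mature=mature,
        natal=patch_of,
        current=patch_of.copy(),
    )


def allele_summary(pop: Population, riverscape: Riverscape | None = None) -> dict:
    """Global (and per-patch) recessive-allele summaries.

    Returns a dict with ``n``, ``mean_allelic_state`` (mean recessive-copy
    count over living individuals, in [0, 2]), ``allele_frequency``
    (= mean/2) and, when a riverscape is given, a per-patch DataFrame.
    An empty population is flagged with ``empty=True`` and NaN statistics.
    """
    if len(pop) == 0:
        return {
            "empty": True,
            "n": 0,
            "mean_allelic_state": float("nan"),
            "allele_frequency": float("nan"),
        }
    mean_state = float(pop.genotype.mean())
    out = {
        "empty": False,
        "n": len(pop),
        "mean_allelic_state": mean_state,
        "allele_frequency": mean_state / 2.0,
    }
    if riverscape is not None:
        n_patch = np.bincount(pop.current, minlength=riverscape.n_patches)
        sum_state = np.bincount(
            pop.current, weights=pop.genotype.astype(float), minlength=riverscape.n_patches
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_per = np.where(n_patch > 0, sum_state / np.maximum(n_patch, 1), np.nan)
        out["per_patch"] = pd.DataFrame(
            {
                "patch_id": riverscape.patch_ids,
                "n": n_patch,
                "mean_allelic_state": mean_per,
                "allele_frequency": mean_per / 2.0,
            }
        )
    return out
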
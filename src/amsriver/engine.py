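"""Simulation engine: annual cycle, burn-in, replicates, fixation detection.

One simulated year runs, in order:

1. spawning return — mature fish return to their natal patch (straying at a
   low probability, kernel-weighted), paying one migration-survival leg;
2. mating and spawning within each natal patch;
3. additive sneaker-male mortality in natal patches (all age classes);
4. age-class mortality, then density-dependent truncation of each patch to
   its carrying capacity (young-of-year removed first, then uniformly);
5. von Bertalanffy growth and the size-based maturation draw;
6. outbound migration of mature fish to overwintering patches
   (inverse-linear distance weights), paying one migration-survival leg;
7. age increment and maximum-age cull.

The run starts with a demographic/genetic burn-in; the reporting clock
starts at year 0 at the end of burn-in (burn-in years carry negative
labels).  Sneaker *fixation* is judged on alleles, not phenotypes: the
first post-burn-in year with zero copies of the dominant (territorial-side)
allele population-wide, so latent heterozygote carriers block fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .life_history import (
    LifeHistoryParams,
    class_survival_mask,
    density_dependent_cull,
    grow,
    sneaker_survival_mask,
)
from .mating import MatingConfig, breed_patch
from .movement import MovementConfig, overwinter_destinations, spawning_return_all
from .population import Population, initialize_population
from .riverscape import Riverscape

__all__ = [
    "ScenarioParameters",
    "SimulationTimeSeries",
    "run_simulation",
    "run_replicates",
    "detect_fixation",
]


@dataclass
class ScenarioParameters:
    """One simulation scenario: the four varied parameters plus fixed configs.

    The four sensitivity-varied parameters are ``assortative_c``,
    ``sneaker_maturation_slope``, ``sneaker_male_proportion`` and
    ``sneaker_additive_mortality``.  ``years`` counts post-burn-in years;
    the reporting clock starts at 0 when burn-in ends.
    """

    assortative_c: float = 1.0
    sneaker_maturation_slope: float = 0.01704
    sneaker_male_proportion: float = 0.5
    sneaker_additive_mortality: float = 0.0
    life_history: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    movement: MovementConfig = field(default_factory=MovementConfig)
    mates_per_female: int = 2
    preference_model: str = "dominant_preference"
    genotype_mode: str = "hardy_weinberg"
    initial_n: int | None = None  # default: total natal carrying capacity
    seed: int = 0
    years: int = 300
    burn_in: int = 50
    snapshot_interval: int = 10

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "ScenarioParameters":
        """The baseline scenario: no trait differences between the AMSs.

        Random mating (c = 1), identical maturation curves, no additive
        sneaker mortality, and genotypes initialized in equal thirds so the
        initial mean allelic state is exactly 1.0 — under these settings the
        sneaker allele is selectively neutral and its trajectory is pure
        drift around 1.
        """
        return cls(
            assortative_c=1.0,
            sneaker_maturation_slope=None,  # resolved to the territorial slope
            sneaker_male_proportion=0.5,
            sneaker_additive_mortality=0.0,
            genotype_mode="equal_thirds",
            seed=seed,
            **kwargs,
        )

    def resolved_life_history(self) -> LifeHistoryParams:
        slope = self.sneaker_maturation_slope
        if slope is None:
            slope = self.life_history.maturation_B_territorial_and_female
        return replace(
            self.life_history,
            maturation_B_sneaker=slope,
            sneaker_additive_mortality=self.sneaker_additive_mortality,
        )

    def mating_config(self) -> MatingConfig:
        return MatingConfig(
            assortative_c=self.assortative_c,
            mates_per_female=self.mates_per_female,
            preference_model=self.preference_model,
        )


PATCH_COLUMNS = [
    "year", "patch_id", "n_g0", "n_g1", "n_g2", "n_female", "n_male",
    "n_mature_sneaker", "n_mature_territorial",
]


@dataclass
class SimulationTimeSeries:
    """Per-year global summaries plus per-patch snapshot counts.

    ``global_`` has one row per simulated year (burn-in years labelled
    negatively), with genotype/sex counts, mean allelic state, the dominant
    (territorial-side) allele count, and mature male counts by phenotype.
    ``per_patch`` holds the same counts per patch at snapshot years.
    """

    global_: pd.DataFrame
    per_patch: pd.DataFrame
    extinct: bool
    burn_in: int
    years: int
    seed: int

    def final_year(self) -> int:
        return int(self.global_["year"].max())

    def write(self, global_path, per_patch_path=None) -> None:
        self.global_.to_csv(global_path, index=False)
        if per_patch_path is not None:
            self.per_patch.to_csv(per_patch_path, index=False)


def _global_row(year: int, pop: Population) -> dict:
    g = np.bincount(pop.genotype, minlength=3) if len(pop) else np.zeros(3, int)
    male = pop.is_male
    mature_male = male & pop.mature
    sneaker = pop.genotype == 2
    n = len(pop)
    return {
        "year": year,
        "n": n,
        "n_g0": int(g[0]),
        "n_g1": int(g[1]),
        "n_g2": int(g[2]),
        "n_female": int((~male).sum()),
        "n_male": int(male.sum()),
        "n_male_territorial": int((male & ~sneaker).sum()),
        "n_male_sneaker": int((male & sneaker).sum()),
        "n_mature_territorial": int((mature_male & ~sneaker).sum()),
        "n_mature_sneaker": int((mature_male & sneaker).sum()),
        "mean_allelic_state": float(pop.genotype.mean()) if n else float("nan"),
        "dominant_allele_count": int(2 * g[0] + g[1]),
    }


def _patch_rows(year: int, pop: Population, riverscape: Riverscape) -> list[dict]:
    rows = []
    n_patches = riverscape.n_patches
    cur = pop.current
    male = pop.is_male
    mature_male = male & pop.mature
    sneaker = pop.genotype == 2
    counts = {
        "n_g0": np.bincount(cur[pop.genotype == 0], minlength=n_patches),
        "n_g1": np.bincount(cur[pop.genotype == 1], minlength=n_patches),
        "n_g2": np.bincount(cur[pop.genotype == 2], minlength=n_patches),
        "n_female": np.bincount(cur[~male], minlength=n_patches),
        "n_male": np.bincount(cur[male], minlength=n_patches),
        "n_mature_sneaker": np.bincount(cur[mature_male & sneaker], minlength=n_patches),
        "n_mature_territorial": np.bincount(cur[mature_male & ~sneaker], minlength=n_patches),
    }
    for i, pid in enumerate(riverscape.patch_ids):
        rows.append({"year": year, "patch_id": pid,
                     **{k: int(v[i]) for k, v in counts.items()}})
    return rows


def _annual_cycle(pop: Population, riverscape: Riverscape, params: LifeHistoryParams,
                  mating: MatingConfig, movement: MovementConfig,
                  rng: np.random.Generator, id_counter: int) -> int:
    """Advance the population one year in place; returns the new id counter."""
    ks = riverscape.carrying_capacities

    # 1. spawning return with straying; one migration-survival leg for the mature
    mature = pop.mature
    if mature.any():
        dest = spawning_return_all(pop.natal[mature], riverscape, movement, rng)
        cur = pop.current.copy()
        cur[np.flatnonzero(mature)] = dest
        pop.current = cur
        if movement.migration_survival < 1:
            survive = np.ones(len(pop), dtype=bool)
            survive[mature] = rng.random(int(mature.sum())) < movement.migration_survival
            pop.keep(survive)

    # 2. breeding within each natal patch
    offspring_sex, offspring_geno, offspring_patch = [], [], []
    breeders = pop.mature
    if breeders.any():
        for patch in np.unique(pop.current[breeders]):
            sel = (pop.current == patch) & breeders
            fem = sel & ~pop.is_male
            mal = sel & pop.is_male
            if not fem.any() or not mal.any():
                continue
            sexes, genos = breed_patch(
                pop.length[fem], pop.genotype[fem], pop.genotype[mal],
                mating, params, rng, egg_survival=params.egg_survival,
            )
            if sexes.size:
                offspring_sex.append(sexes)
                offspring_geno.append(genos)
                offspring_patch.append(np.full(sexes.size, patch, dtype=np.int32))
    if offspring_sex:
        sexes = np.concatenate(offspring_sex)
        genos = np.concatenate(offspring_geno)
        patches = np.concatenate(offspring_patch)
        n_off = sexes.size
        recruits = Population(
            id=np.arange(id_counter, id_counter + n_off, dtype=np.int64),
            sex=sexes,
            age=np.zeros(n_off, dtype=np.int32),
            length=np.full(n_off, params.length_age0),
            genotype=genos,
            mature=np.zeros(n_off, dtype=bool),
            natal=patches,
            current=patches,
        )
        id_counter += n_off
        pop.append(recruits)

    # 3. additive sneaker-male mortality: the returning mature spawners pay it
    pop.keep(sneaker_survival_mask(pop, params, rng, mature_only=True))

    # 4. age-class mortality, then density truncation per occupied patch
    pop.keep(class_survival_mask(pop, params, rng))
    if len(pop):
        occupancy = np.bincount(pop.current, minlength=riverscape.n_patches)
        over = np.flatnonzero(occupancy > ks)
        if over.size:
            keep = np.ones(len(pop), dtype=bool)
            for patch in over:
                idx = np.flatnonzero(pop.current == patch)
                mask = density_dependent_cull(
                    idx.size, int(ks[patch]), rng, age=pop.age[idx], yoy_first=True
                )
                keep[idx[~mask]] = False
            pop.keep(keep)

    # 5. growth then the maturation draw for the still-immature
    pop.length = grow(pop.length, params)
    immature = ~pop.mature
    if immature.any():
        p = params.maturation_probability_for(
            pop.length[immature], pop.sex[immature], pop.genotype[immature]
        )
        newly = rng.random(int(immature.sum())) < p
        pop.mature[np.flatnonzero(immature)[newly]] = True

    # 6. outbound migration of the mature; second migration-survival leg
    mature = pop.mature
    if mature.any():
        dest = overwinter_destinations(pop.current[mature], riverscape, rng)
        pop.current[np.flatnonzero(mature)] = dest
        if movement.migration_survival < 1:
            survive = np.ones(len(pop), dtype=bool)
            survive[mature] = rng.random(int(mature.sum())) < movement.migration_survival
            pop.keep(survive)

    # 7. ageing and maximum-age cull
    pop.age += 1
    pop.keep(pop.age <= params.max_age)
    return id_counter


def run_simulation(riverscape: Riverscape, scenario: ScenarioParameters) -> SimulationTimeSeries:
    """Run burn-in plus the reporting period for one scenario.

    Fully reproducible from ``scenario.seed``.  Population extinction
    truncates the series and sets ``extinct=True`` rather than raising.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    params = scenario.resolved_life_history()
    mating = scenario.mating_config()
    movement = scenario.movement

    total_n = scenario.initial_n
    if total_n is None:
        total_n = int(riverscape.carrying_capacities[riverscape.natal_indices].sum())
    pop = initialize_population(
        riverscape,
        total_n,
        scenario.sneaker_male_proportion,
        seed=rng,
        genotype_mode=scenario.genotype_mode,
        life_history=params,
    )
    id_counter = len(pop)

    glob, patch_rows = [], []
    extinct = False
    year0 = -scenario.burn_in
    glob.append(_global_row(year0, pop))
    patch_rows.extend(_patch_rows(year0, pop, riverscape))

    for step in range(scenario.burn_in + scenario.years):
        year = year0 + step + 1
        id_counter = _annual_cycle(pop, riverscape, params, mating, movement, rng, id_counter)
        glob.append(_global_row(year, pop))
        if year % scenario.snapshot_interval == 0 or year == scenario.years:
            patch_rows.extend(_patch_rows(year, pop, riverscape))
        if len(pop) == 0:
            extinct = True
            break

    return SimulationTimeSeries(
        global_=pd.DataFrame(glob),
        per_patch=pd.DataFrame(patch_rows),
        extinct=extinct,
        burn_in=scenario.burn_in,
        years=scenario.years,
        seed=scenario.seed,
    )


def detect_fixation(ts: SimulationTimeSeries, horizon: int | None = None):
    """Time to sneaker fixation and the final territorial-male count.

    Returns ``(T_fix, N_ter)``.  ``T_fix`` is the first post-burn-in year
    (clock starting at 0 when burn-in ends) at which the dominant allele
    count is zero population-wide, or ``None`` if that never happens within
    the horizon.  ``N_ter`` is the number of territorial-phenotype males in
    the final reported year (0 whenever the sneaker allele has fixed).
    """
    g = ts.global_
    post = g[g["year"] >= 0]
    if horizon is not None:
        post = post[post["year"] <= horizon]
    alive = post[post["n"] > 0]
    fixed = alive[alive["dominant_allele_count"] == 0]
    t_fix = int(fixed["year"].iloc[0]) if len(fixed) else None
    n_ter = int(post["n_male_territorial"].iloc[-1]) if len(post) else 0
    if t_fix is not None:
        n_ter = 0
    return t_fix, n_ter


def run_replicates(riverscape: Riverscape, scenario: ScenarioParameters,
                   n_iterations: int) -> list[SimulationTimeSeries]:
    """Independent replicate runs with seeds derived from the scenario seed."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    # replicate 0 is the scenario itself; further replicates use spawned seeds
    seeds = [scenario.seed] + [
        int(child.generate_state(1)[0] % (2**31))
        for child in np.random.SeedSequence(scenario.seed).spawn(n_iterations - 1)
    ]
    return [run_simulation(riverscape, replace(scenario, seed=s)) for s in seeds]
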
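# Methods

`amsriver` is an individual-based, spatially explicit simulator of a
salmonid metapopulation carrying two genetically fixed alternative mating
strategies (AMS) — sneaker and territorial males — together with the
analysis pipeline used to ask *which mechanisms let sneakers persist or take
over*: Latin-hypercube parameter sweeps, a bounded relative-sneaker-success
metric, and a boosted-regression-tree (BRT) surrogate of the sweep.

## The model

**Genetics.** One autosomal locus, two alleles. An individual's allelic
state is its count of the recessive sneaker allele (0, 1, 2). Males with
two copies develop as sneakers; all other males are territorial; females
express no AMS phenotype but carry and transmit the alleles. Inheritance is
fair Mendelian; there is no mutation. *Sneaker fixation* is judged on
alleles, not phenotypes: the first post-burn-in year with zero copies of
the dominant allele population-wide, so heterozygous carriers (who look
territorial) block fixation.

**Space.** Habitat patches on a branching river network: natal
(headwater spawning/rearing) patches and migratory (mainstem overwintering)
patches, with along-network pairwise distances in km. Patch carrying
capacity is `floor(area × density)` at a default density of one individual
per 100 m². The synthetic generator draws a random tree with migratory
patches on the mainstem and natal patches at the tips, log-uniform areas,
and uniform edge lengths (1–8 km by default); it exists because the
package must run without the original GIS inputs, and patch counts and
capacity distributions are exposed as parameters rather than guessed.

**Annual cycle** (each simulated year, in order):

1. *Spawning return.* Mature fish return to their natal patch; with a small
   stray probability (default 0.02) they instead spawn in another natal
   patch, chosen with probability proportional to a leptokurtic dispersal
   kernel evaluated at network distance (strays never "stray" home; with a
   single natal patch they stay). Each migration leg applies a
   density-independent migration survival (default 0.97) once.
2. *Mating.* Within each natal patch, every mature female draws
   `mates_per_female` (default 2) sires with replacement. Under the
   dominant-preference model each territorial male has unnormalized weight
   `c` (the assortative mating factor) and each sneaker male weight 1, so
   with equal phenotype frequencies and c = 2 a territorial male is twice
   as likely to sire as a sneaker; c = 1 is random mating. A literal
   genotype-matching variant (weight c when female and male genotypes are
   identical) is selectable via `MatingConfig.preference_model`. The
   female's total clutch is one Poisson draw of her length-based mean
   fecundity, `eggs = 9.5576·exp(0.0181·L)`, split equally among her sires
   (remainder to random sires). Offspring get fair-coin sex, age 0, and
   the natal patch of their mother.
3. *Additive sneaker mortality.* Returning mature sneaker males survive
   with probability `1 − m_s`, the scenario-varied additive mortality,
   applied at the same rate across all age classes. It lands after mating,
   as a cost of the spawning return, so even extreme values leave each
   mature sneaker at least one breeding season; the standalone mortality
   operator can also apply it to all sneaker males irrespective of
   maturity.
4. *Survival and density dependence.* Every individual survives an
   independent Bernoulli draw from the age-class mortality schedule; then
   each patch above carrying capacity is truncated to K, removing
   young-of-year first (recruitment is capped by the space older fish
   leave) and then uniformly. The cull is phenotype-blind by construction.
5. *Growth and maturation.* Lengths follow von Bertalanffy growth,
   `ΔL = (L∞ − L)(1 − e^(−k))`. Immature fish then mature with logistic
   probability `expit(A + B·L)`; the intercept A is shared, and the slope
   B is steeper for sneaker males (scenario-varied), which is what makes
   them mature at smaller size and younger age.
6. *Outbound migration.* Mature fish move to an overwintering patch drawn
   with inverse-linear distance weights, `max(0, 1 − d/d_max)` normalized
   over migratory patches (uniform fallback if all weights vanish), and
   pay the second migration-survival leg. Immature fish rear in their
   natal patch.
7. *Ageing.* Ages increment; fish beyond the maximum age die.

Runs start from a Hardy–Weinberg population allocated across natal patches
proportionally to capacity (1:1 sex ratio; ages from the survivorship-
weighted stable age distribution; lengths on the growth curve), run a
demographic/genetic burn-in (default 50 y) and then the reporting period
(default 300 y); the fixation clock starts at 0 when burn-in ends.
Extinction truncates the series with a flag rather than raising.

## Parameters

Scenario-varied (the sweep's four axes, with their study ranges):

| parameter | range | meaning |
|---|---|---|
| `assortative_c` | 1–3 | female preference for territorial males; 1 = random mating |
| `sneaker_maturation_slope` | 0.01704–0.05112 /mm | sneaker logistic slope; larger ⇒ earlier maturity |
| `sneaker_male_proportion` | 0.02–0.50 | share of males with the sneaker phenotype at initialization |
| `sneaker_additive_mortality` | 0.0375–0.60 /yr | extra mortality of returning mature sneaker males |

Fixed life-history defaults (all overridable via `LifeHistoryParams` /
`MovementConfig`): fecundity intercept 9.5576 eggs and slope 0.0181 /mm;
dispersal-kernel component means 1.79 km and 3.49 km (exponential mixture,
weight 0.5 on the short component — the family is our choice; only the two
component means are given in the source literature); density 0.01 /m². The
remaining constants are this package's own parameterization, chosen to
express the system's central trade-off — early sneaker maturation against
female preference and reproductive-lifespan costs — for a large migratory
char: L∞ = 800 mm, k = 0.18 /yr, fry length 30 mm; maturation intercept
A = −10 with territorial/female slope 0.01704 /mm, putting the
territorial/female length at 50% maturity near 587 mm (typical maturation
age ≈ 6–7 y, at the upper end of the species' 4–7 y generation time, while
the sneaker slope range spans L50 ≈ 196–587 mm, i.e. maturation from ≈ age
2 up to the territorial schedule); annual age-class mortality
(0.60, 0.40, 0.30, 0.30, 0.35, 0.35, 0.40, 0.40, 0.45, 0.50, 0.60, 0.75)
from age 0 with maximum age 12; egg→age-0 survival 2×10⁻⁴ (the fecundity
curve yields 10⁵–5×10⁵ eggs for large females, so this composite
egg-to-recruit survival produces realistic recruitment; Poisson clutches
thinned by it remain Poisson, which is how the engine avoids materializing
million-egg arrays); migration survival 0.97 per leg. Under these defaults
the sweep reproduces the qualitative behaviour reported for the full-scale
system: sneakers fix or reach allele majority in most scenarios, and
success falls with `c` and mortality and rises with initial proportion.

## The null (baseline) scenario

`ScenarioParameters.null()` removes every trait difference: identical
maturation curves, no additive mortality, c = 1, and genotypes initialized
in equal thirds across {0, 1, 2} so the initial mean allelic state is
exactly 1.0. The sneaker allele is then selectively neutral and its
trajectory is a martingale: replicate means stay near 1.0, with pure drift
around it. This is the strongest internal check of the engine — any
asymmetry in mating, mortality, movement, or culling would show up as a
systematic trend. (Initializing at 50% recessive homozygotes instead, an
alternative reading of "equal proportions of the two genotype classes",
would put the neutral expectation at 1.25; both readings, and an exact
phenotype split, are available via `genotype_mode`.)

## Sensitivity sweep and the success metric

`lhs_scenarios(n)` draws a Latin hypercube over the four ranges
(`scipy.stats.qmc`): each marginal places exactly one sample per
equal-width stratum. Each scenario is simulated once (replicates
configurable), and two outcomes recorded: `T_fix`, the year of sneaker
fixation (or none), and `N_ter`, territorial males remaining in the final
year (0 whenever fixed). With batch extrema `T_min/T_max` and
`N_min/N_max` (non-fixing scenarios take `T_fix = T_max`, the horizon),

    success = ½ [ (1 − (T_fix − T_min)/(T_max − T_min))
                + (1 − (N_ter − N_min)/(N_max − N_min)) ]

bounded in [0, 1], decreasing in both arguments: 1 means fastest fixation
and no territorial males; 0 means never fixed with the most territorial
males. A degenerate denominator (all scenarios identical in that
coordinate) sets that component to 1, since every scenario then sits at
both bounds at once. The printed rendering of this metric in the source
literature is typographically ambiguous; the mean-of-two-normalized-
components form used here is the unique reading consistent with its stated
bounds and directions.

## BRT surrogate

The sweep's parameter→success relationship is summarized with gradient-
boosted regression trees (`sklearn.ensemble.GradientBoostingRegressor`,
squared-error loss): a 70/30 train/test split; a 36-cell grid (bag
fraction 0.5/0.6/0.7 × tree complexity 2/3/4 × learning rate
0.01/0.005/0.001/0.0005), each cell scored by K-fold cross-validated MAE
with the tree count chosen along the boosting path (up to `max_trees`,
default 800); the lowest-MAE cell is refit on the full training set. Tree
complexity follows the gbm convention (number of splits) and maps to
best-first trees with `max_leaf_nodes = complexity + 1`. Backward
elimination then drops the least-important predictor while CV MAE does not
worsen by more than one CV standard error (the tolerance is our choice).
Relative importances and partial-dependence curves (mean prediction over
the empirical distribution of the other predictors, on a 25-point grid)
are averaged over `n_bootstrap` (default 1000) refits on resampled
training rows, with min/max envelopes; the resampling unit — rows, with
refitting — is our choice. Validation reports the Spearman rank
correlation, its square (a rank-based R², reported separately from MAE to
avoid conflating the two), and the MAE on the held-out rows.

## Numerical and degenerate-input choices

- Logistic maturation uses `scipy.special.expit` (overflow-safe).
- Equal clutch splitting assigns the indivisible remainder to sires drawn
  uniformly without replacement.
- An empty mature-male (or mature-female) pool skips that patch's breeding
  for the year; an empty population flags extinction.
- Migration weights fall back to uniform when every candidate destination
  sits at the matrix-maximum distance.
- Replicate seeds, scenario seeds and pipeline stage seeds all descend
  from one root seed via `numpy.random.SeedSequence.spawn`; replicate 0
  reuses the scenario seed so a single replicate equals a direct run.
- Ties in backward elimination resolve toward dropping (the candidate is
  kept when CV MAE is within tolerance).

## What the synthetic riverscape does and does not emulate

It reproduces the structural features the model needs — a connected
branching network, headwater natal patches, mainstem overwintering
patches, area-proportional capacities, along-network distances — but not
the real system's patch count, capacity distribution, or geometry. Tests
passing on it show the mechanisms behave correctly (neutrality of the null
model, direction and rough strength of each selective mechanism), not that
any quantitative outcome (fixation counts, fixation times, importance
percentages) transfers to the real riverscape, where they depend on the
true spatial configuration and cluster-scale replication. For the same
reason the test suite and the examples run the protocol at reduced scale
(riverscapes of 10–20 patches and total natal capacity of 10³–10⁴,
horizons of 100 years, sweeps of ~24 scenarios, bootstrap counts of
25–100), sizes chosen so the full suite exercises every stage at
desk scale.

## Known limitations

- Single locus, two alleles; no mutation, no neutral markers.
- Deterministic growth (no individual variation hook beyond the curve).
- One scalar migration survival for all routes and distances.
- Sneaker phenotype affects only maturation, mating weight, and the
  additive mortality; there is no size divergence between strategies.
- No sub-annual events; the event order within a year is fixed (though
  centrally implemented in one function for sensitivity checks).
- No frequency-dependent selection: mate-choice weights depend on
  phenotype, not phenotype frequency, so observed coexistence or takeover
  emerges from the life-history trade-offs alone.
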
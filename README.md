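# amsriver

Individual-based riverscape simulation of genetically fixed **alternative
mating strategies** (AMS) in salmonids — sneaker versus territorial males —
with a global sensitivity pipeline: Latin-hypercube parameter sweeps, a
bounded relative-sneaker-success metric, and a boosted-regression-tree
surrogate that identifies which mechanisms drive sneaker persistence.

It is written for population ecologists and evolutionary biologists who
want to ask, for a spatially structured migratory fish population: *under
what combinations of female mating preference, maturation schedule,
initial frequency, and strategy-specific mortality do early-maturing
sneaker males coexist with, take over from, or lose to late-maturing
territorial males?*

## The model in brief

A single autosomal locus controls the strategy: males homozygous for the
recessive allele (allelic state 2) develop as sneakers, all other males as
territorials; females carry the alleles silently. Individuals live on a
branching river network of natal (headwater) and migratory (mainstem
overwintering) patches with carrying capacity K = ⌊area × density⌋ at one
individual per 100 m². Each simulated year: mature fish home to their
natal patch (straying via a leptokurtic two-exponential kernel, component
means 1.79 and 3.49 km); females mate polyandrously with per-male weights

  w(male) ∝ c^[male is territorial],  c ∈ [1, 3]  (c = 1 ⇒ random mating),

and clutch size Poisson with mean 9.5576·e^(0.0181·L) eggs for a female of
length L mm, split equally among sires with Mendelian inheritance;
returning mature sneaker males pay an additive mortality; age-class
mortality and phenotype-blind truncation to K follow; fish grow by von
Bertalanffy increments and mature with logistic probability
expit(A + B·L), the sneaker slope B being steeper (earlier maturity);
mature fish then migrate to overwintering patches by inverse-linear
distance weights.

Per-scenario outcomes — T_fix, the first post-burn-in year with no copies
of the dominant allele left, and N_ter, territorial males remaining in the
final year — combine across a scenario batch into

  success = ½[(1 − (T_fix − T_min)/(T_max − T_min)) + (1 − (N_ter − N_min)/(N_max − N_min))] ∈ [0, 1],

and a tuned gradient-boosted-tree surrogate (36-cell hyperparameter grid,
backward elimination, bootstrap importances and partial dependence)
summarizes how the four varied parameters drive it. See
`docs/methods.md` for the full model description, parameter defaults, and
design rationale.

## Worked example

```python
import amsriver as a

rs = a.generate_riverscape(n_natal=8, n_migratory=4,
                           area_range=(8_000, 30_000), seed=11)
print(f"{rs.n_patches} patches, natal capacity "
      f"{rs.carrying_capacities[rs.natal_indices].sum()}")

scenario = a.ScenarioParameters(
    assortative_c=2.0,                 # females favour territorial males 2:1
    sneaker_maturation_slope=0.047,    # sneakers mature around age 2
    sneaker_male_proportion=0.25,      # 25% of initial males are sneakers
    sneaker_additive_mortality=0.30,   # returning sneaker spawners pay 30%/yr
    years=100, burn_in=30, seed=17,
)
ts = a.run_simulation(rs, scenario)
t_fix, n_ter = a.detect_fixation(ts)
print(f"T_fix={t_fix}, N_ter={n_ter}, final mean allelic state="
      f"{ts.global_['mean_allelic_state'].iloc[-1]:.3f}")

table = a.lhs_scenarios(24, seed=42)
results = a.run_sensitivity(
    rs, table, base_scenario=a.ScenarioParameters(years=100, burn_in=30))
print(f"{int(results['fixed'].sum())}/24 scenarios fixed; "
      f"mean score {results['score'].mean():.3f}")

fit = a.SneakerSuccessBRT(
    results, config=a.SurrogateConfig(n_bootstrap=100, max_trees=400, seed=1)
).fit()
print(fit.summary())
```

prints

```
12 patches, natal capacity 1329
T_fix=None, N_ter=7, final mean allelic state=1.988
7/24 scenarios fixed; mean score 0.362
Sneaker-success BRT surrogate
==============================================
training rows: 17   test rows: 7
selected: bag=0.6, complexity=3, lr=0.01, trees=270
cross-validated MAE: 0.2004 (SE 0.0323)
retained predictors: sneaker_maturation_slope
----------------------------------------------
predictor                       importance %
sneaker_maturation_slope               100.0
----------------------------------------------
validation: Spearman rho=0.519 (rho^2=0.269), MAE=0.2418
```

Reading this: under strong female preference (c = 2) but early sneaker
maturation, the sneaker allele has almost swept after 100 years (mean
allelic state 1.99 of a possible 2) without quite fixing — 7 territorial
males persist as heterozygote descendants. Across the 24-scenario
hypercube, sneakers fix in 7 and reach allele majority in most others; on
a batch this small the surrogate keeps the dominant driver (the
maturation-slope axis separates fixing from non-fixing scenarios at this
horizon) and its held-out rank correlation is 0.52.

The same stages are available from the shell:

```bash
amsriver riverscape --n-natal 8 --n-migratory 4 --seed 11 --out-dir rs/
amsriver simulate   --scenario scenario.yaml --riverscape rs/ --out run/
amsriver sensitivity --n 100 --seed 42 --riverscape rs/ --out results.csv
amsriver analyze    --results results.csv --seed 1 --out report/
amsriver pipeline   --demo --seed 7 --out runs/     # end-to-end, desk scale
```

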
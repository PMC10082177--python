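import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amsriver import LifeHistoryParams, density_dependent_cull, fecundity_mean, grow, maturation_probability
from amsriver.life_history import (
    apply_class_mortality,
    class_survival_mask,
    sneaker_survival_mask,
)
from amsriver.population import Population


def _pop(n, genotype=0, sex=1, age=1, mature=True):
    return Population(
        id=np.arange(n),
        sex=np.full(n, sex),
        age=np.full(n, age),
        length=np.full(n, 300.0),
        genotype=np.full(n, genotype),
        mature=np.full(n, mature),
        natal=np.zeros(n),
        current=np.zeros(n),
    )


# -- maturation ---------------------------------------------------------------

def test_logistic_midpoint():
    # A + B*L = 0 puts the curve at exactly one half
    assert maturation_probability(200.0, A=-6.0, B=0.03) == pytest.approx(0.5)


def test_logistic_hand_value():
    # expit(-5 + 0.03*200) = e/(1+e), evaluated independently to 12 digits
    assert maturation_probability(200.0, A=-5.0, B=0.03) == pytest.approx(
        0.731058578630005, abs=1e-12
    )


def test_logistic_overflow_safe_and_monotone():
    p = maturation_probability(np.array([1.0, 1e6]), A=0.0, B=1.0)
    assert np.all((p > 0) & (p <= 1.0)) and p[1] == 1.0
    lengths = np.linspace(1, 1000, 200)
    p = maturation_probability(lengths, A=-9.0, B=0.02)
    assert np.all(np.diff(p) > 0)


@settings(derandomize=True, max_examples=60)
@given(
    st.floats(min_value=-20, max_value=20),
    st.floats(min_value=1e-4, max_value=0.2),
    st.floats(min_value=1, max_value=2000),
)
def test_logistic_symmetry_property(A, B, length):
    p = maturation_probability(length, A, B)
    q = maturation_probability(length, -A, -B)  # mirrored linear predictor
    assert 0.0 < p < 1.0 or p in (0.0, 1.0)
    assert p + q == pytest.approx(1.0, abs=1e-12)


def test_steeper_sneaker_slope_matures_earlier():
    lh = LifeHistoryParams(maturation_B_sneaker=0.05112)
    lengths = np.linspace(50, 600, 100)
    p_sneaker = lh.maturation_probability_for(lengths, np.ones(100), np.full(100, 2))
    p_terr = lh.maturation_probability_for(lengths, np.ones(100), np.zeros(100))
    root = -lh.maturation_A / lh.maturation_B_territorial_and_female
    assert np.all(p_sneaker[lengths < root] > p_terr[lengths < root])


# -- fecundity ----------------------------------------------------------------

def test_fecundity_at_zero_length():
    assert float(fecundity_mean(0.0)) == pytest.approx(9.5576, abs=0)


def test_fecundity_hand_value_at_400mm():
    # 9.5576 * exp(7.24), evaluated with 30-digit arithmetic
    assert float(fecundity_mean(400.0)) == pytest.approx(13324.1925359532, rel=1e-10)


def test_fecundity_strictly_increasing():
    assert float(fecundity_mean(300.0)) < float(fecundity_mean(301.0))


# -- growth -------------------------------------------------------------------

def test_growth_asymptote_and_hand_value():
    lh = LifeHistoryParams(vonB_Linf=800.0, vonB_k=0.2)
    assert float(grow(800.0, lh)) == 800.0
    # 600 * (1 - e^-0.2) = 108.7615...
    assert float(grow(200.0, lh)) - 200.0 == pytest.approx(108.761548153, rel=1e-9)


def test_growth_limit_large_k_jumps_to_linf():
    lh = LifeHistoryParams(vonB_Linf=800.0, vonB_k=50.0)
    assert float(grow(100.0, lh)) == pytest.approx(800.0, rel=1e-6)


def test_growth_never_shrinks_above_linf():
    lh = LifeHistoryParams(vonB_Linf=800.0)
    assert float(grow(900.0, lh)) == 900.0


# -- mortality ----------------------------------------------------------------

def test_class_mortality_binomial_scale(rng):
    lh = LifeHistoryParams(age_class_mortality=(0.5,) * 13)
    pop = _pop(10_000, age=3)
    survivors = int(class_survival_mask(pop, lh, rng).sum())
    assert abs(survivors - 5_000) < 4 * np.sqrt(10_000 * 0.25)


def test_zero_additive_mortality_is_null(rng):
    lh = LifeHistoryParams(sneaker_additive_mortality=0.0)
    pop = _pop(1_000, genotype=2)
    assert sneaker_survival_mask(pop, lh, rng).all()


def test_full_additive_mortality_removes_all_sneaker_males(rng):
    lh = LifeHistoryParams(
        sneaker_additive_mortality=1.0, age_class_mortality=(0.0,) * 13
    )
    pop = _pop(500, genotype=2)
    out = apply_class_mortality(pop, lh, rng)
    assert len(out) == 0
    # females of the same genotype are untouched by the additive draw
    females = _pop(500, genotype=2, sex=0)
    assert len(apply_class_mortality(females, lh, rng)) == 500


def test_mature_only_restriction(rng):
    lh = LifeHistoryParams(sneaker_additive_mortality=1.0)
    pop = _pop(100, genotype=2, mature=False)
    assert sneaker_survival_mask(pop, lh, rng, mature_only=True).all()
    assert not sneaker_survival_mask(pop, lh, rng, mature_only=False).any()


def test_density_cull_boundaries(rng):
    assert density_dependent_cull(50, 50, rng).all()  # n == K
    assert density_dependent_cull(0, 10, rng).size == 0
    mask = density_dependent_cull(100, 40, rng)
    assert mask.sum() == 40


def test_density_cull_yoy_first(rng):
    age = np.array([0] * 30 + [5] * 20)
    mask = density_dependent_cull(50, 25, rng, age=age, yoy_first=True)
    assert mask.sum() == 25
    assert mask[30:].all()  # older fish survive while young-of-year absorb the cut


def test_density_cull_genotype_unbiased():
    """Uniform without-replacement culling is hypergeometric: the expected
    sneaker fraction among survivors equals the pre-cull fraction."""
    n, k, n_sneaker = 400, 200, 160
    genotype = np.array([2] * n_sneaker + [0] * (n - n_sneaker))
    fractions = []
    for seed in range(200):
        mask = density_dependent_cull(n, k, np.random.default_rng(seed))
        fractions.append(genotype[mask].mean() / 2)
    # hypergeometric SE of the mean fraction over 200 replicates
    se = np.sqrt(0.4 * 0.6 / k * (n - k) / (n - 1) / 200)
    assert abs(np.mean(fractions) - 0.4) < 4 * se


def test_stable_age_distribution_matches_survivorship(rng):
    lh = LifeHistoryParams()
    ages = lh.stable_age_sample(rng, 50_000)
    l = lh.survivorship()[1:]
    expected = l / l.sum()
    observed = np.bincount(ages, minlength=lh.max_age + 1)[1:] / 50_000
    assert np.allclose(observed, expected, atol=0.01)


def test_parameter_validation():
    with pytest.raises(ValueError):
        LifeHistoryParams(sneaker_additive_mortality=1.5)
    with pytest.raises(ValueError):
        LifeHistoryParams(age_class_mortality=(0.2, -0.1))
    with pytest.raises(ValueError):
        LifeHistoryParams(maturation_B_sneaker=0.0)
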
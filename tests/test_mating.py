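from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multinomial

from amsriver import LifeHistoryParams, MatingConfig, mate_weights, select_mates, spawn
from amsriver.mating import _split_equally, breed_patch


def exact_multinomial_pvalue(counts, probs):
    """Exact multinomial goodness-of-fit: total probability of all outcomes
    no more likely than the observed one (k = 3 categories)."""
    n = int(np.sum(counts))
    dist = multinomial(n, probs)
    p_obs = dist.pmf(counts)
    total = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            p = dist.pmf([a, b, n - a - b])
            if p <= p_obs * (1 + 1e-9):
                total += p
    return total


def _female(length=400.0, genotype=1, mature=True):
    return SimpleNamespace(length=length, genotype=genotype, mature=mature)


# -- mate weights -------------------------------------------------------------

def test_ratio_is_exactly_c_with_mixed_pool():
    phen = np.array(["territorial"] * 5 + ["sneaker"] * 5)
    w = mate_weights(phen, c=2.0)
    assert w.sum() == pytest.approx(1.0)
    assert w[0] / w[5] == pytest.approx(2.0, abs=0)


def test_c_equal_one_is_random_mating():
    phen = np.array(["territorial"] * 3 + ["sneaker"] * 7)
    w = mate_weights(phen, c=1.0)
    assert np.allclose(w, 0.1)


def test_single_phenotype_pool_uniform_for_any_c():
    for c in (1.0, 2.0, 10.0):
        w = mate_weights(np.array(["territorial"] * 4), c=c)
        assert np.allclose(w, 0.25)


def test_empty_pool_signals_skipped_breeding():
    assert mate_weights(np.array([], dtype=str), c=2.0).size == 0
    cfg = MatingConfig(assortative_c=2.0)
    sires = select_mates(1, np.array([], dtype=int), cfg, np.random.default_rng(0))
    assert sires.size == 0


def test_weights_invariant_to_order():
    rng = np.random.default_rng(5)
    phen = np.array(["territorial"] * 6 + ["sneaker"] * 4)
    perm = rng.permutation(10)
    w = mate_weights(phen, 2.5)
    w_perm = mate_weights(phen[perm], 2.5)
    assert np.allclose(w[perm], w_perm)


@settings(derandomize=True, max_examples=60)
@given(
    st.integers(min_value=0, max_value=20),
    st.integers(min_value=0, max_value=20),
    st.floats(min_value=1.0, max_value=3.0),
)
def test_weight_properties(n_terr, n_sneak, c):
    if n_terr + n_sneak == 0:
        return
    phen = np.array(["territorial"] * n_terr + ["sneaker"] * n_sneak)
    w = mate_weights(phen, c)
    assert w.sum() == pytest.approx(1.0)
    if n_terr and n_sneak:
        assert w[0] / w[-1] == pytest.approx(c)


def test_weights_accept_genotypes_and_masks():
    w_geno = mate_weights(np.array([0, 1, 2]), 2.0)
    w_mask = mate_weights(np.array([True, True, False]), 2.0)
    assert np.allclose(w_geno, w_mask)
    assert w_geno[0] / w_geno[2] == pytest.approx(2.0)


# -- mate selection -----------------------------------------------------------

def test_large_c_territorial_sires_dominate():
    cfg = MatingConfig(assortative_c=3.0, mates_per_female=1)
    males = np.array([0] * 5 + [2] * 5)  # 5 territorial, 5 sneaker genotypes
    rng = np.random.default_rng(7)
    draws = np.concatenate(
        [select_mates(1, males, cfg, rng) for _ in range(4_000)]
    )
    frac_terr = (males[draws] != 2).mean()
    # closed form: 5*3 / (5*3 + 5*1) = 0.75
    assert abs(frac_terr - 0.75) < 4 * np.sqrt(0.75 * 0.25 / 4_000)


def test_genotype_delta_variant_prefers_matching_genotype():
    cfg = MatingConfig(assortative_c=3.0, mates_per_female=1,
                       preference_model="genotype_delta")
    males = np.array([0] * 5 + [2] * 5)
    rng = np.random.default_rng(8)
    draws = np.concatenate([select_mates(2, males, cfg, rng) for _ in range(4_000)])
    frac_match = (males[draws] == 2).mean()
    assert abs(frac_match - 0.75) < 4 * np.sqrt(0.75 * 0.25 / 4_000)


# -- spawning -----------------------------------------------------------------

def test_equal_clutch_split():
    rng = np.random.default_rng(0)
    assert _split_equally(10, 2, rng).tolist() == [5, 5]
    shares = _split_equally(11, 2, rng)
    assert sorted(shares.tolist()) == [5, 6]


def test_homozygous_cross_breeds_true(lh, rng):
    sexes, genos = spawn(_female(genotype=2), np.array([2, 2]), lh, rng)
    assert (genos == 2).all()


def test_immature_female_rejected(lh, rng):
    with pytest.raises(ValueError, match="immature"):
        spawn(_female(mature=False), np.array([1]), lh, rng)


def test_het_cross_mendelian_ratio(lh):
    """Het x het clutches segregate 1:2:1 (exact multinomial test)."""
    rng = np.random.default_rng(42)
    genos = []
    while len(genos) < 150:
        _, g = spawn(_female(length=200.0, genotype=1), np.array([1]), lh, rng,
                     egg_survival=0.5)
        genos.extend(g.tolist())
    genos = np.array(genos[:150])
    counts = np.bincount(genos, minlength=3)
    assert exact_multinomial_pvalue(counts, [0.25, 0.5, 0.25]) > 0.01


def test_poisson_thinning_matches_mean(lh):
    rng = np.random.default_rng(3)
    totals = [
        spawn(_female(length=300.0), np.array([0]), lh, rng, egg_survival=0.01)[0].size
        for _ in range(400)
    ]
    mean_expected = 9.5576 * np.exp(0.0181 * 300.0) * 0.01
    se = np.sqrt(mean_expected / 400)
    assert abs(np.mean(totals) - mean_expected) < 4 * se


def test_breed_patch_allele_conservation(lh):
    """Under random mating the offspring allele frequency expectation equals
    the mid-parent frequency."""
    rng = np.random.default_rng(9)
    cfg = MatingConfig(assortative_c=1.0, mates_per_female=2)
    mothers = np.full(60, 1)            # q = 0.5
    fathers = np.zeros(40, dtype=int)   # q = 0.0 -> midparent 0.25
    freqs = []
    for _ in range(60):
        _, genos = breed_patch(np.full(60, 300.0), mothers, fathers, cfg, lh, rng,
                               egg_survival=0.01)
        if genos.size:
            freqs.append(genos.mean() / 2)
    assert abs(np.mean(freqs) - 0.25) < 0.02


def test_breed_patch_empty_sides(lh, rng):
    cfg = MatingConfig()
    sexes, genos = breed_patch(np.array([300.0]), np.array([1]), np.array([]), cfg, lh, rng)
    assert sexes.size == 0 and genos.size == 0


def test_mating_config_validation():
    with pytest.raises(ValueError):
        MatingConfig(assortative_c=0.5)
    with pytest.raises(ValueError):
        MatingConfig(mates_per_female=0)
    with pytest.raises(ValueError):
        MatingConfig(preference_model="nope")
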
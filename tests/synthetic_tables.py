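"""Synthetic results tables with known structure, for surrogate tests."""

import numpy as np

from amsriver import TABLE1_RANGES, lhs_scenarios


def monotone_response_table(n=100, seed=0, noise_sd=0.03, with_noise_column=True):
    """An LHS design with a response whose directions mirror the simulated
    system: success falls with the assortative factor and with sneaker
    mortality, rises with the initial sneaker proportion, and ignores the
    maturation slope.  Optionally appends a pure-noise predictor."""
    table = lhs_scenarios(n, seed=seed).drop(columns=["seed"])
    rng = np.random.default_rng(seed + 1)

    def unit(name):
        lo, hi = TABLE1_RANGES[name]
        return (table[name] - lo) / (hi - lo)

    y = (
        0.75
        - 0.35 * unit("assortative_c")
        - 0.25 * unit("sneaker_additive_mortality")
        + 0.30 * unit("sneaker_male_proportion")
        + rng.normal(0.0, noise_sd, n)
    )
    table["score"] = np.clip(y, 0.0, 1.0)
    if with_noise_column:
        table["noise"] = rng.uniform(size=n)
    return table
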
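"""Latin-hypercube scenario sweeps and the relative sneaker success metric.

Scenarios vary four parameters over their study ranges (assortative mating
factor 1–3, sneaker maturation slope 0.01704–0.05112 per mm, initial
sneaker male proportion 2–50%, additive sneaker mortality 3.75–60%) using
Latin hypercube sampling: each parameter's range is divided into n
equal-width strata and each stratum receives exactly one sample.

Per-scenario outcomes (time to sneaker fixation ``T_fix`` and the final
territorial-male count ``N_ter``) are combined into a relative sneaker
success score bounded in [0, 1]: the mean of two min–max-normalized
components, one rewarding fast fixation and one rewarding few remaining
territorial males, with extrema taken across the scenario batch.
Scenarios that never fix take ``T_fix = T_max`` (the simulation horizon);
fixed scenarios have ``N_ter = 0``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .engine import ScenarioParameters, detect_fixation, run_simulation
from .riverscape import Riverscape

__all__ = [
    "TABLE1_RANGES",
    "MetricInputs",
    "lhs_scenarios",
    "sneaker_success",
    "run_sensitivity",
    "scenario_from_row",
]

#: the four varied parameters and their study ranges
TABLE1_RANGES: dict[str, tuple[float, float]] = {
    "assortative_c": (1.0, 3.0),
    "sneaker_maturation_slope": (0.01704, 0.05112),
    "sneaker_male_proportion": (0.02, 0.50),
    "sneaker_additive_mortality": (0.0375, 0.60),
}

PARAM_NAMES = list(TABLE1_RANGES)


def lhs_scenarios(n: int, ranges: dict[str, tuple[float, float]] | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Latin hypercube sample of ``n`` scenario parameter vectors.

    Every marginal places exactly one sample in each of ``n`` equal-width
    strata of its range.  Each row also carries a deterministic per-scenario
    simulation seed derived from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(TABLE1_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"malformed range for {name!r}: [{lo}, {hi}]")
    names = list(ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=np.random.default_rng(seed))
    unit = sampler.random(n)
    lows = np.array([ranges[k][0] for k in names])
    highs = np.array([ranges[k][1] for k in names])
    values = qmc.scale(unit, lows, highs)
    table = pd.DataFrame(values, columns=names)
    table.insert(0, "scenario_id", [f"S{i:03d}" for i in range(n)])
    children = np.random.SeedSequence(seed).spawn(n)
    table["seed"] = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return table


@dataclass
class MetricInputs:
    """Inputs to the relative sneaker success score for one scenario.

    ``t_fix`` is ``None`` when the scenario never fixed; batch extrema
    ``t_min``/``t_max`` and ``n_min``/``n_max`` come from the full sweep.
    """

    t_fix: int | None
    t_min: float
    t_max: float
    n_ter: int
    n_min: float
    n_max: float

    def __post_init__(self) -> None:
        if self.t_min > self.t_max or self.n_min > self.n_max:
            raise ValueError("batch extrema out of order")
        if self.n_ter < 0:
            raise ValueError("n_ter must be non-negative")


def _normalized_success(value: float, lo: float, hi: float) -> float:
    """1 at the favorable (low) bound, 0 at the unfavorable (high) bound.

    A degenerate range (hi == lo) means every scenario sits at both bounds
    at once; the component is then 1.
    """
    if hi == lo:
        return 1.0
    return float(np.clip(1.0 - (value - lo) / (hi - lo), 0.0, 1.0))


def sneaker_success(m: MetricInputs) -> float:
    """Relative sneaker success in [0, 1]; higher = sneakers prevail.

    Mean of the normalized time-to-fixation component (fast fixation → 1)
    and the normalized final territorial-male component (none left → 1).
    Non-fixing scenarios take ``t_fix = t_max``.
    """
    t_fix = m.t_max if m.t_fix is None else m.t_fix
    t_component = _normalized_success(t_fix, m.t_min, m.t_max)
    n_component = _normalized_success(m.n_ter, m.n_min, m.n_max)
    return 0.5 * (t_component + n_component)


def scenario_from_row(row, base: ScenarioParameters) -> ScenarioParameters:
    """Materialize one scenario-table row onto a template scenario."""
    return replace(
        base,
        assortative_c=float(row["assortative_c"]),
        sneaker_maturation_slope=float(row["sneaker_maturation_slope"]),
        sneaker_male_proportion=float(row["sneaker_male_proportion"]),
        sneaker_additive_mortality=float(row["sneaker_additive_mortality"]),
        seed=int(row["seed"]),
    )


def run_sensitivity(riverscape: Riverscape, scenario_table: pd.DataFrame,
                    base_scenario: ScenarioParameters | None = None,
                    progress_path: str | os.PathLike | None = None,
                    verbose: bool = False) -> pd.DataFrame:
    """Run every scenario and score the batch.

    Each row of ``scenario_table`` (from :func:`lhs_scenarios`) is simulated
    once on ``riverscape`` using ``base_scenario`` as the template for all
    fixed settings.  Fixation times and final territorial-male counts are
    collected, batch extrema computed, and the success score assigned.

    With ``progress_path`` set, per-scenario outcomes are appended to a CSV
    as they complete and already-present scenario ids are skipped on rerun,
    making long batches resumable.  Scores are (re)computed over the full
    batch at the end either way.
    """
    if len(scenario_table) < 2:
        raise ValueError("the success metric needs at least 2 scenarios for extrema")
    base = base_scenario if base_scenario is not None else ScenarioParameters()

    done: dict[str, dict] = {}
    if progress_path is not None and os.path.exists(progress_path):
        prev = pd.read_csv(progress_path)
        done = {r["scenario_id"]: dict(r) for _, r in prev.iterrows()}

    records = []
    for _, row in scenario_table.iterrows():
        sid = row["scenario_id"]
        if sid in done:
            records.append(done[sid])
            continue
        scenario = scenario_from_row(row, base)
        ts = run_simulation(riverscape, scenario)
        t_fix, n_ter = detect_fixation(ts)
        rec = {
            "scenario_id": sid,
            **{k: float(row[k]) for k in PARAM_NAMES},
            "seed": int(row["seed"]),
            "T_fix": np.nan if t_fix is None else t_fix,
            "fixed": t_fix is not None,
            "extinct": ts.extinct,
            "N_ter": n_ter,
            "final_allele_frequency": float(
                ts.global_["mean_allelic_state"].iloc[-1] / 2.0
            ),
        }
        records.append(rec)
        if verbose:
            print(f"{sid}: T_fix={rec['T_fix']} N_ter={n_ter}")
        if progress_path is not None:
            pd.DataFrame([rec]).to_csv(
                progress_path, mode="a", index=False,
                header=not os.path.exists(progress_path),
            )

    results = pd.DataFrame(records)
    if results["extinct"].all():
        raise RuntimeError("sensitivity batch failure: every scenario went extinct")

    horizon = base.years
    t_eff = results["T_fix"].fillna(horizon)
    t_min, t_max = float(t_eff.min()), float(t_eff.max())
    n_min, n_max = float(results["N_ter"].min()), float(results["N_ter"].max())
    results["score"] = [
        sneaker_success(
            MetricInputs(
                t_fix=None if pd.isna(r.T_fix) else int(r.T_fix),
                t_min=t_min, t_max=t_max,
                n_ter=int(r.N_ter), n_min=n_min, n_max=n_max,
            )
        )
        for r in results.itertuples()
    ]
    return results
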
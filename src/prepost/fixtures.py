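"""Deterministic datasets used by the test suite and documentation."""

from __future__ import annotations

import numpy as np

from .data import PrePostDataset
from .simulation import SimulationConfig, simulate_prepost

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("worked_example", "null_dgp_small", "slope_heterogeneity")


def make_fixture(name: str, seed: int = 0) -> PrePostDataset:
    """Build a named fixture dataset.

    * ``worked_example`` — the 4-subject dataset whose fits are all hand
      checkable (ignores ``seed``): treatment (0,0,1,1), pretest
      (8,12,10,14), posttest (10,12,13,15).
    * ``null_dgp_small`` — a 20-per-arm draw from the null simulation DGP
      (means 130, SD 15, correlation 0.9, zero effect).
    * ``slope_heterogeneity`` — 200 per arm with arm-specific pretest slopes
      (0.5 control, 0.9 treated) for exercising the interaction models.
    """
    if name == "worked_example":
        return PrePostDataset(
            treatment=np.array([0.0, 0.0, 1.0, 1.0]),
            pretest=np.array([8.0, 12.0, 10.0, 14.0]),
            posttest=np.array([10.0, 12.0, 13.0, 15.0]),
        )
    if name == "null_dgp_small":
        config = SimulationConfig(n_per_group=20, n_reps=1, seed=seed)
        return simulate_prepost(config, 0)
    if name == "slope_heterogeneity":
        rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
        n = 200
        treatment = np.concatenate([np.zeros(n), np.ones(n)])
        pre = rng.normal(130.0, 15.0, 2 * n)
        slope = np.where(treatment == 1.0, 0.9, 0.5)
        post = 130.0 + slope * (pre - 130.0) + rng.normal(0.0, 6.0, 2 * n)
        return PrePostDataset(treatment=treatment, pretest=pre, posttest=post)
    raise ValueError(f"unknown fixture '{name}'; available: {FIXTURE_NAMES}")
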
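"""Centering transforms for covariates.

Two transforms matter for pre/post designs and give very different
statistics:

* **grand-mean centering** subtracts the single overall mean — a fixed linear
  shift that changes nothing but the intercept of any regression using the
  column;
* **group-mean centering** subtracts each subject's *estimated* arm mean —
  the subtracted quantity is itself a statistic, so downstream regressions
  acquire a generated regressor whose naive OLS standard errors are wrong
  (see :mod:`prepost.correction`).

Group-mean-centered columns are orthogonal to the grouping indicator by
construction: within each group the centered values sum to zero.
"""

from __future__ import annotations

import dataclasses
from typing import Dict

import numpy as np

__all__ = ["CenteredColumn", "group_mean_center", "grand_mean_center"]


@dataclasses.dataclass(frozen=True)
class CenteredColumn:
    """A centered covariate plus the means that were subtracted.

    ``kind`` is one of ``"group_mean"``, ``"grand_mean"``, ``"none"``.
    ``group_means`` maps group label -> subtracted mean (group-mean kind),
    or holds the single overall mean under the key ``"grand"``.
    """

    values: np.ndarray
    kind: str
    group_means: Dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def group_mean_center(values, groups) -> CenteredColumn:
    """Subtract each subject's group mean from ``values``.

    ``groups`` is any label array (for pre/post designs, the 0/1 treatment
    indicator). Every group must be non-empty; a group with a single member
    is permitted here (its centered value is 0) — model-level code imposes
    stricter minima where needed.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    if values.size == 0:
        raise ValueError("cannot center an empty column")
    centered = np.empty_like(values)
    means: Dict = {}
    for level in np.unique(groups):
        mask = groups == level
        m = values[mask].mean()
        means[level.item() if hasattr(level, "item") else level] = float(m)
        centered[mask] = values[mask] - m
    return CenteredColumn(values=centered, kind="group_mean", group_means=means)


def grand_mean_center(values) -> CenteredColumn:
    """Subtract the overall mean from ``values``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot center an empty column")
    m = float(values.mean())
    return CenteredColumn(values=values - m, kind="grand_mean", group_means={"grand": m})
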
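"""Subject-level data model for two-occasion (pretest/posttest) designs.

A :class:`PrePostDataset` holds one row per subject: a binary treatment
indicator (0 = control, 1 = treated), the pretest score measured before (or
early in) treatment, and the posttest score measured after. All estimators in
:mod:`prepost.estimators` consume this container.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import IO, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PrePostDataset", "LoadReport", "load_dataset"]


@dataclasses.dataclass(frozen=True)
class LoadReport:
    """Ingest accounting: rows read, rows dropped for missingness, arm sizes."""

    rows_read: int
    rows_dropped: int
    n_control: int
    n_treated: int


@dataclasses.dataclass
class PrePostDataset:
    """A validated two-arm, two-occasion dataset.

    Parameters
    ----------
    treatment
        Binary indicator per subject; 0 = control, 1 = treated. Both levels
        must be present with at least 2 subjects each.
    pretest, posttest
        Real-valued scores per subject; no missing values.
    """

    treatment: np.ndarray
    pretest: np.ndarray
    posttest: np.ndarray

    def __post_init__(self) -> None:
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.pretest = np.asarray(self.pretest, dtype=float)
        self.posttest = np.asarray(self.posttest, dtype=float)
        n = self.treatment.shape[0]
        if self.pretest.shape != (n,) or self.posttest.shape != (n,):
            raise ValueError(
                "treatment, pretest and posttest must be 1-d arrays of equal length"
            )
        for name, arr in (
            ("treatment", self.treatment),
            ("pretest", self.pretest),
            ("posttest", self.posttest),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing or non-finite values")
        levels = {float(v) for v in np.unique(self.treatment)}
        bad = levels - {0.0, 1.0}
        if bad:
            raise ValueError(
                "treatment must be coded 0/1; offending values: "
                f"{sorted(bad)}"
            )
        n_treated = int(self.treatment.sum())
        n_control = n - n_treated
        if n_control < 2 or n_treated < 2:
            raise ValueError(
                "need at least 2 subjects per arm "
                f"(got {n_control} control, {n_treated} treated)"
            )

    @property
    def n(self) -> int:
        return self.treatment.shape[0]

    @property
    def n_control(self) -> int:
        return self.n - self.n_treated

    @property
    def n_treated(self) -> int:
        return int(self.treatment.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatment.astype(int),
                "pretest": self.pretest,
                "posttest": self.posttest,
            }
        )


def load_dataset(
    source: Union[str, IO[str]],
    treatment_col: str = "treatment",
    pre_col: str = "pretest",
    post_col: str = "posttest",
    sep: str = ",",
    treatment_map: Union[dict, None] = None,
    return_report: bool = False,
):
    """Read a delimited text file into a :class:`PrePostDataset`.

    The file must have a header row containing ``treatment_col``, ``pre_col``
    and ``post_col``. Rows with a missing value in any mapped column are
    dropped (listwise deletion) and counted in the :class:`LoadReport`, which
    is logged at INFO level.

    Parameters
    ----------
    treatment_map
        Optional explicit mapping from input treatment labels to 0/1, e.g.
        ``{"placebo": 0, "drug": 1}``. Labels are never guessed: without a
        map, any coding other than 0/1 is an error listing the offending
        values.
    return_report
        If True, return ``(dataset, report)`` instead of the dataset alone.
    """
    frame = pd.read_csv(source, sep=sep)
    missing = [c for c in (treatment_col, pre_col, post_col) if c not in frame.columns]
    if missing:
        raise KeyError(
            f"column(s) {missing} not found in input; available: {list(frame.columns)}"
        )
    rows_read = len(frame)
    sub = frame[[treatment_col, pre_col, post_col]].copy()
    if treatment_map is not None:
        sub[treatment_col] = sub[treatment_col].map(treatment_map)
    sub = sub.dropna()
    rows_dropped = rows_read - len(sub)

    data = PrePostDataset(
        treatment=sub[treatment_col].to_numpy(dtype=float),
        pretest=sub[pre_col].to_numpy(dtype=float),
        posttest=sub[post_col].to_numpy(dtype=float),
    )
    report = LoadReport(
        rows_read=rows_read,
        rows_dropped=rows_dropped,
        n_control=data.n_control,
        n_treated=data.n_treated,
    )
    logger.info(
        "loaded %d rows, dropped %d with missing values; arms: %d control / %d treated",
        report.rows_read,
        report.rows_dropped,
        report.n_control,
        report.n_treated,
    )
    if return_report:
        return data, report
    return data
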
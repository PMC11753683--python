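"""Shared least-squares kernel and the :class:`ModelFit` result container.

All models in this package are ordinary least squares fits of small, benign
designs, solved exactly via a QR decomposition (never iteratively). The
kernel reports, for every coefficient, both the naive OLS standard error and
a slot for the generated-regressor-corrected standard error, plus a
per-coefficient validity flag saying which one is trustworthy.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.stats

__all__ = ["ModelFit", "ols_fit", "OLS_VALID", "NEEDS_2SLS"]

OLS_VALID = "ols_valid"
NEEDS_2SLS = "needs_2sls"

# Relative tolerance below which a diagonal element of R marks a column as
# linearly dependent on its predecessors.
_RANK_RTOL = 1e-10


@dataclasses.dataclass
class ModelFit:
    """Coefficients and both flavours of standard error for one OLS model.

    Attributes
    ----------
    coefficients, naive_se, corrected_se
        Mappings coefficient name -> value. ``corrected_se`` equals
        ``naive_se`` wherever no generated-regressor correction applies.
    se_validity
        Per coefficient, ``"ols_valid"`` if the naive OLS standard error is
        correct, ``"needs_2sls"`` if it must be replaced by the two-stage
        least-squares (actual-for-generated substitution) value.
    naive_residual_ms, df_naive
        OLS residual mean square RSS/(n-k) and its degrees of freedom n-k.
    corrected_residual_ms, df_corrected
        Residual mean square recomputed after substituting actual values for
        generated regressors; absent (None) for models without one.
    first_stage
        For group-mean-centered models, the coefficients of the first-stage
        regression of the pretest on treatment (the group means in disguise).
    """

    model_name: str
    names: List[str]
    coefficients: Dict[str, float]
    naive_se: Dict[str, float]
    corrected_se: Dict[str, float]
    se_validity: Dict[str, str]
    naive_residual_ms: float
    df_naive: int
    corrected_residual_ms: Optional[float] = None
    df_corrected: Optional[int] = None
    first_stage: Optional[Dict[str, float]] = None
    design: Optional[np.ndarray] = dataclasses.field(default=None, repr=False)
    response: Optional[np.ndarray] = dataclasses.field(default=None, repr=False)
    residuals: Optional[np.ndarray] = dataclasses.field(default=None, repr=False)
    xtx_inv: Optional[np.ndarray] = dataclasses.field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.df_naive + len(self.names)

    def se(self, name: str) -> float:
        """The standard error a user should report: corrected where needed."""
        return self.corrected_se[name]

    def t_value(self, name: str, corrected: bool = True) -> float:
        se = self.corrected_se[name] if corrected else self.naive_se[name]
        return self.coefficients[name] / se

    def p_value(self, name: str, corrected: bool = True) -> float:
        """Two-sided t-test p-value.

        Degrees of freedom follow the variance estimate used: ``df_naive``
        for OLS standard errors, ``df_corrected`` for 2SLS-corrected ones.
        """
        if corrected and self.se_validity[name] == NEEDS_2SLS:
            df = self.df_corrected if self.df_corrected is not None else self.df_naive
        else:
            df = self.df_naive
        t = self.t_value(name, corrected=corrected)
        return float(2.0 * scipy.stats.t.sf(abs(t), df))


def ols_fit(
    design: np.ndarray,
    response: np.ndarray,
    names: Sequence[str],
    model_name: str = "ols",
) -> ModelFit:
    """Exact OLS fit of ``response`` on the columns of ``design``.

    Solves the normal equations via QR; the residual mean square is
    RSS/(n-k) and naive standard errors are sqrt(ms * diag((X'X)^-1)).

    Raises
    ------
    ValueError
        If the design is rank deficient (the error names the collinear
        columns) or if n <= k.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-d array")
    n, k = X.shape
    if len(names) != k:
        raise ValueError("names must match the number of design columns")
    if n < k:
        raise ValueError(f"need at least as many observations as coefficients (n={n}, k={k})")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    bad = [names[j] for j in range(k) if diag[j] <= _RANK_RTOL * scale]
    if bad or scale == 0.0:
        raise ValueError(f"design is rank deficient; collinear column(s): {bad or list(names)}")

    beta = scipy.linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    # a saturated fit (n == k) is exact: residual mean square is 0 by definition
    ms = rss / df if df > 0 else 0.0
    r_inv = scipy.linalg.solve_triangular(R, np.eye(k))
    xtx_inv = r_inv @ r_inv.T
    se = np.sqrt(np.maximum(ms * np.diag(xtx_inv), 0.0))

    coefficients = {nm: float(b) for nm, b in zip(names, beta)}
    naive_se = {nm: float(s) for nm, s in zip(names, se)}
    return ModelFit(
        model_name=model_name,
        names=list(names),
        coefficients=coefficients,
        naive_se=naive_se,
        corrected_se=dict(naive_se),
        se_validity={nm: OLS_VALID for nm in names},
        naive_residual_ms=ms,
        df_naive=df,
        design=X,
        response=y,
        residuals=resid,
        xtx_inv=xtx_inv,
    )
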
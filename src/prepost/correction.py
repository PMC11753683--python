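"""Generated-regressor (2SLS) standard-error correction.

Group-mean centering replaces the pretest score Y0 by its deviation from an
*estimated* arm mean. The centered column is therefore a generated
regressor: naive OLS treats it as fixed and underestimates the residual
variance attached to the intercept and treatment coefficients. The remedy is
the two-stage least-squares formula, whose only difference from OLS is that
the residual variance is recomputed with the *actual* variable substituted
for its generated value:

* quasi-ANCOVA — substituting Y0 for the arm mean makes the centered term
  vanish (Y0 - Y0 = 0), so the substituted residuals are exactly the ANOVA
  residuals and the corrected treatment SE equals ANOVA's;
* dual-centered ANCOVA — the arm mean appears on both sides, so substitution
  turns the response into the change score (Y1 - Y0) and the substituted
  residuals are exactly those of the differences model.

The coefficient covariance keeps the original fit's (X'X)^-1; only the
residual variance (and its degrees of freedom) changes. By default the
degrees of freedom count only the regressors that survive the substitution
(n - 2 for all three centered models), which reproduces the ANOVA /
differences standard errors exactly; the textbook 2SLS divisor n - k is
available via ``divisor="model"`` for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np

from .centering import group_mean_center
from .data import PrePostDataset
from .linear import NEEDS_2SLS, OLS_VALID, ModelFit, ols_fit

__all__ = [
    "CorrectionResult",
    "corrected_residual_variance",
    "apply_correction",
    "hill_variant_analysis",
]

_CORRECTABLE = {"quasi_ancova", "dual_centered", "dual_centered_interaction"}


@dataclasses.dataclass(frozen=True)
class CorrectionResult:
    """Output of the actual-for-generated residual-variance recomputation."""

    model_name: str
    corrected_residual_ms: float
    df_corrected: int
    corrected_se: Dict[str, float]
    substitution_note: str


def corrected_residual_variance(
    fit: ModelFit, data: PrePostDataset, divisor: str = "reference"
) -> CorrectionResult:
    """Recompute the residual variance with actual values for generated ones.

    Every occurrence of the arm mean of the pretest is replaced by the
    subject's own pretest score; centered-pretest terms (and any interaction
    with them) then vanish, and for dual-centered models the response becomes
    the change score. The corrected SE of each flagged coefficient is
    sqrt(corrected_ms * diag((X'X)^-1)) with the *original* design's inverse.

    Parameters
    ----------
    divisor
        ``"reference"`` (default): degrees of freedom = n minus the number of
        coefficients whose regressors survive the substitution (intercept and
        treatment, so n-2) — reproduces the reference model's SE exactly.
        ``"model"``: the fitted model's own n-k.
    """
    if fit.model_name not in _CORRECTABLE:
        raise ValueError(
            f"model '{fit.model_name}' has no generated regressor; "
            f"correction applies to {sorted(_CORRECTABLE)}"
        )
    X = data.treatment
    b0 = fit.coefficients["intercept"]
    b1 = fit.coefficients["treatment"]
    if fit.model_name == "quasi_ancova":
        substituted = data.posttest - (b0 + b1 * X)
        note = (
            "arm-mean pretest replaced by actual pretest in the centered "
            "regressor (which vanishes); residuals are those of posttest on "
            "intercept + treatment"
        )
    else:  # dual_centered, dual_centered_interaction
        substituted = (data.posttest - data.pretest) - (b0 + b1 * X)
        note = (
            "arm-mean pretest replaced by actual pretest on both sides; "
            "response becomes the change score and centered terms vanish; "
            "residuals are those of (posttest - pretest) on intercept + treatment"
        )
    rss = float(substituted @ substituted)
    surviving = 2  # intercept and treatment survive the substitution
    if divisor == "reference":
        df = data.n - surviving
    elif divisor == "model":
        df = fit.df_naive
    else:
        raise ValueError("divisor must be 'reference' or 'model'")
    ms = rss / df

    corrected: Dict[str, float] = {}
    for j, name in enumerate(fit.names):
        if fit.se_validity[name] == NEEDS_2SLS:
            corrected[name] = float(np.sqrt(ms * fit.xtx_inv[j, j]))
    return CorrectionResult(
        model_name=fit.model_name,
        corrected_residual_ms=ms,
        df_corrected=df,
        corrected_se=corrected,
        substitution_note=note,
    )


def apply_correction(fit: ModelFit, result: CorrectionResult) -> ModelFit:
    """Merge a :class:`CorrectionResult` into a fit.

    Coefficients flagged ``needs_2sls`` receive the corrected SE; everything
    else keeps its naive OLS SE (for the interaction models, OLS standard
    errors remain valid for the centered-pretest and interaction slopes).
    A fit without generated regressors passes through unchanged when given a
    no-op result (``corrected_se`` empty and matching model name).
    """
    if result.model_name != fit.model_name:
        raise ValueError(
            f"correction for '{result.model_name}' applied to '{fit.model_name}' fit"
        )
    unknown = set(result.corrected_se) - set(fit.names)
    if unknown:
        raise ValueError(f"correction names unknown coefficients: {sorted(unknown)}")
    corrected_se = dict(fit.naive_se)
    corrected_se.update(result.corrected_se)
    return dataclasses.replace(
        fit,
        corrected_se=corrected_se,
        corrected_residual_ms=result.corrected_residual_ms,
        df_corrected=result.df_corrected,
    )


def hill_variant_analysis(outcome, predictor, groups, variant: int) -> ModelFit:
    """Fit one of the three group-mean-centering regressions and label SEs.

    With x̄_g the per-group mean of the predictor, the variants are

    1. ``y = a + B1*x̄_g + B2*(x - x̄_g)`` — B1 rides on a generated
       regressor (needs 2SLS); OLS SEs are fine for B2;
    2. ``y = a + B1*x + B2*x̄_g`` — now B2 needs 2SLS, B1 is fine;
    3. ``y = a + B1*(x - x̄_g)`` — OLS SEs are valid throughout.

    Corrected SEs come from the same actual-for-generated substitution as the
    pre/post models: x̄_g is replaced by x in the fitted equation, the
    residual variance recomputed, and the original (X'X)^-1 retained.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    g = np.asarray(groups)
    if not (y.shape == x.shape == g.shape):
        raise ValueError("outcome, predictor and groups must have equal length")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    singles = [lab for lab, c in zip(labels, counts) if c < 2]
    if singles:
        raise ValueError(
            f"singleton group(s) {singles}: the demeaned value is identically 0 "
            "and the group mean is the observation itself"
        )
    centered = group_mean_center(x, g)
    gmean = x - centered.values
    ones = np.ones_like(y)

    if variant == 1:
        names = ["intercept", "group_mean", "predictor_demeaned"]
        design = np.column_stack([ones, gmean, centered.values])
        fit = ols_fit(design, y, names, model_name="hill_variant_1")
        fit.se_validity["group_mean"] = NEEDS_2SLS
    elif variant == 2:
        names = ["intercept", "predictor", "group_mean"]
        design = np.column_stack([ones, x, gmean])
        fit = ols_fit(design, y, names, model_name="hill_variant_2")
        fit.se_validity["group_mean"] = NEEDS_2SLS
    elif variant == 3:
        names = ["intercept", "predictor_demeaned"]
        design = np.column_stack([ones, centered.values])
        return ols_fit(design, y, names, model_name="hill_variant_3")
    else:
        raise ValueError("variant must be 1, 2 or 3")

    # actual-for-generated substitution: x̄_g -> x in the fitted equation
    a = fit.coefficients["intercept"]
    if variant == 1:
        # B1*x + B2*(x - x) = B1*x
        substituted = y - (a + fit.coefficients["group_mean"] * x)
    else:
        # B1*x + B2*x = (B1 + B2)*x
        substituted = y - (
            a + (fit.coefficients["predictor"] + fit.coefficients["group_mean"]) * x
        )
    rss = float(substituted @ substituted)
    df = y.size - 2  # intercept and the raw predictor survive
    ms = rss / df
    corrected = dict(fit.naive_se)
    for j, name in enumerate(fit.names):
        if fit.se_validity[name] == NEEDS_2SLS:
            corrected[name] = float(np.sqrt(ms * fit.xtx_inv[j, j]))
    fit.corrected_se = corrected
    fit.corrected_residual_ms = ms
    fit.df_corrected = df
    return fit
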
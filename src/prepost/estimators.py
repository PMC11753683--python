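"""The five treatment-effect estimators for randomized pre/post designs.

Writing Y1 for the posttest, Y0 for the pretest, X for the 0/1 treatment
indicator and c(Y0) for the arm-mean-centered pretest:

====================  =====================================================
anova                 Y1 = b0 + b1*X
differences           (Y1 - Y0) = d0 + d1*X
ancova                Y1 = a0 + a1*X + a2*Y0
quasi_ancova          Y1 = g0 + g1*X + g2*c(Y0)
dual_centered         (Y1 - armmean(Y0)) = w0 + w1*X + g2*c(Y0)
====================  =====================================================

plus the two interaction extensions (``dual_centered_interaction`` adds
g3*X*c(Y0); ``ancova_interaction`` adds a3*X*Y0).

Because c(Y0) is orthogonal to X by construction, quasi-ANCOVA returns
exactly the ANOVA treatment estimate and dual-centered ANCOVA exactly the
differences estimate; their naive OLS standard errors, however, borrow the
ANCOVA-sized residual variance and are too small. The centered-model fits
returned here therefore arrive with the generated-regressor correction of
:mod:`prepost.correction` already applied: ``corrected_se`` carries the
2SLS values for the intercept and treatment coefficients.

The interaction identities a2 = g2 + 1 and a3 = g3 link the dual-centered
interaction model to the plain ANCOVA interaction model.
"""

from __future__ import annotations

import numpy as np

from .centering import group_mean_center
from .correction import apply_correction, corrected_residual_variance
from .data import PrePostDataset
from .linear import NEEDS_2SLS, ModelFit, ols_fit

__all__ = [
    "fit_anova",
    "fit_differences",
    "fit_ancova",
    "fit_quasi_ancova",
    "fit_dual_centered",
    "fit_dual_centered_interaction",
    "fit_ancova_interaction",
    "fit_model",
    "MODEL_NAMES",
]

MODEL_NAMES = (
    "anova",
    "differences",
    "ancova",
    "quasi_ancova",
    "dual_centered",
    "dual_centered_interaction",
    "ancova_interaction",
)


def _ones(data: PrePostDataset) -> np.ndarray:
    return np.ones(data.n)


def _first_stage(data: PrePostDataset) -> dict:
    """Regression of the pretest on treatment: phi1 is the arm-mean gap.

    The fitted values of this regression are the arm means of the pretest,
    so the centered pretest equals this fit's residual — the source of the
    generated-regressor problem.
    """
    fs = ols_fit(
        np.column_stack([_ones(data), data.treatment]),
        data.pretest,
        ["intercept", "treatment"],
        model_name="first_stage",
    )
    return {"phi0": fs.coefficients["intercept"], "phi1": fs.coefficients["treatment"]}


def fit_anova(data: PrePostDataset) -> ModelFit:
    """Posttest on intercept + treatment; b1 is the gap in posttest arm means."""
    design = np.column_stack([_ones(data), data.treatment])
    return ols_fit(design, data.posttest, ["intercept", "treatment"], model_name="anova")


def fit_differences(data: PrePostDataset) -> ModelFit:
    """Change score (posttest - pretest) on intercept + treatment."""
    design = np.column_stack([_ones(data), data.treatment])
    return ols_fit(
        design,
        data.posttest - data.pretest,
        ["intercept", "treatment"],
        model_name="differences",
    )


def fit_ancova(data: PrePostDataset) -> ModelFit:
    """Posttest on intercept + treatment + raw pretest."""
    design = np.column_stack([_ones(data), data.treatment, data.pretest])
    return ols_fit(
        design,
        data.posttest,
        ["intercept", "treatment", "pretest"],
        model_name="ancova",
    )


def fit_quasi_ancova(data: PrePostDataset, divisor: str = "reference") -> ModelFit:
    """ANCOVA with the pretest arm-mean-centered; corrected SEs included.

    The treatment coefficient equals ANOVA's exactly, and after the 2SLS
    correction its standard error does too.
    """
    centered = group_mean_center(data.pretest, data.treatment)
    design = np.column_stack([_ones(data), data.treatment, centered.values])
    fit = ols_fit(
        design,
        data.posttest,
        ["intercept", "treatment", "pretest_centered"],
        model_name="quasi_ancova",
    )
    fit.se_validity["intercept"] = NEEDS_2SLS
    fit.se_validity["treatment"] = NEEDS_2SLS
    fit.first_stage = _first_stage(data)
    return apply_correction(fit, corrected_residual_variance(fit, data, divisor))


def fit_dual_centered(data: PrePostDataset, divisor: str = "reference") -> ModelFit:
    """Quasi-ANCOVA with the pretest arm mean also subtracted from the response.

    The treatment coefficient equals the differences model's exactly, and
    after the 2SLS correction so does its standard error.
    """
    centered = group_mean_center(data.pretest, data.treatment)
    arm_mean_pre = data.pretest - centered.values
    design = np.column_stack([_ones(data), data.treatment, centered.values])
    fit = ols_fit(
        design,
        data.posttest - arm_mean_pre,
        ["intercept", "treatment", "pretest_centered"],
        model_name="dual_centered",
    )
    fit.se_validity["intercept"] = NEEDS_2SLS
    fit.se_validity["treatment"] = NEEDS_2SLS
    fit.first_stage = _first_stage(data)
    return apply_correction(fit, corrected_residual_variance(fit, data, divisor))


def fit_dual_centered_interaction(
    data: PrePostDataset, divisor: str = "reference"
) -> ModelFit:
    """Dual-centered ANCOVA plus a treatment-by-centered-pretest interaction.

    Parameterized on the change score: (Y1 - Y0) regressed on intercept,
    treatment, centered pretest and their product. Both added columns are
    orthogonal to the intercept and treatment, so the treatment coefficient
    equals the differences model's exactly; and because the full pretest is
    subtracted on the left, the slope and interaction map onto the ANCOVA
    interaction model via a2 = g2 + 1 and a3 = g3. OLS standard errors
    remain valid for the centered-pretest and interaction slopes; the
    intercept and treatment need the 2SLS correction.
    """
    centered = group_mean_center(data.pretest, data.treatment)
    design = np.column_stack(
        [_ones(data), data.treatment, centered.values, data.treatment * centered.values]
    )
    fit = ols_fit(
        design,
        data.posttest - data.pretest,
        ["intercept", "treatment", "pretest_centered", "interaction"],
        model_name="dual_centered_interaction",
    )
    fit.se_validity["intercept"] = NEEDS_2SLS
    fit.se_validity["treatment"] = NEEDS_2SLS
    fit.first_stage = _first_stage(data)
    return apply_correction(fit, corrected_residual_variance(fit, data, divisor))


def fit_ancova_interaction(data: PrePostDataset) -> ModelFit:
    """ANCOVA plus a treatment-by-pretest interaction (arm-specific slopes)."""
    design = np.column_stack(
        [_ones(data), data.treatment, data.pretest, data.treatment * data.pretest]
    )
    return ols_fit(
        design,
        data.posttest,
        ["intercept", "treatment", "pretest", "interaction"],
        model_name="ancova_interaction",
    )


_FITTERS = {
    "anova": fit_anova,
    "differences": fit_differences,
    "ancova": fit_ancova,
    "quasi_ancova": fit_quasi_ancova,
    "dual_centered": fit_dual_centered,
    "dual_centered_interaction": fit_dual_centered_interaction,
    "ancova_interaction": fit_ancova_interaction,
}


def fit_model(name: str, data: PrePostDataset) -> ModelFit:
    """Dispatch by canonical model name."""
    try:
        fitter = _FITTERS[name]
    except KeyError:
        raise ValueError(f"unknown model '{name}'; choose from {MODEL_NAMES}") from None
    return fitter(data)
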
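"""Monte Carlo engine for the null randomized pre/post design.

The data-generating process draws, per subject, a pretest score
``N(mean_pre, sd^2)`` and a posttest score

    post = mean_post + alpha2 * (pre - mean_pre) + e,   e ~ N(0, sd^2 * (1 - alpha2^2)),

plus ``treatment_effect`` for treated subjects. Pretest and posttest are
then jointly normal with common SD ``sd`` and correlation ``alpha2`` — the
conditional-regression form of a bivariate normal, so the ANCOVA pretest
slope equals ``alpha2`` and the closed-form residual variances are

* ANOVA: sd^2
* ANCOVA / quasi / dual-centered: sd^2 * (1 - alpha2^2)
* differences: 2 * sd^2 * (1 - alpha2)

Each study fits all five estimators on every replication, asserts the exact
cross-model identities within the replication (quasi-ANCOVA treatment
estimate = ANOVA's; dual-centered = differences'), and aggregates the
summary table: mean estimates, mean reported naive SEs, mean corrected SEs,
the empirical SD of the treatment estimate across replications, mean
residual mean square, and empirical type-I-error rates of the nominal-5%
naive and corrected t-tests. Every aggregate carries a Monte-Carlo standard
error (SD/sqrt(R) for means, SD-of-SD via the asymptotic sqrt(2(R-1))
scaling).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .data import PrePostDataset
from .estimators import (
    fit_ancova,
    fit_anova,
    fit_differences,
    fit_dual_centered,
    fit_quasi_ancova,
)

__all__ = [
    "SimulationConfig",
    "ReplicationRecord",
    "ModelSummary",
    "SimulationSummary",
    "simulate_prepost",
    "run_study",
    "render_table1",
    "STUDY_MODELS",
    "MODEL_LABELS",
]

# Paper-table ordering of the five study models.
STUDY_MODELS = ("anova", "ancova", "quasi_ancova", "differences", "dual_centered")
MODEL_LABELS = {
    "anova": "ANOVA",
    "ancova": "ANCOVA",
    "quasi_ancova": "Quasi-ANCOVA",
    "differences": "Differences",
    "dual_centered": "Dual-Centered",
}
# Models whose treatment SE needs (and here receives) the 2SLS correction.
_CORRECTED = {"quasi_ancova", "dual_centered"}
_IDENT_RTOL = 1e-10


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the null pre/post data-generating process.

    Defaults are the study conditions of the reference table: balanced arms
    of 500, pretest/posttest means 130, SD 15, zero treatment effect, 1,000
    replications. ``n_control``/``n_treated`` override ``n_per_group`` for
    unbalanced designs.
    """

    n_per_group: int = 500
    mean_pre: float = 130.0
    mean_post: float = 130.0
    sd: float = 15.0
    alpha2: float = 0.9
    treatment_effect: float = 0.0
    n_reps: int = 1000
    seed: int = 0
    n_control: Optional[int] = None
    n_treated: Optional[int] = None

    def __post_init__(self) -> None:
        if self.arm_sizes[0] < 2 or self.arm_sizes[1] < 2:
            raise ValueError("each arm needs at least 2 subjects")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not -1.0 < self.alpha2 < 1.0:
            raise ValueError("alpha2 must lie strictly inside (-1, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")

    @property
    def arm_sizes(self) -> tuple:
        nc = self.n_control if self.n_control is not None else self.n_per_group
        nt = self.n_treated if self.n_treated is not None else self.n_per_group
        return int(nc), int(nt)


@dataclasses.dataclass(frozen=True)
class ReplicationRecord:
    """Per-replication, per-model estimates (one dict entry per model)."""

    replication: int
    estimate: Dict[str, float]
    naive_se: Dict[str, float]
    corrected_se: Dict[str, float]
    slope: Dict[str, float]
    slope_se: Dict[str, float]
    residual_ms: Dict[str, float]


@dataclasses.dataclass(frozen=True)
class ModelSummary:
    """One model's row of the aggregate table, with MC standard errors."""

    model: str
    mean_estimate: float
    mean_naive_se: float
    mean_corrected_se: Optional[float]
    empirical_sd: Optional[float]
    mean_residual_ms: float
    mean_slope: Optional[float]
    mean_slope_se: Optional[float]
    naive_size: float
    corrected_size: float
    mc_se_mean_estimate: float
    mc_se_empirical_sd: Optional[float]
    mc_se_mean_naive_se: float
    mc_se_mean_residual_ms: float


@dataclasses.dataclass(frozen=True)
class SimulationSummary:
    config: SimulationConfig
    models: Dict[str, ModelSummary]
    records: Optional[List[ReplicationRecord]] = None


def simulate_prepost(config: SimulationConfig, replication: int) -> PrePostDataset:
    """Draw one replication of the null pre/post design.

    Reproducible in isolation: the random stream is seeded from
    ``(config.seed, replication)``, so any single replication can be
    regenerated without running the ones before it.
    """
    nc, nt = config.arm_sizes
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, replication)))
    n = nc + nt
    treatment = np.concatenate([np.zeros(nc), np.ones(nt)])
    pre = rng.normal(config.mean_pre, config.sd, n)
    noise_sd = config.sd * math.sqrt(1.0 - config.alpha2**2)
    post = (
        config.mean_post
        + config.alpha2 * (pre - config.mean_pre)
        + rng.normal(0.0, noise_sd, n)
        + config.treatment_effect * treatment
    )
    return PrePostDataset(treatment=treatment, pretest=pre, posttest=post)


def _fit_all(data: PrePostDataset, replication: int) -> ReplicationRecord:
    fits = {
        "anova": fit_anova(data),
        "ancova": fit_ancova(data),
        "quasi_ancova": fit_quasi_ancova(data),
        "differences": fit_differences(data),
        "dual_centered": fit_dual_centered(data),
    }
    # within-replication exact identities; a failure points at the replication
    _assert_close(
        fits["quasi_ancova"].coefficients["treatment"],
        fits["anova"].coefficients["treatment"],
        "quasi-ANCOVA vs ANOVA treatment estimate",
        replication,
    )
    _assert_close(
        fits["dual_centered"].coefficients["treatment"],
        fits["differences"].coefficients["treatment"],
        "dual-centered vs differences treatment estimate",
        replication,
    )
    slope_key = {"ancova": "pretest", "quasi_ancova": "pretest_centered",
                 "dual_centered": "pretest_centered"}
    return ReplicationRecord(
        replication=replication,
        estimate={m: f.coefficients["treatment"] for m, f in fits.items()},
        naive_se={m: f.naive_se["treatment"] for m, f in fits.items()},
        corrected_se={m: f.corrected_se["treatment"] for m, f in fits.items()},
        slope={m: fits[m].coefficients[k] for m, k in slope_key.items()},
        slope_se={m: fits[m].naive_se[k] for m, k in slope_key.items()},
        residual_ms={m: f.naive_residual_ms for m, f in fits.items()},
    )


def _assert_close(a: float, b: float, what: str, replication: int) -> None:
    scale = max(abs(a), abs(b), 1.0)
    if abs(a - b) > _IDENT_RTOL * scale:
        raise AssertionError(
            f"identity violated at replication {replication}: {what}: {a!r} vs {b!r}"
        )


def run_study(config: SimulationConfig, keep_records: bool = False) -> SimulationSummary:
    """Run the full Monte Carlo study and aggregate the summary table."""
    records = [
        _fit_all(simulate_prepost(config, r), r) for r in range(config.n_reps)
    ]
    n = sum(config.arm_sizes)
    r = config.n_reps
    # critical values: naive df is n-k of the fitted model; corrected df is n-2
    crit_naive = {
        m: scipy.stats.t.ppf(0.975, n - (3 if m in _CORRECTED or m == "ancova" else 2))
        for m in STUDY_MODELS
    }
    crit_corr = scipy.stats.t.ppf(0.975, n - 2)

    models: Dict[str, ModelSummary] = {}
    for m in STUDY_MODELS:
        est = np.array([rec.estimate[m] for rec in records])
        nse = np.array([rec.naive_se[m] for rec in records])
        cse = np.array([rec.corrected_se[m] for rec in records])
        mse = np.array([rec.residual_ms[m] for rec in records])
        has_slope = m in records[0].slope
        slope = np.array([rec.slope[m] for rec in records]) if has_slope else None
        slope_se = np.array([rec.slope_se[m] for rec in records]) if has_slope else None
        emp_sd = float(est.std(ddof=1)) if r > 1 else None
        models[m] = ModelSummary(
            model=m,
            mean_estimate=float(est.mean()),
            mean_naive_se=float(nse.mean()),
            mean_corrected_se=float(cse.mean()) if m in _CORRECTED else None,
            empirical_sd=emp_sd,
            mean_residual_ms=float(mse.mean()),
            mean_slope=float(slope.mean()) if has_slope else None,
            mean_slope_se=float(slope_se.mean()) if has_slope else None,
            naive_size=float(np.mean(np.abs(est / nse) > crit_naive[m])),
            corrected_size=float(np.mean(np.abs(est / cse) > crit_corr)),
            mc_se_mean_estimate=float(est.std(ddof=1) / math.sqrt(r)) if r > 1 else float("nan"),
            mc_se_empirical_sd=(
                float(emp_sd / math.sqrt(2.0 * (r - 1))) if emp_sd is not None else None
            ),
            mc_se_mean_naive_se=float(nse.std(ddof=1) / math.sqrt(r)) if r > 1 else float("nan"),
            mc_se_mean_residual_ms=float(mse.std(ddof=1) / math.sqrt(r)) if r > 1 else float("nan"),
        )
    return SimulationSummary(
        config=config, models=models, records=records if keep_records else None
    )


def _fmt(value: Optional[float], decimals: int) -> str:
    if value is None:
        return "-"
    return f"{value:.{decimals}f}"


def render_table1(
    summaries: Sequence[SimulationSummary],
    decimals: int = 4,
    include_mc_se: bool = False,
) -> pd.DataFrame:
    """Lay out one or more study summaries as the standard five-model table.

    One row per (model, alpha2); models without a pretest slope show "-" in
    the slope columns, matching the usual presentation. The corrected-SE
    column ``se_corrected_2sls`` is an addition to the classical layout and
    is only populated for the centered models.
    """
    rows = []
    for summary in summaries:
        for m in STUDY_MODELS:
            s = summary.models[m]
            row = {
                "model": MODEL_LABELS[m],
                "true_alpha2": summary.config.alpha2,
                "mean_slope": _fmt(s.mean_slope, decimals),
                "se_slope": _fmt(s.mean_slope_se, decimals),
                "mean_estimate": _fmt(s.mean_estimate, decimals),
                "se_naive": _fmt(s.mean_naive_se, decimals),
                "se_corrected_2sls": _fmt(s.mean_corrected_se, decimals),
                "sd_empirical": _fmt(s.empirical_sd, decimals),
                "mse": _fmt(s.mean_residual_ms, decimals),
            }
            if include_mc_se:
                row["mc_se_mean_estimate"] = _fmt(s.mc_se_mean_estimate, decimals)
                row["mc_se_sd_empirical"] = _fmt(s.mc_se_empirical_sd, decimals)
                row["mc_se_se_naive"] = _fmt(s.mc_se_mean_naive_se, decimals)
                row["mc_se_mse"] = _fmt(s.mc_se_mean_residual_ms, decimals)
            rows.append(row)
    return pd.DataFrame(rows)
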
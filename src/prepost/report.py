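"""Run reports: human-readable tables plus a lossless JSON twin.

Every number shown in the human-readable output is also present, at full
precision, in the machine-readable report, so the JSON round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Dict, List, Optional

from . import __version__
from .linear import ModelFit

__all__ = ["EquivalenceCheck", "RunReport", "format_fit", "write_report", "read_report"]

_REL_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class EquivalenceCheck:
    """One cross-model identity, with the observed discrepancy."""

    name: str
    lhs: float
    rhs: float
    rel_tol: float = _REL_TOL

    @property
    def discrepancy(self) -> float:
        return abs(self.lhs - self.rhs)

    @property
    def passed(self) -> bool:
        scale = max(abs(self.lhs), abs(self.rhs), 1.0)
        return self.discrepancy <= self.rel_tol * scale

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lhs": self.lhs,
            "rhs": self.rhs,
            "discrepancy": self.discrepancy,
            "rel_tol": self.rel_tol,
            "passed": self.passed,
        }


@dataclasses.dataclass
class RunReport:
    command: str
    config: Dict
    results: Dict
    equivalence: List[EquivalenceCheck] = dataclasses.field(default_factory=list)
    seed: Optional[int] = None
    version: str = __version__

    @property
    def all_passed(self) -> bool:
        return all(chk.passed for chk in self.equivalence)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "results": self.results,
            "equivalence": [chk.to_dict() for chk in self.equivalence],
        }


def fit_to_dict(fit: ModelFit) -> dict:
    return {
        "model": fit.model_name,
        "coefficients": fit.coefficients,
        "naive_se": fit.naive_se,
        "corrected_se": fit.corrected_se,
        "se_validity": fit.se_validity,
        "naive_residual_ms": fit.naive_residual_ms,
        "corrected_residual_ms": fit.corrected_residual_ms,
        "df_naive": fit.df_naive,
        "df_corrected": fit.df_corrected,
        "first_stage": fit.first_stage,
    }


def format_fit(fit: ModelFit, decimals: int = 4) -> str:
    """Fixed-width coefficient table for terminal display."""
    lines = [f"model: {fit.model_name}  (df={fit.df_naive}"]
    if fit.df_corrected is not None:
        lines[0] += f", df_corrected={fit.df_corrected}"
    lines[0] += ")"
    header = f"{'coefficient':<18}{'estimate':>12}{'se_naive':>12}{'se_corrected':>14}  se_validity"
    lines.append(header)
    for name in fit.names:
        lines.append(
            f"{name:<18}"
            f"{fit.coefficients[name]:>12.{decimals}f}"
            f"{fit.naive_se[name]:>12.{decimals}f}"
            f"{fit.corrected_se[name]:>14.{decimals}f}"
            f"  {fit.se_validity[name]}"
        )
    lines.append(f"residual mean square (naive): {fit.naive_residual_ms:.{decimals}f}")
    if fit.corrected_residual_ms is not None:
        lines.append(
            f"residual mean square (corrected): {fit.corrected_residual_ms:.{decimals}f}"
        )
    return "\n".join(lines)


def write_report(report: RunReport, destination: str) -> None:
    """Serialize the report to JSON; floats survive a round trip exactly."""
    with open(destination, "w") as handle:
        json.dump(report.to_dict(), handle, indent=2)
        handle.write("\n")


def read_report(path: str) -> dict:
    with open(path) as handle:
        return json.load(handle)
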
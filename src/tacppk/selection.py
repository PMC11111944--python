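"""Stepwise covariate selection on CL/F by likelihood-ratio testing.

Forward inclusion adds, one at a time, the candidate whose inclusion
drops the OFV the most, provided the drop reaches the chi-squared
threshold (default 6.63, p < 0.01 at 1 df); backward elimination then
removes retained covariates whose removal raises the OFV by less than a
stricter threshold (default 7.88, p < 0.005 at 1 df).  The model is
refitted between steps; ties are broken by the larger OFV change, then
lexicographically by covariate name, so the outcome does not depend on
the candidate ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from scipy import stats

from .data_model import PatientRecord
from .estimation import FitResult, fit_population
from .pk_model import PopulationModel

__all__ = [
    "CovariateSpec",
    "SelectionStep",
    "SelectionTrace",
    "lrt_threshold",
    "forward_inclusion",
    "backward_elimination",
    "stepwise_selection",
    "DEFAULT_CANDIDATES",
]

logger = logging.getLogger(__name__)

FORWARD_THRESHOLD = 6.63
BACKWARD_THRESHOLD = 7.88

#: tolerance for OFV-change comparisons against a threshold, so that the
#: inclusive boundary convention (change == threshold qualifies) is
#: robust to floating-point round-off
_EPS = 1e-9


@dataclass(frozen=True)
class CovariateSpec:
    """One candidate exponential-linear covariate effect.

    ``covariate`` must be a :class:`~tacppk.data_model.CovariatePanel`
    field; the effect enters as ``P * exp(beta * x)`` on the target
    parameter (only CL/F is searched by default).
    """

    covariate: str
    target_parameter: str = "cl"
    coding: str = "continuous"


#: the standard candidate panel: genotype, labs, demographics, co-medication
DEFAULT_CANDIDATES = (
    CovariateSpec("cyp3a5_code", coding="ordinal"),
    CovariateSpec("hct"),
    CovariateSpec("wt"),
    CovariateSpec("rbc"),
    CovariateSpec("dbil"),
    CovariateSpec("bun"),
    CovariateSpec("clcr"),
    CovariateSpec("alb"),
    CovariateSpec("sex_code", coding="ordinal"),
    CovariateSpec("comed_ca_antagonist", coding="ordinal"),
    CovariateSpec("comed_ppi", coding="ordinal"),
    CovariateSpec("comed_voriconazole", coding="ordinal"),
)


def lrt_threshold(alpha: float, df: int) -> float:
    """Chi-squared (1 - alpha) quantile with ``df`` degrees of freedom,
    rounded to two decimals: the OFV change required for significance."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return round(float(stats.chi2.ppf(1.0 - alpha, df)), 2)


@dataclass(frozen=True)
class SelectionStep:
    phase: str              # "forward" | "backward"
    candidate: str
    delta_ofv: float        # OFV drop on inclusion / rise on removal
    decision: str           # "included" | "rejected" | "removed" | "retained" | "skipped"


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    final_model: PopulationModel | None = None
    final_fit: FitResult | None = None
    base_ofv: float = float("nan")

    @property
    def retained(self) -> list[str]:
        return sorted(self.final_model.covariates) if self.final_model else []


Fitter = Callable[..., FitResult]


def _fit(
    fitter: Fitter,
    records: Sequence[PatientRecord],
    spec: PopulationModel,
    init: PopulationModel | None,
    options: dict | None,
) -> FitResult:
    return fitter(records, spec, init=init, options=options)


def _with_covariate(model: PopulationModel, name: str, beta: float = 0.0) -> PopulationModel:
    out = model.copy()
    out.covariates = dict(model.covariates)
    out.covariates[name] = beta
    return out


def _without_covariate(model: PopulationModel, name: str) -> PopulationModel:
    out = model.copy()
    out.covariates = {k: v for k, v in model.covariates.items() if k != name}
    return out


def forward_inclusion(
    records: Sequence[PatientRecord],
    base_model: PopulationModel,
    candidates: Sequence[CovariateSpec] = DEFAULT_CANDIDATES,
    threshold: float = FORWARD_THRESHOLD,
    fit_options: dict | None = None,
    fitter: Fitter = fit_population,
) -> SelectionTrace:
    """Greedy forward search; returns the trace ending in the full model."""
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    options = dict(fit_options or {})
    options.setdefault("compute_rse", False)
    trace = SelectionTrace()
    current_fit = _fit(fitter, records, base_model, None, options)
    trace.base_ofv = current_fit.ofv
    remaining = sorted({c.covariate for c in candidates})
    while remaining:
        results: dict[str, tuple[float, FitResult]] = {}
        for name in remaining:
            spec = _with_covariate(current_fit.estimates, name)
            try:
                fit = _fit(fitter, records, spec, spec, options)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("forward fit of %s failed (%s); skipped", name, exc)
                trace.steps.append(SelectionStep("forward", name, float("nan"), "skipped"))
                continue
            if not fit.converged:
                logger.warning("forward fit of %s did not converge; skipped", name)
                trace.steps.append(SelectionStep("forward", name, float("nan"), "skipped"))
                continue
            results[name] = (current_fit.ofv - fit.ofv, fit)
        if not results:
            break
        # largest drop wins; lexicographic tie-break
        best = min(results, key=lambda n: (-results[n][0], n))
        best_drop = results[best][0]
        for name in sorted(results):
            if name == best and best_drop >= threshold - _EPS:
                continue
            trace.steps.append(
                SelectionStep("forward", name, results[name][0], "rejected")
            )
        if best_drop >= threshold - _EPS:
            trace.steps.append(SelectionStep("forward", best, best_drop, "included"))
            current_fit = results[best][1]
            remaining.remove(best)
        else:
            break
    trace.final_model = current_fit.estimates
    trace.final_fit = current_fit
    return trace


def backward_elimination(
    records: Sequence[PatientRecord],
    full_model: PopulationModel,
    threshold: float = BACKWARD_THRESHOLD,
    fit_options: dict | None = None,
    fitter: Fitter = fit_population,
    full_fit: FitResult | None = None,
) -> SelectionTrace:
    """Drop retained covariates whose removal raises the OFV < threshold."""
    options = dict(fit_options or {})
    options.setdefault("compute_rse", False)
    trace = SelectionTrace()
    current_fit = full_fit or _fit(fitter, records, full_model, None, options)
    trace.base_ofv = current_fit.ofv
    while current_fit.estimates.covariates:
        results: dict[str, tuple[float, FitResult]] = {}
        for name in sorted(current_fit.estimates.covariates):
            spec = _without_covariate(current_fit.estimates, name)
            try:
                fit = _fit(fitter, records, spec, spec, options)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("backward fit without %s failed (%s); skipped", name, exc)
                trace.steps.append(SelectionStep("backward", name, float("nan"), "skipped"))
                continue
            if not fit.converged:
                trace.steps.append(SelectionStep("backward", name, float("nan"), "skipped"))
                continue
            results[name] = (fit.ofv - current_fit.ofv, fit)
        if not results:
            break
        # smallest rise is the cheapest removal; lexicographic tie-break
        weakest = min(results, key=lambda n: (results[n][0], n))
        rise = results[weakest][0]
        if rise < threshold - _EPS:
            trace.steps.append(SelectionStep("backward", weakest, rise, "removed"))
            current_fit = results[weakest][1]
        else:
            for name in sorted(results):
                trace.steps.append(
                    SelectionStep("backward", name, results[name][0], "retained")
                )
            break
    trace.final_model = current_fit.estimates
    trace.final_fit = current_fit
    return trace


def stepwise_selection(
    records: Sequence[PatientRecord],
    base_model: PopulationModel,
    candidates: Sequence[CovariateSpec] = DEFAULT_CANDIDATES,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    fit_options: dict | None = None,
    fitter: Fitter = fit_population,
) -> SelectionTrace:
    """Forward inclusion followed by backward elimination (one trace)."""
    forward = forward_inclusion(
        records, base_model, candidates, forward_threshold, fit_options, fitter
    )
    backward = backward_elimination(
        records,
        forward.final_model,
        backward_threshold,
        fit_options,
        fitter,
        full_fit=forward.final_fit,
    )
    trace = SelectionTrace(
        steps=forward.steps + backward.steps,
        final_model=backward.final_model,
        final_fit=backward.final_fit,
        base_ofv=forward.base_ofv,
    )
    return trace
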
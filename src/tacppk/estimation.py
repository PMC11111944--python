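"""FOCE population fitting, OFV computation and MAP (empirical-Bayes) etas.

The marginal likelihood of each subject's log-troughs is approximated
the standard FOCE way: the conditional mode ``eta_hat`` of the random
effects is found per subject, the model is linearized about it
(``G`` = gradient of the log-predictions in eta), and the subject's
contribution to the objective function value is

    OFV_i = n_i ln(2 pi) + ln|V_i| + r_i' V_i^{-1} r_i,
    V_i = G Omega G' + sigma^2 I,   r_i = y_i - f(eta_hat) + G eta_hat,

with ``y`` the log observations.  Because the residual is additive on
the log scale (homoscedastic in transformed space) no interaction term
arises.  The total OFV is the sum over subjects, on the
log-transformed-data scale.

Implementation notes: all subjects are advanced simultaneously through
a damped Newton inner optimization on padded (patient x observation x
dose) tensors; the absorption-rate exponentials are precomputed once
per dataset since ka is fixed.  The outer optimization works on
log-transformed positive parameters: an L-BFGS-B stage with
finite-difference gradients, then an optional Nelder-Mead verification
pass and quasi-Newton polish.  Standard errors come from a
central-difference Hessian of the OFV on the natural parameter scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .data_model import PatientRecord
from .pk_model import IndividualParameters, PopulationModel, typical_clearance

__all__ = [
    "FitResult",
    "MapResult",
    "CompiledDataset",
    "compile_dataset",
    "objective_function",
    "fit_population",
    "map_individual",
]

logger = logging.getLogger(__name__)

_ETA_CLAMP = 8.0          # |eta| beyond this is physiologically absurd
_PRIOR_PRECISION_CAP = 1e12   # used when an omega^2 is (numerically) zero
_INNER_GTOL = 1e-6
_INNER_MAXITER = 80


class EstimationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Dataset compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledDataset:
    """Padded tensor view of a cohort for vectorized likelihood work."""

    patient_ids: list[str]
    n_obs: np.ndarray            # (P,) usable observations per patient
    obs_mask: np.ndarray         # (P, O) bool
    log_obs: np.ndarray          # (P, O) ln(conc)
    dt: np.ndarray               # (P, O, D) time since dose, clipped at 0
    active: np.ndarray           # (P, O, D) dose administered before obs
    amounts: np.ndarray          # (P, D) mg
    eka: np.ndarray              # (P, O) sum_d amt * exp(-ka dt) over active
    covariate_values: np.ndarray  # (P, K) per-patient covariate summary
    covariate_names: list[str]
    ka: float

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def total_obs(self) -> int:
        return int(self.n_obs.sum())


def _patient_covariate_summary(record: PatientRecord, name: str) -> float:
    values = [float(getattr(p, name)) for p in record.covariates]
    mean = float(np.nanmean(values))
    if np.isnan(mean):
        raise EstimationError(
            f"patient {record.patient_id}: covariate {name!r} entirely missing"
        )
    return mean


def compile_dataset(
    records: Sequence[PatientRecord],
    covariate_names: Sequence[str] = (),
    ka: float = 3.86,
) -> CompiledDataset:
    """Pack a cohort into padded arrays; censored troughs are excluded."""
    usable = [rec.usable_observations for rec in records]
    for rec, obs in zip(records, usable):
        if not obs:
            raise EstimationError(
                f"patient {rec.patient_id} has no usable (in-range) observation"
            )
    P = len(records)
    O = max(len(obs) for obs in usable)
    D = max(len(rec.doses) for rec in records)
    obs_mask = np.zeros((P, O), dtype=bool)
    log_obs = np.zeros((P, O))
    dt = np.zeros((P, O, D))
    active = np.zeros((P, O, D), dtype=bool)
    amounts = np.zeros((P, D))
    cov = np.zeros((P, len(covariate_names)))
    for p, (rec, obs) in enumerate(zip(records, usable)):
        n_o, n_d = len(obs), len(rec.doses)
        obs_mask[p, :n_o] = True
        log_obs[p, :n_o] = np.log([o.conc for o in obs])
        t_obs = np.array([o.time for o in obs])
        t_dose = np.array([d.time for d in rec.doses])
        amounts[p, :n_d] = [d.amount for d in rec.doses]
        delta = t_obs[:, None] - t_dose[None, :]
        act = delta >= 0
        dt[p, :n_o, :n_d] = np.where(act, delta, 0.0)
        active[p, :n_o, :n_d] = act
        for k, name in enumerate(covariate_names):
            cov[p, k] = _patient_covariate_summary(rec, name)
    eka = np.einsum("pod,pd->po", np.exp(-ka * dt) * active, amounts)
    return CompiledDataset(
        patient_ids=[rec.patient_id for rec in records],
        n_obs=obs_mask.sum(axis=1),
        obs_mask=obs_mask,
        log_obs=log_obs,
        dt=dt,
        active=active,
        amounts=amounts,
        eka=eka,
        covariate_values=cov,
        covariate_names=list(covariate_names),
        ka=ka,
    )


# ---------------------------------------------------------------------------
# Vectorized predictions
# ---------------------------------------------------------------------------

def _log_predictions(
    data: CompiledDataset,
    v: np.ndarray,
    cl: np.ndarray,
    want_jacobian: bool = False,
    want_curvature: bool = False,
):
    """Log-predictions (P, O), optionally with eta-derivatives.

    Derivatives follow from ke = CL/V: d ke/d eta_cl = ke,
    d ke/d eta_v = -ke, and d ln C/d V = -1/V (direct volume scale).
    The eta-Hessian of each log-prediction has the rank-one pattern
    ``m * [[1, -1], [-1, 1]]`` with ``m = g'' ke^2 + g' ke`` where
    ``g(ke) = -ln(ka - ke) + ln S(ke)`` and S is the superposition sum;
    ``want_curvature`` additionally returns that scalar field (P, O).
    """
    ka = data.ka
    ke = cl / v
    ke = np.minimum(ke, ka - 1e-6)  # keep absorption faster than elimination
    expo = np.exp(-ke[:, None, None] * data.dt) * data.active
    t_ke = np.einsum("pod,pd->po", expo, data.amounts)
    shape = t_ke - data.eka  # sum_d amt (e^{-ke dt} - e^{-ka dt})
    # near the ke -> ka clamp the bracket can cancel to <= 0; floor it so
    # the log stays finite (the resulting huge objective steers the
    # optimizer away without breaking a line search)
    shape = np.maximum(shape, 1e-300)
    coef = 1000.0 * ka / ((ka - ke) * v)
    conc = coef[:, None] * shape
    bad = ~np.isfinite(conc) & data.obs_mask
    if bad.any():
        p, o = map(int, np.argwhere(bad)[0])
        raise EstimationError(
            f"non-finite prediction for patient {data.patient_ids[p]} at "
            f"observation index {o}"
        )
    with np.errstate(divide="ignore"):
        log_pred = np.where(data.obs_mask, np.log(np.maximum(conc, 1e-300)), 0.0)
    if not want_jacobian:
        return log_pred, None, None
    safe_shape = np.where(shape > 1e-290, shape, 1.0)
    wdt = expo * data.dt
    t2 = np.einsum("pod,pd->po", wdt, data.amounts)
    # derivative magnitudes beyond ~1e6 only occur at the degenerate
    # floor; clip them so downstream squares cannot overflow
    with np.errstate(invalid="ignore", divide="ignore"):
        gprime = np.clip(1.0 / (ka - ke)[:, None] - t2 / safe_shape, -1e6, 1e6)
    j_cl = ke[:, None] * gprime
    j_v = -1.0 - j_cl
    if not want_curvature:
        return log_pred, j_v * data.obs_mask, j_cl * data.obs_mask
    t3 = np.einsum("pod,pd->po", wdt * data.dt, data.amounts)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        gsecond = np.clip(
            1.0 / (ka - ke)[:, None] ** 2 + t3 / safe_shape - (t2 / safe_shape) ** 2,
            -1e9,
            1e9,
        )
    curv = (gsecond * ke[:, None] ** 2 + gprime * ke[:, None]) * data.obs_mask
    return log_pred, j_v * data.obs_mask, j_cl * data.obs_mask, curv


def _individual_params(
    data: CompiledDataset, model: PopulationModel, eta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(V_i, CL_i) arrays for every patient at the given etas."""
    log_cl = np.full(data.n_patients, np.log(model.theta_cl))
    for k, name in enumerate(data.covariate_names):
        beta = model.covariates.get(name, 0.0)
        log_cl += beta * data.covariate_values[:, k]
    log_cl += np.clip(eta[:, 1], -_ETA_CLAMP, _ETA_CLAMP)
    v = model.theta_v * np.exp(np.clip(eta[:, 0], -_ETA_CLAMP, _ETA_CLAMP))
    cl = np.exp(np.clip(log_cl, -600.0, 600.0))
    return v, cl


# ---------------------------------------------------------------------------
# Inner (conditional-mode) optimization
# ---------------------------------------------------------------------------

def _prior_precision(model: PopulationModel) -> np.ndarray:
    return np.array(
        [
            min(1.0 / max(model.omega2_v, 1e-300), _PRIOR_PRECISION_CAP),
            min(1.0 / max(model.omega2_cl, 1e-300), _PRIOR_PRECISION_CAP),
        ]
    )


def _inner_objective(
    data: CompiledDataset, model: PopulationModel, eta: np.ndarray
) -> np.ndarray:
    v, cl = _individual_params(data, model, eta)
    f, _, _ = _log_predictions(data, v, cl)
    resid = (data.log_obs - f) * data.obs_mask
    w = _prior_precision(model)
    return (resid**2).sum(axis=1) / model.sigma2 + (eta**2) @ w


def _solve_inner(
    data: CompiledDataset,
    model: PopulationModel,
    eta0: np.ndarray | None = None,
) -> np.ndarray:
    """Conditional modes eta_hat for every patient (damped Gauss-Newton)."""
    P = data.n_patients
    eta = np.zeros((P, 2)) if eta0 is None else np.clip(eta0, -_ETA_CLAMP, _ETA_CLAMP).copy()
    w = _prior_precision(model)
    s2 = model.sigma2
    # the gradient carries a 1/sigma^2 scale; keep the tolerance above
    # floating-point noise when sigma^2 is (numerically) tiny
    gtol = _INNER_GTOL * max(1.0, 1e-6 / s2)
    obj = _inner_objective(data, model, eta)
    for _ in range(_INNER_MAXITER):
        v, cl = _individual_params(data, model, eta)
        f, j_v, j_cl, curv = _log_predictions(
            data, v, cl, want_jacobian=True, want_curvature=True
        )
        resid = (data.log_obs - f) * data.obs_mask
        g_v = -2.0 / s2 * (resid * j_v).sum(axis=1) + 2.0 * w[0] * eta[:, 0]
        g_cl = -2.0 / s2 * (resid * j_cl).sum(axis=1) + 2.0 * w[1] * eta[:, 1]
        grad = np.stack([g_v, g_cl], axis=1)
        if np.abs(grad).max() < gtol:
            break
        # Gauss-Newton pieces plus the exact curvature correction
        gn_vv = 2.0 / s2 * (j_v * j_v).sum(axis=1) + 2.0 * w[0]
        gn_cc = 2.0 / s2 * (j_cl * j_cl).sum(axis=1) + 2.0 * w[1]
        gn_vc = 2.0 / s2 * (j_v * j_cl).sum(axis=1)
        rm = (resid * curv).sum(axis=1)  # sum_o r_o m_o
        h_vv = gn_vv - 2.0 / s2 * rm
        h_cc = gn_cc - 2.0 / s2 * rm
        h_vc = gn_vc + 2.0 / s2 * rm
        # fall back to Gauss-Newton where the exact Hessian is not SPD
        spd = (h_vv > 0) & (h_vv * h_cc - h_vc**2 > 0)
        h_vv = np.where(spd, h_vv, gn_vv)
        h_cc = np.where(spd, h_cc, gn_cc)
        h_vc = np.where(spd, h_vc, gn_vc)
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            det = h_vv * h_cc - h_vc**2
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            step_v = -(h_cc * g_v - h_vc * g_cl) / det
            step_c = -(h_vv * g_cl - h_vc * g_v) / det
        step = np.stack([step_v, step_c], axis=1)
        step = np.nan_to_num(step, nan=0.0, posinf=0.0, neginf=0.0)
        norm = np.maximum(np.abs(step).max(axis=1, keepdims=True), 1e-300)
        with np.errstate(invalid="ignore", over="ignore"):
            step = np.where(norm > 2.0, step * (2.0 / norm), step)
        # backtracking where the step fails to decrease the objective
        alpha = np.ones(P)
        improved = np.zeros(P, dtype=bool)
        new_eta = eta.copy()
        new_obj = obj.copy()
        for _ls in range(10):
            trial = np.clip(eta + alpha[:, None] * step, -_ETA_CLAMP, _ETA_CLAMP)
            trial_obj = _inner_objective(data, model, trial)
            accept = (trial_obj <= obj + 1e-12) & ~improved
            new_eta[accept] = trial[accept]
            new_obj[accept] = trial_obj[accept]
            improved |= accept
            if improved.all():
                break
            alpha = np.where(improved, alpha, alpha * 0.5)
        if not improved.any():
            break
        moved = np.abs(new_eta - eta).max()
        eta, obj = new_eta, new_obj
        if moved < 1e-10:
            break
    return eta


# ---------------------------------------------------------------------------
# FOCE objective
# ---------------------------------------------------------------------------

def _foce_terms(data: CompiledDataset, model: PopulationModel, eta: np.ndarray):
    """Per-patient OFV contributions and the linearization pieces."""
    v, cl = _individual_params(data, model, eta)
    f, j_v, j_cl = _log_predictions(data, v, cl, want_jacobian=True)
    mask = data.obs_mask
    r = (data.log_obs - f) * mask + j_v * eta[:, 0:1] + j_cl * eta[:, 1:2]
    omega = np.diag([model.omega2_v, model.omega2_cl])
    s2 = model.sigma2
    # build each patient's linearized marginal covariance explicitly
    # (V = sigma^2 I + A A' with A = G Omega^{1/2}) and factor it; at
    # <= ~17 observations per subject the batched O(O^3) Cholesky is
    # cheap and, unlike a 2x2 Woodbury shortcut, never suffers the
    # catastrophic cancellation that would fake a negative quadratic form
    sq = np.sqrt(np.diag(omega))
    a = np.stack([j_v * sq[0], j_cl * sq[1]], axis=2)  # (P, O, 2)
    cov = np.matmul(a, a.transpose(0, 2, 1))
    O = cov.shape[1]
    diag = np.arange(O)
    cov[:, diag, diag] += np.where(mask, s2, 1.0)  # padded rows -> identity
    pad = ~mask
    cov *= ~(pad[:, :, None] | pad[:, None, :])
    cov[:, diag, diag] = np.where(mask, cov[:, diag, diag], 1.0)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "linearized covariance lost positive definiteness"
        ) from exc
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
    x = np.linalg.solve(cov, r[:, :, None])[:, :, 0]
    quad = np.maximum((r * x).sum(axis=1), 0.0)
    contrib = data.n_obs * np.log(2.0 * np.pi) + logdet + quad
    return contrib, f, j_v, j_cl, r


def objective_function(
    records_or_data: "Sequence[PatientRecord] | CompiledDataset",
    model: PopulationModel,
    eta0: np.ndarray | None = None,
    return_eta: bool = False,
):
    """FOCE objective function value (-2 log marginal likelihood).

    Deterministic given data and model.  Accepts either raw records or a
    pre-compiled dataset (the covariate summary must then match the
    model's covariate set).
    """
    data = _as_compiled(records_or_data, model)
    eta = _solve_inner(data, model, eta0)
    contrib, *_ = _foce_terms(data, model, eta)
    ofv = float(contrib.sum())
    if return_eta:
        return ofv, eta
    return ofv


def _as_compiled(
    records_or_data: "Sequence[PatientRecord] | CompiledDataset", model: PopulationModel
) -> CompiledDataset:
    if isinstance(records_or_data, CompiledDataset):
        data = records_or_data
        missing = [c for c in model.covariates if c not in data.covariate_names]
        if missing:
            raise EstimationError(
                f"compiled dataset lacks covariate column(s) {missing}"
            )
        return data
    return compile_dataset(records_or_data, list(model.covariates), ka=model.ka)


# ---------------------------------------------------------------------------
# Population fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, uncertainty and per-subject empirical-Bayes output."""

    estimates: PopulationModel
    rse_pct: dict[str, float]
    ofv: float
    converged: bool
    ebes: dict[str, IndividualParameters]
    ipre: dict[str, np.ndarray]   # ng/mL, individual (eta = eta_hat)
    pred: dict[str, np.ndarray]   # ng/mL, population (eta = 0)
    n_evaluations: int = 0

    @property
    def iiv_cv_pct(self) -> dict[str, float]:
        """Inter-individual variability reported as CV% = 100 sqrt(omega^2)."""
        return {
            "v_f": 100.0 * float(np.sqrt(self.estimates.omega2_v)),
            "cl_f": 100.0 * float(np.sqrt(self.estimates.omega2_cl)),
        }

    @property
    def residual_sd_pct(self) -> float:
        """Log-scale residual SD expressed as a percentage."""
        return 100.0 * float(np.sqrt(self.estimates.sigma2))


def _pack(model: PopulationModel) -> tuple[np.ndarray, list[str]]:
    names = (
        ["theta_v", "theta_cl"]
        + [f"beta_{c}" for c in model.covariates]
        + ["omega2_v", "omega2_cl", "sigma2"]
    )
    values = np.array(
        [np.log(model.theta_v), np.log(model.theta_cl)]
        + [model.covariates[c] for c in model.covariates]
        + [
            np.log(max(model.omega2_v, 1e-10)),
            np.log(max(model.omega2_cl, 1e-10)),
            np.log(model.sigma2),
        ]
    )
    return values, names


def _unpack(psi: np.ndarray, template: PopulationModel) -> PopulationModel:
    names = list(template.covariates)
    k = len(names)
    model = template.copy()
    model.theta_v = float(np.exp(psi[0]))
    model.theta_cl = float(np.exp(psi[1]))
    model.covariates = {c: float(psi[2 + i]) for i, c in enumerate(names)}
    model.omega2_v = float(np.exp(psi[2 + k]))
    model.omega2_cl = float(np.exp(psi[3 + k]))
    model.sigma2 = float(np.exp(psi[4 + k]))
    return model


def fit_population(
    records: Sequence[PatientRecord],
    model_spec: PopulationModel,
    init: PopulationModel | None = None,
    options: dict | None = None,
) -> FitResult:
    """Fit the population model by FOCE.

    ``model_spec`` fixes the structure (ka, covariate set) and supplies
    default initial values; ``init`` overrides them.  Positivity of
    thetas and variances is enforced by log-parameterization.  On
    failure to converge the best point found is returned with
    ``converged=False`` (never an exception).

    Options: ``maxiter`` (Nelder-Mead iteration cap), ``compute_rse``
    (default True), ``polish`` (L-BFGS-B refinement, default True),
    ``ftol`` (relative OFV tolerance, default 1e-4).
    """
    opts = {
        "maxiter": 2500,
        "compute_rse": True,
        "polish": True,
        "ftol": 1e-4,
        "xatol": 1e-4,
        "nm_verify": True,
    }
    if options:
        opts.update(options)
    start = (init or model_spec).copy()
    start.covariates = {
        c: (init.covariates.get(c, 0.0) if init else model_spec.covariates.get(c, 0.0))
        for c in model_spec.covariates
    }
    start.ka = model_spec.ka
    data = compile_dataset(records, list(model_spec.covariates), ka=model_spec.ka)
    psi0, names = _pack(start)
    eta_warm = {"eta": np.zeros((data.n_patients, 2))}
    n_eval = {"n": 0}

    # scale-aware bounds: a covariate coefficient is capped so that its
    # effect over the observed covariate range stays within e^{+-50};
    # variances and thetas get physiological sanity limits that keep the
    # search away from degenerate flat regions of the approximation
    bounds: list[tuple[float, float]] = []
    cov_names = list(model_spec.covariates)
    for name in names:
        if name.startswith("beta_"):
            k = cov_names.index(name[len("beta_"):])
            span = float(np.max(np.abs(data.covariate_values[:, k]))) or 1.0
            cap = min(25.0, 50.0 / span)
            bounds.append((-cap, cap))
        elif name.startswith(("omega2", "sigma2")):
            # log-scale variances above e^2 (CV far beyond 250%) are
            # unphysical for trough data
            bounds.append((-25.0, 2.0))
        else:
            # thetas between e^-3 and e^12 cover any plausible V/F or CL/F
            bounds.append((-3.0, 12.0))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    psi0 = np.clip(psi0, lo, hi)

    eta_warm["best"] = np.inf

    def ofv_of(psi: np.ndarray) -> float:
        # the inner modes are warm-started from the BEST point seen so
        # far (never from the last evaluation): a line-search excursion
        # must not poison later evaluations, or the outer objective
        # becomes history-dependent and derails quasi-Newton steps
        n_eval["n"] += 1
        psi = np.asarray(psi, dtype=float)
        clipped = np.clip(psi, lo, hi)
        penalty = 1e4 * float(np.sum((psi - clipped) ** 2))
        try:
            model = _unpack(clipped, start)
            eta = _solve_inner(data, model, eta_warm["eta"])
            contrib, *_ = _foce_terms(data, model, eta)
            value = float(contrib.sum())
            if not np.isfinite(value):
                return 1e10
            if value < eta_warm["best"]:
                eta_warm["best"] = value
                eta_warm["eta"] = eta
            return value + penalty
        except (EstimationError, FloatingPointError, ValueError):
            return 1e10
    # stage 1: quasi-Newton with finite-difference gradients (the warm
    # inner start makes adjacent evaluations cheap and smooth)
    qn = optimize.minimize(
        ofv_of,
        psi0,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": 150,
            "maxfun": 600,
            "ftol": 1e-11,
            "gtol": 1e-3,
            "eps": 1e-6,
        },
    )
    psi_best, ofv_best, converged = qn.x, float(qn.fun), bool(qn.success)
    # stage 2: simplex verification escapes any finite-difference artifact
    if opts["nm_verify"]:
        nm = optimize.minimize(
            ofv_of,
            psi_best,
            method="Nelder-Mead",
            options={
                "maxiter": opts["maxiter"],
                "xatol": opts["xatol"],
                "fatol": opts["ftol"],
                "adaptive": True,
            },
        )
        if np.isfinite(nm.fun) and nm.fun <= ofv_best + 1e-9:
            moved = float(np.max(np.abs(nm.x - psi_best)))
            psi_best, ofv_best = nm.x, float(nm.fun)
            converged = converged or bool(nm.success)
            if opts["polish"] and moved > 1e-3:
                pol = optimize.minimize(
                    ofv_of,
                    psi_best,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={
                        "maxiter": 40,
                        "maxfun": 200,
                        "ftol": 1e-11,
                        "gtol": 1e-3,
                        "eps": 1e-6,
                    },
                )
                if np.isfinite(pol.fun) and pol.fun <= ofv_best + 1e-9:
                    psi_best, ofv_best = pol.x, float(pol.fun)
                    converged = converged or bool(pol.success)

    if not converged:
        # gradient-norm criterion on the transformed scale: a slope of
        # ~10 OFV units per unit log-parameter corresponds to an OFV
        # misconvergence far below likelihood-ratio relevance
        grad = np.empty(len(psi_best))
        for i in range(len(psi_best)):
            step = np.zeros(len(psi_best))
            step[i] = 1e-4
            grad[i] = (ofv_of(psi_best + step) - ofv_of(psi_best - step)) / 2e-4
        converged = bool(np.max(np.abs(grad)) < 10.0)

    final = _unpack(psi_best, start)
    eta_hat = _solve_inner(data, final, eta_warm["eta"])

    rse: dict[str, float] = {}
    if opts["compute_rse"]:
        rse = _rse_from_hessian(data, final, names, eta_hat)

    # empirical-Bayes output on the full record list (incl. predictions)
    ebes: dict[str, IndividualParameters] = {}
    ipre: dict[str, np.ndarray] = {}
    pred: dict[str, np.ndarray] = {}
    v, cl = _individual_params(data, final, eta_hat)
    f_ind, _, _ = _log_predictions(data, v, cl)
    v0, cl0 = _individual_params(data, final, np.zeros_like(eta_hat))
    f_pop, _, _ = _log_predictions(data, v0, cl0)
    for p, pid in enumerate(data.patient_ids):
        n_o = int(data.n_obs[p])
        ebes[pid] = IndividualParameters(
            eta_v=float(eta_hat[p, 0]),
            eta_cl=float(eta_hat[p, 1]),
            v_f=float(v[p]),
            cl_f=float(cl[p]),
        )
        ipre[pid] = np.exp(f_ind[p, :n_o])
        pred[pid] = np.exp(f_pop[p, :n_o])
    return FitResult(
        estimates=final,
        rse_pct=rse,
        ofv=ofv_best,
        converged=converged,
        ebes=ebes,
        ipre=ipre,
        pred=pred,
        n_evaluations=n_eval["n"],
    )


def _natural_vector(model: PopulationModel) -> tuple[np.ndarray, list[str]]:
    names = (
        ["theta_v", "theta_cl"]
        + [f"beta_{c}" for c in model.covariates]
        + ["omega2_v", "omega2_cl", "sigma2"]
    )
    values = np.array(
        [model.theta_v, model.theta_cl]
        + list(model.covariates.values())
        + [model.omega2_v, model.omega2_cl, model.sigma2]
    )
    return values, names


def _model_from_natural(values: np.ndarray, template: PopulationModel) -> PopulationModel:
    names = list(template.covariates)
    k = len(names)
    model = template.copy()
    model.theta_v = float(abs(values[0]))
    model.theta_cl = float(abs(values[1]))
    model.covariates = {c: float(values[2 + i]) for i, c in enumerate(names)}
    model.omega2_v = float(max(values[2 + k], 0.0))
    model.omega2_cl = float(max(values[3 + k], 0.0))
    model.sigma2 = float(max(values[4 + k], 1e-12))
    return model


def _rse_from_hessian(
    data: CompiledDataset,
    model: PopulationModel,
    names: list[str],
    eta_warm: np.ndarray,
) -> dict[str, float]:
    """RSE% = 100 SE / |estimate| via a central-difference OFV Hessian.

    The OFV is -2 log L, so the parameter covariance is 2 H^{-1}.
    """
    p0, nat_names = _natural_vector(model)
    k = len(p0)
    steps = np.maximum(np.abs(p0), 1e-4) * 1e-4

    def f(vec: np.ndarray) -> float:
        m = _model_from_natural(vec, model)
        try:
            eta = _solve_inner(data, m, eta_warm)
            contrib, *_ = _foce_terms(data, m, eta)
            return float(contrib.sum())
        except (EstimationError, FloatingPointError):
            return np.nan

    f0 = f(p0)
    hess = np.full((k, k), np.nan)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        hess[i, i] = (f(p0 + ei) - 2 * f0 + f(p0 - ei)) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            hess[i, j] = hess[j, i] = (
                f(p0 + ei + ej) - f(p0 + ei - ej) - f(p0 - ei + ej) + f(p0 - ei - ej)
            ) / (4 * steps[i] * steps[j])
    rse: dict[str, float] = {}
    try:
        cov = 2.0 * np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        for name, s, est in zip(nat_names, se, p0):
            rse[name] = float(100.0 * s / abs(est)) if est != 0 else float("nan")
    except np.linalg.LinAlgError:
        logger.warning("OFV Hessian not invertible; RSE unavailable")
        rse = {name: float("nan") for name in nat_names}
    return rse


# ---------------------------------------------------------------------------
# MAP (POSTHOC) individual estimation
# ---------------------------------------------------------------------------

@dataclass
class MapResult:
    params: IndividualParameters
    ipre: np.ndarray       # ng/mL at the usable observation times
    prior_only: bool = False


def map_individual(record: PatientRecord, model: PopulationModel) -> MapResult:
    """MAP (empirical-Bayes) eta for one subject under a fixed model.

    Minimizes the penalized log-scale least squares
    ``sum (ln C_obs - ln C_pred(eta))^2 / sigma^2 + eta' Omega^{-1} eta``.
    With no usable observations the prior mode (eta = 0) is returned and
    flagged.
    """
    if not record.usable_observations:
        cl = typical_clearance(model, record.covariates[0]) if model.covariates else model.theta_cl
        params = IndividualParameters(0.0, 0.0, model.theta_v, cl)
        return MapResult(params=params, ipre=np.array([]), prior_only=True)
    data = compile_dataset([record], list(model.covariates), ka=model.ka)
    eta = _solve_inner(data, model)
    v, cl = _individual_params(data, model, eta)
    f, _, _ = _log_predictions(data, v, cl)
    n_o = int(data.n_obs[0])
    params = IndividualParameters(
        eta_v=float(eta[0, 0]),
        eta_cl=float(eta[0, 1]),
        v_f=float(v[0]),
        cl_f=float(cl[0]),
    )
    return MapResult(params=params, ipre=np.exp(f[0, :n_o]), prior_only=False)
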
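"""One-compartment oral PK model with exponential covariate effects.

Structural model
----------------
Tacrolimus troughs are described by a one-compartment model with
first-order absorption (rate constant ``ka``, fixed) and first-order
elimination.  Because only pre-dose concentrations are available,
bioavailability F is absorbed into the apparent parameters V/F and CL/F.

Between-subject variability is exponential, ``P_i = TVP * exp(eta_i)``
with ``eta ~ N(0, omega^2)`` on V/F and CL/F, and the residual error is
additive on the log-concentration scale, ``ln C_obs = ln C_pred + eps``
with ``eps ~ N(0, sigma^2)``.

The typical clearance carries exponential-linear covariate effects; the
shipped ``final`` preset uses the CYP3A5 *3 allele count (0/1/2) and the
hematocrit fraction:

    CL/F = theta_CL * exp(beta_cyp * CYP3A5) * exp(beta_hct * HCT)

Units: dose mg, V/F in L, so amount/volume is mg/L == ug/mL; predictions
are multiplied by 1000 to report ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import CovariatePanel, DosingEvent

__all__ = [
    "PopulationModel",
    "IndividualParameters",
    "typical_clearance",
    "individualize",
    "predict_concentration",
    "structural_preset",
    "final_preset",
]

#: mg/L -> ng/mL
UNIT_SCALE = 1000.0

#: below this |ka - ke| the limiting (ka -> ke) form of the absorption
#: term is used to avoid catastrophic cancellation
KA_KE_EPSILON = 1e-8


@dataclass
class PopulationModel:
    """Population (typical) parameters, covariate coefficients and variances.

    ``covariates`` maps a :class:`~tacppk.data_model.CovariatePanel`
    field name to its exponential-linear coefficient on CL/F.  An empty
    map is the covariate-free ("basic") model.
    """

    ka: float = 3.86               # 1/h, fixed during estimation
    theta_v: float = 2560.0        # L
    theta_cl: float = 70.6         # L/h
    covariates: dict[str, float] = field(default_factory=dict)
    omega2_v: float = 0.4225       # variance of eta on V/F
    omega2_cl: float = 0.0529      # variance of eta on CL/F
    sigma2: float = 0.126736       # variance of log-scale residual

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.theta_v <= 0 or self.theta_cl <= 0:
            raise ValueError("ka, theta_v and theta_cl must be positive")
        if self.omega2_v < 0 or self.omega2_cl < 0 or self.sigma2 <= 0:
            raise ValueError("omega2_* must be >= 0 and sigma2 > 0")

    def copy(self) -> "PopulationModel":
        return replace(self, covariates=dict(self.covariates))


@dataclass(frozen=True)
class IndividualParameters:
    """Subject-level parameters implied by a model and an eta pair."""

    eta_v: float
    eta_cl: float
    v_f: float
    cl_f: float

    @property
    def ke(self) -> float:
        return self.cl_f / self.v_f


def _covariate_value(covariates: CovariatePanel | dict, name: str) -> float:
    if isinstance(covariates, dict):
        return float(covariates[name])
    return float(getattr(covariates, name))


def typical_clearance(
    model: PopulationModel, covariates: CovariatePanel | dict | None = None, **overrides: float
) -> float:
    """Typical (population) CL/F for a covariate combination, L/h.

    Covariate values may come from a panel/dict and/or keyword overrides,
    e.g. ``typical_clearance(model, cyp3a5_code=2, hct=0.29)``.  With the
    final preset's coefficients this evaluates
    ``70.6 * exp(-0.348 * code) * exp(-0.122 * hct)``.
    """
    log_cl = np.log(model.theta_cl)
    for name, beta in model.covariates.items():
        if name in overrides:
            value = float(overrides[name])
        elif covariates is not None:
            value = _covariate_value(covariates, name)
        else:
            raise ValueError(f"no value supplied for covariate {name!r}")
        if name == "cyp3a5_code" and value not in (0, 1, 2):
            raise ValueError(f"cyp3a5_code must be 0, 1 or 2, got {value}")
        log_cl += beta * value
    return float(np.exp(log_cl))


def individualize(
    model: PopulationModel,
    covariates: CovariatePanel | dict | None,
    eta_v: float = 0.0,
    eta_cl: float = 0.0,
    **overrides: float,
) -> IndividualParameters:
    """Subject parameters ``P_i = TVP * exp(eta_i)``; eta = 0 gives the
    covariate-adjusted typical values exactly."""
    v_f = model.theta_v * float(np.exp(eta_v))
    cl_f = typical_clearance(model, covariates, **overrides) * float(np.exp(eta_cl))
    return IndividualParameters(eta_v=eta_v, eta_cl=eta_cl, v_f=v_f, cl_f=cl_f)


def predict_concentration(
    ind: IndividualParameters,
    ka: float,
    doses: "list[DosingEvent] | np.ndarray",
    t: "float | np.ndarray",
) -> "float | np.ndarray":
    """Concentration (ng/mL) at time(s) ``t`` by superposition of doses.

    Each dose contributes the standard first-order absorption term

        (amt / V) * ka/(ka - ke) * (exp(-ke*dt) - exp(-ka*dt)),  dt >= 0,

    scaled to ng/mL.  Doses after ``t`` contribute nothing.  When
    ``|ka - ke|`` underflows the limiting form ``(amt/V)*ka*dt*exp(-ka*dt)``
    is used.
    """
    if isinstance(doses, np.ndarray):
        dose_times = doses[:, 0]
        dose_amts = doses[:, 1]
    else:
        dose_times = np.array([d.time for d in doses], dtype=float)
        dose_amts = np.array([d.amount for d in doses], dtype=float)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    ke = ind.ke
    dt = t_arr[:, None] - dose_times[None, :]
    active = dt >= 0
    dt = np.where(active, dt, 0.0)
    if abs(ka - ke) < KA_KE_EPSILON:
        shape = ka * dt * np.exp(-ka * dt)
    else:
        shape = ka / (ka - ke) * (np.exp(-ke * dt) - np.exp(-ka * dt))
    conc = UNIT_SCALE / ind.v_f * (shape * active) @ dose_amts
    conc = np.maximum(conc, 0.0)
    return float(conc[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else conc


def structural_preset() -> PopulationModel:
    """Covariate-free (basic/structural) model parameters."""
    return PopulationModel(
        ka=3.86,
        theta_v=2620.0,
        theta_cl=41.1,
        covariates={},
        omega2_v=0.736**2,
        omega2_cl=0.318**2,
        sigma2=0.377**2,
    )


def final_preset() -> PopulationModel:
    """Final covariate model: CYP3A5 allele count and HCT on CL/F."""
    return PopulationModel(
        ka=3.86,
        theta_v=2560.0,
        theta_cl=70.6,
        covariates={"cyp3a5_code": -0.348, "hct": -0.122},
        omega2_v=0.65**2,
        omega2_cl=0.23**2,
        sigma2=0.356**2,
    )
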
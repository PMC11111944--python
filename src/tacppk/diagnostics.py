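"""Goodness-of-fit residuals, visual predictive check and error metrics.

``cwres`` implements conditional weighted residuals under the FOCE
linearization: per subject the residual vector

    r = ln C_obs - ln C_pred(eta_hat) + G eta_hat

is standardized by the inverse matrix square root of the linearized
marginal covariance ``G Omega G' + sigma^2 I``.  Under a correctly
specified model CWRES are approximately standard normal.

``vpc`` resimulates the whole design (same doses, times and covariates;
fresh etas and residuals) many times and compares observed percentiles
with the simulated percentile bands, binned by postoperative day.

``prediction_error_report`` collects the agreement metrics used
throughout: MAE, MAPE%, RMSE, R^2, plus the signed mean percentage
error (MPE, with a normal-approximation 95% CI) and the root mean
squared relative error (MRSE%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import PatientRecord
from .estimation import (
    FitResult,
    _individual_params,
    _log_predictions,
    _solve_inner,
    compile_dataset,
)
from .pk_model import PopulationModel

__all__ = ["PredictionErrorReport", "VPCResult", "cwres", "vpc", "prediction_error_report"]


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionErrorReport:
    """Agreement metrics between observed and predicted concentrations."""

    mae: float            # ng/mL
    mape_pct: float       # %
    rmse: float           # ng/mL
    r2: float
    mpe_pct: float        # signed mean relative error, %
    mpe_ci: tuple[float, float]   # normal-approximation 95% CI on MPE
    mrse_pct: float       # root mean squared relative error, %
    n: int

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mape_pct": self.mape_pct,
            "rmse": self.rmse,
            "r2": self.r2,
            "mpe_pct": self.mpe_pct,
            "mpe_ci": list(self.mpe_ci),
            "mrse_pct": self.mrse_pct,
            "n": self.n,
        }


def prediction_error_report(
    obs: Sequence[float], pred: Sequence[float]
) -> PredictionErrorReport:
    """Compute MAE, MAPE%, RMSE, R^2, MPE% (95% CI) and MRSE%.

    Relative metrics divide by the observation, so any zero observation
    is an error rather than a silent infinity.
    """
    y = np.asarray(obs, dtype=float)
    yhat = np.asarray(pred, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("obs and pred must be equal-length 1-D vectors")
    if y.size == 0:
        raise ValueError("empty vectors")
    if np.any(y == 0):
        raise ValueError("zero observation: relative metrics undefined")
    err = yhat - y
    rel = err / y
    mae = float(np.mean(np.abs(err)))
    mape = float(np.mean(np.abs(rel)) * 100.0)
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant observations: R^2 undefined, reported as 0")
        r2 = 0.0
    else:
        r2 = float(1.0 - np.sum(err**2) / ss_tot)
    mpe = float(np.mean(rel) * 100.0)
    se = float(np.std(rel, ddof=1) / np.sqrt(y.size) * 100.0) if y.size > 1 else 0.0
    mrse = float(np.sqrt(np.mean(rel**2)) * 100.0)
    return PredictionErrorReport(
        mae=mae,
        mape_pct=mape,
        rmse=rmse,
        r2=r2,
        mpe_pct=mpe,
        mpe_ci=(mpe - 1.96 * se, mpe + 1.96 * se),
        mrse_pct=mrse,
        n=int(y.size),
    )


# ---------------------------------------------------------------------------
# CWRES
# ---------------------------------------------------------------------------

def cwres(records: Sequence[PatientRecord], fit: FitResult) -> dict[str, np.ndarray]:
    """Conditional weighted residuals per patient (one value per usable
    observation), under the FOCE linearization at the empirical-Bayes
    etas of ``fit``."""
    model = fit.estimates
    data = compile_dataset(records, list(model.covariates), ka=model.ka)
    eta = np.array(
        [
            [fit.ebes[pid].eta_v, fit.ebes[pid].eta_cl] if pid in fit.ebes else [0.0, 0.0]
            for pid in data.patient_ids
        ]
    )
    eta = _solve_inner(data, model, eta)
    v, cl = _individual_params(data, model, eta)
    f, j_v, j_cl = _log_predictions(data, v, cl, want_jacobian=True)
    omega = np.diag([model.omega2_v, model.omega2_cl])
    out: dict[str, np.ndarray] = {}
    for p, pid in enumerate(data.patient_ids):
        n_o = int(data.n_obs[p])
        g = np.stack([j_v[p, :n_o], j_cl[p, :n_o]], axis=1)
        r = (
            data.log_obs[p, :n_o]
            - f[p, :n_o]
            + g @ np.array([eta[p, 0], eta[p, 1]])
        )
        cov = g @ omega @ g.T + model.sigma2 * np.eye(n_o)
        vals, vecs = np.linalg.eigh(cov)
        if np.any(vals <= 0):
            raise np.linalg.LinAlgError(
                f"singular linearized covariance for patient {pid}"
            )
        inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
        out[pid] = inv_sqrt @ r
    return out


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VPCResult:
    """Observed percentiles vs simulated percentile bands, binned by POD."""

    bin_edges: np.ndarray           # (B+1,) POD bin edges
    bin_centers: np.ndarray         # (B,)
    percentiles: tuple = (5.0, 50.0, 95.0)
    observed_pct: np.ndarray = None     # (3, B)
    sim_pct_median: np.ndarray = None   # (3, B) median of each percentile over reps
    sim_pct_ci: np.ndarray = None       # (3, B, 2) 95% CI of each percentile
    n_replicates: int = 0
    in_band_fraction: float = float("nan")

    def band_width(self) -> np.ndarray:
        """Per-bin width of the simulated 5th-95th percentile band."""
        return self.sim_pct_median[2] - self.sim_pct_median[0]


def vpc(
    records: Sequence[PatientRecord],
    model: PopulationModel,
    n_replicates: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
) -> VPCResult:
    """Simulate the design ``n_replicates`` times under ``model`` and
    compare observed vs simulated concentration percentiles by POD bin.

    Each replicate redraws every subject's etas and every observation's
    residual; doses, sampling times and covariates are kept as designed.
    Deterministic for a fixed seed.
    """
    if n_replicates < 100:
        warnings.warn(
            f"n_replicates={n_replicates} < 100: percentile confidence bands "
            "will be unstable"
        )
    rng = np.random.default_rng(seed)
    data = compile_dataset(records, list(model.covariates), ka=model.ka)
    mask = data.obs_mask
    pods = np.concatenate(
        [[o.pod for o in rec.usable_observations] for rec in records]
    )
    obs_conc = np.concatenate(
        [[o.conc for o in rec.usable_observations] for rec in records]
    )
    # POD-quantile bin edges (deciles by default); a short discrete
    # schedule gets one bin per distinct POD instead, and bins that end
    # up empty are merged away
    unique_pods = np.unique(pods)
    if len(unique_pods) <= n_bins:
        edges = np.concatenate([unique_pods - 0.5, [unique_pods[-1] + 0.5]])
    else:
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.unique(np.quantile(pods, qs))
        if len(edges) < 2:
            edges = np.array([pods.min() - 0.5, pods.max() + 0.5])
    bin_idx = np.clip(np.searchsorted(edges, pods, side="right") - 1, 0, len(edges) - 2)
    occupied = np.unique(bin_idx)
    edges = np.concatenate([edges[occupied], [edges[-1]]])
    bin_idx = np.searchsorted(occupied, bin_idx)
    B = len(occupied)
    pct = (5.0, 50.0, 95.0)

    sd = np.array([np.sqrt(model.omega2_v), np.sqrt(model.omega2_cl)])
    sim_pct = np.empty((n_replicates, 3, B))
    all_sims = []
    for rep in range(n_replicates):
        eta = rng.normal(0.0, 1.0, size=(data.n_patients, 2)) * sd
        v, cl = _individual_params(data, model, eta)
        f, _, _ = _log_predictions(data, v, cl)
        eps = rng.normal(0.0, np.sqrt(model.sigma2), size=f.shape)
        sim = np.exp(f + eps)[mask]
        all_sims.append(sim)
        for b in range(B):
            sel = sim[bin_idx == b]
            sim_pct[rep, :, b] = (
                np.percentile(sel, pct) if sel.size else np.nan
            )
    observed = np.empty((3, B))
    for b in range(B):
        sel = obs_conc[bin_idx == b]
        observed[:, b] = np.percentile(sel, pct) if sel.size else np.nan
    sim_median = np.nanmedian(sim_pct, axis=0)
    ci = np.stack(
        [
            np.nanpercentile(sim_pct, 2.5, axis=0),
            np.nanpercentile(sim_pct, 97.5, axis=0),
        ],
        axis=-1,
    )
    # pooled 5th/95th band per bin over all simulated values
    pooled = np.stack(all_sims)  # (R, n_obs)
    lo = np.empty(B)
    hi = np.empty(B)
    for b in range(B):
        vals = pooled[:, bin_idx == b].ravel()
        lo[b], hi[b] = (np.percentile(vals, [5.0, 95.0]) if vals.size else (np.nan, np.nan))
    inside = (obs_conc >= lo[bin_idx]) & (obs_conc <= hi[bin_idx])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VPCResult(
        bin_edges=edges,
        bin_centers=centers,
        percentiles=pct,
        observed_pct=observed,
        sim_pct_median=sim_median,
        sim_pct_ci=ci,
        n_replicates=n_replicates,
        in_band_fraction=float(inside.mean()),
    )


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def gof_plot(records: Sequence[PatientRecord], fit: FitResult, path) -> None:
    """Four-panel goodness-of-fit figure (PRED/IPRE vs observed, CWRES
    vs PRED and vs time)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs, preds, ipres, times = [], [], [], []
    for rec in records:
        usable = rec.usable_observations
        obs += [o.conc for o in usable]
        times += [o.time for o in usable]
        preds += list(fit.pred[rec.patient_id])
        ipres += list(fit.ipre[rec.patient_id])
    res = cwres(records, fit)
    flat_cwres = np.concatenate([res[rec.patient_id] for rec in records])
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, (x, y, xl, yl) in zip(
        axes.ravel(),
        [
            (preds, obs, "PRED (ng/mL)", "Observed (ng/mL)"),
            (ipres, obs, "IPRE (ng/mL)", "Observed (ng/mL)"),
            (preds, flat_cwres, "PRED (ng/mL)", "CWRES"),
            (np.array(times) / 24.0, flat_cwres, "Time (days)", "CWRES"),
        ],
    ):
        ax.scatter(x, y, s=8, alpha=0.5)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        if yl == "CWRES":
            ax.axhline(0, color="k", lw=0.8)
        else:
            lim = [0, max(max(x), max(y)) * 1.05]
            ax.plot(lim, lim, "k-", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vpc_plot(result: VPCResult, records: Sequence[PatientRecord], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    x = result.bin_centers
    for i, (label, style) in enumerate(
        [("5th", "--"), ("50th", "-"), ("95th", "--")]
    ):
        ax.fill_between(
            x, result.sim_pct_ci[i, :, 0], result.sim_pct_ci[i, :, 1], alpha=0.25
        )
        ax.plot(x, result.observed_pct[i], "k" + style, label=f"observed {label}")
    pods = [o.pod for r in records for o in r.usable_observations]
    concs = [o.conc for r in records for o in r.usable_observations]
    ax.scatter(pods, concs, s=6, alpha=0.3, color="grey")
    ax.set_xlabel("Postoperative day")
    ax.set_ylabel("Trough concentration (ng/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
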
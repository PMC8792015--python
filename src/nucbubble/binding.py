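"""Global single-site fits of fluorescence-polarization titrations.

A fixed concentration of fluorescent probe (Lt) is titrated with binding
partner (Rt); polarization rises from fp_free to fp_bound as the probe
is bound.  The bound fraction follows the exact (depletion-aware)
single-site quadratic solution, and one shared (Kd, fp_free, fp_bound)
triple is fit jointly across all replicate points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "fraction_bound_quadratic",
    "global_fit",
]


@dataclass(frozen=True)
class TitrationSeries:
    """FP titration points at fixed probe concentration.

    points: DataFrame with columns conc_molar (titrant), polarization,
    replicate.  Concentrations are in molar; polarization in mP.
    """

    probe_conc: float
    points: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"conc_molar", "polarization", "replicate"}
        if not req.issubset(self.points.columns):
            raise ValueError(f"points must have columns {sorted(req)}")
        if (self.points["conc_molar"] < 0).any():
            raise ValueError("titrant concentrations must be >= 0")
        if self.probe_conc < 0:
            raise ValueError("probe_conc must be >= 0")

    def check_reportable(self) -> None:
        pos = np.asarray(self.points.loc[self.points["conc_molar"] > 0, "conc_molar"])
        distinct = np.unique(self.points["conc_molar"])
        if distinct.size < 4 or pos.size == 0 or pos.max() / pos.min() < 100:
            raise ValueError(
                "reportable fit needs >=4 distinct titrant concentrations "
                "spanning >=2 orders of magnitude"
            )


@dataclass(frozen=True)
class BindingFit:
    """Result of a global single-site fit."""

    kd_hat: float
    fp_free: float
    fp_bound: float
    kd_se: float
    fp_free_se: float
    fp_bound_se: float
    converged: bool
    nonbinder: bool
    residual_sd: float
    n_points: int
    model: str = "quadratic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.nonbinder:
            return "no binding detected / Kd above titration bound"
        return f"Kd = {self.kd_hat:.3g} +/- {self.kd_se:.2g} M"


def fraction_bound_quadratic(kd, Rt, Lt):
    """Exact single-site bound fraction of the probe with ligand depletion.

    f = (Rt + Lt + Kd - sqrt((Rt + Lt + Kd)^2 - 4 Rt Lt)) / (2 Lt);
    for Lt -> 0 this reduces to the hyperbola Rt / (Rt + Kd).
    """
    kd = np.asarray(kd, dtype=float)
    Rt = np.asarray(Rt, dtype=float)
    Lt = np.asarray(Lt, dtype=float)
    if np.any(kd <= 0) or np.any(Rt < 0) or np.any(Lt < 0):
        raise ValueError("require kd > 0, Rt >= 0, Lt >= 0")
    s = Rt + Lt + kd
    disc = np.maximum(s * s - 4.0 * Rt * Lt, 0.0)
    # stable form of the smaller quadratic root: avoids s - sqrt cancellation
    denom = s + np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, 2.0 * Rt / np.where(denom > 0, denom, 1.0), 0.0)
    f = np.where(np.asarray(Lt + 0 * f) > 0, f, Rt / (Rt + kd))
    return np.clip(f, 0.0, 1.0)


def _model_fp(params: np.ndarray, Rt: np.ndarray, Lt: float, model: str) -> np.ndarray:
    log_kd, fp_free, fp_bound = params
    kd = 10.0**log_kd
    if model == "quadratic":
        f = fraction_bound_quadratic(kd, Rt, Lt)
    elif model == "hyperbolic":
        f = Rt / (Rt + kd)
    else:
        raise ValueError(f"unknown model {model!r}")
    return fp_free + (fp_bound - fp_free) * f


def global_fit(
    series: TitrationSeries,
    model: str = "quadratic",
    n_starts: int = 7,
    amplitude_snr_min: float = 3.0,
    kd_bound_factor: float = 10.0,
) -> BindingFit:
    """Least-squares fit of (Kd, fp_free, fp_bound) shared across replicates.

    Kd is optimized on a log scale with bounds [min_titrant/100,
    max_titrant*100] and a multistart grid of initial Kd values spanning
    the titration range.  Standard errors come from the Jacobian at the
    optimum.  The nonbinder flag is set when the fitted amplitude is
    below ``amplitude_snr_min`` times the residual SD or the fitted Kd
    exceeds ``kd_bound_factor`` times the largest titrant concentration —
    reported as "no binding detected / Kd above bound".
    """
    series.check_reportable()
    Rt = np.asarray(series.points["conc_molar"], dtype=float)
    fp = np.asarray(series.points["polarization"], dtype=float)
    Lt = float(series.probe_conc)
    pos = Rt[Rt > 0]
    lo_kd, hi_kd = np.log10(pos.min() / 100.0), np.log10(pos.max() * 100.0)

    def resid(params: np.ndarray) -> np.ndarray:
        return _model_fp(params, Rt, Lt, model) - fp

    fp_lo, fp_hi = float(fp.min()), float(fp.max())
    kd_grid = np.linspace(np.log10(pos.min()), np.log10(pos.max()), n_starts)
    best = None
    for log_kd0 in kd_grid:
        x0 = np.array([log_kd0, fp_lo, fp_hi])
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=([lo_kd, -np.inf, -np.inf], [hi_kd, np.inf, np.inf]),
                method="trf",
            )
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        warnings.warn("global fit failed to converge from every start")
        return BindingFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          converged=False, nonbinder=True, residual_sd=np.nan,
                          n_points=fp.size, model=model)

    log_kd, fp_free, fp_bound = best.x
    kd = float(10.0**log_kd)
    dof = max(fp.size - 3, 1)
    resid_sd = float(np.sqrt(2.0 * best.cost / dof))
    # covariance from the Jacobian; singular fits get NaN errors
    try:
        jtj_inv = np.linalg.pinv(best.jac.T @ best.jac)
        perr = np.sqrt(np.maximum(np.diag(jtj_inv), 0.0)) * resid_sd
    except np.linalg.LinAlgError:  # pragma: no cover
        perr = np.full(3, np.nan)
    kd_se = float(kd * np.log(10.0) * perr[0])
    amplitude = abs(fp_bound - fp_free)
    amp_floor = 1e-6 * max(1.0, float(np.ptp(fp)), abs(float(fp_free)))
    nonbinder = bool(
        amplitude <= max(amplitude_snr_min * resid_sd, amp_floor)
        or kd > kd_bound_factor * pos.max()
    )
    return BindingFit(
        kd_hat=kd,
        fp_free=float(fp_free),
        fp_bound=float(fp_bound),
        kd_se=kd_se,
        fp_free_se=float(perr[1]),
        fp_bound_se=float(perr[2]),
        converged=True,
        nonbinder=nonbinder,
        residual_sd=resid_sd,
        n_points=int(fp.size),
        model=model,
    )
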
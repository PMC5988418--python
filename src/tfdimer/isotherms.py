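"""Nonlinear least-squares fitting of Mw(CT) and sw(CT) isotherms.

The SEC-MALS observable is the weight-average molar mass of the eluting
peak; the AUC observable is the signal-weighted sedimentation coefficient
integrated over the c(s) distribution.  Both are fit to the same
monomer–dimer self-association model to estimate the dimerization Kd.

The dimerization constant is searched in log space (bounds 1e-4 – 1e4 µM)
so the optimizer cannot wander into negative Kd, and bound-hit flags mark
fits where the data carry no association signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np

from .equilibria import SelfAssociationModel, SwModel, sw_isotherm, weight_average_mass

__all__ = ["IsothermPoint", "FitResult", "fit_mw_isotherm", "fit_sw_isotherm"]

KD_MIN = 1e-4  # µM, lower search bound for the dimerization constant
KD_MAX = 1e4   # µM, upper search bound
_BOUND_RTOL = 1e-3  # a parameter within this relative distance of a bound counts as pinned


@dataclass(frozen=True)
class IsothermPoint:
    """One concentration point of an isotherm.

    ``CT`` is the loading concentration in monomer units (µM); ``y`` is the
    observed Mw (kDa) or sw (S); ``sigma`` is an optional observation
    standard deviation used for 1/sigma² weighting.
    """

    CT: float
    y: float
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not (self.CT > 0):
            raise ValueError(f"isotherm concentration must be > 0, got {self.CT}")
        if self.sigma is not None and not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0 when given, got {self.sigma}")


@dataclass
class FitResult:
    """Outcome of a least-squares fit.

    ``estimates`` and ``standard_errors`` are keyed by parameter name;
    standard errors come from the Jacobian-based covariance at the optimum
    and are advisory.  ``bounds_hit`` flags parameters pinned at a search
    bound, which signals data with no information about that parameter.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    residual_norm: float
    converged: bool
    bounds_hit: dict[str, bool] = field(default_factory=dict)
    n_points: int = 0

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def _as_points(points: Iterable[IsothermPoint | Sequence[float]]) -> list[IsothermPoint]:
    out = []
    for p in points:
        if isinstance(p, IsothermPoint):
            out.append(p)
        else:
            out.append(IsothermPoint(*p))
    return out


def _weights(pts: list[IsothermPoint]) -> np.ndarray:
    """1/sigma weights when sigmas are given, else unweighted."""
    if all(p.sigma is not None for p in pts):
        return 1.0 / np.array([p.sigma for p in pts])
    return np.ones(len(pts))


def _finish(result: lmfit.minimizer.MinimizerResult, names: Sequence[str],
            transform: dict[str, str], n_points: int) -> FitResult:
    estimates: dict[str, float] = {}
    stderrs: dict[str, float] = {}
    bounds_hit: dict[str, bool] = {}
    for name in names:
        pname = transform.get(name, name)
        par = result.params[pname]
        if pname.startswith("log10_"):
            val = 10.0 ** par.value
            # delta method: se(10^x) = ln(10) * 10^x * se(x)
            se = math.log(10.0) * val * (par.stderr or 0.0)
        else:
            val = par.value
            se = par.stderr or 0.0
        estimates[name] = val
        stderrs[name] = se
        hit = False
        for bound in (par.min, par.max):
            if np.isfinite(bound) and bound != 0:
                if abs(par.value - bound) <= _BOUND_RTOL * abs(bound):
                    hit = True
            elif np.isfinite(bound) and abs(par.value) <= 1e-12:
                hit = True
        bounds_hit[name] = hit
    return FitResult(
        estimates=estimates,
        standard_errors=stderrs,
        residual_norm=float(np.sum(np.asarray(result.residual) ** 2)),
        converged=bool(result.success),
        bounds_hit=bounds_hit,
        n_points=n_points,
    )


def fit_mw_isotherm(
    points: Iterable[IsothermPoint | Sequence[float]],
    Mm: float = 48.0,
    float_Mm: bool = False,
) -> FitResult:
    """Estimate the dimerization Kd from a weight-average-mass isotherm.

    Fits the monomer–dimer Mw(CT) expression to the observed points by
    weighted nonlinear least squares.  ``Mm`` is fixed by default (the
    monomer mass is normally known from sequence); pass ``float_Mm=True``
    to co-estimate it.

    Returns a :class:`FitResult` with ``Kd_dim`` (and ``Mm`` when floated).
    """
    pts = _as_points(points)
    n_free = 2 if float_Mm else 1
    if len(pts) < n_free + 1:
        raise ValueError(
            f"need at least {n_free + 1} points to fit {n_free} parameter(s), got {len(pts)}"
        )
    if len({p.CT for p in pts}) < 2:
        raise ValueError("isotherm points must span at least two distinct concentrations")

    CT = np.array([p.CT for p in pts])
    y = np.array([p.y for p in pts])
    w = _weights(pts)

    params = lmfit.Parameters()
    params.add("log10_Kd", value=0.0, min=math.log10(KD_MIN), max=math.log10(KD_MAX))
    params.add("Mm", value=Mm, min=1e-3, vary=float_Mm)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = SelfAssociationModel(Mm=p["Mm"].value, Kd_dim=10.0 ** p["log10_Kd"].value)
        pred = np.array([weight_average_mass(c, model) for c in CT])
        return w * (pred - y)

    result = lmfit.minimize(residual, params, method="leastsq")
    names = ["Kd_dim", "Mm"] if float_Mm else ["Kd_dim"]
    fit = _finish(result, names, {"Kd_dim": "log10_Kd"}, len(pts))
    if not fit.converged:
        warnings.warn("Mw isotherm fit did not converge; result flagged", RuntimeWarning)
    return fit


def fit_sw_isotherm(
    points: Iterable[IsothermPoint | Sequence[float]],
    fix: dict[str, float] | None = None,
) -> FitResult:
    """Estimate (Kd_dim, sM, sD) from an sw(CT) isotherm.

    The association scheme is ``A + A ⇌ A2``.  ``fix`` may pin ``sM``
    and/or ``sD`` (in S); the ordering constraint ``sM < sD`` is enforced
    by parameterizing the dimer coefficient as ``sD = sM + ds`` with
    ``ds > 0``.
    """
    pts = _as_points(points)
    fix = dict(fix or {})
    n_free = 3 - len(fix)
    if len(pts) < max(n_free, 1):
        raise ValueError(f"need at least {n_free} points for {n_free} free parameters")
    if "sM" in fix and "sD" in fix and not (fix["sM"] < fix["sD"]):
        raise ValueError(f"infeasible fixed values: require sM < sD, got {fix}")

    CT = np.array([p.CT for p in pts])
    y = np.array([p.y for p in pts])
    w = _weights(pts)
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    span = max(y_hi - y_lo, 0.1 * max(abs(y_hi), 1.0))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = SwModel(
            sM=p["sM"].value,
            sD=p["sM"].value + p["ds"].value,
            model=SelfAssociationModel(Kd_dim=10.0 ** p["log10_Kd"].value),
        )
        pred = np.array([sw_isotherm(c, model) for c in CT])
        return w * (pred - y)

    # multistart over the Kd decade to dodge local minima of the 3-parameter fit
    result = None
    for log_kd0 in (-1.5, 0.0, 1.5):
        params = lmfit.Parameters()
        params.add("log10_Kd", value=log_kd0,
                   min=math.log10(KD_MIN), max=math.log10(KD_MAX))
        params.add("sM", value=fix.get("sM", y_lo), min=1e-6, vary="sM" not in fix)
        ds0 = (fix["sD"] - fix.get("sM", y_lo)) if "sD" in fix else span
        params.add("ds", value=max(ds0, 1e-6), min=1e-9, vary="sD" not in fix)
        trial = lmfit.minimize(residual, params, method="leastsq")
        cost = float(np.sum(np.asarray(trial.residual) ** 2))
        if result is None or cost < result_cost:
            result, result_cost = trial, cost
    fit = _finish(result, ["Kd_dim", "sM"], {"Kd_dim": "log10_Kd"}, len(pts))
    # assemble sD = sM + ds with propagated (uncorrelated, advisory) error
    p_sM, p_ds = result.params["sM"], result.params["ds"]
    fit.estimates["sD"] = p_sM.value + p_ds.value
    fit.standard_errors["sD"] = math.hypot(p_sM.stderr or 0.0, p_ds.stderr or 0.0)
    fit.bounds_hit["sD"] = bool(
        np.isfinite(p_ds.min) and abs(p_ds.value - p_ds.min) <= 1e-9
    )
    if not fit.converged:
        warnings.warn("sw isotherm fit did not converge; result flagged", RuntimeWarning)
    return fit
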
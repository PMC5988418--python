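"""Stopped-flow kinetics: simulation and analysis of rapid-mixing traces.

Two experiment classes are covered:

* **Dilution relaxation** — a concentrated, mostly dimeric sample is
  rapidly diluted and the monomer–dimer system relaxes to the new
  equilibrium.  The relaxation is governed by ``dd/dt = kass m^2 - kdiss d``
  with the mass balance ``m = CT - 2 d``; near equilibrium it is
  single-exponential with eigenvalue ``kdiss + 4 kass m_eq``.

* **Substrate association** — unfolded substrate is mixed with chaperone
  that coexists as monomer and dimer.  Because dimer exchange (~10 s⁻¹) is
  slow on the binding timescale, each substrate molecule effectively
  commits to the species it first encounters, and the trace is a sum of two
  exponentials whose observed rates follow the pseudo-first-order law
  ``kobs = kon·C + koff`` per species.  The fast phase belongs to the dimer
  and its amplitude fraction tracks the dimer mass fraction.

Analysis mirrors standard stopped-flow practice: an exponential
photobleach baseline is estimated from the post-equilibration tail
(default after 1000 ms) and subtracted, single/double exponentials are fit
with a variable-projection multi-start, phases are attributed by species
fraction, and kobs values are regressed linearly against species
concentration to extract kon and koff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import linregress

from .equilibria import DEFAULTS, SelfAssociationModel, SpeciationState, solve_speciation

__all__ = [
    "DimerKinetics",
    "BindingModel",
    "KineticTrace",
    "ExponentialFitResult",
    "PhaseAttribution",
    "RateConstants",
    "simulate_dilution_relaxation",
    "fit_dilution_relaxation",
    "simulate_association",
    "fit_exponentials",
    "select_model",
    "attribute_phases",
    "regress_kobs",
    "residence_time",
]

ODE_RTOL = 1e-8
ODE_ATOL = 1e-12
BASELINE_CUT_S = 1.0     # photobleach baseline estimated from data after this time
DEAD_TIME_S = 2e-3       # default instrument dead time
AICC_THRESHOLD = 10.0    # evidence required to prefer the 2-phase model


@dataclass(frozen=True)
class DimerKinetics:
    """Dimer association/dissociation kinetics tied to the equilibrium model.

    ``kdiss`` is the intrinsic dimer dissociation rate (s⁻¹); the
    association rate is derived as ``kass = kdiss / Kd_dim`` (µM⁻¹s⁻¹) so
    that detailed balance with the thermodynamic Kd holds by construction.
    """

    kdiss: float = DEFAULTS["kdiss_per_s"]
    model: SelfAssociationModel = field(default_factory=SelfAssociationModel)

    def __post_init__(self) -> None:
        if not (self.kdiss > 0):
            raise ValueError(f"kdiss must be positive, got {self.kdiss}")

    @property
    def kass(self) -> float:
        """Dimer association rate constant, µM⁻¹s⁻¹."""
        return self.kdiss / self.model.Kd_dim


@dataclass(frozen=True)
class BindingModel:
    """Substrate-binding rate constants for monomer and dimer.

    Association constants are in µM⁻¹s⁻¹ (multiply by 1e6 for M⁻¹s⁻¹),
    dissociation in s⁻¹.  Dimer rates are per dimer particle; the dimer is
    treated as binding a single substrate molecule.  ``coupling`` selects
    whether monomer↔dimer exchange runs during a binding simulation
    ("decoupled" freezes the speciation, matching the observed
    two-independent-phase kinetics).
    """

    kon_m: float = DEFAULTS["kon_m_uM_s"]
    koff_m: float = DEFAULTS["koff_m_per_s"]
    kon_d: float = DEFAULTS["kon_d_uM_s"]
    koff_d: float = DEFAULTS["koff_d_per_s"]
    coupling: str = "decoupled"

    def __post_init__(self) -> None:
        for name in ("kon_m", "koff_m", "kon_d", "koff_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.coupling not in ("decoupled", "coupled"):
            raise ValueError(f"coupling must be 'decoupled' or 'coupled', got {self.coupling!r}")


@dataclass(frozen=True)
class KineticTrace:
    """A time/signal series with mixing metadata.

    ``t`` is in seconds (strictly increasing), ``signal`` in arbitrary
    fluorescence units; ``meta`` records concentrations (µM), dead time and
    anything else needed to interpret the trace.
    """

    t: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass
class ExponentialFitResult:
    """Parameters of a fitted 1- or 2-phase exponential.

    Rates are sorted descending so phase 1 is the fast phase.  Amplitudes
    are extrapolated back to the mixing time t = 0 (dead-time corrected) and
    may be negative for rising signals; amplitude fractions use magnitudes.
    ``baseline`` holds the (amplitude, rate) of a subtracted photobleach
    exponential when the correction was applied.
    """

    n_phases: int
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    offset: float
    residual_norm: float
    aicc: float
    converged: bool
    rate_stderr: tuple[float, ...] = ()
    baseline: tuple[float, float] | None = None

    @property
    def fast_amplitude_fraction(self) -> float:
        """|A_fast| / sum |A_i|; equals 1 for a single phase."""
        mags = [abs(a) for a in self.amplitudes]
        return mags[0] / sum(mags)


@dataclass(frozen=True)
class RateConstants:
    """kon/koff from a kobs regression, with advisory standard errors."""

    kon: float                 # M⁻¹ s⁻¹
    koff: float                # s⁻¹
    kon_stderr: float
    koff_stderr: float
    species: str = ""          # "monomer" | "dimer"


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def simulate_dilution_relaxation(
    pre_CT: float,
    dilution_factor: float,
    kin: DimerKinetics,
    t_grid: np.ndarray,
    signal_coeffs: tuple[float, float] = (1.0, 0.7),
) -> KineticTrace:
    """Relaxation of the monomer–dimer system after rapid dilution.

    The sample is equilibrated at ``pre_CT`` (µM, monomer units), then
    instantaneously diluted by ``dilution_factor``; the trace follows
    ``dd/dt = kass m^2 - kdiss d`` from the out-of-equilibrium initial
    condition.  The fluorescence signal is ``aM*m + aD*2d`` with
    ``signal_coeffs = (aM, aD)`` — distinct coefficients give the
    relaxation a nonzero amplitude.
    """
    if pre_CT <= 0:
        raise ValueError(f"pre-dilution concentration must be > 0, got {pre_CT}")
    if dilution_factor < 1:
        raise ValueError(f"dilution factor must be >= 1, got {dilution_factor}")
    t_grid = np.asarray(t_grid, dtype=float)
    CT = pre_CT / dilution_factor
    d0 = solve_speciation(pre_CT, kin.model).d / dilution_factor
    d = _integrate_dimer_relaxation(CT, d0, kin, t_grid)
    m = CT - 2.0 * d
    aM, aD = signal_coeffs
    return KineticTrace(
        t=t_grid,
        signal=aM * m + aD * 2.0 * d,
        meta={
            "kind": "dilution",
            "pre_CT_uM": pre_CT,
            "CT_uM": CT,
            "dilution_factor": dilution_factor,
            "signal_coeffs": signal_coeffs,
        },
    )


def _integrate_dimer_relaxation(
    CT: float, d0: float, kin: DimerKinetics, t_grid: np.ndarray
) -> np.ndarray:
    """Integrate dd/dt = kass (CT - 2d)^2 - kdiss d on t_grid."""

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        m = CT - 2.0 * y[0]
        return np.array([kin.kass * m * m - kin.kdiss * y[0]])

    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if t0 > 0:  # evolve silently through the dead time
        pre = solve_ivp(rhs, (0.0, t0), [d0], method="LSODA",
                        rtol=ODE_RTOL, atol=ODE_ATOL)
        if not pre.success:
            raise ArithmeticError(f"relaxation integrator failed: {pre.message}")
        d0 = float(pre.y[0, -1])
    sol = solve_ivp(rhs, (t0, t1), [d0], t_eval=t_grid, method="LSODA",
                    rtol=ODE_RTOL, atol=ODE_ATOL)
    if not sol.success:
        raise ArithmeticError(f"relaxation integrator failed: {sol.message}")
    return sol.y[0]


def simulate_association(
    S0: float,
    chap_CT: float,
    bm: BindingModel,
    kin: DimerKinetics,
    t_grid: np.ndarray,
    signal_scale: float = 1.0,
) -> KineticTrace:
    """Substrate-association trace with coexisting monomer and dimer.

    ``S0`` is the post-mix substrate concentration and ``chap_CT`` the
    post-mix total chaperone concentration (µM, monomer units), speciated
    at ``kin.model.Kd_dim``.

    decoupled mode (default)
        Speciation is frozen at its t=0 value and the substrate is
        partitioned between the species in proportion to their mass
        fractions; each pool relaxes independently as a reversible
        pseudo-first-order binding reaction.  This reproduces the
        two-independent-exponential phenomenology with per-species rates
        ``kon·C + koff``.

    coupled mode
        The full five-state network (M, D, S, MS, DS) including dimer
        exchange at ``kdiss``/``kass`` is integrated.

    The signal is ``signal_scale * (MS + DS)`` — proportional to bound
    substrate, which is what the substrate tryptophan fluorescence reports.
    """
    if S0 < 0 or chap_CT < 0:
        raise ValueError("concentrations must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    if chap_CT > 0 and chap_CT < 2.5 * S0:
        warnings.warn(
            f"chaperone ({chap_CT} µM) below 2.5x substrate ({S0} µM); "
            "pseudo-first-order analysis may be biased",
            RuntimeWarning,
        )
    spec = solve_speciation(chap_CT, kin.model)
    meta = {
        "kind": "association",
        "S0_uM": S0,
        "chap_CT_uM": chap_CT,
        "m_uM": spec.m,
        "d_uM": spec.d,
        "coupling": bm.coupling,
    }
    if chap_CT == 0 or S0 == 0:
        return KineticTrace(t=t_grid, signal=np.zeros_like(t_grid), meta=meta)
    if bm.coupling == "decoupled":
        bound = _association_decoupled(S0, spec, bm, t_grid)
    else:
        bound = _association_coupled(S0, spec, bm, kin, t_grid)
    return KineticTrace(t=t_grid, signal=signal_scale * bound, meta=meta)


def _association_decoupled(
    S0: float, spec: SpeciationState, bm: BindingModel, t_grid: np.ndarray
) -> np.ndarray:
    """Bound substrate for frozen speciation and partitioned substrate pools."""
    total = np.zeros_like(t_grid)
    pools = (
        (S0 * spec.monomer_mass_fraction, bm.kon_m, bm.koff_m, spec.m),
        (S0 * spec.dimer_mass_fraction, bm.kon_d, bm.koff_d, spec.d),
    )
    for S_pool, kon, koff, C in pools:
        if S_pool == 0 or (kon == 0 and koff == 0):
            continue

        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            # y = [bound in this pool]; free substrate = S_pool - bound
            return np.array([kon * C * (S_pool - y[0]) - koff * y[0]])

        sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [0.0], t_eval=t_grid,
                        method="LSODA", rtol=ODE_RTOL, atol=ODE_ATOL)
        if not sol.success:
            raise ArithmeticError(f"association integrator failed: {sol.message}")
        total = total + sol.y[0]
    return total


def _association_coupled(
    S0: float,
    spec: SpeciationState,
    bm: BindingModel,
    kin: DimerKinetics,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Bound substrate for the full network with dimer exchange."""

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        m, d, S, MS, DS = y
        v_ex = kin.kass * m * m - kin.kdiss * d    # net dimer formation
        v_m = bm.kon_m * m * S - bm.koff_m * MS
        v_d = bm.kon_d * d * S - bm.koff_d * DS
        return np.array([
            -2.0 * v_ex - v_m,
            v_ex - v_d,
            -v_m - v_d,
            v_m,
            v_d,
        ])

    y0 = [spec.m, spec.d, S0, 0.0, 0.0]
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=ODE_RTOL, atol=ODE_ATOL)
    if not sol.success:
        raise ArithmeticError(f"coupled association integrator failed: {sol.message}")
    return sol.y[3] + sol.y[4]


# --------------------------------------------------------------------------
# exponential fitting
# --------------------------------------------------------------------------

def _exp_design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Design matrix [1, exp(-r1 (t-t0)), ...] for linear amplitude solve."""
    cols = [np.ones_like(t)]
    for r in rates:
        cols.append(np.exp(-r * (t - t[0])))
    return np.column_stack(cols)


def _vp_residual(log_rates: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Variable-projection residual: amplitudes solved linearly per rate set."""
    X = _exp_design(t, np.exp(log_rates))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ beta - y


def _fit_baseline(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fit c + a*exp(-r t) to the tail segment; returns (c, a, r)."""
    res = least_squares(
        _vp_residual, x0=[math.log(1.0 / max(t[-1] - t[0], 1e-6))],
        args=(t, y), method="lm",
    )
    r = float(np.exp(res.x[0]))
    X = _exp_design(t, np.array([r]))
    (c, a_at_t0), *_ = np.linalg.lstsq(X, y, rcond=None)
    # re-reference amplitude to t = 0
    return float(c), float(a_at_t0 * math.exp(r * t[0])), r


def fit_exponentials(
    trace: KineticTrace,
    n_phases: int = 1,
    baseline_policy: str = "none",
    baseline_cut: float = BASELINE_CUT_S,
) -> ExponentialFitResult:
    """Fit a sum of ``n_phases`` exponentials to a stopped-flow trace.

    With ``baseline_policy="photobleach"`` a single exponential is first
    fitted to the data after ``baseline_cut`` seconds (where the chemistry
    has equilibrated and only fluorophore bleaching moves the signal), its
    decaying component is subtracted from the whole trace, and the
    exponential fit is then restricted to the pre-cut segment.

    The rate parameters are optimized by variable projection (amplitudes
    and offset solved linearly for each trial rate set) with log-spaced
    multi-start initial guesses; rates are returned sorted descending so
    phase 1 is fast.  Non-convergence is flagged on the result rather than
    raised.
    """
    if n_phases not in (1, 2):
        raise ValueError(f"n_phases must be 1 or 2, got {n_phases}")
    t = trace.t
    y = trace.signal.copy()
    if len(t) < 10 * n_phases:
        raise ValueError(
            f"need at least {10 * n_phases} points for {n_phases} phase(s), got {len(t)}"
        )

    baseline = None
    if baseline_policy == "photobleach":
        tail = t > baseline_cut
        if tail.sum() < 4:
            raise ValueError(
                f"photobleach policy needs data beyond {baseline_cut} s "
                f"(trace ends at {t[-1]:.3g} s)"
            )
        _c, a, r = _fit_baseline(t[tail], y[tail])
        y = y - a * np.exp(-r * t)
        baseline = (a, r)
        head = t <= baseline_cut
        t, y = t[head], y[head]
    elif baseline_policy != "none":
        raise ValueError(f"unknown baseline policy {baseline_policy!r}")

    span = t[-1] - t[0]
    dt = np.min(np.diff(t))
    lo, hi = math.log(0.5 / span), math.log(1.0 / (2.0 * dt))
    starts: list[np.ndarray]
    if n_phases == 1:
        starts = [np.array([g]) for g in np.linspace(lo, hi, 6)]
    else:
        grid = np.linspace(lo, hi, 5)
        starts = [np.array([g1, g2]) for i, g1 in enumerate(grid)
                  for g2 in grid[:i + 1]]

    best = None
    for x0 in starts:
        try:
            res = least_squares(_vp_residual, x0=x0, args=(t, y), method="lm",
                                max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ArithmeticError("all exponential fit starts failed")

    rates = np.exp(best.x)
    X = _exp_design(t, rates)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    offset, amps = float(beta[0]), beta[1:]

    # sort fast-first; break rate ties by amplitude magnitude
    order = sorted(range(n_phases), key=lambda i: (-rates[i], -abs(amps[i])))
    rates = rates[order]
    amps = amps[order]
    # amplitudes are fitted referenced to the first observed point; report them
    # extrapolated to the mixing time t = 0 (the dead-time correction standard
    # in stopped-flow work, and what phase-fraction comparisons assume)
    amps = amps * np.exp(rates * t[0])

    rss = float(np.sum((X @ beta - y) ** 2))
    n = len(t)
    k = 2 * n_phases + 2  # amplitudes + rates + offset + noise variance
    aicc = n * math.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aicc += 2 * k * (k + 1) / (n - k - 1)

    stderr = _rate_stderr(t, y, rates, beta, rss)
    return ExponentialFitResult(
        n_phases=n_phases,
        amplitudes=tuple(float(a) for a in amps),
        rates=tuple(float(r) for r in rates),
        offset=offset,
        residual_norm=rss,
        aicc=aicc,
        converged=bool(best.status > 0),
        rate_stderr=stderr,
        baseline=baseline,
    )


def _rate_stderr(t, y, rates, beta, rss) -> tuple[float, ...]:
    """Advisory standard errors of the rates from the full Jacobian."""
    n, n_phases = len(t), len(rates)
    dof = n - (2 * n_phases + 1)
    if dof <= 0 or rss <= 0:
        return tuple(0.0 for _ in rates)
    cols = [np.ones_like(t)]
    for a, r in zip(beta[1:], rates):
        cols.append(np.exp(-r * (t - t[0])))
    for a, r in zip(beta[1:], rates):
        cols.append(-a * (t - t[0]) * np.exp(-r * (t - t[0])))  # d/dr
    J = np.column_stack(cols)
    try:
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
    except np.linalg.LinAlgError:
        return tuple(float("nan") for _ in rates)
    diag = np.diag(cov)[1 + n_phases:]
    return tuple(float(math.sqrt(max(v, 0.0))) for v in diag)


def select_model(
    trace: KineticTrace,
    baseline_policy: str = "none",
    baseline_cut: float = BASELINE_CUT_S,
    threshold: float = AICC_THRESHOLD,
) -> int:
    """Choose 1 vs 2 exponential phases by corrected AIC.

    Returns 2 only when the two-phase fit improves AICc by more than
    ``threshold``; ties and marginal improvements resolve to the simpler
    single-phase model.
    """
    fit1 = fit_exponentials(trace, 1, baseline_policy, baseline_cut)
    fit2 = fit_exponentials(trace, 2, baseline_policy, baseline_cut)
    return 2 if (fit1.aicc - fit2.aicc) > threshold else 1


@dataclass(frozen=True)
class PhaseAttribution:
    """Assignment of bi-exponential phases to chaperone species."""

    fast_species: str
    slow_species: str
    fast_amplitude_fraction: float
    dimer_mass_fraction: float

    @property
    def agreement(self) -> float:
        """|fast amplitude fraction − dimer mass fraction|."""
        return abs(self.fast_amplitude_fraction - self.dimer_mass_fraction)


def attribute_phases(fit: ExponentialFitResult, spec: SpeciationState) -> PhaseAttribution:
    """Label the fast phase dimer and the slow phase monomer.

    The dimer binds substrate faster (larger kon and koff), so at any
    concentration its pseudo-first-order kobs exceeds the monomer's; the
    amplitude fraction of the fast phase should track the dimer mass
    fraction of the speciated chaperone, and the returned ``agreement``
    score quantifies that match.
    """
    if fit.n_phases != 2:
        raise ValueError("phase attribution requires a 2-phase fit")
    return PhaseAttribution(
        fast_species="dimer",
        slow_species="monomer",
        fast_amplitude_fraction=fit.fast_amplitude_fraction,
        dimer_mass_fraction=spec.dimer_mass_fraction,
    )


def regress_kobs(
    points: Iterable[Sequence[float]], species: str = ""
) -> RateConstants:
    """Extract kon and koff from the linear law kobs = kon·C + koff.

    ``points`` are (species concentration in µM, kobs in s⁻¹) pairs; the
    ordinary least-squares slope is converted to M⁻¹s⁻¹ (×1e6) and the
    intercept is koff.  A negative intercept (possible with noisy data) is
    clipped to zero with a warning.
    """
    pts = [(float(c), float(k)) for c, k in points]
    if len({c for c, _ in pts}) < 3:
        raise ValueError("kobs regression needs at least 3 distinct concentrations")
    conc = np.array([c for c, _ in pts])
    kobs = np.array([k for _, k in pts])
    res = linregress(conc, kobs)
    koff = float(res.intercept)
    if koff < 0:
        warnings.warn(
            f"negative koff intercept ({koff:.3g} s⁻¹) clipped to 0", RuntimeWarning
        )
        koff = 0.0
    return RateConstants(
        kon=float(res.slope) * 1e6,
        koff=koff,
        kon_stderr=float(res.stderr or 0.0) * 1e6,
        koff_stderr=float(res.intercept_stderr or 0.0),
        species=species,
    )


def residence_time(kin: DimerKinetics) -> float:
    """Mean dimer lifetime 1/kdiss, in seconds."""
    return 1.0 / kin.kdiss


# --------------------------------------------------------------------------
# relaxation-model fitting
# --------------------------------------------------------------------------

def fit_dilution_relaxation(
    trace: KineticTrace,
    model: SelfAssociationModel,
    CT: float | None = None,
    d0: float | None = None,
    log_kdiss_bounds: tuple[float, float] = (-3.0, 4.0),
) -> dict[str, float]:
    """Recover kdiss by fitting the full relaxation ODE to a dilution trace.

    The thermodynamic model (Kd) is held fixed and ``kass = kdiss/Kd``
    throughout, so a single nonlinear parameter (kdiss) governs the
    trajectory shape; the two linear signal coefficients (monomer and
    dimer) are profiled out by least squares at each trial kdiss
    (variable projection), and kdiss is optimized on a log grid by bounded
    scalar minimization.

    ``CT`` (post-dilution total, µM) and ``d0`` (initial dimer, µM) default
    to the trace metadata written by :func:`simulate_dilution_relaxation`.
    Returns ``{"kdiss": ..., "kass": ..., "residual_norm": ...}``.
    """
    if CT is None:
        CT = trace.meta["CT_uM"]
    if d0 is None:
        pre = trace.meta["pre_CT_uM"]
        fac = trace.meta["dilution_factor"]
        d0 = solve_speciation(pre, model).d / fac
    t, y = trace.t, trace.signal

    def profiled_rss(log10_kdiss: float) -> float:
        kin = DimerKinetics(kdiss=10.0 ** log10_kdiss, model=model)
        d = _integrate_dimer_relaxation(CT, d0, kin, t)
        X = np.column_stack([CT - 2.0 * d, 2.0 * d])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((X @ beta - y) ** 2))

    res = minimize_scalar(profiled_rss, bounds=log_kdiss_bounds, method="bounded",
                          options={"xatol": 1e-10})
    kdiss = float(10.0 ** res.x)
    return {
        "kdiss": kdiss,
        "kass": kdiss / model.Kd_dim,
        "residual_norm": float(res.fun),
    }
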
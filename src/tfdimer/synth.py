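"""Seeded synthetic-data generators emulating the instruments.

Every analysis stage in the package can be exercised without real
instrument files: these generators produce SEC-MALS-style Mw isotherms,
AUC-style sw isotherms and stopped-flow-style traces (with dead time,
photobleach baseline and noise), and always return the ground-truth
parameters alongside the "observed" data so parameter-recovery tests stay
honest.  All randomness flows through an explicit integer seed and a
``numpy`` Generator, making every output bit-reproducible.

Default conditions mirror the study protocols: the AUC concentration
ladder (40.18, 12.13, 3.83, 0.596 µM), 10-fold dilution of 1 µM protein
for dissociation kinetics, and 2 µM substrate against 0–40 µM chaperone
for association kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .equilibria import (
    SelfAssociationModel,
    SwModel,
    sw_isotherm,
    weight_average_mass,
)
from .isotherms import IsothermPoint
from .stopflow import (
    BindingModel,
    DimerKinetics,
    KineticTrace,
    simulate_association,
    simulate_dilution_relaxation,
)

__all__ = [
    "NoiseSpec",
    "PhotobleachSpec",
    "AUC_CONCENTRATIONS_UM",
    "make_mw_isotherm",
    "make_sw_isotherm",
    "make_stopflow_trace",
]

#: Loading-concentration ladder of the sedimentation-velocity experiments (µM).
AUC_CONCENTRATIONS_UM: tuple[float, ...] = (40.18, 12.13, 3.83, 0.596)

DEFAULT_DEAD_TIME_S = 2e-3
DEFAULT_TRACE_END_S = 2.0    # spans the >1 s photobleach-baseline window
DEFAULT_TRACE_POINTS = 1000


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise: additive (signal units) or multiplicative (fractional)."""

    kind: str = "additive_gaussian"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "multiplicative_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError(f"noise sigma must be >= 0, got {self.sigma}")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(y, dtype=float)
        eps = rng.normal(0.0, self.sigma, size=np.shape(y))
        if self.kind == "additive_gaussian":
            return y + eps
        return y * (1.0 + eps)


@dataclass(frozen=True)
class PhotobleachSpec:
    """Exponential photobleach baseline added to a trace: amp * exp(-rate t)."""

    amplitude: float = 0.0
    rate: float = 0.3

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"photobleach rate must be >= 0, got {self.rate}")


def make_mw_isotherm(
    model: SelfAssociationModel,
    concentrations: Sequence[float] = AUC_CONCENTRATIONS_UM,
    noise: NoiseSpec | None = None,
) -> tuple[list[IsothermPoint], dict]:
    """Synthetic SEC-MALS weight-average-mass isotherm.

    Evaluates the monomer–dimer Mw(CT) model at the given concentrations
    and applies the noise spec.  Returns ``(points, truth)`` where the
    sidecar ``truth`` records the generating parameters.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    y_true = np.array([weight_average_mass(c, model) for c in concentrations])
    y = noise.apply(y_true, rng)
    sigma = _observed_sigma(noise, y_true)
    points = [
        IsothermPoint(CT=float(c), y=float(v), sigma=s)
        for c, v, s in zip(concentrations, y, sigma)
    ]
    truth = {
        "Mm_kDa": model.Mm,
        "Kd_dim_uM": model.Kd_dim,
        "noise": {"kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed},
    }
    return points, truth


def make_sw_isotherm(
    sw_model: SwModel,
    concentrations: Sequence[float] = AUC_CONCENTRATIONS_UM,
    noise: NoiseSpec | None = None,
) -> tuple[list[IsothermPoint], dict]:
    """Synthetic AUC sw(CT) isotherm; defaults to the standard four-point ladder."""
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    y_true = np.array([sw_isotherm(c, sw_model) for c in concentrations])
    y = noise.apply(y_true, rng)
    sigma = _observed_sigma(noise, y_true)
    points = [
        IsothermPoint(CT=float(c), y=float(v), sigma=s)
        for c, v, s in zip(concentrations, y, sigma)
    ]
    truth = {
        "sM_S": sw_model.sM,
        "sD_S": sw_model.sD,
        "Kd_dim_uM": sw_model.model.Kd_dim,
        "noise": {"kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed},
    }
    return points, truth


def _observed_sigma(noise: NoiseSpec, y_true: np.ndarray) -> list[float | None]:
    if noise.sigma == 0:
        return [None] * len(y_true)
    if noise.kind == "additive_gaussian":
        return [noise.sigma] * len(y_true)
    return [noise.sigma * abs(float(v)) for v in y_true]


def make_stopflow_trace(
    kind: str,
    params: dict,
    photobleach: PhotobleachSpec | None = None,
    noise: NoiseSpec | None = None,
    dead_time: float = DEFAULT_DEAD_TIME_S,
    t_end: float = DEFAULT_TRACE_END_S,
    n_points: int = DEFAULT_TRACE_POINTS,
) -> tuple[KineticTrace, dict]:
    """Synthetic stopped-flow trace: kinetics + photobleach baseline + noise.

    ``kind`` is ``"dilution"`` (dimer dissociation after rapid dilution) or
    ``"association"`` (substrate binding to speciated chaperone).
    ``params`` supplies the simulation arguments:

    dilution
        ``pre_CT_uM``, ``dilution_factor``, ``kdiss_per_s``, and optionally
        ``Mm_kDa``, ``Kd_dim_uM``, ``signal_coeffs``.
    association
        ``S0_uM``, ``chap_CT_uM``, optionally ``Kd_dim_uM``, ``kdiss_per_s``,
        the four binding constants ``kon_m/koff_m/kon_d/koff_d`` and
        ``coupling``.

    The trace starts at ``dead_time`` (signal before the observable window
    is discarded, but the chemistry still evolves through it) and must
    extend beyond the 1 s photobleach-baseline window when a photobleach
    component is requested.
    """
    photobleach = photobleach or PhotobleachSpec()
    noise = noise or NoiseSpec()
    if photobleach.amplitude != 0 and t_end <= 1.0:
        raise ValueError(
            f"trace horizon {t_end} s too short for the >1 s photobleach "
            "baseline window"
        )
    t_grid = np.linspace(dead_time, t_end, n_points)
    model = SelfAssociationModel(
        Mm=params.get("Mm_kDa", 48.0), Kd_dim=params.get("Kd_dim_uM", 2.0)
    )
    kin = DimerKinetics(kdiss=params.get("kdiss_per_s", 10.0), model=model)
    if kind == "dilution":
        trace = simulate_dilution_relaxation(
            pre_CT=params["pre_CT_uM"],
            dilution_factor=params["dilution_factor"],
            kin=kin,
            t_grid=t_grid,
            signal_coeffs=params.get("signal_coeffs", (1.0, 0.7)),
        )
    elif kind == "association":
        bm = BindingModel(
            kon_m=params.get("kon_m", BindingModel().kon_m),
            koff_m=params.get("koff_m", BindingModel().koff_m),
            kon_d=params.get("kon_d", BindingModel().kon_d),
            koff_d=params.get("koff_d", BindingModel().koff_d),
            coupling=params.get("coupling", "decoupled"),
        )
        trace = simulate_association(
            S0=params["S0_uM"], chap_CT=params["chap_CT_uM"],
            bm=bm, kin=kin, t_grid=t_grid,
        )
    else:
        raise ValueError(f"unknown trace kind {kind!r}")

    rng = np.random.default_rng(noise.seed)
    signal = trace.signal + photobleach.amplitude * np.exp(-photobleach.rate * t_grid)
    signal = noise.apply(signal, rng)
    meta = dict(trace.meta)
    meta["dead_time_s"] = dead_time
    observed = KineticTrace(t=t_grid, signal=signal, meta=meta)
    truth = {
        "kind": kind,
        "params": {k: v for k, v in params.items()},
        "kdiss_per_s": kin.kdiss,
        "Kd_dim_uM": model.Kd_dim,
        "photobleach": {"amplitude": photobleach.amplitude, "rate": photobleach.rate},
        "noise": {"kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed},
        "dead_time_s": dead_time,
        "speciation": {k: meta[k] for k in ("m_uM", "d_uM") if k in meta},
    }
    return observed, truth
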
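"""Airflow-thermoelectric response model.

A thermoelectric device (TED) worn over the airways sees alternating warm
(exhale) and cool (inhale) airflow on its upper surface. Forced convection
sets the upper-surface temperature; the Seebeck effect converts the resulting
upper/lower temperature difference into an output voltage.

Model chain:

1. Laminar flat-plate convection coefficient
       h(v) = 0.664 (kappa / L) * Re^0.5 * Pr^(1/3),   Re = rho * v * L / mu
2. Lumped-capacitance surface energy balance (Newton cooling)
       m c_p dT_upper/dt = h A (T_air - T_upper)  =>  dT_upper/dt = f (T_air - T_upper)
   with thermal rate f = h A / (m c_p).
3. Seebeck output
       V = alpha_device * (T_upper - T_lower)

For constant airflow the balance has the closed form
       T_upper(t) = T_air - (T_air - T_upper(0)) * exp(-f t).
For time-varying airflow we treat v(t) and T_air(t) as piecewise-constant over
each sampling interval and apply that exact exponential update per interval,
so the integrator is unconditionally stable and reduces exactly to the closed
form for constant inputs.

All temperatures are kelvin internally. T_lower (skin-side temperature) is
held constant; natural convection at v = 0 is not modelled (f = 0 holds the
surface temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray


@dataclass(frozen=True)
class FluidProperties:
    """Thermophysical constants of the airflow.

    Parameters
    ----------
    kappa : float
        Thermal conductivity, W/(m·K).
    rho_air : float
        Density, kg/m³.
    mu : float
        Dynamic viscosity, Pa·s.
    Pr : float
        Prandtl number (dimensionless).

    Defaults are dry air near 20 °C.
    """

    kappa: float = 0.0257
    rho_air: float = 1.2
    mu: float = 1.8e-5
    Pr: float = 0.71

    def __post_init__(self) -> None:
        for name in ("kappa", "rho_air", "mu", "Pr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"FluidProperties.{name} must be strictly positive")


#: Air properties used throughout as the default fluid.
AIR = FluidProperties()


@dataclass(frozen=True)
class DevicePlate:
    """Lumped model of the TED's fluid-contact end.

    Parameters
    ----------
    L : float
        Characteristic (streamwise) length of the plate, m.
    A : float
        Fluid-contact area, m².
    m : float
        Mass of the contact-end material, kg.
    c_p : float
        Specific heat of the contact end, J/(kg·K).
    alpha_device : float
        Effective Seebeck coefficient of the series device, V/K. The default
        is one p/n couple: 202.5e-6 - (-210e-6) = 412.5e-6 V/K.
    T_lower : float
        Constant lower-surface (skin-side) temperature, K.
    """

    L: float = 0.01
    A: float = 1e-4
    m: float = 1e-3
    c_p: float = 200.0
    alpha_device: float = 412.5e-6
    T_lower: float = 293.15

    def __post_init__(self) -> None:
        for name in ("L", "A", "m", "c_p", "T_lower"):
            if not getattr(self, name) > 0:
                raise ValueError(f"DevicePlate.{name} must be strictly positive")


def _as_1d(a: ArrayLike, name: str) -> NDArray[np.float64]:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class FlowSignal:
    """Airflow time series: sample times (s), speed (m/s), air temperature (K).

    The speed is the scalar magnitude of the flow normal to the plate and must
    be non-negative; sample times must be strictly increasing.
    """

    t: NDArray[np.float64]
    v: NDArray[np.float64]
    T_air: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.t = _as_1d(self.t, "t")
        self.v = _as_1d(self.v, "v")
        self.T_air = _as_1d(self.T_air, "T_air")
        if not (len(self.t) == len(self.v) == len(self.T_air)):
            raise ValueError("t, v, T_air must have equal length")
        if len(self.t) == 0:
            raise ValueError("FlowSignal must contain at least one sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.v < 0):
            raise ValueError("airflow speed must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class VoltageTrace:
    """TED response time series: upper-surface temperature, ΔT and voltage.

    Invariants: ``dT_TED = T_upper - T_lower`` and ``V = alpha_device * dT_TED``
    hold exactly by construction.
    """

    t: NDArray[np.float64]
    T_upper: NDArray[np.float64]
    dT_TED: NDArray[np.float64]
    V: NDArray[np.float64]
    T_lower: float = field(default=293.15)
    alpha_device: float = field(default=412.5e-6)

    @classmethod
    def from_T_upper(
        cls,
        t: ArrayLike,
        T_upper: ArrayLike,
        *,
        T_lower: float,
        alpha_device: float,
    ) -> "VoltageTrace":
        t = _as_1d(t, "t")
        T_upper = _as_1d(T_upper, "T_upper")
        dT = T_upper - T_lower
        return cls(
            t=t,
            T_upper=T_upper,
            dT_TED=dT,
            V=alpha_device * dT,
            T_lower=T_lower,
            alpha_device=alpha_device,
        )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz; requires a uniform time grid."""
        dt = np.diff(self.t)
        if len(dt) == 0:
            raise ValueError("trace has a single sample; sampling rate undefined")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("trace is not uniformly sampled")
        return 1.0 / dt[0]


def convective_coefficient(fluid: FluidProperties, L: float, v: ArrayLike) -> ArrayLike:
    """Laminar flat-plate average convection coefficient h(v), W/(m²·K).

    Implements Nu = 0.664 Re^0.5 Pr^(1/3) with Re = rho v L / mu, hence

        h = 0.664 (kappa / L) (rho v L / mu)^0.5 Pr^(1/3)

    so h grows with the square root of speed and falls with L^(-1/2).
    Accepts a scalar or array speed; h(0) = 0 (no forced convection).
    """
    if not L > 0:
        raise ValueError("characteristic length L must be strictly positive")
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr < 0):
        raise ValueError("airflow speed must be non-negative")
    Re = fluid.rho_air * v_arr * L / fluid.mu
    h = 0.664 * (fluid.kappa / L) * np.sqrt(Re) * fluid.Pr ** (1.0 / 3.0)
    return float(h) if np.isscalar(v) or np.ndim(v) == 0 else h


def thermal_rate(h: ArrayLike, plate: DevicePlate) -> ArrayLike:
    """First-order thermal rate f = h A / (m c_p), in 1/s."""
    h_arr = np.asarray(h, dtype=float)
    f = h_arr * plate.A / (plate.m * plate.c_p)
    return float(f) if np.ndim(h) == 0 else f


def convective_flux(h: float, A: float, T_air: float, T_upper: float) -> float:
    """Convective heat flow q = h A (T_air - T_upper), W.

    Positive during warm exhale (heats the device), negative during cool
    inhale (extracts heat).
    """
    if not A > 0:
        raise ValueError("contact area A must be strictly positive")
    return h * A * (T_air - T_upper)


def step_response(
    plate: DevicePlate,
    fluid: FluidProperties,
    v_const: float,
    T_air: float,
    T_upper0: float,
    times: ArrayLike,
) -> VoltageTrace:
    """Closed-form response to a constant airflow step.

    T_upper(t) = T_air - (T_air - T_upper0) exp(-f t); the voltage approaches
    alpha_device (T_air - T_lower) monotonically, without overshoot. At v = 0
    the rate f vanishes and the surface temperature holds at T_upper0.
    """
    if v_const < 0:
        raise ValueError("airflow speed must be non-negative")
    t = _as_1d(times, "times")
    if len(t) == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    h = convective_coefficient(fluid, plate.L, v_const)
    f = thermal_rate(h, plate)
    T_upper = T_air - (T_air - T_upper0) * np.exp(-f * t)
    return VoltageTrace.from_T_upper(
        t, T_upper, T_lower=plate.T_lower, alpha_device=plate.alpha_device
    )


def simulate_response(
    plate: DevicePlate,
    fluid: FluidProperties,
    flow: FlowSignal,
    T_upper0: float,
) -> VoltageTrace:
    """Integrate the surface energy balance for a time-varying airflow.

    v and T_air are treated as piecewise-constant over each sample interval
    (left endpoint) and the exact exponential update is applied per interval:

        T_{k+1} = T_air,k - (T_air,k - T_k) exp(-f_k dt_k)

    This reduces exactly to :func:`step_response` when the flow is constant,
    and is unconditionally stable for any grid.
    """
    if not T_upper0 > 0:
        raise ValueError("initial upper-surface temperature must be positive (kelvin)")
    h = convective_coefficient(fluid, plate.L, flow.v)
    f = thermal_rate(h, plate)
    n = len(flow)
    T_upper = np.empty(n)
    T_upper[0] = T_upper0
    dt = np.diff(flow.t)
    decay = np.exp(-np.asarray(f)[:-1] * dt) if n > 1 else np.empty(0)
    for k in range(n - 1):
        Ta = flow.T_air[k]
        T_upper[k + 1] = Ta - (Ta - T_upper[k]) * decay[k]
    return VoltageTrace.from_T_upper(
        flow.t, T_upper, T_lower=plate.T_lower, alpha_device=plate.alpha_device
    )


def voltage_from_dT(alpha_device: float, dT: ArrayLike) -> ArrayLike:
    """Seebeck output V = alpha_device * dT (linear, odd in dT)."""
    out = alpha_device * np.asarray(dT, dtype=float)
    return float(out) if np.ndim(dT) == 0 else out
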
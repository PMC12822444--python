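"""Reduced 1-D steady-state thermoelectric leg solver.

Solves the coupled heat/charge balance of a single thermoelectric leg on the
segment x ∈ [0, length], replacing a full 3-D finite-element treatment:

    d/dx (kappa_TED dT/dx) + rho_TED j² = 0          (energy, Joule source)
    dj/dx = 0                                        (charge conservation ⇒ j uniform)
    j = -sigma (dE/dx + alpha dT/dx)                 (generalized Ohm's law)

with a fixed (skin-side) temperature at x = 0 and a convective Robin
condition at the fluid-contact end x = length:

    kappa_TED dT/dx |_L = h (T_air - T(L))

The Seebeck coefficient is taken constant, so the Thomson term
T j (∂alpha/∂T) dT/dx of the full energy equation is identically zero; this
is a modelling choice, not a numerical omission. Side faces are adiabatic and
radiation is neglected.

Discretization is second-order central differences with a ghost-node Robin
boundary, assembled as a tridiagonal system. Because the exact solution is
linear (open circuit) or quadratic (uniform Joule source), the scheme
reproduces it to machine precision on any grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.linalg import solve_banded

from airtherm.thermo_response import FluidProperties, convective_coefficient


@dataclass(frozen=True)
class LegMaterial:
    """Per-leg thermoelectric constants.

    alpha: Seebeck coefficient, V/K (signed: negative for n-type);
    sigma: electrical conductivity, S/m; kappa_TED: thermal conductivity,
    W/(m·K). Resistivity is 1/sigma.
    """

    alpha: float
    sigma: float
    kappa_TED: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be strictly positive")
        if not self.kappa_TED > 0:
            raise ValueError("kappa_TED must be strictly positive")

    @property
    def rho_TED(self) -> float:
        """Electrical resistivity, Ω·m."""
        return 1.0 / self.sigma


#: Bi0.5Sb1.5Te3 p-type cube constants.
P_TYPE = LegMaterial(alpha=202.5e-6, sigma=9.25e5, kappa_TED=0.927)
#: Bi2Te2.7Se0.3 n-type cube constants.
N_TYPE = LegMaterial(alpha=-210e-6, sigma=10e5, kappa_TED=0.965)


@dataclass(frozen=True)
class LegGeometry:
    """Leg dimensions and grid. Defaults are a 1.4 × 1.4 × 2.5 mm cuboid."""

    length: float = 2.5e-3
    cross_section: float = 1.4e-3 * 1.4e-3
    n_nodes: int = 51

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("length must be strictly positive")
        if not self.cross_section > 0:
            raise ValueError("cross_section must be strictly positive")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be at least 3")

    def resistance(self, mat: LegMaterial) -> float:
        """Electrical resistance length/(sigma·A) of this geometry for `mat`, Ω."""
        return self.length / (mat.sigma * self.cross_section)


@dataclass
class LegSolution:
    """Solved 1-D profiles: node positions x (m), temperature T (K), electric
    potential E (V), uniform current density j (A/m²), terminal voltage (V)."""

    x: NDArray[np.float64]
    T: NDArray[np.float64]
    E: NDArray[np.float64]
    j: float
    V_leg: float

    @property
    def T_upper(self) -> float:
        return float(self.T[-1])

    @property
    def dT(self) -> float:
        return float(self.T[-1] - self.T[0])


def _solve_conduction(
    mat: LegMaterial,
    geom: LegGeometry,
    T_lower: float,
    h: float,
    T_air: float,
    source: float,
) -> NDArray[np.float64]:
    """Tridiagonal solve of kappa T'' + source = 0 with Dirichlet bottom and
    Robin top boundary (ghost-node closure, second order)."""
    n = geom.n_nodes
    dx = geom.length / (n - 1)
    kappa = mat.kappa_TED

    # banded storage: rows = upper, main, lower diagonals
    ab = np.zeros((3, n))
    rhs = np.zeros(n)

    ab[1, 0] = 1.0
    rhs[0] = T_lower

    ab[0, 2:] = kappa / dx**2          # upper diagonal (T_{i+1})
    ab[1, 1:-1] = -2.0 * kappa / dx**2  # main diagonal interior
    ab[2, :-2] = kappa / dx**2          # lower diagonal (T_{i-1})
    rhs[1:-1] = -source

    # top node i = n-1: ghost node from kappa (T_n - T_{n-2})/(2 dx) = h (T_air - T_{n-1})
    ab[2, n - 2] = 2.0 * kappa / dx**2
    ab[1, n - 1] = -2.0 * kappa / dx**2 - 2.0 * h / dx
    rhs[n - 1] = -source - 2.0 * h * T_air / dx

    return solve_banded((1, 1), ab, rhs)


def _potential(mat: LegMaterial, x: NDArray, T: NDArray, j: float) -> NDArray:
    """Electrostatic potential from Ohm's law: dE/dx = -j/sigma - alpha dT/dx,
    integrated with E(0) = 0."""
    return -j * x / mat.sigma - mat.alpha * (T - T[0])


def solve_open_circuit(
    mat: LegMaterial,
    geom: LegGeometry,
    T_lower: float,
    h: float,
    T_air: float,
) -> LegSolution:
    """Open-circuit (j = 0) steady state: pure conduction with a convective top.

    With constant conductivity the profile is linear and the fluid-contact
    temperature has the closed form

        T_upper = (h T_air + (kappa/L) T_lower) / (h + kappa/L).

    h = 0 leaves the leg isothermal at T_lower; h → ∞ pins T_upper at T_air.
    The terminal EMF is V_leg = alpha (T_upper - T_lower).
    """
    if h < 0:
        raise ValueError("convection coefficient h must be non-negative")
    T = _solve_conduction(mat, geom, T_lower, h, T_air, source=0.0)
    x = np.linspace(0.0, geom.length, geom.n_nodes)
    E = _potential(mat, x, T, j=0.0)
    V_leg = mat.alpha * (T[-1] - T[0])
    return LegSolution(x=x, T=T, E=E, j=0.0, V_leg=float(V_leg))


def solve_loaded(
    mat: LegMaterial,
    geom: LegGeometry,
    T_lower: float,
    h: float,
    T_air: float,
    R_load: float,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> LegSolution:
    """Loaded steady state by fixed-point iteration on the current density.

    Given a temperature profile, the uniform current follows from the series
    circuit (Seebeck EMF alpha·ΔT driving internal resistance L/(sigma A)
    plus R_load); conduction is then re-solved with the uniform Joule source
    rho_TED j² and the loop repeats until |Δj| / max(|j|, tiny) ≤ tol.
    Terminal voltage is the drop across the load, j·A·R_load.
    """
    if R_load < 0:
        raise ValueError("R_load must be non-negative")
    if h < 0:
        raise ValueError("convection coefficient h must be non-negative")
    R_int = geom.resistance(mat)
    A = geom.cross_section
    x = np.linspace(0.0, geom.length, geom.n_nodes)

    j = 0.0
    T = _solve_conduction(mat, geom, T_lower, h, T_air, source=0.0)
    for _ in range(max_iter):
        dT = T[-1] - T[0]
        I = mat.alpha * dT / (R_int + R_load)
        j_new = I / A
        T = _solve_conduction(
            mat, geom, T_lower, h, T_air, source=mat.rho_TED * j_new**2
        )
        if abs(j_new - j) <= tol * max(abs(j_new), 1e-30):
            j = j_new
            break
        j = j_new
    else:
        raise RuntimeError(
            f"loaded solve did not converge in {max_iter} iterations "
            f"(last j = {j:.6e} A/m², R_load = {R_load:.3e} Ω)"
        )
    E = _potential(mat, x, T, j)
    V_terminal = j * A * R_load
    return LegSolution(x=x, T=T, E=E, j=float(j), V_leg=float(V_terminal))


def couple_sweep(
    p: LegMaterial,
    n: LegMaterial,
    geom: LegGeometry,
    fluid: FluidProperties,
    T_lower: float,
    T_air: float,
    velocities,
) -> pd.DataFrame:
    """Open-circuit velocity sweep for one p/n couple.

    For each inlet speed v the flat-plate correlation gives h, each leg is
    solved open-circuit, and the couple EMF is the series sum
    V_oc = alpha_p ΔT_p - alpha_n ΔT_n. Returns a DataFrame with columns
    ``velocity_mps``, ``dT_K`` (mean of the two legs' ΔT) and ``v_oc_V``.
    |ΔT| and |V_oc| are non-decreasing in v.
    """
    velocities = np.asarray(velocities, dtype=float)
    if velocities.size == 0:
        raise ValueError("velocities must be non-empty")
    if np.any(velocities < 0):
        raise ValueError("velocities must be non-negative")
    L_char = float(np.sqrt(geom.cross_section))
    rows = []
    for v in velocities:
        h = convective_coefficient(fluid, L_char, float(v))
        sol_p = solve_open_circuit(p, geom, T_lower, h, T_air)
        sol_n = solve_open_circuit(n, geom, T_lower, h, T_air)
        dT = 0.5 * (sol_p.dT + sol_n.dT)
        v_oc = p.alpha * sol_p.dT - n.alpha * sol_n.dT
        rows.append((float(v), dT, v_oc))
    return pd.DataFrame(rows, columns=["velocity_mps", "dT_K", "v_oc_V"])
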
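"""Well-mixed receptor-ligand mass-action kinetics and the receptor closure.

Two bookkeeping views of the same chemistry are exposed:

* the *concentration* view evolving five fields — ligand ``c``, free/bound
  normal receptors ``R_f``/``R_b`` and free/bound decoy receptors
  ``D_f``/``D_b`` — which makes conservation laws explicit
  (``c + R_b + D_b`` is conserved without internalization, and total
  receptors ``R_f + R_b`` only ever decay through internalization);

* the *per-cell occupancy* view used by the spatial solver, in which the
  upregulation closures ``R_b + R_f = Gamma_r (n + beta R_b)`` and its decoy
  analogue eliminate the free-receptor fields, leaving the per-cell bound
  occupancies ``rho_r``, ``rho_d``.

The converter between the two and the dimensionless equilibrium occupancies
live here so the chemistry has exactly one implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "WellMixedState",
    "wellmixed_rhs",
    "wellmixed_equilibrium",
    "closure_free_receptors",
    "occupancy_rhs",
    "concentrations_from_occupancies",
    "integrate_wellmixed",
]


@dataclass(frozen=True)
class WellMixedState:
    """Ligand and receptor concentrations at one instant.

    All components are per-volume concentrations in one consistent unit
    system; ``dimensionless`` tags which system is in force.
    """

    c: float
    R_f: float
    R_b: float
    D_f: float
    D_b: float
    dimensionless: bool = True

    def __post_init__(self):
        for name in ("c", "R_f", "R_b", "D_f", "D_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.R_b, self.R_f, self.D_b, self.D_f])

    @classmethod
    def from_array(cls, y, dimensionless: bool = True) -> "WellMixedState":
        c, R_b, R_f, D_b, D_f = (float(v) for v in y)
        return cls(c=c, R_f=R_f, R_b=R_b, D_f=D_f, D_b=D_b, dimensionless=dimensionless)

    def replace(self, **changes) -> "WellMixedState":
        return replace(self, **changes)


def wellmixed_rhs(state: WellMixedState, params) -> WellMixedState:
    """Mass-action time derivatives of the five-component kinetics.

    ``params`` is any object with attributes ``k_a1, k_a2, k_d1, k_d2,
    k_i1, k_i2`` in the unit system matching the state.  Returns a state-like
    object whose components are d/dt of the inputs (its non-negativity check
    is bypassed: derivatives may be negative).
    """
    s, p = state, params
    bind_r = p.k_a1 * s.c * s.R_f
    bind_d = p.k_a2 * s.c * s.D_f
    dc = p.k_d1 * s.R_b - bind_r + p.k_d2 * s.D_b - bind_d
    dR_b = bind_r - (p.k_d1 + p.k_i1) * s.R_b
    dR_f = p.k_d1 * s.R_b - bind_r
    dD_b = bind_d - (p.k_d2 + p.k_i2) * s.D_b
    dD_f = p.k_d2 * s.D_b - bind_d
    deriv = object.__new__(WellMixedState)
    object.__setattr__(deriv, "c", dc)
    object.__setattr__(deriv, "R_b", dR_b)
    object.__setattr__(deriv, "R_f", dR_f)
    object.__setattr__(deriv, "D_b", dD_b)
    object.__setattr__(deriv, "D_f", dD_f)
    object.__setattr__(deriv, "dimensionless", s.dimensionless)
    return deriv


def wellmixed_equilibrium(c_fixed: float, params) -> tuple[float, float]:
    """Equilibrium per-cell occupancies ``(rho_r*, rho_d*)`` at frozen ligand.

    In the dimensionless occupancy view the kinetics are
    ``drho/dt = k_a c (1 + (beta - 1) rho) - (k_d + k_i) rho``, giving the
    fixed point ``rho* = k_a c / (k_d + k_i - k_a c (beta - 1))``.  Requires
    a positive denominator for each receptor class (otherwise upregulation
    outruns removal and occupancy grows without bound).
    """
    p = params

    def fixed_point(k_a, k_d, k_i, upreg):
        denom = k_d + k_i - k_a * c_fixed * (upreg - 1.0)
        if denom <= 0:
            raise ValueError(
                "non-positive denominator: occupancy is unbounded for "
                f"k_a={k_a:g}, k_d={k_d:g}, k_i={k_i:g}, upregulation={upreg:g}, "
                f"c={c_fixed:g}"
            )
        return k_a * c_fixed / denom

    rho_r = fixed_point(p.k_a1, p.k_d1, p.k_i1, p.beta)
    rho_d = fixed_point(p.k_a2, p.k_d2, p.k_i2, p.delta)
    return rho_r, rho_d


def closure_free_receptors(n, rho_r, params, *, decoy: bool = False):
    """Free-receptor concentration implied by the upregulation closure.

    With bound concentration ``R_b = n * rho_r`` the closure
    ``R_b + R_f = Gamma (n + beta R_b)`` gives
    ``R_f = Gamma * n * (1 + beta * rho_r) - n * rho_r``.
    ``decoy=True`` uses ``(Gamma_d, delta)`` instead of ``(Gamma_r, beta)``.
    In dimensionless variables ``Gamma = 1`` for the respective class and the
    free-receptor factor reduces to ``1 + (beta - 1) * rho_r``.
    """
    if decoy:
        gamma, upreg = params.Gamma_d, params.delta
    else:
        gamma, upreg = params.Gamma_r, params.beta
    n = np.asarray(n, dtype=float)
    rho_r = np.asarray(rho_r, dtype=float)
    out = gamma * n * (1.0 + upreg * rho_r) - n * rho_r
    if out.ndim == 0:
        return float(out)
    return out


def occupancy_rhs(c, rho_r, rho_d, params):
    """Pointwise kinetic derivatives in the dimensionless occupancy view.

    This is the reaction core shared with the spatial solver: for each class,
    ``drho/dt = k_a c (1 + (beta - 1) rho) - (k_d + k_i) rho``.
    Returns ``(drho_r, drho_d)``.
    """
    p = params
    drho_r = p.k_a1 * c * (1.0 + (p.beta - 1.0) * rho_r) - (p.k_d1 + p.k_i1) * rho_r
    drho_d = p.k_a2 * c * (1.0 + (p.delta - 1.0) * rho_d) - (p.k_d2 + p.k_i2) * rho_d
    return drho_r, drho_d


def concentrations_from_occupancies(n, c, rho_r, rho_d, params) -> WellMixedState:
    """Convert the occupancy view to the five-concentration view.

    Dimensionless convention: bound concentrations are ``Gamma * n * rho``
    (occupancies are scaled by the resting per-cell content) and free
    concentrations follow from the closures.
    """
    p = params
    R_b = p.Gamma_r * n * rho_r
    D_b = p.Gamma_d * n * rho_d
    R_f = p.Gamma_r * n * (1.0 + (p.beta - 1.0) * rho_r)
    D_f = p.Gamma_d * n * (1.0 + (p.delta - 1.0) * rho_d)
    return WellMixedState(c=float(c), R_f=float(R_f), R_b=float(R_b),
                          D_f=float(D_f), D_b=float(D_b))


def integrate_wellmixed(state: WellMixedState, params, t_span, *,
                        t_eval=None, rtol=1e-10, atol=1e-12):
    """Adaptive high-order reference integration of the well-mixed kinetics.

    Intended as a test oracle (conservation, equilibrium limits); the spatial
    solver evaluates the same reaction terms pointwise instead of calling an
    ODE integrator.  Returns the ``scipy`` solution object; columns of
    ``sol.y`` are ordered ``(c, R_b, R_f, D_b, D_f)``.
    """

    def f(_t, y):
        st = WellMixedState.from_array(np.maximum(y, 0.0))
        d = wellmixed_rhs(st, params)
        return [d.c, d.R_b, d.R_f, d.D_b, d.D_f]

    sol = solve_ivp(f, t_span, state.as_array(), method="DOP853",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"kinetics integration failed: {sol.message}")
    return sol


def trajectory_frame(sol):
    """Tabulate a :func:`integrate_wellmixed` solution (CSV-ready)."""
    import pandas as pd

    c, R_b, R_f, D_b, D_f = sol.y
    return pd.DataFrame({"t": sol.t, "c": c, "R_f": R_f, "R_b": R_b,
                         "D_f": D_f, "D_b": D_b})
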
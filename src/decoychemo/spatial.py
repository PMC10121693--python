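"""Spatial chemotaxis model: discretization, right-hand side, time stepping.

The dimensionless system on the filter (``0 <= x <= 1``) couples cell
density ``n``, ligand ``c`` and per-cell bound receptor occupancies
``rho_r`` (normal, chemo-attracting) and ``rho_d`` (decoy, chemo-repelling)
through the cell flux

    K_n = -D_n dn/dx + chi n drho_r/dx - mu n drho_d/dx.

``n`` evolves by -dK_n/dx, the occupancies are advected with the per-cell
velocity ``K_n / n`` and relax by the closure kinetics, and the ligand
diffuses over the whole chamber while being bound/released on the filter.
In the wells the ligand obeys pure diffusion; because the chamber is one
continuous grid, flux continuity at the filter faces is automatic.  The
filter-face rows of ``n`` follow the reservoir-exchange law
``dn/dt = -K_n/L`` at ``x = 0`` and ``+K_n/L`` at ``x = 1`` (``L`` = cell
diameter), which is how cells enter from the upper well and pile up against
the lower face.

Spatial derivatives are central (second order); the cell-diffusion term uses
the standard 3-point Laplacian and the face values of ``K_n`` use one-sided
second-order differences.  Two steppers are provided: the forward Euler
scheme (``dt`` limited by the ligand-diffusion stability bound
``h^2 / (2 D_c)``) and an IMEX scheme treating ligand diffusion with
Crank-Nicolson and everything else explicitly, which allows ``dt`` around
1e-4 hours on the default grid at indistinguishable accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csc_matrix, csr_matrix, diags, identity
from scipy.sparse.linalg import splu

from .grid import ChamberGrid, build_grid
from .observables import migrated_count, penetration_depth
from .parameters import (
    DimensionalParameters,
    DimensionlessParameters,
    nondimensionalize,
)

__all__ = [
    "StateFields",
    "SimulationResult",
    "initial_state",
    "cell_flux",
    "rhs",
    "step_euler",
    "step_imex",
    "ImexStepper",
    "simulate",
    "no_decoy_overrides",
]

EPS_N = 1e-12        # cell-density floor for the per-cell advection velocity
NEG_TOL = -1e-10     # negativity below this aborts; above it is clipped to 0

# Dimensionless overrides that switch off the decoy channel, reducing the
# model to the three-field (n, c, rho_r) system.
NO_DECOY = {"Gamma_d": 0.0, "mu": 0.0, "k_a2": 0.0, "k_d2": 0.0,
            "k_i2": 0.0, "delta": 0.0}


def no_decoy_overrides() -> dict:
    return dict(NO_DECOY)


@dataclass
class StateFields:
    """Model state at one time: ``c`` on all chamber nodes, the rest on the filter."""

    t: float
    n: np.ndarray
    c: np.ndarray
    rho_r: np.ndarray
    rho_d: np.ndarray

    def copy(self) -> "StateFields":
        return StateFields(self.t, self.n.copy(), self.c.copy(),
                           self.rho_r.copy(), self.rho_d.copy())


@dataclass
class SimulationResult:
    """Snapshots, observable time series and full scheme metadata for one run."""

    snapshots: list[StateFields]
    series: pd.DataFrame          # columns t, N_f, H
    params_used: DimensionlessParameters
    grid: ChamberGrid
    n0: float
    h: float
    dt: float
    stepper: str
    t_max: float
    clip_count: int = 0
    warnings: tuple[str, ...] = ()

    @property
    def final(self) -> StateFields:
        return self.snapshots[-1]

    def migrated_count(self, snapshot: int = -1) -> float:
        return migrated_count(self.snapshots[snapshot].n, self.n0, self.grid)

    def penetration_depth(self, snapshot: int = -1) -> float:
        return penetration_depth(self.snapshots[snapshot].n, self.n0, self.grid)


def initial_state(grid: ChamberGrid, params: DimensionlessParameters) -> StateFields:
    """Initial condition: cells in the upper well, ligand in the lower well.

    Dimensionless form — ``n = 0`` on the filter except ``n = 1`` at the
    ``x = 1`` node adjoining the cell reservoir; ligand ``c = 1`` on the
    lower-well nodes (``x <= 0``, including the face node) and 0 elsewhere;
    no receptors are bound yet.
    """
    M = grid.n_filter_nodes
    n = np.zeros(M)
    n[-1] = 1.0
    c = np.where(grid.x <= 0.0, 1.0, 0.0)
    return StateFields(t=0.0, n=n, c=c,
                       rho_r=np.zeros(M), rho_d=np.zeros(M))


def _grad(f: np.ndarray, h: float) -> np.ndarray:
    """Second-order gradient: central interior, one-sided at the ends."""
    g = np.empty_like(f)
    g[1:-1] = (f[2:] - f[:-2]) / (2.0 * h)
    g[0] = (-3.0 * f[0] + 4.0 * f[1] - f[2]) / (2.0 * h)
    g[-1] = (3.0 * f[-1] - 4.0 * f[-2] + f[-3]) / (2.0 * h)
    return g


def cell_flux(n, rho_r, rho_d, params: DimensionlessParameters,
              grid: ChamberGrid) -> np.ndarray:
    """Dimensionless cell flux ``K_n`` on the filter nodes."""
    h = grid.h
    gn = _grad(np.asarray(n, float), h)
    grr = _grad(np.asarray(rho_r, float), h)
    grd = _grad(np.asarray(rho_d, float), h)
    return -params.D_n * gn + params.chi * n * grr - params.mu * n * grd


def rhs(state: StateFields, params: DimensionlessParameters, grid: ChamberGrid,
        *, upwind: bool = False, include_c_diffusion: bool = True,
        eps_n: float = EPS_N, check: bool = True):
    """Time derivatives ``(dn, dc, drho_r, drho_d)`` of the semi-discrete system.

    ``include_c_diffusion=False`` omits the ligand-diffusion term (the IMEX
    stepper handles it implicitly); every other term is identical between the
    steppers so the model has a single right-hand side.  The per-cell
    advection velocity is ``K_n / max(n, eps_n)`` and advection is skipped
    entirely where ``n < eps_n`` — occupancies are per-cell quantities,
    undefined without cells, so their dynamics stay purely kinetic until
    cells arrive.
    """
    n, c, rho_r, rho_d = state.n, state.c, state.rho_r, state.rho_d
    p = params
    h = grid.h
    inv_h2 = 1.0 / (h * h)
    c_f = c[grid.filter_slice]

    gn = _grad(n, h)
    grr = _grad(rho_r, h)
    grd = _grad(rho_d, h)

    w = p.chi * n * grr - p.mu * n * grd       # chemotactic part of K_n
    K = -p.D_n * gn + w

    dn = np.empty_like(n)
    dn[1:-1] = (p.D_n * (n[2:] - 2.0 * n[1:-1] + n[:-2]) * inv_h2
                - (w[2:] - w[:-2]) / (2.0 * h))
    dn[0] = -K[0] / p.L
    dn[-1] = K[-1] / p.L

    # occupancy advection: zero-gradient ghosts at the faces, so only interior
    active = n[1:-1] > eps_n
    v = np.where(active, K[1:-1] / np.maximum(n[1:-1], eps_n), 0.0)
    adv_r = np.zeros_like(rho_r)
    adv_d = np.zeros_like(rho_d)
    if upwind:
        fwd_r = (rho_r[2:] - rho_r[1:-1]) / h
        bwd_r = (rho_r[1:-1] - rho_r[:-2]) / h
        fwd_d = (rho_d[2:] - rho_d[1:-1]) / h
        bwd_d = (rho_d[1:-1] - rho_d[:-2]) / h
        adv_r[1:-1] = v * np.where(v > 0, bwd_r, fwd_r)
        adv_d[1:-1] = v * np.where(v > 0, bwd_d, fwd_d)
    else:
        adv_r[1:-1] = v * grr[1:-1]
        adv_d[1:-1] = v * grd[1:-1]

    free_r = 1.0 + (p.beta - 1.0) * rho_r      # per-cell free-receptor factor
    free_d = 1.0 + (p.delta - 1.0) * rho_d
    drho_r = -adv_r + p.k_a1 * c_f * free_r - (p.k_d1 + p.k_i1) * rho_r
    drho_d = -adv_d + p.k_a2 * c_f * free_d - (p.k_d2 + p.k_i2) * rho_d

    dc = np.zeros_like(c)
    if include_c_diffusion:
        dc[1:-1] = p.D_c * (c[2:] - 2.0 * c[1:-1] + c[:-2]) * inv_h2
        dc[0] = p.D_c * 2.0 * (c[1] - c[0]) * inv_h2        # no-flux ends
        dc[-1] = p.D_c * 2.0 * (c[-2] - c[-1]) * inv_h2
    dc[grid.filter_slice] += (
        p.k_d1 * p.Gamma_r * n * rho_r - p.k_a1 * c_f * n * p.Gamma_r * free_r
        + p.k_d2 * p.Gamma_d * n * rho_d - p.k_a2 * c_f * n * p.Gamma_d * free_d
    )

    if check:
        for name, arr in (("n", dn), ("c", dc), ("rho_r", drho_r), ("rho_d", drho_d)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise FloatingPointError(
                    f"non-finite derivative in field {name} at node {bad}, t={state.t:g}"
                )
    return dn, dc, drho_r, drho_d


def _clip_negatives(arrays: Sequence[np.ndarray], t: float) -> int:
    """Clip values in ``[NEG_TOL, 0)`` to zero; abort below ``NEG_TOL``."""
    clips = 0
    for arr in arrays:
        m = arr.min() if arr.size else 0.0
        if m < NEG_TOL:
            raise RuntimeError(
                f"field dropped below {NEG_TOL:g} (min {m:g}) at t={t:g}; "
                "the discretization is losing positivity — reduce dt or use upwind=True"
            )
        if m < 0.0:
            mask = arr < 0.0
            clips += int(mask.sum())
            arr[mask] = 0.0
    return clips


def step_euler(state: StateFields, params: DimensionlessParameters,
               grid: ChamberGrid, dt: float, *, upwind: bool = False,
               override_stability: bool = False) -> StateFields:
    """One forward-Euler step.

    Refuses ``dt`` above the ligand-diffusion stability bound
    ``h^2 / (2 D_c)`` unless explicitly overridden.  Tiny negatives produced
    by the central stencils are clipped to zero (counted on the returned
    state as ``_clips``).
    """
    bound = params.stability_dt(grid.h)
    if dt > bound and not override_stability:
        raise ValueError(
            f"dt={dt:g} exceeds the explicit stability bound h^2/(2 D_c)={bound:g}; "
            "pass override_stability=True to force"
        )
    dn, dc, drr, drd = rhs(state, params, grid, upwind=upwind)
    new = StateFields(
        t=state.t + dt,
        n=state.n + dt * dn,
        c=state.c + dt * dc,
        rho_r=state.rho_r + dt * drr,
        rho_d=state.rho_d + dt * drd,
    )
    new._clips = _clip_negatives((new.n, new.c, new.rho_r, new.rho_d), new.t)  # type: ignore[attr-defined]
    return new


class ImexStepper:
    """Crank-Nicolson ligand diffusion, explicit advection/reaction.

    The sparse factorization of ``I - (dt D_c / 2) Lap`` is built once per
    (grid, dt) and reused every step; the same operators serve the forward
    sensitivity fields, whose ligand component obeys the identical linear
    diffusion.
    """

    def __init__(self, params: DimensionlessParameters, grid: ChamberGrid,
                 dt: float, *, upwind: bool = False):
        if dt > 1e-3:
            raise ValueError(f"dt={dt:g} too large for the explicit reaction terms (max 1e-3)")
        self.params = params
        self.grid = grid
        self.dt = dt
        self.upwind = upwind
        N = grid.n_nodes
        inv_h2 = 1.0 / (grid.h * grid.h)
        main = np.full(N, -2.0 * inv_h2)
        off = np.full(N - 1, inv_h2)
        lap = diags([off, main, off], [-1, 0, 1], format="lil")
        lap[0, 1] = 2.0 * inv_h2           # reflective (no-flux) chamber ends
        lap[-1, -2] = 2.0 * inv_h2
        lap = csr_matrix(lap)
        half = 0.5 * dt * params.D_c
        eye = identity(N, format="csr")
        self.B = csr_matrix(eye + half * lap)
        self._lu = splu(csc_matrix(eye - half * lap))

    def solve_c(self, c: np.ndarray, dc_explicit: np.ndarray) -> np.ndarray:
        """Advance a chamber-wide diffusing field by one CN step."""
        out = self._lu.solve(self.B @ c + self.dt * dc_explicit)
        if not np.all(np.isfinite(out)):
            raise RuntimeError("linear solve for ligand diffusion returned non-finite values")
        return out

    def step(self, state: StateFields) -> StateFields:
        dt = self.dt
        dn, dc, drr, drd = rhs(state, self.params, self.grid,
                               upwind=self.upwind, include_c_diffusion=False)
        new = StateFields(
            t=state.t + dt,
            n=state.n + dt * dn,
            c=self.solve_c(state.c, dc),
            rho_r=state.rho_r + dt * drr,
            rho_d=state.rho_d + dt * drd,
        )
        new._clips = _clip_negatives((new.n, new.c, new.rho_r, new.rho_d), new.t)  # type: ignore[attr-defined]
        return new


_imex_cache: dict[tuple, ImexStepper] = {}


def step_imex(state: StateFields, params: DimensionlessParameters,
              grid: ChamberGrid, dt: float, *, upwind: bool = False) -> StateFields:
    """One IMEX step (functional form; the factorization is cached)."""
    key = (params, grid.key(), dt, upwind)
    stepper = _imex_cache.get(key)
    if stepper is None:
        if len(_imex_cache) > 32:
            _imex_cache.clear()
        stepper = _imex_cache[key] = ImexStepper(params, grid, dt, upwind=upwind)
    return stepper.step(state)


def _resolve(params, overrides, n0):
    """Accept dimensional or dimensionless parameters; return (dimless, n0)."""
    if isinstance(params, DimensionalParameters):
        dimless = nondimensionalize(params)
        n0 = params.n0 if n0 is None else n0
    elif isinstance(params, DimensionlessParameters):
        dimless = params
        if n0 is None:
            raise ValueError("n0 is required when passing DimensionlessParameters")
    else:
        raise TypeError(f"unsupported parameter object {type(params)!r}")
    if overrides:
        dimless = dimless.replace(**overrides)
    return dimless, n0


def simulate(params, *, h: float = 0.02, dt: float | None = None,
             t_max: float = 5.0, stepper: str = "imex",
             snapshot_times: Sequence[float] = (1.0, 3.0, 5.0),
             series_interval: float = 0.05, upwind: bool = False,
             overrides: dict | None = None, n0: float | None = None,
             progress: Callable[[float], None] | None = None) -> SimulationResult:
    """Run the Boyden-chamber assay in silico.

    Parameters
    ----------
    params
        :class:`DimensionalParameters` (non-dimensionalized exactly once at
        start) or a ready :class:`DimensionlessParameters` (then ``n0`` is
        required for the observables).
    h, dt, t_max, stepper
        Grid spacing, time step and final time in dimensionless units
        (t in hours).  ``dt=None`` picks 1e-4 for the IMEX stepper and 90% of
        the diffusive stability bound for forward Euler.
    snapshot_times
        Times (snapped to the stepping lattice) at which full states are
        stored; the final state is always stored.
    series_interval
        Cadence of the (t, N_f, H) observable series.
    overrides
        Dimensionless parameter overrides applied after non-dimensionalization
        (used by the beta/delta comparisons and the no-decoy reduction).

    The run is fully deterministic: identical inputs give bit-identical
    results on one platform.
    """
    dimless, n0 = _resolve(params, overrides, n0)
    grid = build_grid(dimless, h)
    if dt is None:
        dt = 1e-4 if stepper == "imex" else 0.9 * dimless.stability_dt(grid.h)
    n_steps = max(1, int(round(t_max / dt)))
    dt = t_max / n_steps

    if stepper == "imex":
        imex = ImexStepper(dimless, grid, dt, upwind=upwind)
        advance = imex.step
    elif stepper == "euler":
        if dt > dimless.stability_dt(grid.h):
            raise ValueError(
                f"dt={dt:g} exceeds the Euler stability bound "
                f"{dimless.stability_dt(grid.h):g}"
            )
        advance = lambda s: step_euler(s, dimless, grid, dt)  # noqa: E731
    else:
        raise ValueError(f"unknown stepper {stepper!r} (use 'euler' or 'imex')")

    snap_steps = sorted({min(n_steps, max(0, int(round(ts / dt))))
                         for ts in snapshot_times} | {n_steps})
    series_every = max(1, int(round(series_interval / dt)))

    state = initial_state(grid, dimless)
    snapshots: list[StateFields] = []
    ts, nfs, hs = [0.0], [migrated_count(state.n, n0, grid)], \
        [penetration_depth(state.n, n0, grid)]
    if 0 in snap_steps:
        snapshots.append(state.copy())
    clip_count = 0
    for k in range(1, n_steps + 1):
        state = advance(state)
        state.t = k * dt        # avoid accumulated float drift
        clip_count += getattr(state, "_clips", 0)
        if k % series_every == 0 or k == n_steps:
            ts.append(state.t)
            nfs.append(migrated_count(state.n, n0, grid))
            hs.append(penetration_depth(state.n, n0, grid))
        if k in snap_steps:
            snapshots.append(state.copy())
        if progress is not None and k % max(1, n_steps // 100) == 0:
            progress(state.t)

    series = pd.DataFrame({"t": ts, "N_f": nfs, "H": hs})
    return SimulationResult(
        snapshots=snapshots, series=series, params_used=dimless, grid=grid,
        n0=n0, h=grid.h, dt=dt, stepper=stepper, t_max=t_max,
        clip_count=clip_count, warnings=grid.warnings,
    )
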
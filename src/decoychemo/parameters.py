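"""Model parameters: dimensional values, validation, and non-dimensionalization.

The model describes glioma cells migrating through the porous filter of a
Boyden chamber, driven by random motility, chemo-attraction up the gradient of
ligand-bound normal receptors (CD95) and chemo-repulsion up the gradient of
ligand-bound decoy receptors (DcR3).  All dynamics are computed in
dimensionless form: lengths are scaled by the filter thickness ``L_f``, time
by ``T`` (one hour), cell density by the initial upper-well density ``n0``,
ligand concentration by the initial lower-well concentration ``c0``, and the
per-cell bound receptor numbers by the resting per-cell receptor contents
``Gamma_r`` / ``Gamma_d``.

This module is the single source of truth for every symbol; the solver never
touches a dimensional quantity after :func:`nondimensionalize` has run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields, replace

__all__ = [
    "DimensionalParameters",
    "DimensionlessParameters",
    "validate",
    "nondimensionalize",
    "redimensionalize",
]

# Dimensional fields that may legitimately be zero: the whole decoy channel
# (no-decoy limit) switches off by zeroing these.
_MAY_BE_ZERO = {"beta", "delta", "mu", "Gamma_d", "k_a2", "k_d2", "k_i2"}


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional model parameters.

    Defaults are the literature/estimated values for glioma cells with CD95 /
    CD95L / DcR3 kinetics.  The ligand unit is treated as opaque ("ligand-unit
    per cm^3"): only the products ``k_a * T * c0`` enter the dimensionless
    system, so no molar-mass conversion is ever needed.

    Units: lengths cm, times s, diffusivities cm^2/s, chemotactic
    coefficients cm^2/(s mol), association rates cm^3/(s ligand-unit),
    dissociation/internalization rates 1/s, receptor contents mol/cell,
    ``beta``/``delta`` 1/mol, ``n0`` cells/cm^3, ``c0`` ligand-unit/cm^3.
    """

    D_n: float = 1.3e-10        # cell random motility
    D_c: float = 7.3e-6         # ligand diffusivity
    chi: float = 2.0e12         # chemo-attractant coefficient
    mu: float = 1.0e10          # chemo-repellent coefficient
    k_a1: float = 1.67e7        # CD95 association rate
    k_a2: float = 8.33e7        # DcR3 association rate
    k_d1: float = 0.0058        # CD95 dissociation rate
    k_d2: float = 0.0029        # DcR3 dissociation rate
    k_i1: float = 0.004         # CD95 internalization rate
    k_i2: float = 8.0e-4        # DcR3 internalization rate
    beta: float = 0.97 / 4.98e-21    # normal-receptor upregulation rate
    delta: float = 0.952 / 3.984e-21  # decoy-receptor upregulation rate
    Gamma_r: float = 4.98e-21   # resting free CD95 per cell
    Gamma_d: float = 3.984e-21  # resting free DcR3 per cell
    L: float = 9.2e-4           # cell diameter
    L_u: float = 0.0375         # upper-well height
    L_f: float = 0.015          # filter thickness
    L_l: float = 0.03125        # lower-well height
    n0: float = 4.0e5           # initial upper-well cell density
    c0: float = 6.0e-8          # initial lower-well ligand concentration
    T: float = 3600.0           # time scale (1 h)

    def replace(self, **changes: float) -> "DimensionalParameters":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DimensionlessParameters:
    """Dimensionless (tilde) parameter set.

    ``beta``/``delta`` here are the dimensionless upregulation rates
    (``beta * Gamma_r`` and ``delta * Gamma_d`` of the dimensional set);
    they must lie below 1 or per-cell receptor numbers grow without bound.
    ``L``, ``L_u``, ``L_l`` are lengths in filter-thickness units.
    """

    D_n: float
    D_c: float
    chi: float
    mu: float
    k_a1: float
    k_a2: float
    k_d1: float
    k_d2: float
    k_i1: float
    k_i2: float
    Gamma_r: float
    Gamma_d: float
    beta: float
    delta: float
    L: float
    L_u: float
    L_l: float

    def replace(self, **changes: float) -> "DimensionlessParameters":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return asdict(self)

    def as_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)

    def stability_dt(self, h: float) -> float:
        """Largest forward-Euler step stable for the ligand diffusion term."""
        return h * h / (2.0 * self.D_c)

    def diffusion_number(self, dt: float, h: float) -> float:
        """Explicit-stability indicator ``dt * D_c / h^2`` (stable below 1/2)."""
        return dt * self.D_c / (h * h)


def validate(params: DimensionalParameters) -> list[str]:
    """Check the admissibility of a dimensional parameter set.

    Returns a list of human-readable violation descriptions (empty iff the
    parameter set is admissible).  Diagnostics, not exceptions: callers that
    need a hard failure raise on a non-empty return.
    """
    violations: list[str] = []
    for f in fields(params):
        value = getattr(params, f.name)
        if not isinstance(value, (int, float)):
            violations.append(f"{f.name}: not a number ({value!r})")
            continue
        if f.name in _MAY_BE_ZERO:
            if value < 0:
                violations.append(f"{f.name}: must be >= 0, got {value!r}")
        elif value <= 0:
            violations.append(f"{f.name}: must be > 0, got {value!r}")
    if params.beta * params.Gamma_r > 1.0:
        violations.append(
            "beta: beta*Gamma_r = "
            f"{params.beta * params.Gamma_r:g} > 1 (unbounded receptor upregulation)"
        )
    if params.delta * params.Gamma_d > 1.0:
        violations.append(
            "delta: delta*Gamma_d = "
            f"{params.delta * params.Gamma_d:g} > 1 (unbounded receptor upregulation)"
        )
    if params.L >= params.L_f:
        violations.append(
            f"L: cell diameter {params.L:g} must be smaller than the filter "
            f"thickness L_f = {params.L_f:g}"
        )
    return violations


def nondimensionalize(params: DimensionalParameters) -> DimensionlessParameters:
    """Map dimensional parameters to the dimensionless (tilde) set.

    Exact arithmetic per the scalings: diffusivities and chemotactic
    coefficients scale with ``T / L_f**2`` (the latter also carrying
    ``Gamma_r`` / ``Gamma_d``), first-order rates with ``T``, association
    rates with ``T * c0``, receptor contents with ``n0 / c0``, upregulation
    rates with the corresponding ``Gamma``, lengths with ``L_f``.
    """
    violations = validate(params)
    if violations:
        raise ValueError(
            "invalid parameters: " + "; ".join(violations)
        )
    p = params
    s = p.T / p.L_f**2
    return DimensionlessParameters(
        D_n=p.D_n * s,
        D_c=p.D_c * s,
        chi=p.chi * s * p.Gamma_r,
        mu=p.mu * s * p.Gamma_d,
        k_a1=p.k_a1 * p.T * p.c0,
        k_a2=p.k_a2 * p.T * p.c0,
        k_d1=p.k_d1 * p.T,
        k_d2=p.k_d2 * p.T,
        k_i1=p.k_i1 * p.T,
        k_i2=p.k_i2 * p.T,
        Gamma_r=p.Gamma_r * p.n0 / p.c0,
        Gamma_d=p.Gamma_d * p.n0 / p.c0,
        beta=p.beta * p.Gamma_r,
        delta=p.delta * p.Gamma_d,
        L=p.L / p.L_f,
        L_u=p.L_u / p.L_f,
        L_l=p.L_l / p.L_f,
    )


def redimensionalize(
    dimless: DimensionlessParameters,
    *,
    L_f: float,
    T: float,
    n0: float,
    c0: float,
) -> DimensionalParameters:
    """Invert :func:`nondimensionalize` given the four scales.

    ``Gamma_r``/``Gamma_d`` are recovered from the dimensionless receptor
    contents and then used to unwind ``chi``, ``mu``, ``beta``, ``delta``.
    Round-trips to machine precision.
    """
    d = dimless
    s = T / L_f**2
    Gamma_r = d.Gamma_r * c0 / n0
    Gamma_d = d.Gamma_d * c0 / n0
    return DimensionalParameters(
        D_n=d.D_n / s,
        D_c=d.D_c / s,
        chi=d.chi / (s * Gamma_r),
        mu=d.mu / (s * Gamma_d) if Gamma_d > 0 else 0.0,
        k_a1=d.k_a1 / (T * c0),
        k_a2=d.k_a2 / (T * c0),
        k_d1=d.k_d1 / T,
        k_d2=d.k_d2 / T,
        k_i1=d.k_i1 / T,
        k_i2=d.k_i2 / T,
        beta=d.beta / Gamma_r,
        delta=d.delta / Gamma_d if Gamma_d > 0 else 0.0,
        Gamma_r=Gamma_r,
        Gamma_d=Gamma_d,
        L=d.L * L_f,
        L_u=d.L_u * L_f,
        L_f=L_f,
        L_l=d.L_l * L_f,
        n0=n0,
        c0=c0,
        T=T,
    )
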
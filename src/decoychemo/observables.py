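"""Migration observables and the parameter sweeps built on them.

Two scalar summaries characterize a run at evaluation time ``t``:

* ``N_f`` — the migrated cell count, ``n0`` times the trapezoid integral of
  the dimensionless cell density over the filter ``[0, 1]``;
* ``H`` — the penetration depth of the cell wavefront, ``1 - sup{x : n(x) <
  1/n0}``: cells enter at ``x = 1``, so ``H`` measures how far the front
  (at the one-cell-per-``n0`` detection threshold) has travelled into the
  filter.  The supremum over an empty set is 0 (``H = 1``) and the front
  position is refined by linear interpolation between the bracketing nodes
  so that sweeps in ``c0`` are not quantized by the mesh.

The initial ligand concentration ``c0`` enters the dimensionless dynamics
through ``k_a * T * c0`` and ``Gamma * n0 / c0``, so each sweep row
re-derives the dimensionless parameter set from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ChamberGrid

__all__ = [
    "MigrationSummary",
    "migrated_count",
    "penetration_depth",
    "percent_change",
    "sweep_c0",
    "find_unimodal_argmax",
    "fl1h_rescale",
]

FL1H_SCALE = 1e9    # maps c0 (ligand-unit/cm^3) onto the FL1-H cytometry axis


@dataclass(frozen=True)
class MigrationSummary:
    """Migrated count ``N_f`` (cells) and penetration depth ``H`` at time ``t`` (h)."""

    N_f: float
    H: float
    t: float

    def __post_init__(self):
        if self.N_f < 0:
            raise ValueError(f"N_f must be non-negative, got {self.N_f!r}")
        if not 0.0 <= self.H <= 1.0:
            raise ValueError(f"H must lie in [0, 1], got {self.H!r}")


def migrated_count(n, n0: float, grid: ChamberGrid) -> float:
    """``N_f = n0 * trapz(n, x)`` over the filter nodes."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("cell density must be non-negative")
    return float(n0 * np.trapezoid(n, dx=grid.h))


def penetration_depth(n, n0: float, grid: ChamberGrid) -> float:
    """Wavefront penetration depth ``H = 1 - sup{x : n(x) < 1/n0}``.

    The supremum is located on the grid and refined by linear interpolation
    between the bracketing nodes.  Conventions: no sub-threshold node means
    the supremum of the empty set, 0, hence ``H = 1``; an entirely
    sub-threshold profile means the supremum is 1 and ``H = 0``.
    """
    n = np.asarray(n, dtype=float)
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if np.any(n < 0):
        raise ValueError("cell density must be non-negative")
    theta = 1.0 / n0
    x = grid.x_filter - grid.x_filter[0]   # filter coordinates in [0, 1]
    below = n < theta
    if not below.any():
        return 1.0
    if below.all():
        return 0.0
    i = int(np.flatnonzero(below)[-1])     # last sub-threshold node
    if i == len(n) - 1:
        sup = x[i]
    else:
        # refine the crossing between node i (below) and node i+1 (at/above)
        dn = n[i + 1] - n[i]
        frac = (theta - n[i]) / dn if dn > 0 else 0.0
        sup = x[i] + frac * grid.h
    return float(1.0 - min(sup, 1.0))


def percent_change(reference: float, variant: float) -> float:
    """Percent change of ``variant`` relative to ``reference`` (> 0)."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference!r}")
    return 100.0 * (variant - reference) / reference


def sweep_c0(params, c0_values, *, t_max: float = 5.0, **controls) -> pd.DataFrame:
    """One full simulation per initial ligand concentration.

    All other inputs are held fixed; the dimensionless parameter set is
    re-derived for every row.  Rows are returned in input order with columns
    ``c0, c0_fl1h, N_f, H, status``; a failing row is marked and the sweep
    continues.
    """
    from .spatial import simulate  # local import: observables <-> spatial

    rows = []
    for c0 in c0_values:
        if c0 <= 0:
            raise ValueError(f"c0 values must be positive, got {c0!r}")
        try:
            res, status = _simulate_with_fallback(
                simulate, params.replace(c0=float(c0)), t_max=t_max, **controls)
            rows.append({"c0": c0, "c0_fl1h": fl1h_rescale(c0),
                         "N_f": res.migrated_count(), "H": res.penetration_depth(),
                         "status": status})
        except Exception as exc:  # isolate per-row failures
            rows.append({"c0": c0, "c0_fl1h": fl1h_rescale(c0),
                         "N_f": np.nan, "H": np.nan,
                         "status": f"failed: {exc}"})
    return pd.DataFrame(rows)


def _simulate_with_fallback(simulate, params, *, t_max=5.0, **controls):
    """Run with the default central advection; on a positivity abort retry
    once with the first-order upwind scheme (monotone, oscillation-free)."""
    controls.setdefault("snapshot_times", (t_max,))
    if controls.get("upwind"):
        return simulate(params, t_max=t_max, **controls), "ok (upwind)"
    try:
        return simulate(params, t_max=t_max, **controls), "ok"
    except RuntimeError:
        controls["upwind"] = True
        return simulate(params, t_max=t_max, **controls), "ok (upwind fallback)"


_INV_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def find_unimodal_argmax(xs, ys, f=None, *, xtol: float = 1e-10) -> float:
    """Locate the interior maximum of a unimodal sampled curve.

    The coarse-grid argmax is refined between its bracketing neighbours: by
    golden-section search re-evaluating ``f`` until the bracket is narrower
    than ``xtol``, or, when no evaluator is given, by the vertex of the
    parabola through the three bracketing points.  Monotone samples (argmax
    on the boundary) raise ``ValueError("no interior maximum")``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    i = int(np.argmax(ys))
    if i == 0 or i == len(xs) - 1:
        raise ValueError("no interior maximum: samples are monotone "
                         "(argmax on the boundary)")
    a, b = xs[i - 1], xs[i + 1]
    if f is None:
        # parabola through the three bracketing points
        x0, x1, x2 = xs[i - 1:i + 2]
        y0, y1, y2 = ys[i - 1:i + 2]
        denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
        if denom == 0:
            return float(x1)
        num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
        vertex = x1 - 0.5 * num / denom
        return float(np.clip(vertex, a, b))
    x1 = b - _INV_GOLDEN * (b - a)
    x2 = a + _INV_GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    while (b - a) > xtol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + _INV_GOLDEN * (b - a)
            f2 = f(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - _INV_GOLDEN * (b - a)
            f1 = f(x1)
    return float(0.5 * (a + b))


def fl1h_rescale(c0: float) -> float:
    """Map ``c0`` to the FL1-H relative-concentration axis (scale 1e9)."""
    if c0 < 0:
        raise ValueError(f"c0 must be non-negative, got {c0!r}")
    return c0 * FL1H_SCALE
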
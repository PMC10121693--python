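"""Uniform 1-D discretization of the Boyden chamber.

The chamber is one continuous node set spanning the lower well
``[-L_l, 0]``, the filter ``[0, 1]`` and the upper well ``[1, 1 + L_u]``
(lengths in filter-thickness units).  Ligand lives on every node; cells and
per-cell receptor occupancies live on the filter nodes only.  The filter
faces ``x = 0`` and ``x = 1`` fall exactly on nodes: the requested spacing is
snapped so the filter holds an integer number of intervals, and each well
length is snapped to the nearest multiple of the spacing (deviations are
recorded as warnings on the grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChamberGrid", "build_grid"]

_SNAP_TOL = 1e-9


@dataclass(frozen=True)
class ChamberGrid:
    h: float                    # node spacing (filter-thickness units)
    m_lower: int                # intervals in the lower well
    m_filter: int               # intervals in the filter
    m_upper: int                # intervals in the upper well
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_nodes(self) -> int:
        return self.m_lower + self.m_filter + self.m_upper + 1

    @property
    def i0(self) -> int:
        """Index of the x = 0 node (lower filter face)."""
        return self.m_lower

    @property
    def i1(self) -> int:
        """Index of the x = 1 node (upper filter face)."""
        return self.m_lower + self.m_filter

    @property
    def filter_slice(self) -> slice:
        return slice(self.i0, self.i1 + 1)

    @property
    def n_filter_nodes(self) -> int:
        return self.m_filter + 1

    @property
    def x(self) -> np.ndarray:
        """Node coordinates spanning ``[-L_l, 1 + L_u]`` (snapped)."""
        return (np.arange(self.n_nodes) - self.m_lower) * self.h

    @property
    def x_filter(self) -> np.ndarray:
        return self.x[self.filter_slice]

    def key(self) -> tuple:
        """Hashable identity for caching operators built on this grid."""
        return (self.h, self.m_lower, self.m_filter, self.m_upper)


def build_grid(params, h: float = 0.02) -> ChamberGrid:
    """Discretize the chamber described by (dimensionless) ``params``.

    ``params`` needs attributes ``L_l`` and ``L_u``.  Requires
    ``0 < h <= 0.1`` and at least 11 filter nodes.  If ``h`` does not divide
    the unit filter thickness it is adjusted to the nearest value that does;
    well lengths are snapped to multiples of the (adjusted) spacing.  Every
    adjustment is recorded in ``grid.warnings``.
    """
    if not 0 < h <= 0.5:
        raise ValueError(f"h must be in (0, 0.5], got {h!r}")
    warnings: list[str] = []
    m_filter = int(round(1.0 / h))
    h_eff = 1.0 / m_filter
    if abs(h_eff - h) > _SNAP_TOL * max(1.0, 1.0 / h):
        warnings.append(f"h adjusted from {h:g} to {h_eff:g} so x=0 and x=1 fall on nodes")
    if m_filter < 10:
        # production runs want >= 11 filter nodes; tiny grids stay legal for
        # hand-checkable examples
        warnings.append(f"filter resolved by only {m_filter + 1} nodes")
    m_lower = max(1, int(round(params.L_l / h_eff)))
    m_upper = max(1, int(round(params.L_u / h_eff)))
    if abs(m_lower * h_eff - params.L_l) > _SNAP_TOL:
        warnings.append(
            f"lower-well length snapped from {params.L_l:g} to {m_lower * h_eff:g}"
        )
    if abs(m_upper * h_eff - params.L_u) > _SNAP_TOL:
        warnings.append(
            f"upper-well length snapped from {params.L_u:g} to {m_upper * h_eff:g}"
        )
    return ChamberGrid(h=h_eff, m_lower=m_lower, m_filter=m_filter,
                       m_upper=m_upper, warnings=tuple(warnings))
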
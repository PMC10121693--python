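"""Count-versus-concentration curves for model-experiment comparison.

The source experiment measured migrated DcR3-transfected glioma cell counts
by flow cytometry over a range of relative CD95L concentrations (the FL1-H
channel).  The model side of the comparison is the ``N_f``-versus-``c0``
curve with ``c0`` rescaled onto the FL1-H axis.  Curves are exchanged as
two-column CSV (a spreadsheet table re-exports to this in one step: open
and save-as CSV).  A deterministic synthetic generator emulating the
experimental shape — counts rising with concentration up to a peak and
falling beyond it, plus counting noise — makes the comparison path testable
without the experimental table.

The comparison is shape-based, never a fit: the two curves live on different
ordinate scales (cell counts vs cytometry events), so each is min-max
normalized before the RMSE is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountsCurve",
    "read_counts_curve",
    "write_counts_curve",
    "synthesize_counts_curve",
    "compare_model_to_counts",
]


@dataclass(frozen=True)
class CountsCurve:
    """Migrated-cell counts over relative ligand concentration (FL1-H units)."""

    fl1h: np.ndarray
    count: np.ndarray
    source: str = "model"       # experimental | synthetic | model

    def __post_init__(self):
        fl1h = np.asarray(self.fl1h, dtype=float)
        count = np.asarray(self.count, dtype=float)
        object.__setattr__(self, "fl1h", fl1h)
        object.__setattr__(self, "count", count)
        if fl1h.shape != count.shape or fl1h.ndim != 1:
            raise ValueError("fl1h and count must be 1-D arrays of equal length")
        if len(fl1h) == 0:
            raise ValueError("curve must be non-empty")
        if np.any(np.diff(fl1h) <= 0):
            raise ValueError("fl1h values must be strictly increasing")
        if np.any(count < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.fl1h)

    @property
    def argmax_fl1h(self) -> float:
        return float(self.fl1h[int(np.argmax(self.count))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fl1h": self.fl1h, "count": self.count})


def read_counts_curve(path, source: str = "experimental") -> CountsCurve:
    """Parse a two-column (fl1h, count) CSV; ``#`` lines are comments.

    Rows are sorted by FL1-H (a warning is issued if the input was
    unsorted); duplicate FL1-H values or non-numeric cells are errors.
    """
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (fl1h, count)")
    df = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise ValueError(f"{path}: non-numeric rows in counts curve")
    fl1h = df.iloc[:, 0].to_numpy(float)
    count = df.iloc[:, 1].to_numpy(float)
    if len(np.unique(fl1h)) != len(fl1h):
        raise ValueError(f"{path}: duplicate fl1h values")
    order = np.argsort(fl1h)
    if not np.array_equal(order, np.arange(len(fl1h))):
        warnings.warn(f"{path}: rows were not sorted by fl1h; sorting", stacklevel=2)
        fl1h, count = fl1h[order], count[order]
    return CountsCurve(fl1h=fl1h, count=count, source=source)


def write_counts_curve(curve: CountsCurve, path, provenance: dict | None = None) -> None:
    """Write a curve as CSV, with the resolved configuration as # comments."""
    with open(path, "w") as fh:
        fh.write(f"# source: {curve.source}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        curve.to_frame().to_csv(fh, index=False)


def synthesize_counts_curve(n_points: int = 25, peak_fl1h: float = 18.0,
                            peak_count: float = 200.0, noise_sd: float = 0.0,
                            seed: int = 0, fl1h_values=None,
                            shape: float = 2.0) -> CountsCurve:
    """Deterministic synthetic stand-in for the experimental counts table.

    The mean is a skewed gamma-type bump ``peak_count * (x/x_p)^a *
    exp(a (1 - x/x_p))`` peaking exactly at ``peak_fl1h``, emulating counts
    that rise with ligand concentration and fall past a threshold; i.i.d.
    Gaussian noise (sd ``noise_sd``) is added and truncated at zero.  The
    same seed always returns identical rows.
    """
    if n_points < 5:
        raise ValueError("need at least 5 points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if fl1h_values is None:
        fl1h_values = np.linspace(peak_fl1h / 6.0, 3.0 * peak_fl1h, n_points)
    x = np.asarray(fl1h_values, dtype=float)
    a = shape
    mean = peak_count * (x / peak_fl1h) ** a * np.exp(a * (1.0 - x / peak_fl1h))
    rng = np.random.default_rng(seed)
    count = np.clip(mean + rng.normal(0.0, noise_sd, size=x.shape)
                    if noise_sd > 0 else mean, 0.0, None)
    return CountsCurve(fl1h=x, count=count, source="synthetic")


@dataclass(frozen=True)
class ComparisonReport:
    model_argmax_fl1h: float
    data_argmax_fl1h: float
    normalized_rmse: float
    model_postpeak_slope_sign: int
    data_postpeak_slope_sign: int
    overlap: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "model_argmax_fl1h": self.model_argmax_fl1h,
            "data_argmax_fl1h": self.data_argmax_fl1h,
            "normalized_rmse": self.normalized_rmse,
            "model_postpeak_slope_sign": self.model_postpeak_slope_sign,
            "data_postpeak_slope_sign": self.data_postpeak_slope_sign,
            "overlap": list(self.overlap),
        }


def _minmax(y: np.ndarray) -> np.ndarray:
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        return np.zeros_like(y)
    return (y - lo) / (hi - lo)


def _postpeak_sign(curve: CountsCurve) -> int:
    i = int(np.argmax(curve.count))
    if i >= len(curve) - 1:
        return 0
    return int(np.sign(curve.count[-1] - curve.count[i]))


def compare_model_to_counts(model_curve: CountsCurve,
                            data_curve: CountsCurve) -> ComparisonReport:
    """Shape comparison of a model curve against a data curve (no fitting).

    Reports each curve's FL1-H at peak, the min-max-normalized RMSE over the
    overlapping FL1-H range (model linearly interpolated onto the data
    abscissae), and the sign of each curve's post-peak slope.
    """
    lo = max(model_curve.fl1h[0], data_curve.fl1h[0])
    hi = min(model_curve.fl1h[-1], data_curve.fl1h[-1])
    if lo >= hi:
        raise ValueError("curves have disjoint FL1-H ranges")
    mask = (data_curve.fl1h >= lo) & (data_curve.fl1h <= hi)
    xs = data_curve.fl1h[mask]
    model_on_data = np.interp(xs, model_curve.fl1h, model_curve.count)
    rmse = float(np.sqrt(np.mean((_minmax(model_on_data) -
                                  _minmax(data_curve.count[mask])) ** 2)))
    return ComparisonReport(
        model_argmax_fl1h=model_curve.argmax_fl1h,
        data_argmax_fl1h=data_curve.argmax_fl1h,
        normalized_rmse=rmse,
        model_postpeak_slope_sign=_postpeak_sign(model_curve),
        data_postpeak_slope_sign=_postpeak_sign(data_curve),
        overlap=(float(lo), float(hi)),
    )
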
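"""Full response-surface enumeration and the deterministic yield demo.

The study grid crosses three levels each of progeny count, marker count,
QTL count and heritability with five levels of the epistatic proportion
(3 x 3 x 3 x 5 x 3 = 405 factor combinations).  ``summarize_surface``
reduces a table of per-point mean responses to the maximum, its argmax,
threshold-exceedance fractions and a histogram.  ``yield_surface`` is the
closed-form two-factor toy surface (yield vs temperature and drought) used
to illustrate response-surface ideas; its trigonometric arguments are in
radians, the only reading under which the maximum falls at 73-74 degrees F.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "STUDY_GRID_LEVELS",
    "SurfaceSummary",
    "enumerate_grid",
    "summarize_surface",
    "yield_surface",
    "yield_argmax",
]

#: The study grid (405 combinations). The top heritability level is 0.8;
#: a variant with h = 1.0 as the top level is obtained by passing custom
#: levels to :func:`enumerate_grid`.
STUDY_GRID_LEVELS: dict[str, list] = {
    "ind": [200, 1000, 2000],
    "m": [100, 400, 1000],
    "qtl": [10, 50, 100],
    "epi": [0.0, 0.2, 0.5, 0.8, 1.0],
    "h": [0.2, 0.5, 0.8],
}


def enumerate_grid(levels: dict[str, list] | None = None) -> pd.DataFrame:
    """Cartesian product of per-factor level lists, one row per design point.

    Rows are ordered with the last factor cycling fastest (itertools order);
    duplicate-free as long as each level list is.
    """
    levels = levels or STUDY_GRID_LEVELS
    if not levels or any(len(v) == 0 for v in levels.values()):
        raise ConfigurationError("every factor needs at least one level")
    rows = list(itertools.product(*levels.values()))
    return pd.DataFrame(rows, columns=list(levels))


@dataclass
class SurfaceSummary:
    """Reduction of a grid of mean responses."""

    max_response: float
    argmax: dict
    threshold_fractions: dict[float, float]
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    n_points: int


def summarize_surface(
    grid_results: pd.DataFrame,
    response_col: str,
    thresholds: tuple[float, ...] = (0.2,),
    bin_width: float = 0.05,
) -> SurfaceSummary:
    """Maximum, argmax, exceedance fractions and histogram of a response column."""
    if response_col not in grid_results:
        raise ConfigurationError(f"no column {response_col!r} in the grid results")
    r = grid_results[response_col].to_numpy(dtype=float)
    imax = int(np.argmax(r))
    lo = np.floor(r.min() / bin_width) * bin_width
    hi = np.ceil(r.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width) if hi > lo else np.array([lo, lo + bin_width])
    counts, edges = np.histogram(r, bins=edges)
    return SurfaceSummary(
        max_response=float(r[imax]),
        argmax=grid_results.iloc[imax].to_dict(),
        threshold_fractions={t: float(np.mean(r > t)) for t in thresholds},
        histogram_counts=counts,
        histogram_edges=edges,
        n_points=len(r),
    )


def yield_surface(temperature, drought):
    """Toy crop-yield surface (temperature in degrees F, drought in SPI).

    yield = 110 + cos(0.25 d)^2 + sin(0.15 T)^2 + 0.0024375 d T,
    trigonometric arguments in radians.  Vectorized over both inputs.
    """
    t = np.asarray(temperature, dtype=float)
    d = np.asarray(drought, dtype=float)
    out = 110.0 + np.cos(0.25 * d) ** 2 + np.sin(0.15 * t) ** 2 + 0.0024375 * d * t
    return float(out) if out.ndim == 0 else out


def yield_argmax(
    resolution: float = 0.01,
    t_range: tuple[float, float] = (64.0, 80.0),
    d_range: tuple[float, float] = (-4.0, 4.0),
) -> dict:
    """Grid argmax of the yield surface at the given resolution."""
    ts = np.arange(t_range[0], t_range[1] + resolution / 2, resolution)
    ds = np.arange(d_range[0], d_range[1] + resolution / 2, resolution)
    Y = yield_surface(ts[:, None], ds[None, :])
    i, j = np.unravel_index(np.argmax(Y), Y.shape)
    return {"temperature": float(ts[i]), "drought": float(ds[j]), "yield": float(Y[i, j])}
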
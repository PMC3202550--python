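"""Equal-count size binning and the U-shaped size-specific mortality curve.

Trees alive at the start of an observation window are sorted by diameter and
grouped into bins of equal count; the annual mortality rate of each bin is
derived from the interval-censored death fraction via the constant-annual-
rate identity S(t) = (1 - m)^t, and the flexible three-parameter function

    m(D) = a + b * D * exp(c * D)        (D in mm)

is fitted to the binned (mean D, m) points by nonlinear least squares.  For
a > 0, b < 0 and c < 0 the curve is U-shaped on D > 0 with a unique minimum
at D = -1/c, and the decline below the minimum is steeper than the rise
above it -- the shape expected when asymmetric competition kills small
trees and exogenous disturbance kills large ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .census import STATUS_DEAD, TreeRecord, ValidationError

__all__ = [
    "SizeBin",
    "SizeCurveFit",
    "FitError",
    "equal_count_bins",
    "annual_mortality",
    "mortality_bins",
    "eval_mortality_curve",
    "curve_minimum",
    "fit_mortality_curve",
]


class FitError(RuntimeError):
    """The nonlinear fit failed to converge from every starting point."""


@dataclass(frozen=True)
class SizeBin:
    """One equal-count diameter bin with its interval-censored mortality."""

    mean_d_mm: float
    n: int
    deaths: int
    annual_m: float


@dataclass(frozen=True)
class SizeCurveFit:
    bins: tuple[SizeBin, ...]
    params: tuple[float, float, float]  # (a, b, c)
    rss: float
    converged: bool


def equal_count_bins(
    records: Sequence[TreeRecord], census: str, bin_size: int = 1000
) -> list[list[TreeRecord]]:
    """Sort live trees by (D, tree_id) and cut into consecutive equal bins.

    All bins hold exactly ``bin_size`` trees except the last, which holds
    the remainder.  The (D, tree_id) sort key makes the split deterministic
    under ties and input reordering.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bad = [r.tree_id for r in records if not r.is_alive(census)]
    if bad:
        raise ValidationError(
            f"{len(bad)} record(s) not alive at census {census!r}", bad
        )
    ordered = sorted(records, key=lambda r: (r.diameter_at(census), r.tree_id))
    return [ordered[i : i + bin_size] for i in range(0, len(ordered), bin_size)]


def annual_mortality(n: int, deaths: int, t: float) -> float:
    """Annual rate m solving (1 - m)^t = 1 - deaths/n.

    The inverse of the constant-annual-survival identity; for t = 1 it
    reduces to the raw death fraction, and deaths = n gives m = 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= deaths <= n):
        raise ValueError("deaths must be between 0 and n")
    if t <= 0:
        raise ValueError("t must be positive")
    return 1.0 - (1.0 - deaths / n) ** (1.0 / t)


def mortality_bins(
    records: Sequence[TreeRecord],
    start_census: str,
    end_census: str,
    t_years: float,
    bin_size: int = 1000,
) -> list[SizeBin]:
    """Equal-count bins at the start census with annualized mortality.

    Trees absent at the end census (e.g. never remeasured) are excluded
    before binning; a tree counts as a death if its end status is dead.
    """
    tracked = [
        r
        for r in records
        if r.is_alive(start_census) and r.status_at(end_census) != "absent"
    ]
    bins = equal_count_bins(tracked, start_census, bin_size)
    out = []
    for group in bins:
        n = len(group)
        deaths = sum(1 for r in group if r.status_at(end_census) == STATUS_DEAD)
        mean_d = float(np.mean([r.diameter_at(start_census) for r in group]))
        out.append(
            SizeBin(mean_d_mm=mean_d, n=n, deaths=deaths, annual_m=annual_mortality(n, deaths, t_years))
        )
    return out


def eval_mortality_curve(
    d_mm: float | np.ndarray, params: Sequence[float]
) -> float | np.ndarray:
    """Evaluate m(D) = a + b*D*exp(c*D) with D in mm."""
    a, b, c = params
    d = np.asarray(d_mm, dtype=float)
    m = a + b * d * np.exp(c * d)
    return float(m) if np.isscalar(d_mm) else m


def curve_minimum(params: Sequence[float]) -> tuple[float, float]:
    """Analytic minimum of the U-shaped curve: D = -1/c (mm) and m there.

    Valid for the U-shaped regime b < 0, c < 0, where dm/dD =
    b*exp(cD)*(1 + cD) has its unique root at D = -1/c.
    """
    a, b, c = params
    if c >= 0 or b >= 0:
        raise ValueError("curve is U-shaped only for b < 0 and c < 0")
    d_min = -1.0 / c
    return d_min, float(eval_mortality_curve(d_min, params))


_DEFAULT_C_STARTS = (-0.02, -0.01, -0.005, -0.002)


def fit_mortality_curve(
    bins: Sequence[SizeBin],
    c_starts: Sequence[float] = _DEFAULT_C_STARTS,
) -> SizeCurveFit:
    """Unweighted nonlinear least squares of m(D) on the binned points.

    Multi-start over a small grid of c (the curvature sets the scale of the
    size axis and is the hard parameter); a starts at the largest observed
    bin rate, b at zero.  The best converged start by residual sum of
    squares wins; if every start fails a :class:`FitError` is raised.
    """
    if len(bins) < 4:
        raise ValueError("need at least 4 bins to fit 3 parameters")
    x = np.array([b.mean_d_mm for b in bins])
    y = np.array([b.annual_m for b in bins])

    def model(d, a, b, c):
        return a + b * d * np.exp(c * d)

    best: tuple[float, tuple[float, float, float]] | None = None
    failures: list[str] = []
    for c0 in c_starts:
        try:
            popt, _ = curve_fit(model, x, y, p0=(float(y.max()), 0.0, c0), maxfev=20000)
        except RuntimeError as err:
            failures.append(f"c0={c0}: {err}")
            continue
        rss = float(np.sum((y - model(x, *popt)) ** 2))
        if np.isfinite(rss) and (best is None or rss < best[0]):
            best = (rss, tuple(float(v) for v in popt))
    if best is None:
        raise FitError("no start converged: " + " | ".join(failures))
    return SizeCurveFit(bins=tuple(bins), params=best[1], rss=best[0], converged=True)
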
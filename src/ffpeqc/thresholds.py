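"""Data-driven derivation of the QC cutoffs.

The three cutoffs are read off smoothed cohort relationships:

* the correlation cutoff from the inflection (knee) of the replicate
  FPR vs median correlation curve,
* the detected-gene cutoff by mapping the correlation cutoff through
  the (approximately monotone) correlation vs detected-genes relation,
* the read-depth cutoff from the saturation curve of detected genes vs
  gene-mapped reads: the depth at which the fit reaches a fraction
  (default 85%) of its plateau.

Smoothing is locally weighted quadratic regression (loess, tricube
weights) evaluated on an even grid. A windowed local failure-rate curve
relates a lab metric (e.g. library concentration) to QC outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class NoInflectionError(ValueError):
    """The smoothed curve has no detectable curvature."""


class ExtrapolationError(ValueError):
    """Requested evaluation point lies outside the data range."""


@dataclass
class SmoothedCurve:
    x_grid: np.ndarray
    y_fit: np.ndarray
    span: float


@dataclass
class FailureRateCurve:
    window_centers: np.ndarray
    local_rate: np.ndarray
    window_n: np.ndarray

    @property
    def overall_rate(self) -> float:
        return float(np.sum(self.local_rate * self.window_n) / np.sum(self.window_n))


def _local_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray, x0: float, degree: int) -> float:
    xc = x - x0
    sw = np.sqrt(w)
    for deg in range(degree, -1, -1):
        design = np.vander(xc, deg + 1, increasing=True)
        a = design * sw[:, None]
        b = y * sw
        beta, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        if rank == deg + 1:
            return float(beta[0])
    return float(np.average(y, weights=w))


def loess_fit(x, y, span: float = 0.75, n_grid: int = 100, degree: int = 2) -> SmoothedCurve:
    """Locally weighted polynomial regression on an even grid.

    At each grid point the ``ceil(span * n)`` nearest data points are
    fit with a weighted degree-2 polynomial under tricube weights
    ``(1 - (d/h)^3)^3`` where ``h`` is the bandwidth (distance to the
    furthest neighbor). Exact polynomials of degree <= 2 are reproduced
    exactly. Rank-deficient local fits (too few distinct x) fall back
    to lower degree.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 10:
        raise ValueError("loess needs at least 10 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = x.size
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(
            f"span {span} covers only {k} points, need at least {degree + 2}; use a larger span"
        )
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n_grid = max(int(n_grid), 100)
    grid = np.linspace(xs[0], xs[-1], n_grid)
    fit = np.empty(n_grid)
    for i, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:
            fit[i] = float(np.mean(ys[idx]))
            continue
        w = np.clip(1 - (d[idx] / h) ** 3, 0, None) ** 3
        pos = w > 0
        if pos.sum() < 2:
            fit[i] = float(np.mean(ys[idx]))
            continue
        fit[i] = _local_fit(xs[idx][pos], ys[idx][pos], w[pos], x0, degree)
    return SmoothedCurve(x_grid=grid, y_fit=fit, span=float(span))


def find_inflection(curve: SmoothedCurve) -> float:
    """Grid x maximizing the absolute second difference of the fit.

    This operationalizes the "inflection point" of a knee-shaped curve:
    where the smoothed curve bends hardest. A (numerically) straight
    line has no inflection and raises :class:`NoInflectionError`.
    """
    y = np.asarray(curve.y_fit, dtype=float)
    if y.size < 3:
        raise NoInflectionError("curve too short for second differences")
    d2 = np.abs(np.diff(y, 2))
    scale = float(np.ptp(y))
    if d2.max() <= 1e-8 * max(scale, 1e-12):
        raise NoInflectionError("curve has no detectable curvature (straight line?)")
    return float(curve.x_grid[int(np.argmax(d2)) + 1])


def map_threshold(
    x, y, x_cutoff: float, span: float = 0.75, resolution: float = 1.0
) -> float:
    """Map a cutoff on x to the corresponding y via a loess fit.

    The smoothed y is evaluated at ``x_cutoff`` (which must lie inside
    the data range) and rounded to the declared resolution of y, e.g.
    ``resolution=100`` for a detected-gene count.
    """
    x = np.asarray(x, dtype=float)
    if x_cutoff < x.min() or x_cutoff > x.max():
        raise ExtrapolationError(
            f"x_cutoff {x_cutoff} outside data range [{x.min():g}, {x.max():g}]"
        )
    curve = loess_fit(x, y, span=span)
    y_at = float(np.interp(x_cutoff, curve.x_grid, curve.y_fit))
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return float(np.round(y_at / resolution) * resolution)


def saturation_threshold(
    reads, tpm4, fraction: float = 0.85, span: float = 0.5
) -> tuple[float, float]:
    """Read-depth cutoff from the detected-genes saturation curve.

    The plateau is the maximum of the loess fit; the cutoff is the
    smallest grid depth whose fitted detected-gene count reaches
    ``fraction`` of the plateau. Returns ``(reads_cutoff, plateau)``.
    The default span is tighter than elsewhere because the saturation
    curve bends sharply at low depth and a wide window underfits the
    knee region.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    curve = loess_fit(reads, tpm4, span=span)
    plateau = float(curve.y_fit.max())
    target = fraction * plateau
    reached = np.nonzero(curve.y_fit >= target)[0]
    if reached.size == 0:
        raise ValueError("fitted curve never reaches the target fraction of plateau")
    return float(curve.x_grid[reached[0]]), plateau


def local_failure_rate(metric, status, n_windows: int) -> FailureRateCurve:
    """Windowed failure rate along a lab metric.

    Samples are split into ``n_windows`` quantile windows of the metric
    (equal occupancy; tied windows are merged with a warning) and the
    FAIL fraction is computed per window. The occupancy-weighted mean
    of the window rates equals the overall failure rate exactly.
    """
    metric = pd.Series(np.asarray(metric, dtype=float))
    status = np.asarray(status)
    if metric.size != status.size:
        raise ValueError("metric and status have different lengths")
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    fail = status == "FAIL"
    bins = pd.qcut(metric, q=n_windows, duplicates="drop")
    if bins.cat.categories.size < n_windows:
        warnings.warn(
            f"ties reduced {n_windows} windows to {bins.cat.categories.size}",
            stacklevel=2,
        )
    grouped = pd.DataFrame({"metric": metric, "fail": fail, "bin": bins}).groupby(
        "bin", observed=True
    )
    centers = grouped["metric"].mean().to_numpy()
    rates = grouped["fail"].mean().to_numpy()
    ns = grouped["fail"].size().to_numpy()
    return FailureRateCurve(window_centers=centers, local_rate=rates, window_n=ns)


def derive_thresholds(
    fpr_vs_cor: tuple,
    cor_vs_tpm4: tuple,
    reads_vs_tpm4: tuple,
    span: float = 0.75,
    fraction: float = 0.85,
    tpm4_resolution: float = 100.0,
    cor_cutoff: float | None = None,
    saturation_span: float = 0.5,
) -> dict:
    """Derive the (cor_min, tpm4_min, reads_min) triple from cohort data.

    Parameters are three (x, y) pairs: replicate FPR vs median
    correlation, median correlation vs detected genes, and gene reads
    vs detected genes. ``cor_cutoff`` overrides the knee-derived
    correlation cutoff (the study's choice near the knee is ultimately
    a judgement call).
    """
    if cor_cutoff is None:
        curve = loess_fit(*fpr_vs_cor, span=span)
        cor_cutoff = find_inflection(curve)
    tpm4_min = map_threshold(
        cor_vs_tpm4[0], cor_vs_tpm4[1], cor_cutoff, span=span, resolution=tpm4_resolution
    )
    reads_grid, tpm4_grid = reads_vs_tpm4
    reads_min, plateau = saturation_threshold(
        reads_grid, tpm4_grid, fraction=fraction, span=saturation_span
    )
    return {
        "cor_min": float(cor_cutoff),
        "tpm4_min": float(tpm4_min),
        "reads_min": float(reads_min),
        "saturation_plateau": plateau,
        "span": span,
        "saturation_fraction": fraction,
    }
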
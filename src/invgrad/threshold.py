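"""Invasion-impact threshold detection and performance-standard compliance.

The threshold procedure sorts plots by descending invader relative
abundance, smooths both the abundance and native-richness series with a
running average whose bin equals the number of transects, fits a
polynomial trend of smoothed richness on smoothed abundance, and locates
either the native-richness maximum or the onset of its declining limb.
The invader abundance at that point is the impact threshold that
motivates a relative-abundance performance standard (10% by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .datamodel import DataModelError, PlotSample, StudyDataset

logger = logging.getLogger(__name__)


def sort_by_invader(
    dataset: StudyDataset, invaders: Iterable[str] | None = None
) -> tuple[PlotSample, ...]:
    """Plots in non-increasing order of invader relative abundance.

    Ties are broken by (transect_id, plot_id), making the order
    deterministic for any input.
    """
    names = frozenset(invaders) if invaders is not None else dataset.target_invader
    return tuple(
        sorted(
            dataset.plots,
            key=lambda p: (
                -dataset.invader_relative_abundance(p, names),
                p.transect_id,
                p.plot_id,
            ),
        )
    )


@dataclass(frozen=True)
class RunningAverageCurve:
    """Sliding-window means of (invader abundance %, native richness).

    ``bin`` is the window width b; there are n_plots - b + 1 points,
    ordered by descending smoothed abundance.
    """

    bin: int
    points: tuple[tuple[float, float], ...]

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["invader_relabund", "native_richness"])


def running_average(
    x: Sequence[float], y: Sequence[float], bin: int
) -> RunningAverageCurve:
    """Sliding window of width ``bin`` (unit step) over paired series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if bin < 1:
        raise DataModelError("bin must be >= 1")
    if bin > n:
        raise DataModelError(f"bin {bin} exceeds number of plots {n}")
    kernel = np.ones(bin) / bin
    xbar = np.convolve(x, kernel, mode="valid")
    ybar = np.convolve(y, kernel, mode="valid")
    return RunningAverageCurve(
        bin=int(bin), points=tuple(zip(xbar.tolist(), ybar.tolist()))
    )


def running_average_curve(
    dataset: StudyDataset,
    bin: int | None = None,
    invaders: Iterable[str] | None = None,
) -> RunningAverageCurve:
    """Running-average richness curve for a study.

    ``bin`` defaults to the number of transects, the original group bin
    size of the study design.
    """
    names = frozenset(invaders) if invaders is not None else dataset.target_invader
    b = bin if bin is not None else dataset.n_transects
    ordered = sort_by_invader(dataset, names)
    x = [dataset.invader_relative_abundance(p, names) for p in ordered]
    y = [dataset.native_richness(p) for p in ordered]
    return running_average(x, y, b)


@dataclass(frozen=True)
class PolynomialFit:
    """Least-squares polynomial trend of smoothed native richness.

    ``axis`` records the predictor: ``"abundance"`` fits richness on the
    smoothed invader abundance directly; ``"sequence"`` fits richness on
    the sorted plot-sequence position (ascending invasion), the axis on
    which the richness trend is superimposed over the invasion-gradient
    curve.
    """

    degree: int
    coefficients: tuple[float, ...]  # ascending powers
    r_squared: float
    axis: str = "abundance"

    def polynomial(self) -> Polynomial:
        return Polynomial(self.coefficients)

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.polynomial()(x)


def _fit_xy(x: np.ndarray, y: np.ndarray, degree: int, axis: str) -> PolynomialFit:
    if len(x) <= degree:
        raise DataModelError(f"need more than degree={degree} points, got {len(x)}")
    if np.ptp(x) == 0:
        raise DataModelError("degenerate design: all predictor values equal")
    poly = Polynomial.fit(x, y, deg=degree).convert()
    resid = y - poly(x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PolynomialFit(
        degree=int(degree),
        coefficients=tuple(float(c) for c in poly.coef),
        r_squared=r2,
        axis=axis,
    )


def fit_polynomial_trend(
    curve: RunningAverageCurve, degree: int = 3, axis: str = "abundance"
) -> PolynomialFit:
    """Least-squares polynomial trend of the running-average richness.

    ``axis="abundance"``: ybar ~ P(xbar).  ``axis="sequence"``: ybar ~
    P(s) where s = 0, 1, ... indexes the sorted plots from the uninvaded
    end upward (evenly spaced, so the fit is not skewed by the strongly
    non-uniform distribution of abundances along the gradient).
    """
    if axis not in {"abundance", "sequence"}:
        raise DataModelError(f"unknown fit axis {axis!r}")
    if axis == "abundance":
        return _fit_xy(curve.x, curve.y, degree, axis)
    s = np.arange(len(curve.points), dtype=float)
    return _fit_xy(s, curve.y[::-1], degree, axis)


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float            # % invader relative abundance
    fit_degree: int
    coefficients: tuple[float, ...]
    r_squared: float
    mode: str                   # "peak" | "declining_limb_onset"
    axis: str = "sequence"      # predictor the trend was fitted on
    flagged: bool = False       # True when no interior peak existed


def _locate_on_fit(
    poly: Polynomial, lo: float, hi: float, mode: str
) -> tuple[float, bool]:
    """Peak or declining-limb-onset position of P over [lo, hi].

    Scanning from ``lo`` upward, the declining-limb onset is the first
    point where P' turns from >= 0 to < 0 (the first interior local
    maximum); with no interior maximum the relevant endpoint is returned,
    flagged.
    """
    dp = poly.deriv()
    d2p = dp.deriv()
    interior_maxima = sorted(
        float(r.real)
        for r in dp.roots()
        if abs(r.imag) < 1e-9 and lo < r.real < hi and d2p(r.real) < 0
    )
    if mode == "peak":
        candidates = interior_maxima + [lo, hi]
        pos = max(candidates, key=lambda c: poly(c))
        flagged = not interior_maxima and pos in (lo, hi)
        if flagged:
            logger.warning("no interior richness peak; threshold at range endpoint")
        return pos, flagged
    if interior_maxima:
        return interior_maxima[0], False
    if dp(lo) < 0:
        logger.warning("trend declining over entire range; threshold at low end")
        return lo, True
    logger.warning("trend never declines; threshold at high end")
    return hi, True


def detect_threshold(
    curve: RunningAverageCurve,
    degree: int = 3,
    mode: str = "declining_limb_onset",
    axis: str = "sequence",
    fit: PolynomialFit | None = None,
) -> ThresholdEstimate:
    """Locate the invasion threshold on the fitted richness trend.

    ``mode="peak"`` takes the native-richness maximum of the trend;
    ``mode="declining_limb_onset"`` (default) the point where the trend
    first turns downward scanning from the uninvaded end — the start of
    the declining limb of the richness hump.

    With the default ``axis="sequence"`` the trend is fitted over the
    sorted plot sequence and the threshold is the smoothed invader
    abundance at the detected sequence position (the vertical-projection
    reading of the superimposed gradient and richness curves).
    ``axis="abundance"`` fits and detects directly on the smoothed
    abundance values.  Results are clipped to the observed abundance
    range; a monotone trend yields a flagged endpoint estimate.
    """
    if mode not in {"peak", "declining_limb_onset"}:
        raise DataModelError(f"unknown threshold mode {mode!r}")
    if fit is None:
        fit = fit_polynomial_trend(curve, degree=degree, axis=axis)
    elif fit.axis != axis:
        raise DataModelError(
            f"fit axis {fit.axis!r} does not match requested axis {axis!r}"
        )
    poly = fit.polynomial()
    x = curve.x
    lo, hi = float(x.min()), float(x.max())
    if axis == "abundance":
        pos, flagged = _locate_on_fit(poly, lo, hi, mode)
        threshold = pos
    else:
        s = np.arange(len(curve.points), dtype=float)
        x_ascending = x[::-1]  # uninvaded end first
        pos, flagged = _locate_on_fit(poly, 0.0, float(s[-1]), mode)
        threshold = float(np.interp(pos, s, x_ascending))
    return ThresholdEstimate(
        threshold=float(np.clip(threshold, lo, hi)),
        fit_degree=fit.degree,
        coefficients=fit.coefficients,
        r_squared=fit.r_squared,
        mode=mode,
        axis=axis,
        flagged=flagged,
    )


def estimate_threshold(
    dataset: StudyDataset,
    bin: int | None = None,
    degree: int = 3,
    mode: str = "declining_limb_onset",
    axis: str = "sequence",
    invaders: Iterable[str] | None = None,
) -> ThresholdEstimate:
    """End-to-end: sort, running average, polynomial fit, detection."""
    curve = running_average_curve(dataset, bin=bin, invaders=invaders)
    return detect_threshold(curve, degree=degree, mode=mode, axis=axis)


@dataclass(frozen=True)
class ZoneCompliance:
    zone: str
    cumulative_relabund: float  # percent
    standard: float
    passed: bool


@dataclass(frozen=True)
class ComplianceReport:
    standard: float
    zones: tuple[ZoneCompliance, ...]
    overall: ZoneCompliance

    def as_frame(self) -> pd.DataFrame:
        rows = [*self.zones, self.overall]
        return pd.DataFrame(
            [
                {
                    "zone": z.zone,
                    "cumulative_invader_relabund_pct": z.cumulative_relabund,
                    "standard_pct": z.standard,
                    "pass": z.passed,
                }
                for z in rows
            ]
        )


def _cumulative_relabund(plots: Sequence[PlotSample], invaders: frozenset[str]) -> float:
    total = sum(p.total_cover for p in plots)
    if total == 0:
        raise DataModelError("zone has zero total cover")
    inv = sum(c for p in plots for sp, c in p.cover.items() if sp in invaders)
    return 100.0 * inv / total


def evaluate_standard(
    dataset: StudyDataset,
    invaders: Iterable[str] | None = None,
    standard: float = 10.0,
    zone_of: Mapping[str, str] | None = None,
) -> ComplianceReport:
    """Performance-standard compliance check.

    Cumulative invader relative abundance (summed over all listed
    invaders, pooled covers) is compared against the standard with
    "no greater than" semantics: a zone passes iff its cumulative value
    is <= the standard (a value exactly at the standard complies).
    ``zone_of`` maps plot_id to a monitoring zone; by default each
    transect is a zone.
    """
    if invaders is None:
        names = dataset.target_invader
    else:
        names = frozenset(invaders)
    unknown = [n for n in names if n not in dataset.species]
    if unknown:
        raise DataModelError(f"unknown invader name(s): {unknown}")
    if not names:
        raise DataModelError("invader set is empty")

    zones: dict[str, list[PlotSample]] = {}
    for p in dataset.plots:
        z = zone_of[p.plot_id] if zone_of is not None else p.transect_id
        zones.setdefault(z, []).append(p)

    zone_rows = []
    for z in sorted(zones):
        val = _cumulative_relabund(zones[z], names)
        zone_rows.append(
            ZoneCompliance(zone=z, cumulative_relabund=val, standard=standard,
                           passed=val <= standard)
        )
    overall_val = _cumulative_relabund(dataset.plots, names)
    overall = ZoneCompliance(
        zone="overall", cumulative_relabund=overall_val, standard=standard,
        passed=overall_val <= standard,
    )
    return ComplianceReport(standard=standard, zones=tuple(zone_rows), overall=overall)
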
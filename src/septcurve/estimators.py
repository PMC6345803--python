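"""Measurement procedures: persistence length, binding isotherm,
membrane moduli from aspiration, and vesicle spike geometry.

Each estimator is a reusable fit over a plain data container; the
matching synthetic generators live in :mod:`septcurve.synth`, and each
generator/estimator pair closes a round trip in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .errors import DomainError, EstimationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FilamentTrackSet",
    "TangentCorrelation",
    "BindingCurve",
    "AspirationSeries",
    "SpikeStats",
    "PersistenceLengthFit",
    "HillFit",
    "ModulusFit",
    "tangent_correlation",
    "fit_persistence_length",
    "fit_hill",
    "fit_bending_modulus",
    "fit_stretching_modulus",
    "measure_spikes",
    "tension_from_aspiration",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class FilamentTrackSet:
    """Digitized 2D filament backbones.

    ``tracks``: list of (M, 2) float arrays of (x, y) points in nm,
    each an ordered polyline of one filament in one frame.
    ``frame_ids`` / ``filament_ids``: parallel integer labels.
    """

    tracks: Sequence[np.ndarray]
    frame_ids: Sequence[int] = ()
    filament_ids: Sequence[int] = ()
    pixel_size_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValidationError("FilamentTrackSet requires >= 1 track")
        for i, t in enumerate(self.tracks):
            a = np.asarray(t, dtype=float)
            if a.ndim != 2 or a.shape[1] != 2:
                raise ValidationError(f"track {i} is not an (M, 2) array")
            if a.shape[0] < 3:
                raise ValidationError(f"track {i} has fewer than 3 points")
            if np.any(np.all(np.diff(a, axis=0) == 0.0, axis=1)):
                raise ValidationError(f"track {i} has repeated consecutive points")


@dataclass(frozen=True)
class TangentCorrelation:
    """Binned tangent-angle correlation <cos theta>(L)."""

    L_nm: np.ndarray  # bin centers (arclength separation)
    mean_cos: np.ndarray
    count: np.ndarray  # ordered point pairs per bin
    bin_width_nm: float = 0.0


@dataclass(frozen=True)
class BindingCurve:
    """Saturation-binding curve: surface density vs bulk concentration."""

    bulk_nM: np.ndarray
    bound_per_um2: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.bulk_nM, dtype=float)
        y = np.asarray(self.bound_per_um2, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValidationError("bulk and bound arrays must be equal-length 1D")
        if np.any(x < 0) or np.any(np.diff(x) <= 0):
            raise ValidationError("bulk concentrations must be >= 0 and strictly increasing")
        if np.any(y < 0):
            raise ValidationError("bound densities must be >= 0")


@dataclass(frozen=True)
class AspirationSeries:
    """Micropipette aspiration series: tension vs relative projected area."""

    tension_N_per_m: np.ndarray
    rel_area: np.ndarray
    rel_volume: np.ndarray | None = None
    sigma0_N_per_m: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.tension_N_per_m, dtype=float)
        a = np.asarray(self.rel_area, dtype=float)
        if s.shape != a.shape or s.ndim != 1:
            raise ValidationError("tension and area arrays must be equal-length 1D")
        if np.any(s <= 0):
            raise ValidationError("tensions must be > 0")
        if np.any(np.diff(s) < 0):
            raise ValidationError("series must be sorted by tension")

    @property
    def sigma0(self) -> float:
        if self.sigma0_N_per_m is not None:
            return self.sigma0_N_per_m
        return float(np.min(self.tension_N_per_m))


@dataclass(frozen=True)
class SpikeStats:
    """Per-vesicle spike geometry: mean height A, mean inter-spike
    distance lambda, mean concave osculating radius R between spikes."""

    amplitude_um: float
    period_um: float
    concave_radius_um: float
    n_spikes: int


@dataclass(frozen=True)
class PersistenceLengthFit:
    Lp_nm: float
    se_nm: float
    slope_per_nm: float
    intercept: float
    n_bins: int


@dataclass(frozen=True)
class HillFit:
    S_sat: float
    Kd_nM: float
    hill_n: float
    se_S_sat: float
    se_Kd_nM: float
    se_hill_n: float


@dataclass(frozen=True)
class ModulusFit:
    value: float  # kappa in k_bT, or Ka in mN/m
    se: float
    n_points: int


# ---------------------------------------------------------------------------
# persistence length


def _smooth_polyline(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    kernel = np.ones(window) / window
    out = np.empty_like(points)
    for k in (0, 1):
        out[:, k] = np.convolve(points[:, k], kernel, mode="same")
    # 'same' convolution distorts the ends; keep raw endpoints there
    half = window // 2
    out[:half] = points[:half]
    out[len(points) - half:] = points[len(points) - half:]
    return out


def tangent_correlation(
    tracks: FilamentTrackSet,
    bin_width_nm: float,
    smoothing_window: int = 3,
) -> TangentCorrelation:
    """Tangent-angle correlation <cos theta>(L) pooled over all tracks.

    Tangents are computed by central differences on each (optionally
    moving-average smoothed) polyline; <cos theta> is averaged over all
    ordered point pairs whose arclength separation falls in each bin,
    equal-weighted per pair and pooled across tracks and frames.  The
    L = 0 bin contains the self pairs and is exactly 1.

    Tracks too short to carry a central-difference tangent are skipped
    with a warning; an all-skipped set raises :class:`EstimationError`.
    """
    if bin_width_nm <= 0:
        raise DomainError(f"bin_width_nm must be > 0, got {bin_width_nm}")
    sums: dict[int, float] = {}
    lsums: dict[int, float] = {}
    counts: dict[int, int] = {}
    used = 0
    for idx, raw in enumerate(tracks.tracks):
        pts = np.asarray(raw, dtype=float)
        if pts.shape[0] < 3:
            logger.warning("track %d too short for tangents; skipped", idx)
            continue
        pts = _smooth_polyline(pts, smoothing_window)
        # central differences: tangent at interior point i from i-1, i+1
        diffs = pts[2:] - pts[:-2]
        norms = np.linalg.norm(diffs, axis=1)
        ok = norms > 0
        if np.count_nonzero(ok) < 2:
            logger.warning("track %d degenerate after smoothing; skipped", idx)
            continue
        tangents = diffs[ok] / norms[ok, None]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])[1:-1][ok]
        cosmat = tangents @ tangents.T
        sep = np.abs(arclen[:, None] - arclen[None, :])
        iu, ju = np.triu_indices(len(arclen))
        seps = sep[iu, ju]
        # bin 0 holds only the zero-separation (self) pairs, so that
        # <cos theta>(0) = 1 exactly; all others round to >= 1
        bins = np.maximum(np.rint(seps / bin_width_nm).astype(int), 1)
        bins[seps == 0.0] = 0
        np.clip(cosmat, -1.0, 1.0, out=cosmat)
        vals = cosmat[iu, ju]
        for b in np.unique(bins):
            m = bins == b
            sums[b] = sums.get(b, 0.0) + float(vals[m].sum())
            lsums[b] = lsums.get(b, 0.0) + float(seps[m].sum())
            counts[b] = counts.get(b, 0) + int(m.sum())
        used += 1
    if used == 0:
        raise EstimationError("all tracks were skipped; no tangent pairs")
    keys = sorted(counts)
    # report the mean pair separation per bin (unbiased abscissa)
    L = np.array([lsums[k] / counts[k] for k in keys])
    mc = np.array([sums[k] / counts[k] for k in keys])
    ct = np.array([counts[k] for k in keys])
    return TangentCorrelation(L_nm=L, mean_cos=mc, count=ct, bin_width_nm=bin_width_nm)


def fit_persistence_length(
    corr: TangentCorrelation,
    fit_range_nm: tuple[float, float] | None = None,
    min_mean_cos: float = 0.2,
    min_count: int = 50,
) -> PersistenceLengthFit:
    """Persistence length from the semi-log decay of <cos theta>(L).

    For a 2D worm-like chain <cos theta>(L) = exp(-L / (2 Lp)), so a
    weighted linear regression (weights = pair counts) of
    ln <cos theta> on L gives Lp = -1 / (2 * slope).  By default the fit
    uses bins with <cos theta> > ``min_mean_cos`` and at least
    ``min_count`` pairs; an explicit ``fit_range_nm`` restricts L
    further, shrinking with a warning if it includes non-positive
    correlations.
    """
    L = np.asarray(corr.L_nm, dtype=float)
    mc = np.asarray(corr.mean_cos, dtype=float)
    ct = np.asarray(corr.count, dtype=float)
    mask = (mc > max(min_mean_cos, 0.0)) & (ct >= min_count)
    if fit_range_nm is not None:
        lo, hi = fit_range_nm
        in_range = (L >= lo) & (L <= hi)
        bad = in_range & (mc <= 0)
        if np.any(bad):
            logger.warning(
                "fit range shrunk: %d bins with non-positive <cos theta>",
                int(bad.sum()),
            )
        mask = in_range & (mc > 0) & (ct >= 1)
    if np.count_nonzero(mask) < 2:
        raise EstimationError("fewer than 2 usable bins for the semilog fit")
    x = L[mask]
    y = np.log(mc[mask])
    w = ct[mask]
    # weighted least squares, y = intercept + slope * x
    W = np.sqrt(w)
    A = np.stack([np.ones_like(x), x], axis=1) * W[:, None]
    b = y * W
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    intercept, slope = coef
    resid = b - A @ coef
    dof = max(len(x) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    se_slope = math.sqrt(cov[1, 1])
    if slope >= 0:
        raise EstimationError(
            f"non-negative semilog slope ({slope:.3g}); correlation does not decay"
        )
    Lp = -1.0 / (2.0 * slope)
    se_Lp = se_slope / (2.0 * slope * slope)
    return PersistenceLengthFit(
        Lp_nm=Lp,
        se_nm=se_Lp,
        slope_per_nm=float(slope),
        intercept=float(intercept),
        n_bins=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# binding isotherm


def _hill(x: np.ndarray, s_sat: float, kd: float, h: float) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = s_sat / ((kd / x[pos]) ** h + 1.0)
    return out


def fit_hill(
    curve: BindingCurve, fix_hill_n: float | None = None
) -> HillFit:
    """Nonlinear least squares of the Hill saturation isotherm

        bound = S_sat / ((Kd / bulk)^n + 1)

    Initial values: S_sat = max density, Kd = concentration nearest the
    half-maximal density, n = 1; all parameters bounded positive.
    ``fix_hill_n`` freezes the Hill coefficient (n = 1 recovers the
    one-site Langmuir isotherm).
    """
    x = np.asarray(curve.bulk_nM, dtype=float)
    y = np.asarray(curve.bound_per_um2, dtype=float)
    if len(x) < 4:
        logger.warning("fewer than 4 points: Hill fit may be unstable")
    ymax = float(np.max(y))
    if ymax <= 0:
        raise EstimationError("all densities are zero; nothing to fit")
    if not (np.any(y < 0.5 * ymax) and np.any(y > 0.5 * ymax)):
        logger.warning("densities do not span both sides of half-saturation")
    kd0 = float(x[np.argmin(np.abs(y - 0.5 * ymax))])
    kd0 = max(kd0, np.min(x[x > 0], initial=1.0))
    if fix_hill_n is None:
        p0 = [ymax, kd0, 1.0]
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
        fun = _hill
    else:
        if fix_hill_n <= 0:
            raise DomainError("fix_hill_n must be > 0")
        p0 = [ymax, kd0]
        bounds = ([0.0, 0.0], [np.inf, np.inf])

        def fun(xx, s_sat, kd):  # type: ignore[misc]
            return _hill(xx, s_sat, kd, fix_hill_n)

    try:
        popt, pcov = curve_fit(
            fun, x, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise EstimationError(f"Hill fit did not converge: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if fix_hill_n is None:
        s_sat, kd, h = popt
        se_s, se_kd, se_h = se
    else:
        s_sat, kd = popt
        h = fix_hill_n
        se_s, se_kd = se
        se_h = 0.0
    return HillFit(
        S_sat=float(s_sat),
        Kd_nM=float(kd),
        hill_n=float(h),
        se_S_sat=float(se_s),
        se_Kd_nM=float(se_kd),
        se_hill_n=float(se_h),
    )


# ---------------------------------------------------------------------------
# aspiration moduli


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope with standard error; returns (slope, se, intercept)."""
    A = np.stack([np.ones_like(x), x], axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = max(len(x) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    return float(coef[1]), math.sqrt(cov[1, 1]), float(coef[0])


def fit_bending_modulus(
    series: AspirationSeries, low_tension_cutoff_N_per_m: float = 5.0e-4
) -> ModulusFit:
    """Bending modulus from the low-tension (entropic) aspiration regime.

    In the fluctuation-dominated regime ln(sigma/sigma0) ~ 8 pi kappa *
    (dA/A0) / kT, so kappa = slope / (8 pi) in k_bT from a linear
    regression of ln(sigma/sigma0) on dA/A0 over points with
    sigma <= cutoff (default 0.5 mN/m).  Invariant to the choice of
    sigma0 (absorbed by the intercept).
    """
    s = np.asarray(series.tension_N_per_m, dtype=float)
    a = np.asarray(series.rel_area, dtype=float)
    mask = s <= low_tension_cutoff_N_per_m
    if np.count_nonzero(mask) < 4:
        raise EstimationError(
            f"need >= 4 points with tension <= {low_tension_cutoff_N_per_m} N/m, "
            f"got {int(mask.sum())}"
        )
    y = np.log(s[mask] / series.sigma0)
    slope, se, _ = _linfit(a[mask], y)
    if slope <= 0:
        raise EstimationError(
            f"non-positive low-tension slope ({slope:.3g}); no entropic regime"
        )
    return ModulusFit(
        value=slope / (8.0 * math.pi),
        se=se / (8.0 * math.pi),
        n_points=int(mask.sum()),
    )


def fit_stretching_modulus(
    series: AspirationSeries, high_tension_cutoff_N_per_m: float = 1.0e-3
) -> ModulusFit:
    """Stretching (area-dilation) modulus from the high-tension regime.

    There the area dilation follows dA/A0 = sigma/Ka + const, so
    Ka = 1/slope from a linear fit of dA/A0 on sigma over points with
    sigma >= cutoff (default 1 mN/m).  Reported in mN/m.
    """
    s = np.asarray(series.tension_N_per_m, dtype=float)
    a = np.asarray(series.rel_area, dtype=float)
    mask = s >= high_tension_cutoff_N_per_m
    if np.count_nonzero(mask) < 3:
        raise EstimationError(
            f"need >= 3 points with tension >= {high_tension_cutoff_N_per_m} N/m, "
            f"got {int(mask.sum())}"
        )
    slope, se, _ = _linfit(s[mask], a[mask])
    if slope <= 0:
        raise EstimationError(
            f"non-positive high-tension slope ({slope:.3g}); no dilation regime"
        )
    ka_N_per_m = 1.0 / slope
    return ModulusFit(
        value=ka_N_per_m * 1.0e3,
        se=(se / slope**2) * 1.0e3,
        n_points=int(mask.sum()),
    )


def tension_from_aspiration(
    delta_P_Pa: float, R_pipette_um: float, R_vesicle_um: float
) -> float:
    """Membrane tension from the aspiration Laplace relation:
    sigma = dP * Rp / (2 (1 - Rp/Rv)), in N/m."""
    if not (0 < R_pipette_um < R_vesicle_um):
        raise DomainError(
            f"need 0 < R_pipette < R_vesicle, got {R_pipette_um}, {R_vesicle_um}"
        )
    if delta_P_Pa < 0:
        raise DomainError(f"pressure difference must be >= 0, got {delta_P_Pa}")
    rp_m = R_pipette_um * 1e-6
    return delta_P_Pa * rp_m / (2.0 * (1.0 - R_pipette_um / R_vesicle_um))


# ---------------------------------------------------------------------------
# spike geometry


def _circular_smooth(r: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return r
    kernel = np.ones(window) / window
    ext = np.concatenate([r[-window:], r, r[:window]])
    return np.convolve(ext, kernel, mode="same")[window:-window]


def _kasa_circle_radius(xy: np.ndarray) -> float:
    """Least-squares (Kasa) circle fit; returns the radius."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.stack([x, y, np.ones_like(x)], axis=1)
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    return math.sqrt(max(sol[2] + cx * cx + cy * cy, 0.0))


def measure_spikes(
    contour_xy_um: np.ndarray,
    smoothing_window: int = 5,
    prominence_frac: float = 0.05,
) -> SpikeStats:
    """Quantify spike geometry of a closed quasi-circular vesicle contour.

    The contour (N x 2, µm; closure implied, last point != first) is
    unwrapped to polar coordinates r(phi) around its centroid.  Spikes
    are local maxima of the (circularly smoothed) radial profile with
    prominence >= ``prominence_frac`` * median(r).  Reported statistics:

    * amplitude A: mean over spikes of r_peak minus the mean radius at
      the two flanking inter-spike minima (the local baseline),
    * period lambda: mean Euclidean distance between consecutive spike
      tips,
    * concave radius R: mean least-squares circle radius over the
      bottom of each inter-spike window (points within 10% of the local
      valley depth above the minimum) -- the osculating circle of the
      concave membrane between protrusions.

    A contour with fewer than two detected spikes reports NaN statistics
    with the spike count.  Invariant to rotation, translation and cyclic
    point order.
    """
    pts = np.asarray(contour_xy_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("contour must be an (N, 2) array")
    if pts.shape[0] < 64:
        raise ValidationError("contour must have >= 64 points")
    try:
        from shapely.geometry import LinearRing

        if not LinearRing(pts).is_valid:
            raise ValidationError("contour is not a simple closed curve")
    except ImportError:  # pragma: no cover - shapely is a soft dependency
        pass
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.argsort(phi)
    pts = pts[order]
    rel = rel[order]
    r = np.linalg.norm(rel, axis=1)
    n = len(r)
    r_s = _circular_smooth(r, smoothing_window)
    # coordinate-smoothed contour for the osculating-circle fits: a
    # least-squares circle on raw jittered points of a shallow arc is
    # biased toward small radii, and smoothing tames the noise while
    # perturbing the arc's own curvature only to second order
    pts_s = np.stack(
        [_circular_smooth(pts[:, 0], smoothing_window),
         _circular_smooth(pts[:, 1], smoothing_window)],
        axis=1,
    )
    prominence = prominence_frac * float(np.median(r))
    ext = np.concatenate([r_s, r_s, r_s])
    peaks, _ = signal.find_peaks(ext, prominence=prominence)
    peaks = np.unique(peaks[(peaks >= n) & (peaks < 2 * n)] - n)
    n_spikes = int(len(peaks))
    if n_spikes < 2:
        return SpikeStats(math.nan, math.nan, math.nan, n_spikes)
    # inter-peak minima (on the smoothed profile, circular)
    minima = []
    for k in range(n_spikes):
        i0 = peaks[k]
        i1 = peaks[(k + 1) % n_spikes]
        idx = np.arange(i0, i1 if i1 > i0 else i1 + n) % n
        minima.append(int(idx[np.argmin(r_s[idx])]))
    minima = np.array(minima)
    # amplitude: peak radius minus mean of flanking minima radii
    amps = []
    for k in range(n_spikes):
        left = r[minima[k - 1]]
        right = r[minima[k]]
        amps.append(r[peaks[k]] - 0.5 * (left + right))
    # period: Euclidean distance between consecutive spike tips
    tips = pts[peaks]
    dists = np.linalg.norm(np.diff(np.vstack([tips, tips[:1]]), axis=0), axis=1)
    # concave radius: circle fit over the valley bottom of each window
    # (points within 10% of the local depth above the minimum radius,
    # which isolates the concave arc from the straight spike flanks)
    radii = []
    for k in range(n_spikes):
        i0 = peaks[k]
        i1 = peaks[(k + 1) % n_spikes]
        span = (i1 - i0) % n
        if span < 5:
            continue
        idx = np.arange(i0, i0 + span + 1) % n
        r_min = float(np.min(r_s[idx]))
        depth = min(r_s[i0], r_s[i1 % n]) - r_min
        sel = idx[r_s[idx] <= r_min + 0.10 * depth]
        if len(sel) < 5:
            # shallow or under-sampled valley: fall back to the central 20%
            lo = i0 + int(0.40 * span)
            hi = i0 + int(0.60 * span) + 1
            sel = np.arange(lo, hi) % n
        if len(sel) >= 3:
            radii.append(_kasa_circle_radius(pts_s[sel]))
    return SpikeStats(
        amplitude_um=float(np.mean(amps)),
        period_um=float(np.mean(dists)),
        concave_radius_um=float(np.mean(radii)) if radii else math.nan,
        n_spikes=n_spikes,
    )
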
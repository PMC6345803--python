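"""Seeded synthetic-data generators.

Every generator is a pure function of its configuration and seed: the
same inputs give bit-identical output.  A single top-level seed fans
out to per-generator child seeds through a fixed registry of spawn
keys, so adding a generator never perturbs the streams of the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .estimators import AspirationSeries, BindingCurve, FilamentTrackSet

logger = logging.getLogger(__name__)

__all__ = [
    "child_rng",
    "WavySubstrate",
    "generate_wlc",
    "generate_binding_curve",
    "generate_aspiration_series",
    "generate_spiky_contour",
    "generate_wavy_substrate",
]

#: fixed spawn keys: append-only, never renumber
_GENERATOR_KEYS = {
    "wlc": 0,
    "binding": 1,
    "aspiration": 2,
    "contour": 3,
    "substrate": 4,
}


def child_rng(seed: int, generator: str, replicate: int = 0) -> np.random.Generator:
    """Deterministic per-generator, per-replicate random stream."""
    key = _GENERATOR_KEYS[generator]
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(replicate)))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# worm-like chains


def generate_wlc(
    Lp_nm: float,
    contour_length_nm: float,
    n_chains: int,
    seed: int,
    step_nm: float | None = None,
    mode: str = "independent",
    frame_mixing: float = 0.5,
    replicate: int = 0,
) -> FilamentTrackSet:
    """Sample 2D worm-like-chain conformations.

    A chain is a tangent-angle random walk: i.i.d. Gaussian angle
    increments of mean 0 and variance step/Lp per step of length
    ``step_nm`` (default Lp/100), which yields the 2D correlation
    <cos theta(L)> = exp(-L / (2 Lp)).

    ``mode="independent"`` treats each chain as an independent
    conformation (the default); ``mode="time-correlated"`` emulates one
    filament imaged over frames whose angle increments mix a fraction
    ``frame_mixing`` of the previous frame with fresh noise (stationary,
    same marginal statistics).
    """
    if Lp_nm <= 0 or contour_length_nm <= 0:
        raise DomainError("Lp and contour length must be > 0")
    if n_chains < 1:
        raise DomainError("n_chains must be >= 1")
    if step_nm is None:
        step_nm = Lp_nm / 100.0
    if step_nm <= 0:
        raise DomainError("step_nm must be > 0")
    if step_nm >= Lp_nm / 10.0:
        logger.warning(
            "step (%g nm) >= Lp/10: discretization bias in tangent statistics",
            step_nm,
        )
    rng = child_rng(seed, "wlc", replicate)
    n_steps = max(int(round(contour_length_nm / step_nm)), 2)
    sd = math.sqrt(step_nm / Lp_nm)
    tracks = []
    prev_inc: np.ndarray | None = None
    for _ in range(n_chains):
        theta0 = rng.uniform(-math.pi, math.pi)
        fresh = rng.normal(0.0, sd, size=n_steps - 1)
        if mode == "time-correlated" and prev_inc is not None:
            rho = float(frame_mixing)
            inc = rho * prev_inc + math.sqrt(1.0 - rho * rho) * fresh
        elif mode not in ("independent", "time-correlated"):
            raise DomainError(f"unknown WLC mode {mode!r}")
        else:
            inc = fresh
        prev_inc = inc
        theta = theta0 + np.concatenate([[0.0], np.cumsum(inc)])
        dx = step_nm * np.cos(theta)
        dy = step_nm * np.sin(theta)
        xy = np.zeros((n_steps + 1, 2))
        xy[1:, 0] = np.cumsum(dx)
        xy[1:, 1] = np.cumsum(dy)
        tracks.append(xy)
    return FilamentTrackSet(
        tracks=tracks,
        frame_ids=list(range(n_chains)),
        filament_ids=[0] * n_chains if mode == "time-correlated" else list(range(n_chains)),
        pixel_size_nm=step_nm,
    )


# ---------------------------------------------------------------------------
# binding curves


def generate_binding_curve(
    S_sat: float,
    Kd_nM: float,
    conc_grid_nM: np.ndarray,
    hill_n: float = 1.0,
    cv_noise: float = 0.05,
    seed: int = 0,
    replicate: int = 0,
) -> BindingCurve:
    """Hill-isotherm binding curve with multiplicative Gaussian noise.

    densities = S_sat / ((Kd/c)^n + 1) * (1 + eps), eps ~ N(0, cv^2),
    truncated at zero.
    """
    if S_sat <= 0 or Kd_nM <= 0 or hill_n <= 0:
        raise DomainError("S_sat, Kd and hill_n must be > 0")
    if cv_noise < 0:
        raise DomainError("cv_noise must be >= 0")
    conc = np.asarray(conc_grid_nM, dtype=float)
    ideal = np.zeros_like(conc)
    pos = conc > 0
    ideal[pos] = S_sat / ((Kd_nM / conc[pos]) ** hill_n + 1.0)
    rng = child_rng(seed, "binding", replicate)
    eps = rng.normal(0.0, cv_noise, size=conc.shape) if cv_noise > 0 else 0.0
    bound = np.clip(ideal * (1.0 + eps), 0.0, None)
    return BindingCurve(bulk_nM=conc, bound_per_um2=bound)


# ---------------------------------------------------------------------------
# aspiration series


def generate_aspiration_series(
    sigma_grid_N_per_m: np.ndarray,
    kappa_kT: float | None = 10.5,
    Ka_mN_per_m: float | None = 65.0,
    sigma0_N_per_m: float | None = None,
    noise_sd: float = 1.0e-3,
    seed: int = 0,
    replicate: int = 0,
) -> AspirationSeries:
    """Two-regime tension-area aspiration series.

    dA/A0 = ln(sigma/sigma0) / (8 pi kappa)  [entropic, low tension]
          + sigma / Ka                       [dilation, high tension]
          + N(0, noise_sd)

    Either branch can be disabled by passing ``None`` for its modulus.
    The volume channel is constant (no osmotic effects).
    """
    sigma = np.asarray(sigma_grid_N_per_m, dtype=float)
    if np.any(sigma <= 0):
        raise DomainError("tensions must be > 0")
    if np.any(np.diff(sigma) < 0):
        raise DomainError("sigma grid must be sorted ascending")
    if kappa_kT is None and Ka_mN_per_m is None:
        raise DomainError("at least one of kappa_kT, Ka_mN_per_m is required")
    sigma0 = float(np.min(sigma)) if sigma0_N_per_m is None else float(sigma0_N_per_m)
    rel_area = np.zeros_like(sigma)
    if kappa_kT is not None:
        if kappa_kT <= 0:
            raise DomainError("kappa_kT must be > 0")
        rel_area += np.log(sigma / sigma0) / (8.0 * math.pi * kappa_kT)
    if Ka_mN_per_m is not None:
        if Ka_mN_per_m <= 0:
            raise DomainError("Ka_mN_per_m must be > 0")
        rel_area += sigma / (Ka_mN_per_m * 1.0e-3)
    if noise_sd > 0:
        rng = child_rng(seed, "aspiration", replicate)
        rel_area = rel_area + rng.normal(0.0, noise_sd, size=sigma.shape)
    return AspirationSeries(
        tension_N_per_m=sigma,
        rel_area=rel_area,
        rel_volume=np.zeros_like(sigma),
        sigma0_N_per_m=sigma0,
    )


# ---------------------------------------------------------------------------
# spiky vesicle contours


def _rotate(xy: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return xy @ np.array([[c, s], [-s, c]])


def generate_spiky_contour(
    base_radius_um: float = 10.0,
    amplitude_um: float = 0.9,
    period_um: float = 3.9,
    concave_radius_um: float = 1.0 / 1.1,
    n_points: int = 1024,
    jitter_sd_um: float = 0.02,
    seed: int = 0,
    replicate: int = 0,
) -> np.ndarray:
    """Closed spiky vesicle contour with controlled spike geometry.

    The contour alternates sharp spike tips at radius ``base_radius``
    with concave circular-arc valleys of exactly the requested
    osculating radius at radius base_radius - amplitude; tips connect
    to the valley arcs by tangent lines.  The spike count is
    round(2 pi base_radius / period).  Arcs-plus-tangents (rather than
    a Fourier star) keep the inter-spike concave radius an exact
    construction parameter.  The sampled polygon (uniform in arclength)
    gets radial Gaussian jitter and a random rigid rotation.

    Returns an (n_points, 2) array in µm (closure implied).
    """
    r0, A, lam, Rc = base_radius_um, amplitude_um, period_um, concave_radius_um
    if min(r0, lam, Rc) <= 0 or A < 0:
        raise DomainError("geometry parameters must be positive")
    if A >= r0:
        raise DomainError("amplitude must be smaller than the base radius")
    if lam >= 2.0 * math.pi * r0:
        raise DomainError("period must be smaller than the circumference")
    rng = child_rng(seed, "contour", replicate)
    if A == 0.0:
        phi = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
        r = r0 + (rng.normal(0.0, jitter_sd_um, size=n_points) if jitter_sd_um > 0 else 0.0)
        return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
    m = int(round(2.0 * math.pi * r0 / lam))
    if m < 3:
        raise DomainError("fewer than 3 spikes; decrease the period")
    r_valley = r0 - A
    d = r_valley + Rc  # valley-circle center distance from the origin
    half = math.pi / m
    tip = np.array([r0, 0.0])
    center = d * np.array([math.cos(half), math.sin(half)])
    tc = tip - center
    t = float(np.linalg.norm(tc))
    if t <= Rc:
        raise DomainError(
            "infeasible spike geometry: tip lies inside the valley circle "
            "(amplitude too small or concave radius too large)"
        )
    # tangent touch point on the origin-facing side of the valley circle
    gamma = math.acos(Rc / t)
    base_ang = math.atan2(tc[1], tc[0])
    cands = [
        center + Rc * np.array([math.cos(base_ang + s * gamma),
                                math.sin(base_ang + s * gamma)])
        for s in (+1.0, -1.0)
    ]
    touch = min(cands, key=lambda p: float(np.hypot(*p)))
    # arc from the touch point through the valley bottom to its mirror image
    bottom_ang = math.atan2(-center[1], -center[0])
    touch_ang = math.atan2(touch[1] - center[1], touch[0] - center[0])
    sweep = (bottom_ang - touch_ang) % (2.0 * math.pi)
    if sweep > math.pi:
        sweep -= 2.0 * math.pi
    # half-period piece: tangent line tip -> touch, then arc touch -> bottom
    n_dense = 400
    line = tip[None, :] + np.linspace(0.0, 1.0, n_dense, endpoint=False)[:, None] * (
        touch - tip
    )[None, :]
    arc_t = touch_ang + np.linspace(0.0, sweep, n_dense, endpoint=False)
    arc = center[None, :] + Rc * np.stack([np.cos(arc_t), np.sin(arc_t)], axis=1)
    half_piece = np.vstack([line, arc])
    # mirror across the bisector to complete one period, then replicate
    mirrored = _rotate(_rotate(half_piece, -half) * np.array([1.0, -1.0]), half)[::-1]
    period_piece = np.vstack([half_piece, mirrored])
    pieces = [
        _rotate(period_piece, 2.0 * math.pi * j / m) for j in range(m)
    ]
    dense = np.vstack(pieces)
    # resample uniformly in arclength
    closed = np.vstack([dense, dense[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_cum[-1]
    s_new = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(s_new, s_cum, closed[:, 0])
    y = np.interp(s_new, s_cum, closed[:, 1])
    contour = np.stack([x, y], axis=1)
    if jitter_sd_um > 0:
        radial = contour / np.linalg.norm(contour, axis=1, keepdims=True)
        contour = contour + radial * rng.normal(0.0, jitter_sd_um, size=(n_points, 1))
    return _rotate(contour, rng.uniform(0.0, 2.0 * math.pi))


# ---------------------------------------------------------------------------
# wavy substrates


@dataclass(frozen=True)
class WavySubstrate:
    """Sinusoidal substrate h(x) = A0 sin(2 pi x / lambda0) with its
    signed curvature field (hill crests positive)."""

    amplitude_um: float
    period_um: float
    x_um: np.ndarray
    height_um: np.ndarray
    curvature_per_um: np.ndarray

    @property
    def max_curvature_per_um(self) -> float:
        return float(np.max(self.curvature_per_um))

    @property
    def min_curvature_per_um(self) -> float:
        return float(np.min(self.curvature_per_um))


def generate_wavy_substrate(
    A0_um: float, lambda0_um: float, n_points: int = 2048
) -> WavySubstrate:
    """Wavy substrate profile and its exact curvature field.

    c(x) = -h'' / (1 + h'^2)^(3/2), signed so the crest of a hill is
    positive; at small slope the extremal |c| tends to A0 (2 pi/lambda0)^2.
    """
    if A0_um < 0 or lambda0_um <= 0:
        raise DomainError("need A0 >= 0 and lambda0 > 0")
    x = np.linspace(0.0, lambda0_um, n_points)
    k = 2.0 * math.pi / lambda0_um
    h = A0_um * np.sin(k * x)
    h1 = A0_um * k * np.cos(k * x)
    h2 = -A0_um * k * k * np.sin(k * x)
    c = -h2 / (1.0 + h1 * h1) ** 1.5
    return WavySubstrate(
        amplitude_um=A0_um,
        period_um=lambda0_um,
        x_um=x,
        height_um=h,
        curvature_per_um=c,
    )
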
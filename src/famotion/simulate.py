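"""Synthetic data generators with known ground truth.

Three generators emulate the three data streams of an EGF dose-response
migration experiment, so every analysis stage can be validated by parameter
recovery against a known truth:

* :func:`simulate_prw_tracks` -- cell centroid trajectories from a
  discrete-time Ornstein-Uhlenbeck velocity process whose *exact*
  discretization reproduces the persistent-random-walk ensemble MSD
  2 S^2 P (t - P(1 - exp(-t/P))) in expectation (no Euler bias).

* :func:`simulate_fa_movie` -- TIRF-like 16-bit movies of focal adhesions
  rendered as anisotropic 2-D Gaussian spots on a dim cell footprint over a
  noisy background, with birth/death events, trapezoidal
  assembly/plateau/disassembly intensity profiles, centroid sliding and
  optional photobleaching.  The ground truth lists every adhesion's
  per-frame centroid, half-maximum area, mean/integrated intensity and
  elongation, in the same :class:`~famotion.adhesions.FATrack` container the
  segmentation pipeline produces.

* :func:`simulate_edge_movie` -- binary cell-mask movies whose boundary
  radius is an analytic function of angle and time: either disorganized
  (spatially smooth, temporally independent perturbations) or a laterally
  traveling sinusoidal protrusion wave.  Ground-truth sector velocities are
  computed from the analytic boundary before rasterization.

:func:`make_condition_dataset` bundles all three per EGF dose with
configurable dose-dependent parameter overrides.

Every generator is a pure function of its parameter record including the
seed: identical parameters give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .adhesions import FAMovie, FATrack
from .migration import Trajectory
from .protrusion import EdgeMap

__all__ = [
    "PRWParams",
    "FAMovieParams",
    "EdgeSimParams",
    "ConditionMap",
    "ConditionOverrides",
    "sample_dist",
    "simulate_prw_tracks",
    "simulate_fa_movie",
    "simulate_edge_movie",
    "make_condition_dataset",
    "EGF_DOSE_PANEL",
]

EGF_DOSE_PANEL = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)

# mean intensity of a 2-D Gaussian over its half-maximum ellipse is
# peak / (2 ln 2); the region area is 2 pi ln 2 sigma_maj sigma_min
_HALFMAX_MEAN_FACTOR = 1.0 / (2.0 * math.log(2.0))
_HALFMAX_AREA_FACTOR = 2.0 * math.pi * math.log(2.0)


def sample_dist(rng: np.random.Generator, spec, size=None):
    """Draw from a small parametric-family spec ``(family, params_dict)``.

    Families: ``lognormal`` (mean_log, sigma_log), ``weibull`` (shape,
    scale), ``gaussian`` (mean, sd), ``exponential`` (mean), ``uniform``
    (low, high), ``constant`` (value).
    """
    family, params = spec
    if family == "lognormal":
        return rng.lognormal(params["mean_log"], params["sigma_log"], size)
    if family == "weibull":
        return params["scale"] * rng.weibull(params["shape"], size)
    if family == "gaussian":
        return rng.normal(params["mean"], params["sd"], size)
    if family == "exponential":
        return rng.exponential(params["mean"], size)
    if family == "uniform":
        return rng.uniform(params["low"], params["high"], size)
    if family == "constant":
        return np.full(size if size is not None else (), params["value"], dtype=float)
    raise ValueError(f"unknown distribution family {family!r}")


def dist_cdf(spec, x):
    """CDF of a :func:`sample_dist` family spec (for self-consistency checks)."""
    from scipy import stats

    family, params = spec
    x = np.asarray(x, dtype=float)
    if family == "lognormal":
        return stats.lognorm.cdf(x, s=params["sigma_log"], scale=np.exp(params["mean_log"]))
    if family == "weibull":
        return stats.weibull_min.cdf(x, c=params["shape"], scale=params["scale"])
    if family == "gaussian":
        return stats.norm.cdf(x, loc=params["mean"], scale=params["sd"])
    if family == "exponential":
        return stats.expon.cdf(x, scale=params["mean"])
    if family == "uniform":
        return stats.uniform.cdf(x, loc=params["low"], scale=params["high"] - params["low"])
    raise ValueError(f"no CDF for family {family!r}")


# ---------------------------------------------------------------------------
# persistent-random-walk trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRWParams:
    """Persistent-random-walk simulation parameters.

    speed ``S`` is the RMS cell speed in um/hr, ``persistence`` P the
    directional memory time in hours; sampling every ``dt`` minutes for
    ``duration`` minutes (defaults mirror 2-min sampling over 8 hr).
    """

    speed: float = 30.0  # S, um/hr
    persistence: float = 0.2  # P, hr
    dt: float = 2.0  # min
    duration: float = 480.0  # min
    n_cells: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.persistence <= 0:
            raise ValueError("persistence must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 2 * self.dt:
            raise ValueError("duration must cover at least 2 sampling intervals")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def simulate_prw_tracks(params: PRWParams, egf_dose: float | None = None,
                        speeds=None, id_prefix: str = "") -> list[Trajectory]:
    """Simulate cell trajectories whose ensemble MSD follows the PRW law.

    The velocity of each cell is a stationary 2-D Ornstein-Uhlenbeck process
    with per-axis variance S^2/2 and correlation time P; positions integrate
    it with the exact joint (position, velocity) Gaussian transition, so the
    ensemble MSD equals 2 S^2 P (t - P(1 - exp(-t/P))) at every lag in
    expectation.  ``speeds`` optionally gives one RMS speed per cell
    (cell-to-cell heterogeneity); otherwise all cells share ``params.speed``.
    """
    rng = np.random.default_rng(params.seed)
    n_steps = int(np.floor(params.duration / params.dt + 1e-9))
    times = np.arange(n_steps + 1) * params.dt
    P = params.persistence * 60.0  # min
    dt = params.dt

    if speeds is None:
        speeds = np.full(params.n_cells, params.speed, dtype=float)
    else:
        speeds = np.asarray(speeds, dtype=float)
        if speeds.shape != (params.n_cells,):
            raise ValueError("speeds must have one entry per cell")
        if np.any(speeds < 0):
            raise ValueError("speeds must be >= 0")

    a = math.exp(-dt / P)
    # exact transition moments of the integrated OU process (unit velocity
    # variance; scaled per cell below)
    var_v = 1.0 - a * a
    cov_xv = (1.0 - a) ** 2 * P
    var_x = (2.0 / P) * (dt - 2.0 * P * (1.0 - a) + 0.5 * P * (1.0 - a * a)) * P * P
    cov = np.array([[var_x, cov_xv], [cov_xv, var_v]])
    # Cholesky of the 2x2 transition covariance
    l11 = math.sqrt(cov[0, 0])
    l21 = cov[1, 0] / l11 if l11 > 0 else 0.0
    l22 = math.sqrt(max(cov[1, 1] - l21 * l21, 0.0))

    sigma_axis = speeds / 60.0 / math.sqrt(2.0)  # per-axis velocity SD, um/min
    n = params.n_cells
    pos = np.zeros((n, n_steps + 1, 2))
    vel = rng.standard_normal((n, 2)) * sigma_axis[:, None]  # stationary start
    for k in range(n_steps):
        z = rng.standard_normal((n, 2, 2))  # (cell, axis, [x-noise, v-noise])
        eta_x = l11 * z[:, :, 0]
        eta_v = l21 * z[:, :, 0] + l22 * z[:, :, 1]
        pos[:, k + 1] = pos[:, k] + P * (1.0 - a) * vel + eta_x * sigma_axis[:, None]
        vel = a * vel + eta_v * sigma_axis[:, None]
    return [
        Trajectory(cell_id=f"{id_prefix}{i}" if id_prefix else i,
                   times=times.copy(), positions=pos[i], egf_dose=egf_dose)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# focal-adhesion movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FAMovieParams:
    """Parameters of a TIRF-like focal-adhesion movie.

    Distributions are ``(family, params)`` specs for :func:`sample_dist`.
    Defaults mirror 10-s frames over ~40 min; intensities are 16-bit
    grayscale units.  ``bleach_rate`` is the fractional intensity loss per
    frame (0 disables photobleaching).  ``cell_radius_um`` sets the dim cell
    footprint adhesions live on; ``overlap_warn_fraction`` triggers a
    metadata warning when the expected adhesion footprint exceeds that
    fraction of the cell area.
    """

    frame_shape: tuple = (256, 256)
    pixel_size: float = 0.16  # um/px
    frame_interval: float = 10.0  # s
    n_frames: int = 240
    birth_rate: float = 0.5  # FA births per frame
    lifetime_dist: tuple = ("exponential", {"mean": 300.0})  # s
    area_dist: tuple = ("lognormal", {"mean_log": 0.0, "sigma_log": 0.5})  # um^2
    peak_intensity_dist: tuple = ("lognormal", {"mean_log": np.log(8000.0), "sigma_log": 0.4})
    slide_speed_dist: tuple = ("lognormal", {"mean_log": np.log(8.0), "sigma_log": 0.5})  # um/hr
    elongation_dist: tuple = ("uniform", {"low": 1.2, "high": 2.5})
    background_level: float = 400.0
    cell_level: float = 600.0
    noise_sd: float = 30.0
    bleach_rate: float = 0.0
    cell_radius_um: float = 17.0
    intensity_profile: str = "trapezoid"  # or "flat"
    overlap_warn_fraction: float = 0.25
    min_separation_um: float = 0.0  # enforce FA spacing (0 = off)
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        for name in ("birth_rate", "background_level", "cell_level", "noise_sd",
                     "bleach_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.intensity_profile not in ("trapezoid", "flat"):
            raise ValueError("intensity_profile must be 'trapezoid' or 'flat'")


def _profile(age: np.ndarray, n_live: int, kind: str) -> np.ndarray:
    """Relative intensity over an adhesion's life (assembly/plateau/disassembly)."""
    if kind == "flat" or n_live <= 2:
        return np.ones_like(age, dtype=float)
    frac = (age + 0.5) / n_live
    up = np.clip(frac / 0.25, None, 1.0)
    down = np.clip((1.0 - frac) / 0.25, None, 1.0)
    return np.minimum(up, down)


def simulate_fa_movie(params: FAMovieParams):
    """Render a focal-adhesion movie and its ground-truth track list.

    Returns ``(FAMovie, list[FATrack])``.  Each live adhesion is an
    anisotropic 2-D Gaussian spot; ground-truth area is the analytic region
    above half its current maximum (constant over life), mean intensity the
    analytic mean over that region (peak / (2 ln 2)), scaled by the
    assembly/disassembly profile and photobleaching.  Adhesions sit on a dim
    disk-shaped cell footprint so the cell-segmentation stage has a target.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.frame_shape
    px = params.pixel_size
    T = params.n_frames
    cy_um, cx_um = H * px / 2.0, W * px / 2.0
    cell_r = min(params.cell_radius_um, 0.48 * min(H, W) * px)

    # population bookkeeping: (birth_frame, death_frame) inclusive, clipped
    mean_life_frames = float(np.mean(
        sample_dist(rng, params.lifetime_dist, 1000))) / params.frame_interval
    mean_life_frames = max(mean_life_frames, 1.0)
    births = []
    n0 = rng.poisson(params.birth_rate * mean_life_frames) if params.birth_rate > 0 else 0
    for _ in range(n0):
        life = max(1, round(float(sample_dist(rng, params.lifetime_dist)) / params.frame_interval))
        age = int(rng.integers(0, life))
        births.append((-age, life))
    for t in range(1, T):
        for _ in range(rng.poisson(params.birth_rate)):
            life = max(1, round(float(sample_dist(rng, params.lifetime_dist)) / params.frame_interval))
            births.append((t, life))

    fas = []
    expected_area = 0.0
    for birth, life in births:
        death = birth + life - 1
        if death < 0 or birth > T - 1:
            continue
        area = float(sample_dist(rng, params.area_dist))
        elong = max(float(sample_dist(rng, params.elongation_dist)), 1.0)
        peak = float(sample_dist(rng, params.peak_intensity_dist))
        slide = float(sample_dist(rng, params.slide_speed_dist))  # um/hr
        direction = rng.uniform(0, 2 * np.pi)
        orient = rng.uniform(0, np.pi)
        # rejection-sample the birth position; separation is enforced along
        # the whole slide path (sliding adhesions must not drift into each
        # other mid-movie)
        path_steps = np.linspace(0.0, max(life - 1, 0), 5)
        for _ in range(200):
            rr = cell_r * 0.8 * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            x0 = cx_um + rr * math.cos(th)
            y0 = cy_um + rr * math.sin(th)
            if params.min_separation_um <= 0:
                break
            step = slide / 3600.0 * params.frame_interval
            xs_p = x0 + step * math.cos(direction) * path_steps
            ys_p = y0 + step * math.sin(direction) * path_steps
            ok = True
            for f in fas:
                o_steps = np.linspace(0.0, max(f["life"] - 1, 0), 5)
                o_step = f["slide"] / 3600.0 * params.frame_interval
                oxs = f["x0"] + o_step * math.cos(f["direction"]) * o_steps
                oys = f["y0"] + o_step * math.sin(f["direction"]) * o_steps
                dmin = np.min(np.hypot(xs_p[:, None] - oxs[None, :],
                                       ys_p[:, None] - oys[None, :]))
                if dmin < params.min_separation_um:
                    ok = False
                    break
            if ok:
                break
        # sigma_maj * sigma_min = area / (2 pi ln 2); sigma_maj/sigma_min = elong
        sig_prod = area / _HALFMAX_AREA_FACTOR
        sig_min = math.sqrt(sig_prod / elong)
        sig_maj = sig_min * elong
        fas.append(dict(
            birth=birth, death=death, life=life, area=area, elong=elong,
            peak=peak, slide=slide, direction=direction, orient=orient,
            x0=x0, y0=y0, sig_maj=sig_maj, sig_min=sig_min,
        ))
        visible = min(death, T - 1) - max(birth, 0) + 1
        expected_area += area * visible / T

    metadata = dict(params=params, warnings=[])
    cell_area = math.pi * cell_r**2
    if cell_area > 0 and expected_area / cell_area > params.overlap_warn_fraction:
        metadata["warnings"].append(
            f"expected adhesion footprint {expected_area / cell_area:.2f} of cell "
            f"area exceeds {params.overlap_warn_fraction}; overlaps likely"
        )

    # render
    yy, xx = np.mgrid[0:H, 0:W]
    cell_mask = ((xx * px - cx_um) ** 2 + (yy * px - cy_um) ** 2) <= cell_r**2
    base = np.full((H, W), params.background_level, dtype=float)
    base[cell_mask] += params.cell_level
    frames = np.repeat(base[None], T, axis=0)
    bleach = (1.0 - params.bleach_rate) ** np.arange(T)

    tracks = []
    for fid, fa in enumerate(fas, start=1):
        t0, t1 = max(fa["birth"], 0), min(fa["death"], T - 1)
        n_vis = t1 - t0 + 1
        ages = np.arange(t0, t1 + 1) - fa["birth"]
        prof = _profile(ages, fa["life"], params.intensity_profile)
        amp = fa["peak"] * prof * bleach[t0:t1 + 1]
        vx = fa["slide"] / 3600.0 * params.frame_interval * math.cos(fa["direction"])
        vy = fa["slide"] / 3600.0 * params.frame_interval * math.sin(fa["direction"])
        xs = fa["x0"] + vx * (np.arange(t0, t1 + 1) - t0)
        ys = fa["y0"] + vy * (np.arange(t0, t1 + 1) - t0)

        co, so = math.cos(fa["orient"]), math.sin(fa["orient"])
        s1, s2 = fa["sig_maj"] / px, fa["sig_min"] / px  # px units
        # inverse covariance in pixel coords
        a_ = co**2 / (2 * s1**2) + so**2 / (2 * s2**2)
        b_ = so * co * (1 / (2 * s1**2) - 1 / (2 * s2**2))
        c_ = so**2 / (2 * s1**2) + co**2 / (2 * s2**2)
        ext = 3.5 * s1
        for i, t in enumerate(range(t0, t1 + 1)):
            cx_px, cy_px = xs[i] / px, ys[i] / px
            x_lo, x_hi = int(max(cx_px - ext, 0)), int(min(cx_px + ext + 1, W))
            y_lo, y_hi = int(max(cy_px - ext, 0)), int(min(cy_px + ext + 1, H))
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            gx = np.arange(x_lo, x_hi) - cx_px
            gy = np.arange(y_lo, y_hi) - cy_px
            GX, GY = np.meshgrid(gx, gy)
            frames[t, y_lo:y_hi, x_lo:x_hi] += amp[i] * np.exp(
                -(a_ * GX**2 + 2 * b_ * GX * GY + c_ * GY**2)
            )

        mean_int = amp * _HALFMAX_MEAN_FACTOR
        hm_area = fa["area"]
        integ = amp * math.pi * fa["sig_maj"] * fa["sig_min"]
        tracks.append(FATrack(
            fa_id=fid,
            frames=np.arange(t0, t1 + 1),
            centroids=np.column_stack([xs, ys]),
            areas=np.full(n_vis, hm_area),
            mean_intensities=mean_int,
            integrated_intensities=integ,
            elongations=np.full(n_vis, fa["elong"]),
            censored_start=(t0 == 0),
            censored_end=(t1 == T - 1),
        ))

    if params.noise_sd > 0:
        frames = frames + rng.normal(0.0, params.noise_sd, frames.shape)
    frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    movie = FAMovie(frames=frames, pixel_size=px,
                    frame_interval=params.frame_interval, metadata=metadata)
    return movie, tracks


# ---------------------------------------------------------------------------
# edge-mask movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeSimParams:
    """Parameters of a synthetic cell-edge mask movie.

    ``mode='random'`` produces disorganized protrusion/retraction: a
    boundary-radius field that is smooth along the edge but independent
    between frames, with amplitude ``noise_sd`` (um).  ``mode='wave'`` adds a
    sinusoidal boundary wave traveling laterally at ``wave_lateral_speed``
    sectors per frame with temporal period ``wave_period`` (s); the integer
    wavenumber constraint of a closed boundary rounds the requested lateral
    speed -- the realized value is reported in the returned metadata.
    """

    mode: str = "random"
    base_radius: float = 15.0  # um
    wave_amplitude: float = 0.0  # um
    wave_period: float = 200.0  # s
    wave_lateral_speed: float = 2.0  # sectors per frame
    noise_sd: float = 0.0  # um
    n_frames: int = 40
    n_sectors: int = 100
    pixel_size: float = 0.3  # um/px
    frame_interval: float = 10.0  # s
    smooth_sectors: float = 3.0  # angular smoothing of the random field
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("random", "wave"):
            raise ValueError("mode must be 'random' or 'wave'")
        if self.mode == "wave":
            if self.wave_period <= 0:
                raise ValueError("wave mode requires wave_period > 0")
            if self.wave_lateral_speed == 0:
                raise ValueError("wave mode requires wave_lateral_speed != 0")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be > 0")
        if self.wave_amplitude + 4 * self.noise_sd >= self.base_radius:
            raise ValueError("wave_amplitude (plus noise) must stay below base_radius")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _circular_smooth(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with wrap-around along the last axis, variance kept."""
    if sigma <= 0:
        return values
    n = values.shape[-1]
    k = np.arange(n)
    k = np.minimum(k, n - k)
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    fk = np.fft.rfft(kernel)
    out = np.fft.irfft(np.fft.rfft(values, axis=-1) * fk, n=n, axis=-1)
    # renormalize to unit variance gain
    gain = math.sqrt(float(np.sum(kernel**2)))
    return out / gain


def simulate_edge_movie(params: EdgeSimParams):
    """Simulate a binary cell-mask movie plus its analytic edge-velocity map.

    Returns ``(mask_stack, EdgeMap, info)`` where ``mask_stack`` is a
    (T, H, W) boolean array, the :class:`EdgeMap` holds ground-truth sector
    velocities (um/min) computed from the analytic boundary radius before
    rasterization, and ``info`` records the realized wave parameters.
    """
    rng = np.random.default_rng(params.seed)
    n_sec, T = params.n_sectors, params.n_frames
    theta = (np.arange(n_sec) + 0.5) / n_sec * 2 * np.pi - np.pi  # sector centers

    radii = np.full((T, n_sec), params.base_radius, dtype=float)
    info = dict(mode=params.mode)
    if params.mode == "wave" and params.wave_amplitude > 0:
        omega = 2 * np.pi / params.wave_period  # rad/s
        d_theta = 2 * np.pi / n_sec
        # lateral speed v (sectors/frame) fixes the wavenumber m:
        # v = omega * frame_interval / (m * d_theta)
        m = max(1, round(omega * params.frame_interval
                         / (abs(params.wave_lateral_speed) * d_theta)))
        v_real = omega * params.frame_interval / (m * d_theta)
        v_real *= np.sign(params.wave_lateral_speed)
        t_s = np.arange(T)[:, None] * params.frame_interval
        radii += params.wave_amplitude * np.sin(
            m * theta[None, :] - np.sign(v_real) * omega * t_s
        )
        info.update(wavenumber=int(m), lateral_speed_sectors_per_frame=float(v_real))
    if params.noise_sd > 0:
        noise = rng.standard_normal((T, n_sec))
        noise = _circular_smooth(noise, params.smooth_sectors)
        radii += params.noise_sd * noise

    gt_velocities = np.diff(radii, axis=0).T / (params.frame_interval / 60.0)
    edge_map = EdgeMap(velocities=gt_velocities,
                       frame_interval=params.frame_interval, n_sectors=n_sec)

    # rasterize: pixel inside iff rho <= r(theta_pixel, t) (circular interp)
    px = params.pixel_size
    extent = params.base_radius + params.wave_amplitude + 4 * params.noise_sd + 2 * px
    half = int(math.ceil(extent / px))
    size = 2 * half + 1
    c = half
    yy, xx = np.mgrid[0:size, 0:size]
    ang = np.arctan2((yy - c), (xx - c))  # [-pi, pi)
    rho = np.hypot(yy - c, xx - c) * px
    frac = (ang + np.pi) / (2 * np.pi) * n_sec - 0.5
    ext_theta = np.arange(-1, n_sec + 1)
    masks = np.empty((T, size, size), dtype=bool)
    for t in range(T):
        r_ext = np.concatenate([[radii[t, -1]], radii[t], [radii[t, 0]]])
        r_at = np.interp(frac, ext_theta, r_ext)
        masks[t] = rho <= r_at
    return masks, edge_map, info


# ---------------------------------------------------------------------------
# dose-condition datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionOverrides:
    """Per-dose generator overrides.

    ``speed_median`` / ``speed_cv`` control the lognormal cell-to-cell speed
    distribution (um/hr); ``persistence`` the shared P (hr);
    ``intensity_scale`` multiplies the adhesion peak-intensity distribution;
    ``birth_rate`` the adhesion birth rate per frame; ``wave_fraction`` the
    probability that an edge movie carries a lateral wave.
    """

    speed_median: float = 30.0
    speed_cv: float = 0.3
    persistence: float = 0.2
    intensity_scale: float = 1.0
    birth_rate: float = 0.5
    wave_fraction: float = 0.4


# defaults emulating the qualitative dose structure of the experiment:
# median speed rises on stimulation then saturates, cell-to-cell speed
# spread (CoV) grows with dose, adhesion intensity falls monotonically with
# dose, and adhesion number per cell peaks at low (intermediate) doses.
DEFAULT_CONDITIONS = {
    0.0: ConditionOverrides(speed_median=25.0, speed_cv=0.20, persistence=0.25,
                            intensity_scale=1.00, birth_rate=0.50),
    0.01: ConditionOverrides(speed_median=28.0, speed_cv=0.25, persistence=0.22,
                             intensity_scale=0.85, birth_rate=0.80),
    0.1: ConditionOverrides(speed_median=30.0, speed_cv=0.32, persistence=0.20,
                            intensity_scale=0.75, birth_rate=0.90),
    1.0: ConditionOverrides(speed_median=32.0, speed_cv=0.42, persistence=0.18,
                            intensity_scale=0.60, birth_rate=0.70),
    10.0: ConditionOverrides(speed_median=32.0, speed_cv=0.52, persistence=0.17,
                             intensity_scale=0.50, birth_rate=0.60),
    100.0: ConditionOverrides(speed_median=32.0, speed_cv=0.60, persistence=0.16,
                              intensity_scale=0.42, birth_rate=0.50),
}


@dataclass(frozen=True)
class ConditionMap:
    """EGF dose -> generator overrides for a full synthetic experiment."""

    conditions: dict = field(default_factory=lambda: dict(DEFAULT_CONDITIONS))
    n_cells_per_dose: int = 20
    n_fa_movies_per_dose: int = 2
    n_edge_movies_per_dose: int = 2
    prw: PRWParams = PRWParams()
    fa: FAMovieParams = FAMovieParams()
    edge: EdgeSimParams = EdgeSimParams(noise_sd=0.25)
    #: waves ride on fast-moving cells (the structure the speed-group
    #: analysis looks for); False assigns wave movies independent of speed
    couple_waves_to_speed: bool = True

    def __post_init__(self):
        if len(self.conditions) < 2:
            raise ValueError("need at least two EGF doses")
        for dose in self.conditions:
            if float(dose) not in EGF_DOSE_PANEL:
                raise ValueError(
                    f"dose {dose!r} nM outside the allowed panel {EGF_DOSE_PANEL}"
                )


def make_condition_dataset(cmap: ConditionMap, seed: int) -> dict:
    """Generate a per-dose bundle of trajectories, FA movies and edge movies.

    Returns ``{dose: {"trajectories", "fa_movies", "edge_movies",
    "cell_speeds"}}`` where each FA movie entry is a dict with the movie, its
    ground-truth tracks and an attached imaged-cell migration speed (drawn
    from the dose's speed distribution, so adhesion data can also be grouped
    by the speed scheme), and each edge movie entry likewise carries masks,
    the ground-truth edge map and its cell speed.
    """
    root = np.random.default_rng(seed)
    bundle = {}
    for dose in sorted(cmap.conditions, key=float):
        cond = cmap.conditions[dose]
        sub = np.random.default_rng(root.integers(2**31))

        # per-cell RMS speeds: lognormal with the requested median and CoV
        sigma = math.sqrt(math.log(1.0 + cond.speed_cv**2))
        mu = math.log(cond.speed_median)
        speeds = sub.lognormal(mu, sigma, cmap.n_cells_per_dose)
        prw = replace(cmap.prw, speed=cond.speed_median,
                      persistence=cond.persistence,
                      n_cells=cmap.n_cells_per_dose,
                      seed=int(sub.integers(2**31)))
        trajectories = simulate_prw_tracks(prw, egf_dose=float(dose), speeds=speeds,
                                           id_prefix=f"d{dose:g}_c")

        fa_movies = []
        fam, fap = cmap.fa.peak_intensity_dist
        for _ in range(cmap.n_fa_movies_per_dose):
            scaled = dict(fap)
            if fam == "lognormal":
                scaled["mean_log"] = fap["mean_log"] + math.log(cond.intensity_scale)
            elif fam == "constant":
                scaled["value"] = fap["value"] * cond.intensity_scale
            else:
                raise ValueError(
                    "intensity_scale override supports lognormal/constant peaks"
                )
            fa_params = replace(cmap.fa, birth_rate=cond.birth_rate,
                                peak_intensity_dist=(fam, scaled),
                                seed=int(sub.integers(2**31)))
            movie, truth = simulate_fa_movie(fa_params)
            cell_speed = float(sub.lognormal(mu, sigma))
            fa_movies.append(dict(movie=movie, truth=truth,
                                  cell_speed_um_hr=cell_speed, params=fa_params))

        edge_movies = []
        for _ in range(cmap.n_edge_movies_per_dose):
            is_wave = bool(sub.uniform() < cond.wave_fraction)
            # fast movers carry the waves: draw the movie cell's speed from
            # the upper (wave) or lower (random) half of the dose distribution
            if cmap.couple_waves_to_speed:
                q = sub.uniform(0.55, 0.97) if is_wave else sub.uniform(0.03, 0.45)
            else:
                q = sub.uniform(0.03, 0.97)
            from scipy import stats as _st
            cell_speed = float(_st.lognorm.ppf(q, s=sigma, scale=math.exp(mu)))
            edge_params = replace(
                cmap.edge,
                mode="wave" if is_wave else "random",
                wave_amplitude=1.5 if is_wave else 0.0,
                noise_sd=cmap.edge.noise_sd,
                seed=int(sub.integers(2**31)),
            )
            masks, gt_map, info = simulate_edge_movie(edge_params)
            edge_movies.append(dict(masks=masks, truth=gt_map, info=info,
                                    cell_speed_um_hr=cell_speed,
                                    params=edge_params))

        bundle[float(dose)] = dict(
            trajectories=trajectories,
            fa_movies=fa_movies,
            edge_movies=edge_movies,
            cell_speeds=speeds,
        )
    return bundle
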
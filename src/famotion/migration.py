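"""Cell-migration statistics: MSD curves, persistent-random-walk fits, speed partitions.

A cell undergoing uncorrelated ("random-walk") migration with short-term
directional memory is well described by the persistent random walk (PRW)
model, whose ensemble mean squared displacement is

    MSD(t) = 2 S^2 P (t - P (1 - exp(-t / P)))

with root-mean-square speed ``S`` and directional persistence time ``P``.
This module computes MSD curves from centroid tracks using non-overlapping
time intervals, fits the PRW model by nonlinear least squares
(:class:`PRWModel` / :class:`PRWResults`), summarizes population variability
(coefficient of variation) and partitions cells into slow/fast groups with an
exact one-dimensional 2-means clustering.

Internal units are micrometres and minutes; speeds are reported in um/hr and
persistence times in hours, matching the conventions of the migration
literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Trajectory",
    "MSDCurve",
    "PRWEstimate",
    "PRWModel",
    "PRWResults",
    "SpeedPartition",
    "compute_msd",
    "prw_msd",
    "fit_prw",
    "coefficient_of_variation",
    "kmeans_speed_cutoff",
]

#: multi-start grid for the persistence time, in minutes.  The PRW objective
#: is multimodal in P, so the fit is restarted from each of these.
P_START_GRID_MIN = (1.0, 2.0, 5.0, 10.0, 20.0, 60.0)


@dataclass(frozen=True)
class Trajectory:
    """A single cell's centroid track.

    Parameters
    ----------
    cell_id : str or int
        Identifier of the tracked cell.
    times : array of float
        Sample times in minutes, strictly increasing with uniform spacing.
    positions : (n, 2) array of float
        Centroid positions in micrometres.
    egf_dose : float or None
        EGF dose the cell was exposed to, in nM (None when unknown).
    """

    cell_id: object
    times: np.ndarray
    positions: np.ndarray
    egf_dose: float | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("trajectory needs at least 2 time samples")
        if positions.shape != (times.size, 2):
            raise ValueError(
                f"positions shape {positions.shape} does not match {times.size} times"
            )
        steps = np.diff(times)
        if np.any(steps <= 0):
            idx = int(np.argmax(steps <= 0))
            raise ValueError(f"times not strictly increasing at index {idx + 1}")

    @property
    def dt(self) -> float:
        """Sampling interval in minutes (first step)."""
        return float(self.times[1] - self.times[0])

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    def check_uniform(self, rtol: float = 1e-6) -> None:
        """Raise if sampling is non-uniform, naming the offending index."""
        steps = np.diff(self.times)
        bad = np.nonzero(~np.isclose(steps, steps[0], rtol=rtol, atol=0.0))[0]
        if bad.size:
            raise ValueError(
                f"non-uniform sampling in trajectory {self.cell_id!r}: "
                f"interval at index {int(bad[0]) + 1} is {steps[bad[0]]:g} min, "
                f"expected {steps[0]:g} min"
            )

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class MSDCurve:
    """Mean squared displacement at multiples of the sampling interval.

    ``msd[k]`` averages squared displacements over *non-overlapping* index
    pairs (0, k), (k, 2k), ..., so for a track with N steps the lag k*dt uses
    floor(N / k) displacements (``n_disp``).
    """

    lags: np.ndarray  # minutes
    msd: np.ndarray  # um^2
    n_disp: np.ndarray  # displacements per lag

    def __post_init__(self):
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        object.__setattr__(self, "msd", np.asarray(self.msd, dtype=float))
        object.__setattr__(self, "n_disp", np.asarray(self.n_disp, dtype=int))
        if not (self.lags.size == self.msd.size == self.n_disp.size):
            raise ValueError("lags, msd and n_disp must have equal length")
        if np.any(self.msd < 0):
            raise ValueError("MSD values must be non-negative")


def compute_msd(traj: Trajectory, max_lag: float | None = None) -> MSDCurve:
    """Compute the non-overlapping-interval MSD of a uniformly sampled track.

    Parameters
    ----------
    traj : Trajectory
    max_lag : float, optional
        Largest time lag (minutes) to evaluate; defaults to the full track
        duration.

    Returns
    -------
    MSDCurve
        Lags are k*dt for k = 1.. floor(max_lag/dt); lags with no complete
        displacement are omitted.
    """
    traj.check_uniform()
    dt = traj.dt
    n_steps = traj.n_steps
    if max_lag is None:
        max_lag = traj.duration
    if max_lag > traj.duration + 1e-9:
        raise ValueError(f"max_lag {max_lag} min exceeds track duration {traj.duration} min")
    k_max = min(int(np.floor(max_lag / dt + 1e-9)), n_steps)
    lags, msd, counts = [], [], []
    pos = traj.positions
    for k in range(1, k_max + 1):
        m = n_steps // k  # number of non-overlapping displacements
        if m < 1:
            continue
        idx = np.arange(m + 1) * k
        disp = pos[idx[1:]] - pos[idx[:-1]]
        msd.append(float(np.mean(np.sum(disp**2, axis=1))))
        lags.append(k * dt)
        counts.append(m)
    return MSDCurve(np.array(lags), np.array(msd), np.array(counts))


def prw_msd(t, S, P):
    """PRW ensemble MSD, 2 S^2 P (t - P(1 - exp(-t/P))); units consistent in/out."""
    t = np.asarray(t, dtype=float)
    return 2.0 * S**2 * P * (t - P * (1.0 - np.exp(-t / P)))


@dataclass(frozen=True)
class PRWEstimate:
    """Fitted PRW parameters.

    Attributes
    ----------
    S : float
        RMS cell speed, um/hr.
    P : float
        Directional persistence time, hours.
    residual_ss : float
        Sum of squared MSD residuals over the fitted lags, um^4.
    converged : bool
    identifiability_flag : bool
        Set when the fitted persistence falls below one sampling interval or
        above the fitted lag window: there S and P are not separately
        identifiable (only the diffusivity S^2 P, or the ballistic speed,
        is constrained).
    n_lags : int
        Number of MSD points used.
    """

    S: float
    P: float
    residual_ss: float
    converged: bool
    identifiability_flag: bool
    n_lags: int = 0


def _fit_prw_minutes(lags_min, msd, dt_min, max_fit_lag):
    """Core fit in (um, min) units; returns (S_um_min, P_min, ss, ok, flag, n)."""
    sel = lags_min <= max_fit_lag + 1e-9
    t = lags_min[sel]
    y = msd[sel]
    if t.size < 3:
        raise ValueError(
            f"need at least 3 MSD lags within {max_fit_lag} min, got {t.size}"
        )

    def residual(theta):
        S, P = theta
        return prw_msd(t, S, P) - y

    scale = max(float(np.sqrt(np.max(y) / max(t[-1], 1.0))), 1e-8)
    best = None
    for P0 in P_START_GRID_MIN:
        # closed-form optimal S^2 given P0 as the start for S
        f = 2.0 * P0 * (t - P0 * (1.0 - np.exp(-t / P0)))
        denom = float(f @ f)
        S0 = np.sqrt(max(float(f @ y) / denom, 0.0)) if denom > 0 else scale
        S0 = max(S0, 1e-8)
        try:
            res = least_squares(
                residual,
                x0=[S0, P0],
                bounds=([0.0, 1e-8], [np.inf, np.inf]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer failure fallback
            continue
        ss = float(np.sum(res.fun**2))
        if best is None or ss < best[2] - 1e-12 * max(best[2], 1.0):
            best = (float(res.x[0]), float(res.x[1]), ss, bool(res.success))
    if best is None:  # pragma: no cover
        raise RuntimeError("PRW fit failed from every start")
    S, P, ss, ok = best
    flag = (P < dt_min) or (P > float(t[-1]))
    return S, P, ss, ok, flag, int(t.size)


def fit_prw(msd: MSDCurve, max_fit_lag: float = 30.0) -> PRWEstimate:
    """Fit the PRW MSD model to an :class:`MSDCurve` by least squares.

    The fit is restricted to lags <= ``max_fit_lag`` (default 30 min, where
    non-overlapping displacement counts remain usable for 2-min sampling of
    6-8 hr tracks) and restarted from a grid of persistence times because the
    objective is multimodal in P.  Unweighted least squares.

    Returns
    -------
    PRWEstimate
        With S in um/hr and P in hours.
    """
    lags = np.asarray(msd.lags, dtype=float)
    if lags.size < 3:
        raise ValueError("MSD curve has fewer than 3 lags")
    dt = float(lags[0])
    S_m, P_m, ss, ok, flag, n = _fit_prw_minutes(lags, np.asarray(msd.msd), dt, max_fit_lag)
    return PRWEstimate(
        S=S_m * 60.0, P=P_m / 60.0, residual_ss=ss, converged=ok,
        identifiability_flag=flag, n_lags=n,
    )


class PRWModel:
    """Persistent-random-walk MSD model bound to one cell's data.

    Construct from an :class:`MSDCurve` or via :meth:`from_trajectory`, then
    call :meth:`fit` to obtain a :class:`PRWResults`.
    """

    def __init__(self, msd: MSDCurve, cell_id: object = None):
        self.msd = msd
        self.cell_id = cell_id

    @classmethod
    def from_trajectory(cls, traj: Trajectory, max_lag: float | None = None) -> "PRWModel":
        return cls(compute_msd(traj, max_lag=max_lag), cell_id=traj.cell_id)

    def predict(self, S: float, P: float, lags_min=None):
        """Model MSD (um^2) at the given lags (minutes) for S in um/hr, P in hr."""
        t = self.msd.lags if lags_min is None else np.asarray(lags_min, float)
        return prw_msd(t, S / 60.0, P * 60.0)

    def fit(self, max_fit_lag: float = 30.0) -> "PRWResults":
        est = fit_prw(self.msd, max_fit_lag=max_fit_lag)
        return PRWResults(self, est, max_fit_lag)


class PRWResults:
    """Results of a PRW fit: parameter estimates, diagnostics, summary table."""

    def __init__(self, model: PRWModel, estimate: PRWEstimate, max_fit_lag: float):
        self.model = model
        self.estimate = estimate
        self.max_fit_lag = max_fit_lag

    @property
    def speed(self) -> float:
        """RMS speed S, um/hr."""
        return self.estimate.S

    @property
    def persistence(self) -> float:
        """Persistence time P, hours."""
        return self.estimate.P

    @property
    def residual_ss(self) -> float:
        return self.estimate.residual_ss

    @property
    def converged(self) -> bool:
        return self.estimate.converged

    @property
    def identifiability_flag(self) -> bool:
        return self.estimate.identifiability_flag

    def fittedvalues(self):
        return self.model.predict(self.speed, self.persistence)

    def summary(self) -> str:
        e = self.estimate
        rmse = np.sqrt(e.residual_ss / max(e.n_lags, 1))
        lines = [
            "Persistent random walk MSD fit",
            "=" * 46,
            f"cell id:             {self.model.cell_id!r}",
            f"lags used:           {e.n_lags} (<= {self.max_fit_lag:g} min)",
            f"speed S:             {e.S:10.3f} um/hr",
            f"persistence P:       {e.P:10.4f} hr  ({e.P * 60:.2f} min)",
            f"residual SS:         {e.residual_ss:10.4g} um^4",
            f"residual RMSE:       {rmse:10.4g} um^2",
            f"converged:           {e.converged}",
            f"identifiability:     {'FLAGGED (diffusive/ballistic ridge)' if e.identifiability_flag else 'ok'}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed MSD points with the fitted PRW curve (lags in minutes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        msd = self.model.msd
        ax.plot(msd.lags, msd.msd, "o", mfc="none", label="observed MSD")
        tt = np.linspace(0, float(msd.lags[-1]), 200)
        ax.plot(tt, self.model.predict(self.speed, self.persistence, tt), "-",
                label=f"PRW fit: S={self.speed:.1f} um/hr, P={self.persistence:.2f} hr")
        ax.axvline(self.max_fit_lag, ls=":", color="gray", lw=1)
        ax.set_xlabel("time lag (min)")
        ax.set_ylabel(r"MSD ($\mu m^2$)")
        ax.legend(frameon=False)
        return ax

    def __repr__(self):
        return (
            f"<PRWResults S={self.speed:.2f} um/hr, P={self.persistence:.3f} hr, "
            f"converged={self.converged}>"
        )


def coefficient_of_variation(samples: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean.

    Raises on fewer than two samples or a zero mean.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("coefficient of variation needs at least 2 samples")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(np.std(x, ddof=1) / mean)


@dataclass(frozen=True)
class SpeedPartition:
    """Slow/fast split of a speed sample.

    ``labels[i]`` is 'slow' or 'fast' for the i-th input speed; every slow
    speed is < ``cutoff`` and every fast speed >= ``cutoff``.
    """

    cutoff: float
    labels: np.ndarray
    within_cluster_ss: float

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))


def kmeans_speed_cutoff(speeds: Sequence[float]) -> SpeedPartition:
    """Exact two-cluster 1-D k-means on migration speeds.

    In one dimension the optimal 2-means partition is a split of the sorted
    sample, so the global optimum is found by exhaustive search over the
    n-1 sorted splits (deterministic; no seeding, unlike Lloyd iterations).
    The cutoff is the midpoint between the slow cluster's maximum and the
    fast cluster's minimum.
    """
    x = np.asarray(speeds, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 speeds")
    if np.all(x == x[0]):
        raise ValueError("all speeds identical: no two-cluster structure")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csum2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def ss(i, j):  # within-cluster SS of xs[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / m

    best_i, best_ss, best_gap = None, np.inf, -np.inf
    for i in range(1, n):
        total = ss(0, i) + ss(i, n)
        gap = xs[i] - xs[i - 1]
        # strictly better SS wins; among numerically tied splits prefer the
        # widest inter-cluster gap (gives a well-defined midpoint cutoff)
        if best_i is None or total < best_ss - 1e-12 * max(1.0, best_ss) or (
            np.isclose(total, best_ss, rtol=1e-12, atol=1e-12) and gap > best_gap
        ):
            best_i, best_ss, best_gap = i, total, gap
    cutoff = 0.5 * (xs[best_i - 1] + xs[best_i])
    labels = np.where(x < cutoff, "slow", "fast").astype(object)
    return SpeedPartition(cutoff=float(cutoff), labels=labels,
                          within_cluster_ss=float(best_ss))
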
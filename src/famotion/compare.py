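"""Distribution comparison and fitting for grouped single-cell samples.

The effect-size currency throughout is the Kolmogorov-Smirnov statistic
D = sup |F_a - F_b| between empirical CDFs: a nonparametric, scale-free
measure of how different two sample distributions are, used here both to
rank which adhesion/protrusion characteristics separate experimental groups
most strongly and -- in its one-sample form -- as the objective for fitting
parametric families (lognormal, Weibull, Gaussian) to skewed single-cell
property distributions.

Grouping schemes follow the dose-response design: EGF doses are binned into
no (0 nM), low (0.01 and 0.1 nM) and high (1, 10 and 100 nM) stimulation,
or cells are split into slow/fast movers at a data-derived speed cutoff.
Three-group comparisons are summarized by the arithmetic mean of the three
pairwise D values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "EGF_DOSE_PANEL",
    "GroupedSamples",
    "FittedDistribution",
    "ks_statistic",
    "one_sample_ks",
    "mean_pairwise_ks",
    "fit_distribution",
    "group_by_egf",
    "group_by_speed",
    "mean_difference_test",
]

#: the admissible EGF dose panel, nM
EGF_DOSE_PANEL = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)

#: dose -> stimulation group
_EGF_GROUPS = {0.0: "no", 0.01: "low", 0.1: "low", 1.0: "high", 10.0: "high",
               100.0: "high"}

#: minimum group size for distribution-level comparisons to be meaningful
MIN_GROUP_SIZE = 8


@dataclass
class GroupedSamples:
    """Named groups of scalar samples under one grouping scheme.

    scheme : 'egf' (labels no/low/high) or 'speed' (labels slow/fast).
    groups : dict label -> 1-D float array.
    provenance : optional dict label -> sequence of record identifiers.
    """

    scheme: str
    groups: dict
    provenance: dict = field(default_factory=dict)

    _SCHEMES = {"egf": ("no", "low", "high"), "speed": ("slow", "fast")}

    def __post_init__(self):
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        allowed = self._SCHEMES[self.scheme]
        for label in self.groups:
            if label not in allowed:
                raise ValueError(
                    f"label {label!r} not in scheme {self.scheme!r} labels {allowed}"
                )
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}

    def labels(self):
        return [l for l in self._SCHEMES[self.scheme] if l in self.groups]

    def sizes(self):
        return {k: v.size for k, v in self.groups.items()}


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D in [0, 1].

    The supremum absolute difference between the two empirical CDFs over the
    pooled support; symmetric in its arguments.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic needs two non-empty samples")
    return float(stats.ks_2samp(a, b).statistic)


def one_sample_ks(sample, cdf) -> float:
    """One-sample KS distance between a sample's ECDF and a model CDF.

    Standard sup over sample points of both one-sided gaps:
    max_i max(i/n - F(x_i), F(x_i) - (i-1)/n).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    F = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - F, F - (i - 1) / n)))


def mean_pairwise_ks(groups: dict) -> float:
    """Mean of the three pairwise KS statistics among exactly three groups.

    Summarizes a three-way (e.g. no/low/high stimulation) comparison as the
    arithmetic mean of D(a,b), D(a,c), D(b,c).
    """
    if len(groups) != 3:
        raise ValueError(f"need exactly 3 groups, got {len(groups)}")
    labels = list(groups)
    ds = []
    for i in range(3):
        for j in range(i + 1, 3):
            ds.append(ks_statistic(groups[labels[i]], groups[labels[j]]))
    return float(np.mean(ds))


@dataclass(frozen=True)
class FittedDistribution:
    """A parametric family fitted by KS-distance minimization.

    family : 'lognormal' (params mu, sigma of log), 'weibull' (shape, scale)
    or 'gaussian' (mu, sigma).  ``ks_distance`` is the achieved one-sample KS
    distance in [0, 1]; ``ks_init`` the distance at the moment-estimate
    initialization.
    """

    family: str
    params: tuple
    ks_distance: float
    ks_init: float
    n: int

    def cdf(self, x):
        return _family_cdf(self.family, self.params, x)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.lognorm.pdf(x, s=sigma, scale=np.exp(mu))
        if self.family == "weibull":
            shape, scale = self.params
            return stats.weibull_min.pdf(x, c=shape, scale=scale)
        mu, sigma = self.params
        return stats.norm.pdf(x, loc=mu, scale=sigma)

    def summary(self) -> str:
        names = {
            "lognormal": ("mu_log", "sigma_log"),
            "weibull": ("shape", "scale"),
            "gaussian": ("mu", "sigma"),
        }[self.family]
        lines = [
            f"KS-minimization fit: {self.family}",
            "=" * 38,
            f"n:            {self.n}",
        ]
        for name, value in zip(names, self.params):
            lines.append(f"{name + ':':<14}{value:12.6g}")
        lines.append(f"KS distance:  {self.ks_distance:12.6g}")
        lines.append(f"KS at init:   {self.ks_init:12.6g}")
        return "\n".join(lines)


def _family_cdf(family, params, x):
    x = np.asarray(x, dtype=float)
    if family == "lognormal":
        mu, sigma = params
        return stats.lognorm.cdf(x, s=sigma, scale=np.exp(mu))
    if family == "weibull":
        shape, scale = params
        return stats.weibull_min.cdf(x, c=shape, scale=scale)
    if family == "gaussian":
        mu, sigma = params
        return stats.norm.cdf(x, loc=mu, scale=sigma)
    raise ValueError(f"unknown family {family!r}")


def _initial_params(x, family):
    """Moment/quantile starting estimates per family."""
    if family == "lognormal":
        logs = np.log(x)
        return (float(np.mean(logs)), float(np.std(logs, ddof=1)))
    if family == "gaussian":
        return (float(np.mean(x)), float(np.std(x, ddof=1)))
    if family == "weibull":
        # quantile-matching start: shape from the spread of log-quantiles,
        # scale from the ~63.2% quantile (F(scale) = 1 - 1/e)
        q25, q632, q75 = np.quantile(x, [0.25, 1 - np.exp(-1.0), 0.75])
        num = np.log(np.log(4.0)) - np.log(np.log(4.0 / 3.0))
        den = np.log(q75) - np.log(q25)
        shape = num / den if den > 0 else 1.0
        return (float(max(shape, 0.05)), float(max(q632, np.mean(x))))
    raise ValueError(f"unknown family {family!r}")


def _transform(family, params):
    if family == "weibull":
        return np.log(params)
    # mu free, sigma positive
    return np.array([params[0], np.log(params[1])])


def _untransform(family, theta):
    if family == "weibull":
        return tuple(np.exp(theta))
    return (float(theta[0]), float(np.exp(theta[1])))


def fit_distribution(samples, family: str) -> FittedDistribution:
    """Fit a parametric family to a sample by minimizing the KS distance.

    Derivative-free simplex (Nelder-Mead) over log-transformed positive
    parameters, started at moment/quantile estimates.  Positive-support
    families (lognormal, Weibull) require strictly positive samples;
    constant samples are rejected.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < MIN_GROUP_SIZE:
        raise ValueError(f"need at least {MIN_GROUP_SIZE} samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: distribution fit is degenerate")
    if family in ("lognormal", "weibull") and np.any(x <= 0):
        raise ValueError(f"{family} fit requires strictly positive samples")
    if family not in ("lognormal", "weibull", "gaussian"):
        raise ValueError(f"unknown family {family!r}")

    xs = np.sort(x)
    p0 = _initial_params(xs, family)
    if p0[1] <= 0:
        raise ValueError("degenerate scale at initialization")

    def objective(theta):
        params = _untransform(family, theta)
        return one_sample_ks(xs, lambda v: _family_cdf(family, params, v))

    theta0 = _transform(family, p0)
    ks0 = objective(theta0)
    res = optimize.minimize(
        objective, theta0, method="Nelder-Mead",
        options=dict(xatol=1e-7, fatol=1e-6, maxiter=2000),
    )
    params = _untransform(family, res.x)
    ks = float(res.fun)
    if ks > ks0:  # optimizer never reports worse than its start
        params, ks = p0, ks0
    return FittedDistribution(family=family, params=tuple(params),
                              ks_distance=ks, ks_init=float(ks0), n=x.size)


def egf_group_label(dose: float) -> str:
    """Stimulation-group label (no/low/high) of one EGF dose in nM."""
    label = _EGF_GROUPS.get(float(dose))
    if label is None:
        raise ValueError(
            f"unrecognized EGF dose {dose!r} nM; allowed: {EGF_DOSE_PANEL}"
        )
    return label


def group_by_egf(doses, values, provenance=None) -> GroupedSamples:
    """Bin samples into no/low/high EGF stimulation groups.

    0 nM -> no; 0.01 and 0.1 nM -> low; 1, 10 and 100 nM -> high.  A dose
    outside the panel raises, naming it.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if doses.shape != values.shape:
        raise ValueError("doses and values must align")
    groups: dict[str, list] = {}
    prov: dict[str, list] = {}
    prov_in = list(provenance) if provenance is not None else None
    for i, d in enumerate(doses):
        label = _EGF_GROUPS.get(float(d))
        if label is None:
            raise ValueError(
                f"unrecognized EGF dose {d!r} nM; allowed: {EGF_DOSE_PANEL}"
            )
        groups.setdefault(label, []).append(values[i])
        if prov_in is not None:
            prov.setdefault(label, []).append(prov_in[i])
    return GroupedSamples(scheme="egf",
                          groups={k: np.array(v) for k, v in groups.items()},
                          provenance=prov)


def group_by_speed(speeds, values, cutoff: float, provenance=None) -> GroupedSamples:
    """Split samples into slow/fast groups at a migration-speed cutoff.

    Speed strictly greater than the cutoff is fast, otherwise slow.  The
    cutoff comes from the data (2-means partition of the speed sample), not
    from a hard-coded constant.
    """
    if not np.isfinite(cutoff) or cutoff <= 0:
        raise ValueError(f"cutoff must be a positive finite speed, got {cutoff!r}")
    speeds = np.asarray(speeds, dtype=float)
    values = np.asarray(values, dtype=float)
    if speeds.shape != values.shape:
        raise ValueError("speeds and values must align")
    if np.any(~np.isfinite(speeds)):
        idx = int(np.argmax(~np.isfinite(speeds)))
        raise ValueError(f"missing speed at index {idx}")
    groups: dict[str, list] = {}
    prov: dict[str, list] = {}
    prov_in = list(provenance) if provenance is not None else None
    for i, s in enumerate(speeds):
        label = "fast" if s > cutoff else "slow"
        groups.setdefault(label, []).append(values[i])
        if prov_in is not None:
            prov.setdefault(label, []).append(prov_in[i])
    return GroupedSamples(scheme="speed",
                          groups={k: np.array(v) for k, v in groups.items()},
                          provenance=prov)


def mean_difference_test(group_a, group_b, alpha: float = 0.01,
                         equal_var: bool = False):
    """Two-sample t-test on group means with a significance flag.

    Welch's unequal-variance variant by default (``equal_var=True`` selects
    the pooled-variance Student form).  Returns ``(t, p, significant)`` with
    ``significant = p < alpha`` (default threshold 0.01).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both groups with equal means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), bool(p < alpha)
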
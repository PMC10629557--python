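"""Arrival kinetics and censored dwell-time statistics.

Time-to-first-binding at DNA locations is modeled as a mixture of
specific and nonspecific arrivals,

    F(t) = A_f * (1 - exp(-(k_a + k_ns) t)) + (1 - A_f) * (1 - exp(-k_ns t)),

where ``k_a`` is the apparent first-order specific association rate,
``A_f`` the fraction of DNAs competent to bind, and ``k_ns`` the
nonspecific surface-binding rate measured independently at non-DNA
control locations.  The fit is two-stage maximum likelihood on arrival
times with end-of-record censoring: ``k_ns`` from the controls first,
then ``(k_a, A_f)`` with ``k_ns`` held fixed.

Dwell times truncated by the end of recording are handled with the
Kaplan-Meier estimator (Greenwood 95% CI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .intervals import Interval

__all__ = [
    "FirstBindingCurve", "FirstBindingFit", "SurvivalCurve", "BinomialSummary",
    "first_arrival_times", "empirical_first_binding", "first_binding_cdf",
    "fit_first_binding", "fit_first_binding_ls", "lrt_specific_binding",
    "survival_curve", "binomial_fraction",
]


# ---------------------------------------------------------------------------
# Empirical time-to-first-binding
# ---------------------------------------------------------------------------

@dataclass
class FirstBindingCurve:
    """Cumulative fraction of locations with >=1 binding by time t."""

    times: np.ndarray       # step positions, s (sorted)
    fraction: np.ndarray    # value of the curve at and after times[i]
    n_locations: int
    record_length: float

    def at(self, t) -> np.ndarray:
        """Curve value at arbitrary times (right-continuous step)."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right")
        vals = np.concatenate([[0.0], self.fraction])
        return vals[idx]


def first_arrival_times(intervals_per_location: Dict[int, Sequence[Interval]],
                        location_ids: Sequence[int]) -> np.ndarray:
    """First interval start per location; +inf where nothing ever bound."""
    out = []
    for lid in location_ids:
        ivs = intervals_per_location.get(lid, [])
        out.append(min((iv.start_time for iv in ivs), default=math.inf))
    return np.asarray(out, float)


def empirical_first_binding(first_times: np.ndarray,
                            record_length: float) -> FirstBindingCurve:
    """Step curve of the fraction bound at least once by each time.

    ``first_times`` may contain +inf (or values beyond the record) for
    locations that never bound; those stay censored at the record end.
    """
    t = np.asarray(first_times, float)
    if t.size == 0:
        raise ValueError("empirical_first_binding requires >= 1 location")
    n = t.size
    obs = np.sort(t[t < record_length])
    frac = np.arange(1, len(obs) + 1) / n
    return FirstBindingCurve(obs, frac, n, record_length)


# ---------------------------------------------------------------------------
# Two-stage specific + nonspecific arrival fit
# ---------------------------------------------------------------------------

def first_binding_cdf(t, k_a: float, A_f: float, k_ns: float):
    """Model CDF of time to first binding at a DNA location."""
    t = np.asarray(t, float)
    return (A_f * (1.0 - np.exp(-(k_a + k_ns) * t))
            + (1.0 - A_f) * (1.0 - np.exp(-k_ns * t)))


@dataclass
class FirstBindingFit:
    k_a: float
    A_f: float
    k_ns: float
    se_k_a: float
    se_A_f: float
    se_k_ns: float
    n_locations: int
    log_likelihood: float
    converged: bool = True
    flags: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"k_a": self.k_a, "A_f": self.A_f, "k_ns": self.k_ns,
                "se_k_a": self.se_k_a, "se_A_f": self.se_A_f,
                "se_k_ns": self.se_k_ns, "n_locations": self.n_locations,
                "log_likelihood": self.log_likelihood,
                "converged": self.converged, "flags": self.flags}


def _censored_exp_mle(times: np.ndarray, T: float) -> Tuple[float, float, float]:
    """Exponential-rate MLE with type-I censoring at T.

    Returns (rate, SE, log-likelihood).  Rate = events / total exposure;
    SE = rate / sqrt(events).
    """
    t = np.asarray(times, float)
    obs = t[t < T]
    exposure = float(np.sum(np.minimum(t, T)))
    n_ev = len(obs)
    if n_ev == 0:
        return 0.0, 0.0, 0.0
    rate = n_ev / exposure
    ll = n_ev * math.log(rate) - rate * exposure
    return rate, rate / math.sqrt(n_ev), ll


def _dna_nll(params: np.ndarray, obs: np.ndarray, n_cens: int, T: float,
             k_ns: float) -> float:
    k_a, A_f = params
    if k_a < 0 or not (0.0 <= A_f <= 1.0):
        return np.inf
    lam = k_a + k_ns
    dens = A_f * lam * np.exp(-lam * obs) + (1 - A_f) * k_ns * np.exp(-k_ns * obs)
    if np.any(dens <= 0):
        return np.inf
    ll = float(np.sum(np.log(dens)))
    if n_cens:
        surv = A_f * math.exp(-lam * T) + (1 - A_f) * math.exp(-k_ns * T)
        if surv <= 0:
            return np.inf
        ll += n_cens * math.log(surv)
    return -ll


def _hessian_se(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """SEs from the observed information (numerical Hessian of the NLL)."""
    k = len(x)
    h = np.maximum(np.abs(x), 1e-8) * rel_step
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h[i]
            ej = np.eye(k)[j] * h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return se


def fit_first_binding(dna_times: np.ndarray, control_times: np.ndarray,
                      record_length: float) -> FirstBindingFit:
    """Two-stage MLE of (k_a, A_f, k_ns) from first-arrival times.

    Stage 1 fits ``k_ns`` to the non-DNA control arrivals by censored
    exponential MLE.  Stage 2 maximizes the DNA-location likelihood over
    ``(k_a, A_f)`` with ``k_ns`` fixed; SEs come from the observed
    information matrix.
    """
    T = float(record_length)
    dna = np.asarray(dna_times, float)
    ctrl = np.asarray(control_times, float)
    if dna.size == 0 or ctrl.size == 0:
        raise ValueError("both DNA and non-DNA first-arrival data are required")
    k_ns, se_k_ns, _ = _censored_exp_mle(ctrl, T)
    obs = dna[dna < T]
    n_cens = int(np.sum(dna >= T))
    if len(obs) == 0:
        raise ValueError("no DNA location bound within the record")

    nll = lambda p: _dna_nll(p, obs, n_cens, T, k_ns)
    k0 = max(len(obs) / np.sum(np.minimum(dna, T)) - k_ns, 1e-6)
    best = None
    for a0 in (0.9, 0.5, 0.99):
        res = optimize.minimize(nll, x0=np.array([k0, a0]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    k_a, A_f = float(best.x[0]), float(min(max(best.x[1], 0.0), 1.0))
    se = _hessian_se(nll, best.x)
    flags: List[str] = []
    if not best.success:
        flags.append("optimizer did not report convergence")
    if k_ns >= k_a:
        flags.append("low signal: fitted k_ns >= k_a")
    return FirstBindingFit(k_a, A_f, k_ns, float(se[0]), float(se[1]),
                           se_k_ns, dna.size, -float(best.fun),
                           converged=bool(best.success), flags=flags)


def fit_first_binding_ls(dna_times: np.ndarray, control_times: np.ndarray,
                         record_length: float) -> FirstBindingFit:
    """Least-squares fit of the model CDF to the empirical curve.

    Comparison fallback for the MLE; same two-stage structure (``k_ns``
    from controls by censored MLE, then curve_fit for ``k_a`` and
    ``A_f``).
    """
    T = float(record_length)
    k_ns, se_k_ns, _ = _censored_exp_mle(np.asarray(control_times, float), T)
    curve = empirical_first_binding(np.asarray(dna_times, float), T)
    grid = np.linspace(0, T, 400)
    emp = curve.at(grid)

    def model(t, k_a, A_f):
        return first_binding_cdf(t, k_a, A_f, k_ns)

    popt, pcov = optimize.curve_fit(model, grid, emp, p0=[0.003, 0.8],
                                    bounds=([0, 0], [np.inf, 1]), maxfev=20000)
    se = np.sqrt(np.diag(pcov))
    return FirstBindingFit(float(popt[0]), float(popt[1]), k_ns,
                           float(se[0]), float(se[1]), se_k_ns,
                           len(np.asarray(dna_times)), math.nan,
                           flags=["least-squares comparison fit"])


def lrt_specific_binding(dna_times: np.ndarray, control_times: np.ndarray,
                         record_length: float) -> float:
    """Likelihood-ratio p-value for any specific binding at DNA locations.

    Null: DNA arrivals are pure background (A_f = 0, k_ns from controls).
    Alternative: the full (k_a, A_f) model.  2 df chi-square reference;
    conservative because the null lies on the parameter boundary.
    """
    T = float(record_length)
    dna = np.asarray(dna_times, float)
    k_ns, _, _ = _censored_exp_mle(np.asarray(control_times, float), T)
    obs = dna[dna < T]
    n_cens = int(np.sum(dna >= T))
    ll_null = (len(obs) * math.log(k_ns) - k_ns * float(np.sum(obs))
               - k_ns * T * n_cens) if k_ns > 0 else -math.inf
    fit = fit_first_binding(dna, control_times, T)
    stat = max(0.0, 2.0 * (fit.log_likelihood - ll_null))
    return float(stats.chi2.sf(stat, df=2))


# ---------------------------------------------------------------------------
# Censored dwell-time survival analysis
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Kaplan-Meier survival estimate with Greenwood 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_events: int
    n_censored: int
    median: float                   # +inf if S never reaches 0.5
    median_is_lower_bound: bool

    @property
    def median_label(self) -> str:
        if math.isinf(self.median):
            return f"> {np.max(self.times):g} s"
        note = " (lower bound)" if self.median_is_lower_bound else ""
        return f"{self.median:g} s{note}"


def survival_curve(durations: Sequence[float],
                   censored: Optional[Sequence[bool]] = None) -> SurvivalCurve:
    """Kaplan-Meier estimate of a dwell-time distribution.

    ``censored[i]`` marks dwells truncated by the end of recording.  The
    median is the earliest time with S(t) <= 0.5; if the curve never
    reaches 0.5 it is +inf and flagged as a lower bound (as is any
    median in the presence of heavy censoring).
    """
    from lifelines import KaplanMeierFitter

    d = np.asarray(durations, float)
    if d.size == 0:
        raise ValueError("survival_curve requires >= 1 dwell")
    c = (np.zeros(d.size, bool) if censored is None
         else np.asarray(censored, bool))
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(d, event_observed=~c)
    times = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    ci = kmf.confidence_interval_
    lo = ci.iloc[:, 0].to_numpy(float)
    hi = ci.iloc[:, 1].to_numpy(float)
    below = np.nonzero(surv <= 0.5)[0]
    if len(below):
        median = float(times[below[0]])
        lower_bound = bool(np.any(c))
    else:
        median = math.inf
        lower_bound = True
    return SurvivalCurve(times, surv, lo, hi,
                         n_events=int(np.sum(~c)), n_censored=int(np.sum(c)),
                         median=median, median_is_lower_bound=lower_bound)


# ---------------------------------------------------------------------------
# Binomial summaries
# ---------------------------------------------------------------------------

@dataclass
class BinomialSummary:
    k: int
    n: int
    percent: float
    sem_percent: float

    def __str__(self) -> str:
        return f"{self.percent:.0f} ± {self.sem_percent:.0f}% ({self.k}/{self.n})"


def binomial_fraction(k: int, n: int) -> BinomialSummary:
    """Percent +- binomial SEM for k successes out of n trials."""
    if n < 1:
        raise ValueError("binomial_fraction requires n >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    p = k / n
    return BinomialSummary(k, n, 100.0 * p,
                           100.0 * math.sqrt(p * (1 - p) / n))
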
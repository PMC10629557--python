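"""Apparent FRET efficiency analysis for the Mcm2-5 gate and MO assays.

``E_FRET = A_em / (A_em + D_em)`` on donor-excited frames, uncorrected
for gamma, spectral leakage, or direct acceptor excitation (the ratio
definition used throughout; it is invariant under common rescaling of
the two emission channels).  Frames are valid only while both
fluorophores are present, excluding the first and last frame of each
colocalization episode and everything after a second Mcm2-7 arrival.

States are called by strict thresholding (>0.3 for a closed Mcm2-5
gate, >0.5 for the MO complex) sustained for at least two consecutive
valid frames.  Pooled E_FRET samples are fit to a two-component
Gaussian mixture density

    P_low/(sqrt(2 pi) s_low) exp(-(E-m_low)^2/(2 s_low^2))
      + (1-P_low)/(sqrt(2 pi) s_high) exp(-(E-m_high)^2/(2 s_high^2))

on the 0.1-0.7 window, with bootstrap standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .intervals import Interval
from .render import Trace

__all__ = ["EfretTrace", "compute_efret", "call_state", "MixtureFit",
           "mixture_pdf", "fit_mixture", "HeatMap", "efret_heatmap"]

RING_THRESHOLD = 0.3    # open/closed midpoint of the ~0.20 / ~0.37 states
MO_THRESHOLD = 0.5      # OCCM/MO midpoint
MIN_STATE_FRAMES = 2


@dataclass
class EfretTrace:
    """Per-frame apparent FRET efficiency with a validity mask."""

    location_id: int
    times: np.ndarray           # frame start times, s
    efret: np.ndarray           # NaN where invalid
    valid: np.ndarray           # bool
    frame_interval: float
    qc: dict = field(default_factory=dict)

    @property
    def valid_samples(self) -> np.ndarray:
        return self.efret[self.valid]

    def aligned(self, t0: float) -> "EfretTrace":
        """Copy with times shifted so that ``t0`` becomes 0."""
        return replace(self, times=self.times - t0)


def compute_efret(donor: Trace, acceptor: Trace,
                  episodes: Sequence[Interval],
                  stop_time: Optional[float] = None) -> EfretTrace:
    """Compute E_FRET over both-fluorophore episodes of one location.

    ``episodes`` are the frame intervals during which both dyes of the
    pair are present; the first and last frame of each episode are
    discarded.  ``stop_time`` (e.g. a second Mcm2-7 arrival) invalidates
    everything at or after it.  Nominally valid frames with non-positive
    total emission are masked and counted in ``qc``.
    """
    if donor.n_frames != acceptor.n_frames:
        raise ValueError("donor and acceptor traces must share the frame clock")
    d = np.asarray(donor.values, float)
    a = np.asarray(acceptor.values, float)
    n = len(d)
    valid = np.zeros(n, bool)
    for ep in episodes:
        lo, hi = ep.start_frame + 1, ep.end_frame - 1
        if hi > lo:
            valid[lo:hi] = True
    times = donor.times
    if stop_time is not None:
        valid &= times < stop_time
    total = a + d
    bad_total = valid & (total <= 0)
    valid &= total > 0
    e = np.full(n, np.nan)
    e[valid] = a[valid] / total[valid]
    return EfretTrace(donor.location_id, times, e, valid, donor.frame_interval,
                      qc={"n_masked_nonpositive_total": int(bad_total.sum())})


def call_state(efret: EfretTrace, threshold: float = RING_THRESHOLD,
               min_frames: int = MIN_STATE_FRAMES) -> List[Interval]:
    """Maximal runs of consecutive valid frames above threshold.

    A masked frame breaks a run (strict consecutive-frame rule); runs
    shorter than ``min_frames`` are not called.  Used with (0.3, 2) for
    ring closing and (0.5, 2) for MO formation.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    above = efret.valid & (efret.efret > threshold)
    out: List[Interval] = []
    n = len(above)
    i = 0
    while i < n:
        if above[i]:
            j = i + 1
            while j < n and above[j]:
                j += 1
            if j - i >= min_frames:
                out.append(Interval(efret.location_id, "state", i, j,
                                    efret.frame_interval,
                                    censored_end=(j == n),
                                    tags={"threshold": threshold}))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture fitting
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    p_low: float
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    se_p_low: float = math.nan
    se_mu_low: float = math.nan
    se_mu_high: float = math.nan
    se_sigma_low: float = math.nan
    se_sigma_high: float = math.nan
    n_samples: int = 0
    window: Tuple[float, float] = (0.1, 0.7)
    n_boot: int = 0
    log_likelihood: float = math.nan
    flags: List[str] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.p_low, self.mu_low, self.mu_high,
                         self.sigma_low, self.sigma_high])

    def to_dict(self) -> dict:
        return {"P_low": self.p_low, "mu_low": self.mu_low,
                "mu_high": self.mu_high, "sigma_low": self.sigma_low,
                "sigma_high": self.sigma_high,
                "se_P_low": self.se_p_low, "se_mu_low": self.se_mu_low,
                "se_mu_high": self.se_mu_high,
                "se_sigma_low": self.se_sigma_low,
                "se_sigma_high": self.se_sigma_high,
                "n_samples": self.n_samples, "window": list(self.window),
                "n_boot": self.n_boot, "flags": self.flags}


_SIGMA_MIN = 0.01
_SIGMA_MAX = 0.5


def mixture_pdf(x, p_low: float, mu_low: float, mu_high: float,
                sigma_low: float, sigma_high: float,
                window: Optional[Tuple[float, float]] = None):
    """The two-component mixture density; optionally renormalized to a window."""
    x = np.asarray(x, float)
    pdf = (p_low * norm.pdf(x, mu_low, sigma_low)
           + (1 - p_low) * norm.pdf(x, mu_high, sigma_high))
    if window is not None:
        lo, hi = window
        mass = (p_low * (norm.cdf(hi, mu_low, sigma_low)
                         - norm.cdf(lo, mu_low, sigma_low))
                + (1 - p_low) * (norm.cdf(hi, mu_high, sigma_high)
                                 - norm.cdf(lo, mu_high, sigma_high)))
        pdf = pdf / mass
    return pdf


def _order(theta: np.ndarray) -> np.ndarray:
    p, ml, mh, sl, sh = theta
    if ml > mh:
        return np.array([1 - p, mh, ml, sh, sl])
    return theta


def _fit_once(x: np.ndarray, theta0: np.ndarray, truncated: bool,
              window: Tuple[float, float]):
    win = window if truncated else None

    def nll(theta):
        p, ml, mh, sl, sh = theta
        dens = mixture_pdf(x, p, ml, mh, sl, sh, window=win)
        if np.any(dens <= 0) or not np.all(np.isfinite(dens)):
            return np.inf
        return -float(np.sum(np.log(dens)))

    bounds = [(1e-4, 1 - 1e-4), (0.0, 1.0), (0.0, 1.0),
              (_SIGMA_MIN, _SIGMA_MAX), (_SIGMA_MIN, _SIGMA_MAX)]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    return _order(res.x), float(res.fun)


def fit_mixture(samples: Sequence[float],
                window: Tuple[float, float] = (0.1, 0.7),
                n_boot: int = 1000,
                truncated: bool = False,
                n_restarts: int = 10,
                seed: int = 0) -> MixtureFit:
    """Maximum-likelihood two-Gaussian mixture fit of E_FRET samples.

    Samples outside ``window`` are dropped before fitting.  By default
    the untruncated density is fit to the in-window samples; with
    ``truncated=True`` the likelihood is renormalized to the window.
    Initialization is a quantile split at the sample median with
    jittered restarts; the best likelihood wins (ties to the lower
    mu_low).  Bootstrap SEs resample individual E_FRET values.
    """
    x = np.asarray(samples, float)
    x = x[(x >= window[0]) & (x <= window[1])]
    if len(x) < 50:
        raise ValueError("fit_mixture requires >= 50 samples inside the window")
    rng = np.random.Generator(np.random.PCG64(seed))
    med = float(np.median(x))
    lo, hi = x[x <= med], x[x > med]
    theta0 = np.array([0.5, float(np.mean(lo)), float(np.mean(hi)),
                       max(float(np.std(lo)), _SIGMA_MIN),
                       max(float(np.std(hi)), _SIGMA_MIN)])
    candidates = [theta0]
    for _ in range(max(n_restarts - 1, 0)):
        jit = theta0 * (1 + rng.normal(0, 0.15, 5))
        jit[0] = float(np.clip(rng.uniform(0.2, 0.8), 1e-3, 1 - 1e-3))
        jit[3:] = np.clip(jit[3:], _SIGMA_MIN, _SIGMA_MAX)
        jit[1:3] = np.clip(jit[1:3], 0, 1)
        candidates.append(jit)
    best_theta, best_nll = None, np.inf
    for t0 in candidates:
        theta, val = _fit_once(x, t0, truncated, window)
        if val < best_nll - 1e-9 or (abs(val - best_nll) <= 1e-9
                                     and best_theta is not None
                                     and theta[1] < best_theta[1]):
            best_theta, best_nll = theta, val
    assert best_theta is not None
    flags: List[str] = []
    if best_theta[3] <= _SIGMA_MIN + 1e-9 or best_theta[4] <= _SIGMA_MIN + 1e-9:
        flags.append("sigma at lower bound (0.01)")
    if abs(best_theta[1] - best_theta[2]) < 1e-3:
        flags.append("degenerate components: mu_low ~= mu_high")
    if not np.isfinite(best_nll):
        flags.append("fit did not converge")

    ses = np.full(5, np.nan)
    if n_boot > 0:
        boots = np.empty((n_boot, 5))
        for b in range(n_boot):
            xb = rng.choice(x, size=len(x), replace=True)
            boots[b], _ = _fit_once(xb, best_theta, truncated, window)
        ses = boots.std(axis=0, ddof=1)
    p, ml, mh, sl, sh = best_theta
    return MixtureFit(float(p), float(ml), float(mh), float(sl), float(sh),
                      *[float(s) for s in ses],
                      n_samples=len(x), window=window, n_boot=n_boot,
                      log_likelihood=-best_nll, flags=flags)


# ---------------------------------------------------------------------------
# Time-aligned kernel heat maps
# ---------------------------------------------------------------------------

@dataclass
class HeatMap:
    """2-D kernel histogram of E_FRET vs. time since first Mcm2-7 arrival."""

    t_grid: np.ndarray
    e_grid: np.ndarray
    density: np.ndarray             # (len(t_grid), len(e_grid)), slice-normalized
    remaining: np.ndarray           # fraction of molecules still valid at t
    bw_time: float
    bw_efret: float
    n_molecules: int


def efret_heatmap(traces: Sequence[EfretTrace],
                  bw_time: float = 2.7, bw_efret: float = 0.005,
                  t_max: Optional[float] = None,
                  e_grid: Optional[np.ndarray] = None) -> HeatMap:
    """Gaussian-kernel (t, E_FRET) histogram with per-slice normalization.

    Input traces must already be aligned so each molecule's first Mcm2-7
    arrival is t = 0 (see :meth:`EfretTrace.aligned`).  Each time slice
    of the density integrates to 1 over the E_FRET grid; the remaining
    fraction is the raw step fraction of molecules whose last valid
    frame lies at or beyond each grid time.
    """
    pts_t: List[np.ndarray] = []
    pts_e: List[np.ndarray] = []
    last_valid: List[float] = []
    for tr in traces:
        if not np.any(tr.valid):
            continue
        pts_t.append(tr.times[tr.valid])
        pts_e.append(tr.efret[tr.valid])
        last_valid.append(float(tr.times[tr.valid].max()))
    if not pts_t:
        raise ValueError("efret_heatmap requires at least one valid frame")
    t_all = np.concatenate(pts_t)
    e_all = np.concatenate(pts_e)
    if t_max is None:
        t_max = float(t_all.max())
    t_grid = np.arange(0.0, t_max + bw_time, bw_time)
    if e_grid is None:
        e_grid = np.linspace(0.0, 1.0, 401)
    # time weights (n_t, n_points) then kernel in E -> (n_t, n_e)
    wt = np.exp(-0.5 * ((t_grid[:, None] - t_all[None, :]) / bw_time) ** 2)
    ker = np.exp(-0.5 * ((e_grid[None, :] - e_all[:, None]) / bw_efret) ** 2)
    density = wt @ ker                       # (n_t, n_e)
    area = np.trapezoid(density, e_grid, axis=1)
    density = np.where(area[:, None] > 0, density / area[:, None], 0.0)
    lv = np.asarray(last_valid)
    remaining = np.array([(lv >= t).mean() for t in t_grid])
    return HeatMap(t_grid, np.asarray(e_grid), density, remaining,
                   bw_time, bw_efret, n_molecules=len(last_valid))
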
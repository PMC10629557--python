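"""Convert normalized intensity traces into colocalization intervals.

A trace is first normalized so the unbound background sits at 0 and a
single bound fluorophore at 1; hysteresis thresholding then segments
bound episodes, and intensity near 2 within an episode marks
stoichiometry-2 stretches (two simultaneously bound proteins, e.g. a
second Mcm2-7).  Episodes still bound on the last frame are flagged
censored.  Frame indexing is half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .config import SimConfig
from .render import Trace, frame_occupancy
from .simulate import LocationTimeline

__all__ = ["Interval", "CallParams", "normalize_trace", "call_intervals",
           "merge_episodes", "LinkedEpisode", "pair_channels", "truth_intervals"]


@dataclass
class Interval:
    """One protein-DNA colocalization stretch at constant stoichiometry."""

    location_id: int
    channel: str
    start_frame: int
    end_frame: int                  # half-open
    frame_interval: float
    t0: float = 0.0
    stoichiometry: int = 1
    censored_start: bool = False
    censored_end: bool = False
    episode_id: int = 0
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("interval requires start < end")
        if self.stoichiometry not in (1, 2):
            raise ValueError("stoichiometry must be 1 or 2")

    @property
    def start_time(self) -> float:
        return self.t0 + self.start_frame * self.frame_interval

    @property
    def end_time(self) -> float:
        return self.t0 + self.end_frame * self.frame_interval

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def overlaps(self, other: "Interval") -> bool:
        return (self.start_time < other.end_time
                and other.start_time < self.end_time)


@dataclass
class CallParams:
    up: float = 0.5                 # episode starts above this (unit levels)
    down: float = 0.3               # and continues until below this
    stoich2_level: float = 1.5      # >= this marks a two-protein stretch
    min_frames: int = 1

    def __post_init__(self) -> None:
        if self.down >= self.up:
            raise ValueError("down-threshold must be below up-threshold")


def _kde_peaks(values: np.ndarray, rel_height: float = 0.05):
    """Local maxima of a Gaussian KDE, as (position, density) pairs."""
    if len(values) < 3 or np.ptp(values) < 1e-12:
        return [(float(np.median(values)), 1.0)]
    kde = gaussian_kde(values)
    pad = 0.1 * np.ptp(values)
    grid = np.linspace(values.min() - pad, values.max() + pad, 512)
    dens = kde(grid)
    idx = [i for i in range(1, len(grid) - 1)
           if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1]]
    idx = [i for i in idx if dens[i] >= rel_height * dens.max()]
    if not idx:
        idx = [int(np.argmax(dens))]
    return [(float(grid[i]), float(dens[i])) for i in idx]


def _noise_sigma(v: np.ndarray) -> float:
    """Frame noise SD from successive differences (robust to binding steps)."""
    if len(v) < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(v))) * 1.4826 / np.sqrt(2.0))


def normalize_trace(trace: Trace) -> Trace:
    """Rescale a trace so background ~= 0 and one fluorophore ~= 1.

    Input traces are already background-subtracted (spatially, during
    extraction), so the residual baseline is taken from an intensity
    mode near zero when one exists and left at zero otherwise -- a trace
    bound for nearly the whole record must not have its bound level
    mistaken for background.  The unit level is the lowest prominent
    mode of the above-background frames, so stoichiometry-2 stretches do
    not inflate it.
    """
    if trace.n_frames < 20:
        raise ValueError("normalization requires at least 20 frames")
    v = np.asarray(trace.values, float)
    sigma = _noise_sigma(v)
    near_zero = [p for p, _ in _kde_peaks(v) if abs(p) <= max(3 * sigma, 1e-9)]
    baseline = min(near_zero, key=abs) if near_zero else 0.0
    shifted = v - baseline
    bound = shifted[shifted > max(3 * sigma, 1e-9)]
    if len(bound) < 3:
        unit = 1.0
        if not np.allclose(shifted, 0):
            warnings.warn("no discernible bound level; leaving scale at 1")
    else:
        # Bound levels are integer multiples of one fluorophore.  A
        # (u, 2u) peak pair pins the unit even when the single-protein
        # stretch is brief; otherwise take the lowest prominent mode so
        # stoichiometry-2 stretches do not inflate the estimate.
        peaks = _kde_peaks(bound, rel_height=0.02)
        top = max(d for _, d in peaks)
        unit = 0.0
        best = -np.inf
        for i, (p, d) in enumerate(peaks):
            for q, e in peaks[i + 1:]:
                if p > 0 and 1.7 <= q / p <= 2.3 and d + e > best:
                    best, unit = d + e, p
        if unit <= 0:
            strong = [p for p, d in peaks if d >= 0.1 * top]
            unit = strong[0] if strong else peaks[0][0]
        if unit <= 0:
            warnings.warn("non-positive unit level estimate; leaving scale at 1")
            unit = 1.0
    out = replace(trace, values=shifted / unit)
    out.meta = dict(trace.meta, baseline=float(baseline), unit=float(unit),
                    noise_sigma=float(sigma))
    return out


def call_intervals(trace: Trace, params: Optional[CallParams] = None) -> List[Interval]:
    """Segment a normalized trace into bound intervals.

    Hysteresis thresholding: an episode opens on a frame at or above the
    up-threshold and runs until the first frame below the down-threshold.
    Within an episode, maximal runs at or above ``stoich2_level`` are
    emitted as stoichiometry-2 sub-intervals.  Episodes reaching the last
    frame are censored.
    """
    params = params or CallParams()
    v = np.asarray(trace.values, float)
    n = len(v)
    intervals: List[Interval] = []
    episode_id = 0
    i = 0
    while i < n:
        if v[i] >= params.up:
            j = i + 1
            while j < n and v[j] >= params.down:
                j += 1
            if j - i >= params.min_frames:
                levels = np.where(v[i:j] >= params.stoich2_level, 2, 1)
                k = i
                for lev, run in _runs(levels):
                    intervals.append(Interval(
                        trace.location_id, trace.channel, k, k + run,
                        trace.frame_interval, t0=trace.t0,
                        stoichiometry=int(lev),
                        censored_end=(k + run == n),
                        censored_start=(k == 0),
                        episode_id=episode_id))
                    k += run
                episode_id += 1
            i = j
        else:
            i += 1
    return intervals


def _runs(levels: np.ndarray):
    start = 0
    for i in range(1, len(levels) + 1):
        if i == len(levels) or levels[i] != levels[start]:
            yield levels[start], i - start
            start = i


def merge_episodes(intervals: Sequence[Interval]) -> List[Interval]:
    """Merge stoichiometry sub-intervals back into whole bound episodes.

    The merged interval carries ``stoichiometry=1`` semantics for its own
    span and records the level-2 stretches in ``tags['stoich2_frames']``.
    """
    episodes: List[Interval] = []
    by_ep: Dict[tuple, List[Interval]] = {}
    for iv in intervals:
        by_ep.setdefault((iv.location_id, iv.channel, iv.episode_id), []).append(iv)
    for (_loc, _ch, _ep), parts in sorted(by_ep.items()):
        parts.sort(key=lambda p: p.start_frame)
        first, last = parts[0], parts[-1]
        ep = Interval(first.location_id, first.channel, first.start_frame,
                      last.end_frame, first.frame_interval, t0=first.t0,
                      censored_start=first.censored_start,
                      censored_end=last.censored_end,
                      episode_id=first.episode_id,
                      tags={"stoich2_frames": [(p.start_frame, p.end_frame)
                                               for p in parts
                                               if p.stoichiometry == 2]})
        episodes.append(ep)
    return episodes


@dataclass
class LinkedEpisode:
    """One Mcm2-7 episode linked to overlapping partner-channel intervals."""

    location_id: int
    mcm: Interval
    cdt1: Optional[Interval] = None
    cdc6: List[Interval] = field(default_factory=list)
    orc: Optional[Interval] = None

    @property
    def cdc6_dwell_after_mcm(self) -> Optional[float]:
        """Cdc6 retention after first Mcm2-7 arrival (OCCM duration), s."""
        overl = [c for c in self.cdc6
                 if c.start_time <= self.mcm.start_time < c.end_time]
        if not overl:
            return None
        return overl[0].end_time - self.mcm.start_time

    @property
    def cdc6_dwell_censored(self) -> bool:
        overl = [c for c in self.cdc6
                 if c.start_time <= self.mcm.start_time < c.end_time]
        return bool(overl) and overl[0].censored_end


def pair_channels(intervals_by_channel: Dict[str, Sequence[Interval]],
                  mcm_channel: str = "Mcm2-7") -> List[LinkedEpisode]:
    """Link each Mcm2-7 episode to overlapping Cdc6/Cdt1/ORC intervals.

    Input intervals must all belong to one location.  Sub-intervals are
    merged to episodes first; the Cdt1 (and ORC) link is the overlapping
    interval with the largest time overlap; all overlapping Cdc6
    intervals are kept (first and second Cdc6).
    """
    mcm_eps = merge_episodes(intervals_by_channel.get(mcm_channel, []))
    links: List[LinkedEpisode] = []

    def best_overlap(episode: Interval, cands: List[Interval]) -> Optional[Interval]:
        best, score = None, 0.0
        for c in cands:
            ov = (min(episode.end_time, c.end_time)
                  - max(episode.start_time, c.start_time))
            if ov > score:
                best, score = c, ov
        return best

    for ep in mcm_eps:
        cdt1 = best_overlap(ep, list(merge_episodes(
            intervals_by_channel.get("Cdt1", []))))
        orc = best_overlap(ep, list(merge_episodes(
            intervals_by_channel.get("ORC", []))))
        cdc6 = [c for c in merge_episodes(intervals_by_channel.get("Cdc6", []))
                if c.overlaps(ep)]
        links.append(LinkedEpisode(ep.location_id, ep, cdt1=cdt1,
                                   cdc6=sorted(cdc6, key=lambda c: c.start_time),
                                   orc=orc))
    return links


def truth_intervals(loc: LocationTimeline, config: SimConfig) -> Dict[str, List[Interval]]:
    """Frame-quantized ground-truth intervals per species for one location.

    Uses the same half-frame occupancy rule as the trace renderer, so on
    noiseless, fully labeled, bleach-free traces the called intervals
    must match these exactly.
    """
    n, dt = config.n_frames_per_color, config.frame_interval
    out: Dict[str, List[Interval]] = {}
    by_species: Dict[str, np.ndarray] = {}
    for ev in loc.events:
        occ = frame_occupancy(ev.arrival, ev.departure, n, dt)
        by_species[ev.species] = by_species.get(ev.species, np.zeros(n)) + occ
    for species, occ in by_species.items():
        levels = np.minimum(occ.astype(int), 2)
        intervals: List[Interval] = []
        ep = 0
        i = 0
        while i < n:
            if levels[i] > 0:
                j = i + 1
                while j < n and levels[j] > 0:
                    j += 1
                k = i
                for lev, run in _runs(levels[i:j]):
                    intervals.append(Interval(loc.location_id, species, k,
                                              k + run, dt,
                                              stoichiometry=int(lev),
                                              censored_end=(k + run == n),
                                              episode_id=ep))
                    k += run
                ep += 1
                i = j
            else:
                i += 1
        out[species] = intervals
    return out
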
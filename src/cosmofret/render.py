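"""Render ground-truth timelines into fluorescence traces and TIRF images.

Traces are the inverse of the experimental extraction step: per location
and channel, the intensity on each frame is the number of labeled,
unbleached fluorophores bound during that frame (in single-fluorophore
units) plus Gaussian noise.  FRET-pair emission on donor-excited frames
is split between donor and acceptor channels so that
``A_em / (A_em + D_em)`` equals the current state's apparent FRET center.

Frame occupancy uses a half-open ``[start, end)`` convention: a molecule
contributes to a frame iff its visible interval overlaps at least half
the frame, which keeps noiseless trace -> interval round trips exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import erf

from .config import SimConfig
from .simulate import BindingEvent, EventTimeline, LocationTimeline

__all__ = ["Trace", "TraceSet", "render_traces", "Optics", "ImageStack",
           "render_image_stack", "frame_occupancy"]


@dataclass
class Trace:
    """Per-location, per-channel intensity time series."""

    location_id: int
    channel: str
    values: np.ndarray
    frame_interval: float
    excitation: str = ""
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        """Frame start times (s)."""
        return self.t0 + np.arange(len(self.values)) * self.frame_interval

    @property
    def n_frames(self) -> int:
        return len(self.values)


class TraceSet(dict):
    """``{location_id: {channel: Trace}}`` with a couple of conveniences."""

    def get_trace(self, location_id: int, channel: str) -> Trace:
        return self[location_id][channel]

    def channels(self) -> List[str]:
        seen: List[str] = []
        for chans in self.values():
            for c in chans:
                if c not in seen:
                    seen.append(c)
        return seen


def frame_occupancy(start: float, end: float, n_frames: int, dt: float) -> np.ndarray:
    """Binary occupancy per frame for a visible interval ``[start, end)``.

    A frame counts as occupied when the overlap with the interval is at
    least half the frame width.
    """
    occ = np.zeros(n_frames, dtype=float)
    if end <= start:
        return occ
    i0 = max(0, int(math.floor(start / dt)))
    i1 = min(n_frames, int(math.ceil(end / dt)))
    if i1 <= i0:
        return occ
    idx = np.arange(i0, i1)
    lo = np.maximum(start, idx * dt)
    hi = np.minimum(end, (idx + 1) * dt)
    occ[idx] = (hi - lo) >= 0.5 * dt
    return occ


def _visible_interval(rng: np.random.Generator, ev_start: float, ev_end: float,
                      label_p: float, bleach_rate: float) -> Optional[Tuple[float, float]]:
    """Fluorophore visibility window after labeling and photobleaching."""
    if rng.random() >= label_p:
        return None
    if bleach_rate > 0:
        end = min(ev_end, ev_start + rng.exponential(1.0 / bleach_rate))
    else:
        end = ev_end
    if end <= ev_start:
        return None
    return ev_start, end


def _ring_state_centers(loc: LocationTimeline, cfg: SimConfig,
                        times: np.ndarray) -> np.ndarray:
    """Gate-FRET center per frame-midpoint time (NaN outside the episode)."""
    centers = np.full(len(times), np.nan)
    for seg in loc.ring_segments:
        c = cfg.efret_closed_center if seg.state == "closed" else cfg.efret_open_center
        m = (times >= seg.start) & (times < seg.end)
        centers[m] = c
    return centers


def render_traces(timeline: EventTimeline, config: Optional[SimConfig] = None) -> TraceSet:
    """Render per-location, per-channel intensity traces from a timeline.

    Channels
    --------
    One direct-excitation channel per protein species present, plus -- for
    the configured FRET assay -- donor-excited donor (``D_em``) and
    acceptor (``A_em``) emission and the directly excited acceptor
    (``A_direct``).  For the ``"ring"`` assay the FRET pair sits on
    Mcm2/Mcm5 of each Mcm2-7; for the ``"mo"`` assay the donor is on Orc6
    and the acceptor on Mcm3.
    """
    cfg = config if config is not None else timeline.config
    if abs(cfg.record_length - timeline.config.record_length) > 1e-9:
        raise ValueError(
            "timeline and config disagree on record length: "
            f"{timeline.config.record_length} vs {cfg.record_length}")
    n = cfg.n_frames_per_color
    dt = cfg.frame_interval
    mid = (np.arange(n) + 0.5) * dt
    root = np.random.SeedSequence(cfg.seed, spawn_key=(1,))
    children = root.spawn(len(timeline.locations))
    out = TraceSet()
    for child, loc in zip(children, timeline.locations):
        rng = np.random.Generator(np.random.PCG64(child))
        chans: Dict[str, np.ndarray] = {}

        # Direct-excitation channels, one per species.
        for ev in loc.events:
            vis = _visible_interval(rng, ev.arrival, ev.departure,
                                    cfg.label_p(ev.species), cfg.bleach_rate)
            occ = (frame_occupancy(vis[0], vis[1], n, dt)
                   if vis is not None else np.zeros(n))
            chans[ev.species] = chans.get(ev.species, np.zeros(n)) + occ

        # FRET channels.
        d_em = np.zeros(n)
        a_em = np.zeros(n)
        a_direct = np.zeros(n)
        if cfg.fret_assay == "ring":
            mcms = [e for e in loc.events if e.species == "Mcm2-7" and e.specific]
            for ev in mcms:
                don = _visible_interval(rng, ev.arrival, ev.departure,
                                        cfg.label_p("donor"), cfg.bleach_rate)
                acc = _visible_interval(rng, ev.arrival, ev.departure,
                                        cfg.label_p("acceptor"), cfg.bleach_rate)
                if acc is not None:
                    a_direct += frame_occupancy(acc[0], acc[1], n, dt)
                if don is None:
                    continue
                occ_d = frame_occupancy(don[0], don[1], n, dt) > 0
                if ev.ordinal == 1:
                    centers = _ring_state_centers(loc, cfg, mid)
                else:
                    centers = np.full(n, cfg.efret_open_center)
                occ_a = (frame_occupancy(acc[0], acc[1], n, dt) > 0
                         if acc is not None else np.zeros(n, bool))
                e = np.where(occ_a, centers, 0.0)
                e = np.where(np.isnan(e), 0.0, e)
                if cfg.efret_sd > 0:
                    e = np.clip(e + np.where(occ_a & occ_d,
                                             rng.normal(0, cfg.efret_sd, n), 0.0),
                                0.0, 1.0)
                d_em += occ_d * (1.0 - e)
                a_em += occ_d * e
        elif cfg.fret_assay == "mo":
            orcs = [e for e in loc.events if e.species == "ORC"]
            mcm1 = next((e for e in loc.events
                         if e.species == "Mcm2-7" and e.specific and e.ordinal == 1),
                        None)
            acc = (_visible_interval(rng, mcm1.arrival, mcm1.departure,
                                     cfg.label_p("acceptor"), cfg.bleach_rate)
                   if mcm1 is not None else None)
            if acc is not None:
                a_direct += frame_occupancy(acc[0], acc[1], n, dt)
            for ev in orcs:
                don = _visible_interval(rng, ev.arrival, ev.departure,
                                        cfg.label_p("donor"), cfg.bleach_rate)
                if don is None:
                    continue
                occ_d = frame_occupancy(don[0], don[1], n, dt) > 0
                occ_a = (frame_occupancy(acc[0], acc[1], n, dt) > 0
                         if acc is not None else np.zeros(n, bool))
                centers = np.full(n, cfg.efret_occm_center)
                if loc.mo_time is not None:
                    centers[mid >= loc.mo_time] = cfg.efret_mo_center
                e = np.where(occ_a, centers, 0.0)
                if cfg.efret_sd > 0:
                    e = np.clip(e + np.where(occ_a & occ_d,
                                             rng.normal(0, cfg.efret_sd, n), 0.0),
                                0.0, 1.0)
                d_em += occ_d * (1.0 - e)
                a_em += occ_d * e
        chans["D_em"] = d_em
        chans["A_em"] = a_em
        chans["A_direct"] = a_direct

        loc_traces: Dict[str, Trace] = {}
        for name, vals in chans.items():
            if cfg.noise_sd > 0:
                vals = vals + rng.normal(0, cfg.noise_sd, n)
            exc = ("green" if name in ("Cdc6", "Cdt1", "ORC", "D_em", "A_em")
                   else "red")
            loc_traces[name] = Trace(loc.location_id, name, vals, dt,
                                     excitation=exc,
                                     meta={"is_dna": loc.is_dna})
        out[loc.location_id] = loc_traces
    return out


# ---------------------------------------------------------------------------
# Synthetic TIRF image stacks
# ---------------------------------------------------------------------------

@dataclass
class Optics:
    """Camera/optics model for synthetic image rendering."""

    shape: Tuple[int, int] = (64, 64)
    psf_sigma: float = 1.2          # px
    unit_flux: float = 400.0        # photons per fluorophore per frame
    dna_ref_flux: float = 1200.0    # DNA stain flux in blue reference frames
    baseline: float = 100.0         # camera offset, counts
    read_noise_sd: float = 2.0
    poisson: bool = True
    n_fiducials: int = 2
    fiducial_flux: float = 3000.0
    n_impurities: int = 3
    impurity_flux: float = 300.0
    drift_per_frame: Tuple[float, float] = (0.0, 0.0)   # (drow, dcol) px/frame
    n_ref_dna: int = 5              # blue-excitation reference frames
    n_ref_impurity: int = 10        # green+red reference frames
    species_channel: dict = field(
        default_factory=lambda: {"Mcm2-7": "red", "Cdc6": "green"})
    margin: float = 8.0             # keep spots this far from the border


@dataclass
class ImageStack:
    """Multi-channel image time series with per-frame excitation labels."""

    frames: np.ndarray              # (T, rows, cols), float counts
    excitation: List[str]           # per-frame label
    times: np.ndarray               # frame times, s
    pixel_size: float = 1.0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.frames < 0):
            raise ValueError("image intensities must be non-negative")
        drift = self.truth.get("drift")
        if drift is not None and len(drift) != len(self.frames):
            raise ValueError("drift trajectory length must equal frame count")

    def select(self, excitation: str) -> np.ndarray:
        idx = [i for i, e in enumerate(self.excitation) if e == excitation]
        return self.frames[idx]


def gaussian_spot(shape: Tuple[int, int], center: Tuple[float, float],
                  sigma: float, flux: float) -> np.ndarray:
    """Pixel-integrated 2-D Gaussian PSF (pixel i covers [i-0.5, i+0.5])."""
    r = np.arange(shape[0])
    c = np.arange(shape[1])
    s = sigma * math.sqrt(2.0)
    fr = 0.5 * (erf((r + 0.5 - center[0]) / s) - erf((r - 0.5 - center[0]) / s))
    fc = 0.5 * (erf((c + 0.5 - center[1]) / s) - erf((c - 0.5 - center[1]) / s))
    return flux * np.outer(fr, fc)


def _draw_positions(rng: np.random.Generator, n: int, shape, margin: float,
                    min_sep: float, existing: List[np.ndarray]) -> np.ndarray:
    pts: List[np.ndarray] = []
    others = [p for arr in existing for p in arr]
    attempts = 0
    while len(pts) < n and attempts < 10000:
        attempts += 1
        p = np.array([rng.uniform(margin, shape[0] - 1 - margin),
                      rng.uniform(margin, shape[1] - 1 - margin)])
        if all(np.hypot(*(p - q)) >= min_sep for q in pts + others):
            pts.append(p)
    if len(pts) < n:
        raise RuntimeError("could not place spots with requested separation")
    return np.array(pts) if pts else np.zeros((0, 2))


def render_image_stack(timeline: EventTimeline, config: Optional[SimConfig] = None,
                       optics: Optional[Optics] = None,
                       positions: Optional[np.ndarray] = None) -> ImageStack:
    """Render a small synthetic TIRF stack from a timeline.

    Layout: ``n_ref_dna`` blue reference frames (DNA stain + fiducials),
    then ``n_ref_impurity`` green+red reference frames (impurities +
    fiducials), then the kinetic series alternating green/red excitation.
    Fiducial beads are broadly fluorescent and appear in every frame; all
    spots drift by ``drift_per_frame`` per kinetic frame.  Ground-truth
    positions and the applied drift are stored in ``truth``.
    """
    cfg = config if config is not None else timeline.config
    opt = optics if optics is not None else Optics()
    shape = opt.shape
    if shape[0] > 128 or shape[1] > 128:
        raise ValueError("requested field too large (<=128x128 supported)")
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(cfg.seed, spawn_key=(2,))))

    dna_locs = timeline.dna_locations
    if positions is None:
        positions = _draw_positions(rng, len(dna_locs), shape, opt.margin, 7.0, [])
    else:
        positions = np.asarray(positions, float)
        if len(positions) != len(dna_locs):
            raise ValueError("positions must match number of DNA locations")
    if len(positions) and (
            positions.min() < 0
            or positions[:, 0].max() > shape[0] - 1
            or positions[:, 1].max() > shape[1] - 1):
        raise ValueError("spot positions outside field")
    fid_pos = _draw_positions(rng, opt.n_fiducials, shape, opt.margin, 10.0,
                              [positions])
    imp_pos = _draw_positions(rng, opt.n_impurities, shape, opt.margin, 7.0,
                              [positions, fid_pos])

    dt_half = cfg.frame_interval / 2.0
    n_kin = 2 * cfg.n_frames_per_color
    excitation = (["blue"] * opt.n_ref_dna + ["greenred"] * opt.n_ref_impurity
                  + ["green" if k % 2 == 0 else "red" for k in range(n_kin)])
    n_ref = opt.n_ref_dna + opt.n_ref_impurity
    times = np.concatenate([np.zeros(n_ref),
                            (np.arange(n_kin) + 0.5) * dt_half])
    drift = np.zeros((len(excitation), 2))
    kin_idx = np.arange(n_kin, dtype=float)
    drift[n_ref:, 0] = kin_idx * opt.drift_per_frame[0]
    drift[n_ref:, 1] = kin_idx * opt.drift_per_frame[1]

    frames = np.full((len(excitation), *shape), opt.baseline, dtype=float)

    def add_spot(f: int, pos: np.ndarray, flux: float) -> None:
        frames[f] += gaussian_spot(shape, tuple(pos + drift[f]), opt.psf_sigma, flux)

    for f, exc in enumerate(excitation):
        for p in fid_pos:
            add_spot(f, p, opt.fiducial_flux)
        if exc == "blue":
            for p in positions:
                add_spot(f, p, opt.dna_ref_flux)
        elif exc == "greenred":
            for p in imp_pos:
                add_spot(f, p, opt.impurity_flux)
        else:  # kinetic frame
            t = times[f]
            for loc, p in zip(dna_locs, positions):
                n_bound = sum(1 for ev in loc.events
                              if opt.species_channel.get(ev.species) == exc
                              and ev.arrival <= t < ev.departure)
                if n_bound:
                    add_spot(f, p, opt.unit_flux * n_bound)

    if opt.poisson:
        frames = rng.poisson(np.maximum(frames, 0)).astype(float)
    if opt.read_noise_sd > 0:
        frames = frames + rng.normal(0, opt.read_noise_sd, frames.shape)
    frames = np.maximum(frames, 0.0)

    truth = {"dna": positions, "fiducial": fid_pos, "impurity": imp_pos,
             "drift": drift, "n_ref": n_ref, "optics": opt}
    return ImageStack(frames=frames, excitation=excitation, times=times,
                      truth=truth)
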
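"""Kinetic Monte-Carlo simulation of the helicase-loading pathway.

Each surface location is an independent realization of the loading
reaction.  Active DNAs recruit a first Mcm2-7--Cdt1 complex with
exponential waiting time (rate ``k_specific``); every location also
receives nonspecific surface binders as a Poisson process
(``k_background``).  A recruited complex then proceeds through ordered
sub-events: Cdc6 release, the Cdt1-release branch point (productive
Cdt1-only release vs. nonproductive simultaneous Cdt1--Mcm2-7 release),
Mcm2-5 gate open/closed dynamics, MO-complex formation, and -- for
MO-positive complexes -- recruitment of a second Cdc6 and second Mcm2-7
(collapsed to a retained terminal state).  Everything extending past the
end of the recording is marked censored.

The ground-truth event log (:class:`EventTimeline`) is the oracle against
which every downstream analysis stage is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, List, Optional

import numpy as np

from .config import SimConfig

__all__ = [
    "BindingEvent",
    "RingSegment",
    "LocationTimeline",
    "EventTimeline",
    "simulate_timeline",
]

SPECIES = ("ORC", "Cdc6", "Cdt1", "Mcm2-7")


@dataclass
class BindingEvent:
    """One protein-DNA (or protein-surface) binding episode."""

    species: str
    arrival: float
    departure: float          # clipped to record end when censored
    censored: bool = False    # departure truncated by end of recording
    specific: bool = True     # False for nonspecific surface binding
    ordinal: int = 1          # 1 = first, 2 = second arrival of the species
    tags: dict = field(default_factory=dict)

    @property
    def dwell(self) -> float:
        return self.departure - self.arrival


@dataclass
class RingSegment:
    """A maximal constant-state stretch of the Mcm2-5 gate trajectory."""

    start: float
    end: float
    state: str  # "open" | "closed"


@dataclass
class LocationTimeline:
    """Ground truth for one surface location."""

    location_id: int
    is_dna: bool
    is_active: bool
    events: List[BindingEvent] = field(default_factory=list)
    ring_segments: List[RingSegment] = field(default_factory=list)
    mo_time: Optional[float] = None        # MO formation time, None if never
    release_class: Optional[str] = None    # "cdt1_only" | "simultaneous"
    salt_stable: bool = False              # second Mcm2-7 retained at record end

    def events_of(self, species: str, specific: Optional[bool] = None):
        out = [e for e in self.events if e.species == species]
        if specific is not None:
            out = [e for e in out if e.specific == specific]
        return out

    def first_arrival(self, species: str = "Mcm2-7",
                      specific: Optional[bool] = None) -> Optional[float]:
        ev = self.events_of(species, specific)
        return min((e.arrival for e in ev), default=None)


@dataclass
class EventTimeline:
    """Simulator output: one :class:`LocationTimeline` per surface location."""

    config: SimConfig
    locations: List[LocationTimeline]

    def __iter__(self) -> Iterator[LocationTimeline]:
        return iter(self.locations)

    def __len__(self) -> int:
        return len(self.locations)

    @property
    def dna_locations(self) -> List[LocationTimeline]:
        return [l for l in self.locations if l.is_dna]

    @property
    def control_locations(self) -> List[LocationTimeline]:
        return [l for l in self.locations if not l.is_dna]


def _exp(rng: np.random.Generator, mean: float) -> float:
    return float(rng.exponential(mean))


def _ring_trajectory(rng: np.random.Generator, start: float, end: float,
                     cfg: SimConfig, mo_time: Optional[float]) -> List[RingSegment]:
    """Two-state open/closed gate trajectory tiling [start, end).

    The closed->open rate drops to ``k_close_open_mo`` once the MO forms;
    by memorylessness the dwell in a closed state straddling ``mo_time``
    is re-drawn at ``mo_time`` with the stabilized rate.
    """
    segs: List[RingSegment] = []
    t = start
    state = "open"
    while t < end:
        if state == "open":
            rate = cfg.k_open_close
            t_next = t + _exp(rng, 1.0 / rate) if rate > 0 else math.inf
        else:
            pre_mo = mo_time is None or t < mo_time
            rate = cfg.k_close_open if pre_mo else cfg.k_close_open_mo
            t_next = t + _exp(rng, 1.0 / rate) if rate > 0 else math.inf
            if pre_mo and mo_time is not None and t_next > mo_time:
                # stabilized from mo_time onward
                rate2 = cfg.k_close_open_mo
                t_next = mo_time + (_exp(rng, 1.0 / rate2) if rate2 > 0 else math.inf)
        seg_end = min(t_next, end)
        segs.append(RingSegment(t, seg_end, state))
        t = t_next
        state = "closed" if state == "open" else "open"
    return segs


def _background_events(rng: np.random.Generator, cfg: SimConfig) -> List[BindingEvent]:
    """Poisson-process nonspecific surface binding over the record."""
    T = cfg.record_length
    events: List[BindingEvent] = []
    if cfg.k_background <= 0:
        return events
    t = _exp(rng, 1.0 / cfg.k_background)
    while t < T:
        dep = t + _exp(rng, cfg.background_dwell_mean)
        censored = dep >= T
        events.append(BindingEvent("Mcm2-7", t, min(dep, T), censored=censored,
                                   specific=False, ordinal=0,
                                   tags={"background": True}))
        t += _exp(rng, 1.0 / cfg.k_background)
    return events


def _clip(ev: BindingEvent, T: float) -> BindingEvent:
    if ev.departure >= T:
        ev.departure = T
        ev.censored = True
    return ev


def _simulate_dna_location(rng: np.random.Generator, cfg: SimConfig,
                           loc_id: int) -> LocationTimeline:
    T = cfg.record_length
    is_active = bool(rng.random() < cfg.active_fraction)
    loc = LocationTimeline(loc_id, is_dna=True, is_active=is_active)

    t_arr = math.inf
    if is_active and cfg.k_specific > 0:
        t_arr = _exp(rng, 1.0 / cfg.k_specific)

    if t_arr < T:
        # ORC occupies the origin throughout the record (unlabeled in most
        # assay configurations; needed as FRET donor in the MO assay).
        loc.events.append(BindingEvent("ORC", 0.0, T, censored=True,
                                       tags={"origin": True}))
        # Cdc6 arrives before Mcm2-7-Cdt1 and departs after OCCM formation.
        cdc6_arr = max(0.0, t_arr - _exp(rng, cfg.cdc6_lead_mean))
        cdc6_dep = t_arr + _exp(rng, cfg.cdc6_dwell_mean)
        loc.events.append(_clip(BindingEvent("Cdc6", cdc6_arr, cdc6_dep), T))

        # Cdt1 arrives in complex with the first Mcm2-7.
        release_t = t_arr + _exp(rng, cfg.cdt1_release_mean)
        productive = bool(rng.random() < cfg.p_productive)
        mo_time: Optional[float] = None
        if productive:
            mo_forms = bool(rng.random() < cfg.p_mo)
            if mo_forms:
                mo_time = release_t + _exp(rng, cfg.mo_delay_mean)
                mcm_dep = release_t + _exp(rng, cfg.postMO_retention_mean)
                if mo_time >= min(mcm_dep, T):
                    mo_time = None  # Mcm2-7 left (or record ended) first
            else:
                mcm_dep = release_t + _exp(rng, cfg.closed_dwell_unstable_mean)
            cls = "cdt1_only"
        else:
            mcm_dep = release_t
            cls = "simultaneous"

        mcm = BindingEvent("Mcm2-7", t_arr, mcm_dep, ordinal=1,
                           tags={"release_class": cls, "mo": mo_time is not None})
        cdt1 = BindingEvent("Cdt1", t_arr, release_t, ordinal=1,
                            tags={"release_class": cls})
        loc.release_class = cls if release_t < T else None
        loc.mo_time = mo_time

        # Second Cdc6 then second Mcm2-7, only from the MO intermediate.
        if mo_time is not None and rng.random() < cfg.p_second_mcm:
            c2_arr = mo_time + _exp(rng, cfg.second_cdc6_delay_mean)
            m2_arr = c2_arr + _exp(rng, cfg.second_mcm_delay_mean)
            if m2_arr < min(mcm.departure, T):
                c2_dep = m2_arr + _exp(rng, cfg.cdc6_dwell_mean)
                loc.events.append(_clip(BindingEvent("Cdc6", c2_arr, c2_dep,
                                                     ordinal=2), T))
                # Loaded pair: both hexamers retained to the record end.
                mcm.departure = T
                mcm.censored = True
                loc.events.append(BindingEvent("Mcm2-7", m2_arr, T, ordinal=2,
                                               censored=True,
                                               tags={"terminal": True}))
                loc.salt_stable = True

        _clip(mcm, T)
        _clip(cdt1, T)
        if cdt1.censored:
            loc.release_class = None  # branch unobservable within the record
        loc.events.extend([mcm, cdt1])
        loc.ring_segments = _ring_trajectory(rng, t_arr, mcm.departure, cfg,
                                             mo_time)

    loc.events.extend(_background_events(rng, cfg))
    loc.events.sort(key=lambda e: e.arrival)
    return loc


def simulate_timeline(config: SimConfig) -> EventTimeline:
    """Simulate ground-truth event timelines for every surface location.

    DNA locations come first (ids ``0 .. n_locations-1``) followed by
    non-DNA control locations.  Each location uses an independent RNG
    substream spawned deterministically from ``config.seed``, so results
    are bit-reproducible and independent of location order.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_locations + config.n_control_locations
    children = root.spawn(n_total)
    locations: List[LocationTimeline] = []
    for i in range(config.n_locations):
        rng = np.random.Generator(np.random.PCG64(children[i]))
        locations.append(_simulate_dna_location(rng, config, i))
    for j in range(config.n_control_locations):
        i = config.n_locations + j
        rng = np.random.Generator(np.random.PCG64(children[i]))
        loc = LocationTimeline(i, is_dna=False, is_active=False)
        loc.events = _background_events(rng, config)
        locations.append(loc)
    return EventTimeline(config=config, locations=locations)
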
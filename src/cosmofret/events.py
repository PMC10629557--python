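"""Per-molecule loading-outcome classification and condition summaries.

Each first Mcm2-7 episode is classified by how its associated Cdt1
resolved (productive Cdt1-only release vs. nonproductive simultaneous
Cdt1--Mcm2-7 release), whether a second Cdc6 and second Mcm2-7 were
recruited (second Mcm2-7 = stoichiometry-2 onset while the first is
still present, long-lived when >15 s), whether the MO complex formed
(E_FRET > 0.5 for two consecutive frames) and whether the Mcm2-5 gate
closed (E_FRET > 0.3 rule).  The MO and ring-closing assays use
different label pairs, so a single record never carries both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .fret import (EfretTrace, MIN_STATE_FRAMES, MO_THRESHOLD, RING_THRESHOLD,
                   call_state)
from .intervals import Interval, LinkedEpisode
from .kinetics import BinomialSummary, SurvivalCurve, binomial_fraction, survival_curve

__all__ = ["ReleaseCall", "classify_release", "SecondEvents",
           "detect_second_events", "PathwayRecord", "build_pathway_record",
           "ConditionSummary", "summarize_condition"]

LONG_LIVED_S = 15.0     # long-lived binding threshold, s


@dataclass
class ReleaseCall:
    klass: str                          # cdt1_only | simultaneous | unresolved
    post_cdt1_dwell: Optional[float]    # Mcm2-7 dwell after Cdt1 release, s
    censored: bool = False              # dwell truncated by record end


def classify_release(cdt1: Interval, mcm: Interval,
                     tolerance_frames: int = 1) -> ReleaseCall:
    """Classify a linked Cdt1/Mcm2-7 episode by its release pathway.

    End times within ``tolerance_frames`` frames of each other count as
    simultaneous; a Cdt1 end earlier than that is a Cdt1-only release
    (with a censored post-Cdt1 dwell when the Mcm2-7 episode reaches the
    record end).  A censored Cdt1 signal, or a Cdt1 end after the Mcm2-7
    end, is unresolved.
    """
    if cdt1.location_id != mcm.location_id:
        raise ValueError("classify_release requires intervals from one location")
    tol = tolerance_frames * mcm.frame_interval + 1e-9
    if cdt1.censored_end:
        return ReleaseCall("unresolved", None)
    diff = mcm.end_time - cdt1.end_time
    if mcm.censored_end and diff > tol:
        return ReleaseCall("cdt1_only", diff, censored=True)
    if abs(diff) <= tol:
        return ReleaseCall("simultaneous", 0.0)
    if diff > tol:
        return ReleaseCall("cdt1_only", diff)
    return ReleaseCall("unresolved", None)


@dataclass
class SecondEvents:
    second_mcm: str = "none"            # none | short | long
    second_mcm_duration: Optional[float] = None
    second_cdc6: bool = False


def detect_second_events(link: LinkedEpisode,
                         long_lived_s: float = LONG_LIVED_S,
                         min_frames: int = 2) -> SecondEvents:
    """Detect second Mcm2-7 and second Cdc6 recruitment on one episode.

    A second Mcm2-7 is a stoichiometry-2 stretch of at least
    ``min_frames`` frames (single-frame doublings are indistinguishable
    from noise) beginning while the first Mcm2-7 persists; multiple
    stretches are counted once using the longest.  A second Cdc6 is a
    new Cdc6 interval starting after the first Cdc6 ends and before the
    first Mcm2-7 episode ends.
    """
    out = SecondEvents()
    runs = [r for r in link.mcm.tags.get("stoich2_frames", [])
            if r[1] - r[0] >= min_frames]
    if runs:
        dt = link.mcm.frame_interval
        longest = max((e - s) for s, e in runs) * dt
        out.second_mcm = "long" if longest > long_lived_s else "short"
        out.second_mcm_duration = float(longest)
    if link.cdc6:
        first = link.cdc6[0]
        for later in link.cdc6[1:]:
            if (later.start_time >= first.end_time
                    and later.start_time < link.mcm.end_time):
                out.second_cdc6 = True
                break
    return out


@dataclass
class PathwayRecord:
    """Classified loading outcome for one first-Mcm2-7 landing."""

    location_id: int
    release: str = "unresolved"
    post_cdt1_dwell: Optional[float] = None
    post_cdt1_censored: bool = False
    second_cdc6: bool = False
    second_mcm: str = "none"
    long_lived_first: bool = False
    mo_positive: Optional[bool] = None      # None: MO assay not run
    ring_closed: Optional[bool] = None      # None: ring assay not run
    salt_stable: Optional[bool] = None
    mcm_duration: float = 0.0
    mcm_censored: bool = False


def build_pathway_record(link: LinkedEpisode,
                         efret: Optional[EfretTrace] = None,
                         assay: Optional[str] = None,
                         tolerance_frames: int = 1,
                         long_lived_s: float = LONG_LIVED_S) -> PathwayRecord:
    """Assemble the full per-molecule outcome record for one episode.

    ``assay`` selects how the FRET trace is scored: ``"ring"`` applies
    the gate-closing rule (>0.3, 2 frames), ``"mo"`` the MO rule (>0.5,
    2 frames).  The two assays use distinct label pairs and are never
    scored on the same record.
    """
    rec = PathwayRecord(link.location_id,
                        mcm_duration=link.mcm.duration,
                        mcm_censored=link.mcm.censored_end)
    rec.long_lived_first = link.mcm.duration > long_lived_s
    if link.cdt1 is not None:
        call = classify_release(link.cdt1, link.mcm, tolerance_frames)
        rec.release = call.klass
        rec.post_cdt1_dwell = call.post_cdt1_dwell
        rec.post_cdt1_censored = call.censored
    sec = detect_second_events(link, long_lived_s)
    rec.second_cdc6 = sec.second_cdc6
    rec.second_mcm = sec.second_mcm
    if efret is not None:
        if assay == "ring":
            rec.ring_closed = bool(call_state(efret, RING_THRESHOLD,
                                              MIN_STATE_FRAMES))
        elif assay == "mo":
            rec.mo_positive = bool(call_state(efret, MO_THRESHOLD,
                                              MIN_STATE_FRAMES))
        else:
            raise ValueError("assay must be 'ring' or 'mo' when efret is given")
    return rec


@dataclass
class ConditionSummary:
    label: str
    n_records: int
    fractions: dict                     # name -> BinomialSummary
    post_cdt1_survival: Optional[SurvivalCurve] = None
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        d = {"condition": self.label, "n_records": self.n_records}
        for name, b in self.fractions.items():
            d[name] = {"k": b.k, "n": b.n, "percent": b.percent,
                       "sem_percent": b.sem_percent}
        if self.post_cdt1_survival is not None:
            d["post_cdt1_median_s"] = self.post_cdt1_survival.median
            d["post_cdt1_median_label"] = self.post_cdt1_survival.median_label
        return d


def _frac(k: int, n: int) -> BinomialSummary:
    return binomial_fraction(k, n) if n > 0 else BinomialSummary(0, 0, 0.0, 0.0)


def summarize_condition(records: Sequence[PathwayRecord],
                        label: str = "") -> ConditionSummary:
    """Per-condition counts and binomial fractions over pathway records.

    Release-pathway fractions use only episodes with a resolved release
    class; FRET fractions use only records from the matching assay.
    Unresolved records are excluded from denominators but counted.
    """
    recs = list(records)
    n = len(recs)
    resolved = [r for r in recs if r.release in ("cdt1_only", "simultaneous")]
    mo_scored = [r for r in recs if r.mo_positive is not None]
    ring_scored = [r for r in recs if r.ring_closed is not None]
    salt_scored = [r for r in recs if r.salt_stable is not None]
    dwellers = [r for r in recs if r.post_cdt1_dwell is not None
                and r.release == "cdt1_only"]

    fr = {
        "long_lived_first": _frac(sum(r.long_lived_first for r in recs), n),
        "long_lived_second": _frac(sum(r.second_mcm == "long" for r in recs), n),
        "second_cdc6": _frac(sum(r.second_cdc6 for r in recs), n),
        "cdt1_only": _frac(sum(r.release == "cdt1_only" for r in resolved),
                           len(resolved)),
        "mo_positive": _frac(sum(bool(r.mo_positive) for r in mo_scored),
                             len(mo_scored)),
        "ring_closed": _frac(sum(bool(r.ring_closed) for r in ring_scored),
                             len(ring_scored)),
        "salt_stable": _frac(sum(bool(r.salt_stable) for r in salt_scored),
                             len(salt_scored)),
        "censored_dwell": _frac(sum(r.post_cdt1_censored for r in dwellers),
                                len(dwellers)),
        "unresolved": _frac(sum(r.release == "unresolved" for r in recs), n),
    }
    surv = None
    if dwellers:
        surv = survival_curve([r.post_cdt1_dwell for r in dwellers],
                              [r.post_cdt1_censored for r in dwellers])
    rows = []
    for name, b in fr.items():
        rows.append({"quantity": name, "k": b.k, "n": b.n,
                     "percent": b.percent, "sem_percent": b.sem_percent})
    table = pd.DataFrame(rows)
    if surv is not None:
        med = surv.median if math.isfinite(surv.median) else np.nan
        table.attrs["post_cdt1_median_s"] = med
    return ConditionSummary(label, n, fr, surv, table)
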
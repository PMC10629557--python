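"""End-to-end orchestration: simulate -> traces -> intervals -> statistics.

``analyze_condition`` runs the complete trace-level analysis for one
reaction condition and returns every intermediate product, so the same
code path serves the library API, the CLI, and the validation suite.
``run_pipeline`` executes one or more conditions into a run directory
with provenance (config, seed, package version) and summary tables;
``write_report`` renders the standard figure panels from those outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SimConfig, phos_orc_config
from .events import ConditionSummary, PathwayRecord, build_pathway_record, \
    summarize_condition
from .fret import EfretTrace, HeatMap, MixtureFit, compute_efret, efret_heatmap, \
    fit_mixture
from .intervals import CallParams, Interval, LinkedEpisode, call_intervals, \
    merge_episodes, normalize_trace, pair_channels
from .io import intervals_to_frame, write_intervals_csv, write_timeline_csv
from .kinetics import FirstBindingFit, empirical_first_binding, \
    first_arrival_times, fit_first_binding, survival_curve
from .render import Trace, TraceSet, render_traces
from .simulate import EventTimeline, simulate_timeline

log = logging.getLogger("cosmofret")

__all__ = ["PipelineConfig", "ConditionResult", "analyze_condition",
           "run_pipeline", "write_report"]

ANALYSIS_CHANNELS = ("Mcm2-7", "Cdc6", "Cdt1")


def _mask_to_intervals(mask: np.ndarray, location_id: int, channel: str,
                       dt: float) -> List[Interval]:
    """Maximal True runs of a boolean frame mask as Interval records."""
    out: List[Interval] = []
    n = len(mask)
    i = 0
    ep = 0
    while i < n:
        if mask[i]:
            j = i + 1
            while j < n and mask[j]:
                j += 1
            out.append(Interval(location_id, channel, i, j, dt,
                                censored_end=(j == n), episode_id=ep))
            ep += 1
            i = j
        else:
            i += 1
    return out


def call_location_intervals(traces: Dict[str, Trace],
                            channels: Sequence[str] = ANALYSIS_CHANNELS,
                            params: Optional[CallParams] = None
                            ) -> Dict[str, List[Interval]]:
    """Normalize and segment the requested channels of one location."""
    out: Dict[str, List[Interval]] = {}
    for ch in channels:
        tr = traces.get(ch)
        if tr is None:
            continue
        try:
            norm = normalize_trace(tr)
        except ValueError:
            continue
        out[ch] = call_intervals(norm, params)
    return out


def occm_links(intervals_by_channel: Dict[str, List[Interval]],
               coarrival_frames: int = 1) -> List[LinkedEpisode]:
    """Mcm2-7 episodes with a co-arriving Cdt1 (OCCM landings).

    An episode counts as an OCCM when a linked Cdt1 interval starts
    within ``coarrival_frames`` frames of the Mcm2-7 arrival -- the
    Mcm2-7--Cdt1 complex arrives as one unit, which separates specific
    landings from nonspecific surface events.
    """
    links = pair_channels(intervals_by_channel)
    out = []
    for ln in links:
        if ln.cdt1 is None:
            continue
        tol = coarrival_frames * ln.mcm.frame_interval + 1e-9
        if abs(ln.cdt1.start_time - ln.mcm.start_time) <= tol:
            out.append(ln)
    return out


def fret_efret_trace(traces: Dict[str, Trace],
                     params: Optional[CallParams] = None) -> Optional[EfretTrace]:
    """E_FRET for one location from D_em / A_em / A_direct channels.

    Valid frames require both the donor-excited pair signal (total
    emission) and the directly excited acceptor; the computation stops
    at a second-Mcm2-7 arrival (stoichiometry-2 onset in A_direct).
    """
    if not all(k in traces for k in ("D_em", "A_em", "A_direct")):
        return None
    d, a, adir = traces["D_em"], traces["A_em"], traces["A_direct"]
    total = Trace(d.location_id, "total", np.asarray(d.values) + np.asarray(a.values),
                  d.frame_interval, t0=d.t0)
    try:
        tot_iv = call_intervals(normalize_trace(total), params)
        adir_iv = call_intervals(normalize_trace(adir), params)
    except ValueError:
        return None
    if not tot_iv or not adir_iv:
        return None
    n = total.n_frames
    both = np.zeros(n, bool)
    tot_mask = np.zeros(n, bool)
    adir_mask = np.zeros(n, bool)
    for iv in merge_episodes(tot_iv):
        tot_mask[iv.start_frame:iv.end_frame] = True
    for iv in merge_episodes(adir_iv):
        adir_mask[iv.start_frame:iv.end_frame] = True
    both = tot_mask & adir_mask
    episodes = _mask_to_intervals(both, d.location_id, "pair", d.frame_interval)
    stop = None
    for iv in adir_iv:
        if iv.stoichiometry == 2:
            stop = iv.start_time if stop is None else min(stop, iv.start_time)
    return compute_efret(d, a, episodes, stop_time=stop)


@dataclass
class ConditionResult:
    label: str
    config: SimConfig
    timeline: EventTimeline
    traces: TraceSet
    intervals: Dict[int, Dict[str, List[Interval]]]
    links: Dict[int, List[LinkedEpisode]]
    records: List[PathwayRecord]
    arrival_fit: Optional[FirstBindingFit]
    efret_traces: Dict[int, EfretTrace]
    mixture: Optional[MixtureFit]
    heatmap: Optional[HeatMap]
    summary: ConditionSummary


def analyze_condition(config: SimConfig, label: str = "condition",
                      tolerance_frames: int = 1,
                      call_params: Optional[CallParams] = None,
                      fit_arrival: bool = True,
                      fit_fret: bool = True,
                      n_boot: int = 200) -> ConditionResult:
    """Simulate one condition and run the full trace-level analysis."""
    log.info("condition %s: simulating %d DNA + %d control locations",
             label, config.n_locations, config.n_control_locations)
    call_params = call_params or CallParams(min_frames=2)
    timeline = simulate_timeline(config)
    traces = render_traces(timeline)

    intervals: Dict[int, Dict[str, List[Interval]]] = {}
    links: Dict[int, List[LinkedEpisode]] = {}
    records: List[PathwayRecord] = []
    efret_traces: Dict[int, EfretTrace] = {}
    for loc in timeline.dna_locations:
        ivs = call_location_intervals(traces[loc.location_id],
                                      params=call_params)
        intervals[loc.location_id] = ivs
        lnk = occm_links(ivs)
        links[loc.location_id] = lnk
        ef = None
        if fit_fret:
            ef = fret_efret_trace(traces[loc.location_id], call_params)
        for ln in lnk:
            ef_aligned = None
            if ef is not None and np.any(ef.valid):
                ef_aligned = ef.aligned(ln.mcm.start_time)
            records.append(build_pathway_record(
                ln, efret=ef_aligned,
                assay=config.fret_assay if ef_aligned is not None else None,
                tolerance_frames=tolerance_frames))
            if ef_aligned is not None and ln is lnk[0]:
                efret_traces[loc.location_id] = ef_aligned

    arrival_fit = None
    if fit_arrival and timeline.control_locations:
        mcm_by_loc = {lid: ivs.get("Mcm2-7", [])
                      for lid, ivs in intervals.items()}
        dna_ids = [l.location_id for l in timeline.dna_locations]
        dna_first = first_arrival_times(mcm_by_loc, dna_ids)
        ctrl_first = []
        for loc in timeline.control_locations:
            ivs = call_location_intervals(traces[loc.location_id],
                                          channels=("Mcm2-7",),
                                          params=call_params)
            firsts = [iv.start_time for iv in ivs.get("Mcm2-7", [])]
            ctrl_first.append(min(firsts) if firsts else np.inf)
        try:
            arrival_fit = fit_first_binding(dna_first, np.asarray(ctrl_first),
                                            config.record_length)
        except ValueError as exc:
            log.warning("arrival fit skipped: %s", exc)

    mixture = None
    heatmap = None
    if fit_fret and efret_traces:
        aligned = list(efret_traces.values())
        samples = np.concatenate([t.valid_samples for t in aligned])
        if len(samples) >= 50:
            try:
                mixture = fit_mixture(samples, n_boot=n_boot, seed=config.seed)
            except ValueError as exc:
                log.warning("mixture fit skipped: %s", exc)
        heatmap = efret_heatmap(aligned, t_max=min(
            150.0, float(max(t.times[t.valid].max() for t in aligned))))

    summary = summarize_condition(records, label)
    return ConditionResult(label, config, timeline, traces, intervals, links,
                           records, arrival_fit, efret_traces, mixture,
                           heatmap, summary)


# ---------------------------------------------------------------------------
# Run directories and reports
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One run = a base simulation config plus per-condition overrides."""

    base: SimConfig = field(default_factory=SimConfig)
    conditions: Dict[str, dict] = field(default_factory=lambda: {
        "unphosORC": {},
        "phosORC": dict(k_specific=0.0020, p_productive=0.15, p_mo=0.0,
                        closed_dwell_unstable_mean=130.0),
    })
    out_dir: str = "cosmofret_run"
    seed: int = 0
    tolerance_frames: int = 1
    fit_fret: bool = True
    fit_arrival: bool = True
    n_boot: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        base = SimConfig.from_dict(d.pop("base", {}))
        return cls(base=base, **d)


def _records_frame(records: Sequence[PathwayRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def run_pipeline(pcfg: PipelineConfig) -> Path:
    """Execute every condition and write tables + provenance to a run dir."""
    out = Path(pcfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = {"base": pcfg.base.to_dict(),
                "conditions": pcfg.conditions, "seed": pcfg.seed,
                "tolerance_frames": pcfg.tolerance_frames}
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    provenance = {"version": __version__, "seed": pcfg.seed,
                  "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest()}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "config.yaml").write_text(cfg_yaml)

    for i, (label, overrides) in enumerate(sorted(pcfg.conditions.items())):
        cfg = pcfg.base.replace(seed=pcfg.seed + 1000 * (i + 1), **overrides)
        res = analyze_condition(cfg, label,
                                tolerance_frames=pcfg.tolerance_frames,
                                fit_arrival=pcfg.fit_arrival,
                                fit_fret=pcfg.fit_fret, n_boot=pcfg.n_boot)
        cdir = out / label
        cdir.mkdir(exist_ok=True)
        write_timeline_csv(res.timeline, cdir / "timeline.csv")
        all_iv = [iv for ivs in res.intervals.values()
                  for lst in ivs.values() for iv in lst]
        write_intervals_csv(all_iv, cdir / "intervals.csv")
        _records_frame(res.records).to_csv(cdir / "records.csv", index=False)
        res.summary.table.to_csv(cdir / "summary.csv", index=False)
        extra = {}
        if res.arrival_fit is not None:
            extra["arrival_fit"] = res.arrival_fit.to_dict()
        if res.mixture is not None:
            extra["mixture_fit"] = res.mixture.to_dict()
        if res.summary.post_cdt1_survival is not None:
            extra["post_cdt1_median_label"] = \
                res.summary.post_cdt1_survival.median_label
        (cdir / "fits.json").write_text(json.dumps(extra, indent=2))
        if res.heatmap is not None:
            np.savetxt(cdir / "heatmap.csv", res.heatmap.density, delimiter=",")
    return out


def write_report(run_dir, conditions_results: Optional[Dict[str, ConditionResult]] = None):
    """Render the standard figure panels for a completed run.

    When the in-memory results are given, figures are drawn from them;
    otherwise only the table-backed bar panel is produced from the run
    directory.  Returns the list of files written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    written: List[Path] = []

    summaries = {}
    for cdir in sorted(run_dir.iterdir()):
        if (cdir / "summary.csv").exists():
            summaries[cdir.name] = pd.read_csv(cdir / "summary.csv")
    if summaries:
        fig, ax = plt.subplots(figsize=(7, 4))
        names = None
        width = 0.8 / max(len(summaries), 1)
        for i, (label, df) in enumerate(summaries.items()):
            names = df["quantity"]
            ax.bar(np.arange(len(df)) + i * width, df["percent"], width,
                   yerr=df["sem_percent"], label=label, capsize=2)
        ax.set_xticks(np.arange(len(names)) + width / 2)
        ax.set_xticklabels(names, rotation=45, ha="right")
        ax.set_ylabel("percent of events (± SEM)")
        ax.legend()
        fig.tight_layout()
        p = run_dir / "summary_fractions.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if conditions_results:
        # cumulative first-binding curves with fits
        fig, ax = plt.subplots(figsize=(6, 4))
        for label, res in conditions_results.items():
            if res.arrival_fit is None:
                continue
            tl = res.timeline
            dna_first = np.array([
                loc.first_arrival("Mcm2-7") or np.inf
                if loc.first_arrival("Mcm2-7") is not None else np.inf
                for loc in tl.dna_locations])
            curve = empirical_first_binding(dna_first, res.config.record_length)
            grid = np.linspace(0, res.config.record_length, 300)
            ax.step(curve.times, curve.fraction, where="post", label=label)
            from .kinetics import first_binding_cdf
            f = res.arrival_fit
            ax.plot(grid, first_binding_cdf(grid, f.k_a, f.A_f, f.k_ns), "--")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("cumulative fraction bound")
        ax.legend()
        fig.tight_layout()
        p = run_dir / "first_binding.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        for label, res in conditions_results.items():
            if res.heatmap is None:
                continue
            hm = res.heatmap
            fig, (ax1, ax2) = plt.subplots(
                2, 1, figsize=(6, 5), sharex=True,
                gridspec_kw={"height_ratios": [3, 1]})
            ax1.imshow(hm.density.T, origin="lower", aspect="auto",
                       extent=[hm.t_grid[0], hm.t_grid[-1],
                               hm.e_grid[0], hm.e_grid[-1]],
                       cmap="viridis")
            ax1.set_ylabel("E_FRET")
            ax1.set_ylim(0, 0.6)
            ax1.set_title(f"{label} (N={hm.n_molecules})")
            ax2.step(hm.t_grid, hm.remaining, where="post")
            ax2.set_xlabel("time after first Mcm2-7 arrival (s)")
            ax2.set_ylabel("remaining")
            fig.tight_layout()
            p = run_dir / f"heatmap_{label}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

        # post-Cdt1 dwell survival curves
        fig, ax = plt.subplots(figsize=(6, 4))
        any_surv = False
        for label, res in conditions_results.items():
            sc = res.summary.post_cdt1_survival
            if sc is None:
                continue
            any_surv = True
            ax.step(sc.times, sc.survival, where="post", label=label)
            ax.fill_between(sc.times, sc.ci_lower, sc.ci_upper, step="post",
                            alpha=0.25)
        if any_surv:
            ax.set_xlabel("Mcm2-7 dwell after Cdt1 release (s)")
            ax.set_ylabel("fraction remaining")
            ax.legend()
            fig.tight_layout()
            p = run_dir / "post_cdt1_survival.png"
            fig.savefig(p, dpi=120)
            written.append(p)
        plt.close(fig)
    return written
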
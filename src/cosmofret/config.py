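"""Simulation and pipeline configuration.

The simulator models helicase loading at surface-tethered origin DNAs as
observed by multi-wavelength single-molecule TIRF: ORC/Cdc6-dependent
recruitment of the first Mcm2-7--Cdt1 complex, Cdc6 release, the two Cdt1
release pathways (Cdt1-only vs. simultaneous Cdt1--Mcm2-7 release), Mcm2-5
gate open/closed dynamics read out by intramolecular FRET, MO-complex
formation, and recruitment of a second Cdc6 and second Mcm2-7.

Defaults correspond to an unphosphorylated-ORC reaction imaged with
alternating green/red excitation (600 frames per color, 2.6 s per
same-color frame, ~26 min records).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = ["SimConfig", "PHOS_ORC_OVERRIDES", "phos_orc_config"]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_rate(name: str, value: float) -> None:
    import math

    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative rate, got {value!r}")


def _check_pos(name: str, value: float) -> None:
    import math

    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a finite positive number, got {value!r}")


@dataclass
class SimConfig:
    """Parameters of the kinetic Monte-Carlo helicase-loading simulator.

    Rates are s^-1, times are seconds, FRET quantities dimensionless.

    Attributes
    ----------
    n_locations:
        Number of DNA-tethered surface locations.
    n_control_locations:
        Number of non-DNA control locations (background binding only).
    active_fraction:
        Fraction A_f of DNAs competent to recruit Mcm2-7 specifically.
    k_specific:
        Apparent first-order rate k_a of first Mcm2-7--Cdt1 arrival at an
        active DNA.
    k_background:
        Rate k_ns of nonspecific Mcm2-7 surface binding per location.
    background_dwell_mean:
        Mean dwell of a nonspecific binding event (exponential).
    cdc6_lead_mean / cdc6_dwell_mean:
        Mean Cdc6 arrival lead before first Mcm2-7 arrival, and mean Cdc6
        dwell after Mcm2-7 arrival (OCCM duration).
    cdt1_release_mean:
        Mean time from Mcm2-7 arrival to first Cdt1 departure.
    p_productive:
        Probability the Cdt1 departure follows the productive Cdt1-only
        pathway (Mcm2-7 retained); otherwise Cdt1 and Mcm2-7 release
        simultaneously.
    p_mo:
        Probability that a productive release is followed by MO-complex
        formation (ORC bound to the Mcm2-7 N-face).
    mo_delay_mean:
        Mean delay from Cdt1 release to MO formation.
    closed_dwell_unstable_mean:
        Mean post-Cdt1 Mcm2-7 retention when no MO forms.
    postMO_retention_mean:
        Mean post-Cdt1 Mcm2-7 retention when the MO forms.
    p_second_mcm:
        Probability that an MO-positive complex recruits a second Cdc6 and
        then a second Mcm2-7 (retained to record end: terminal state).
    second_cdc6_delay_mean / second_mcm_delay_mean:
        Mean waits MO -> second Cdc6 arrival and second Cdc6 -> second
        Mcm2-7 arrival.
    k_open_close / k_close_open:
        Mcm2-5 gate two-state rates before MO formation.
    k_close_open_mo:
        Residual closed->open rate after MO formation (stabilized gate).
    efret_open_center / efret_closed_center:
        Apparent FRET centers of the open and closed gate states.
    efret_mo_center / efret_occm_center:
        Apparent FRET centers of the ORC--Mcm2-7 MO assay (high after MO,
        low in the OCCM).
    efret_sd:
        Frame-to-frame SD of rendered apparent FRET.
    frame_interval:
        Seconds per same-color frame (alternating excitation).
    n_frames_per_color:
        Frames per excitation color; record length is the product with
        ``frame_interval``.
    label_efficiency:
        Per-protein labeling probability, keyed by species name; missing
        species default to 1.
    bleach_rate:
        Per-fluorophore exponential photobleaching rate.
    noise_sd:
        Additive Gaussian intensity noise, in single-fluorophore units.
    fret_assay:
        ``"ring"`` (Mcm2/Mcm5 gate FRET) or ``"mo"`` (Orc6--Mcm3 FRET).
    seed:
        Root RNG seed; per-location substreams are derived from it.
    """

    n_locations: int = 500
    n_control_locations: int = 1000
    active_fraction: float = 0.8
    k_specific: float = 0.0047
    k_background: float = 2.0e-4
    background_dwell_mean: float = 5.0
    cdc6_lead_mean: float = 20.0
    cdc6_dwell_mean: float = 30.0
    cdt1_release_mean: float = 90.0
    p_productive: float = 0.47
    p_mo: float = 0.45
    mo_delay_mean: float = 10.0
    closed_dwell_unstable_mean: float = 100.0
    postMO_retention_mean: float = 584.0
    p_second_mcm: float = 0.75
    second_cdc6_delay_mean: float = 30.0
    second_mcm_delay_mean: float = 60.0
    k_open_close: float = 0.033
    k_close_open: float = 0.04
    k_close_open_mo: float = 0.001
    efret_open_center: float = 0.20
    efret_closed_center: float = 0.37
    efret_mo_center: float = 0.65
    efret_occm_center: float = 0.15
    efret_sd: float = 0.05
    frame_interval: float = 2.6
    n_frames_per_color: int = 600
    label_efficiency: dict = field(default_factory=dict)
    bleach_rate: float = 1.0e-4
    noise_sd: float = 0.15
    fret_assay: str = "ring"
    seed: int = 0

    # -- derived -----------------------------------------------------------
    @property
    def record_length(self) -> float:
        """Total record length in seconds (same-color clock)."""
        return self.n_frames_per_color * self.frame_interval

    def label_p(self, species: str) -> float:
        return float(self.label_efficiency.get(species, 1.0))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("active_fraction", "p_productive", "p_mo", "p_second_mcm"):
            _check_prob(name, getattr(self, name))
        for name in ("k_specific", "k_background", "k_open_close",
                     "k_close_open", "k_close_open_mo", "bleach_rate"):
            _check_rate(name, getattr(self, name))
        for name in ("background_dwell_mean", "cdc6_lead_mean", "cdc6_dwell_mean",
                     "cdt1_release_mean", "mo_delay_mean",
                     "closed_dwell_unstable_mean", "postMO_retention_mean",
                     "second_cdc6_delay_mean", "second_mcm_delay_mean",
                     "frame_interval"):
            _check_pos(name, getattr(self, name))
        for name, p in self.label_efficiency.items():
            _check_prob(f"label_efficiency[{name!r}]", p)
        if self.n_frames_per_color < 1:
            raise ValueError("n_frames_per_color must be >= 1")
        if self.n_locations < 0 or self.n_control_locations < 0:
            raise ValueError("location counts must be non-negative")
        if self.fret_assay not in ("ring", "mo"):
            raise ValueError(f"fret_assay must be 'ring' or 'mo', got {self.fret_assay!r}")
        if self.noise_sd < 0 or self.efret_sd < 0:
            raise ValueError("noise_sd and efret_sd must be non-negative")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


#: Parameter overrides emulating a CDK-phosphorylated-ORC reaction:
#: slower first recruitment, mostly simultaneous Cdt1-Mcm2-7 release,
#: no MO formation, unstable gate closing, short post-Cdt1 retention.
PHOS_ORC_OVERRIDES = dict(
    k_specific=0.0020,
    p_productive=0.15,
    p_mo=0.0,
    closed_dwell_unstable_mean=130.0,
)


def phos_orc_config(base: Optional[SimConfig] = None, **kw) -> SimConfig:
    """A phosphorylated-ORC condition derived from ``base`` (default config)."""
    base = base if base is not None else SimConfig()
    over = dict(PHOS_ORC_OVERRIDES)
    over.update(kw)
    return base.replace(**over)
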
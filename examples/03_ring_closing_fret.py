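"""Mcm2-5 gate FRET: state calling, mixture fit, and kernel heat map.

The doubly labeled Mcm2-7 reports its gate state through apparent FRET
(E_FRET = A_em / (A_em + D_em)): ~0.20 open, ~0.37 closed.  This script
computes per-molecule E_FRET traces (valid only while both fluorophores
are present, first/last episode frames discarded, stopped at a second
Mcm2-7 arrival), scores ring closing with the >0.3 / 2-frame rule, fits
the pooled E_FRET histogram on [0.1, 0.7] with the two-Gaussian mixture,
and builds the time-aligned kernel heat map (bandwidths 2.7 s / 0.005)
whose every time slice integrates to 1.
"""

import warnings

import numpy as np

from cosmofret import SimConfig
from cosmofret.pipeline import analyze_condition

warnings.filterwarnings("ignore", message="no discernible bound level")

cfg = SimConfig(n_locations=200, n_control_locations=0, seed=21)
res = analyze_condition(cfg, "unphosORC", fit_arrival=False, n_boot=200)

rc = res.summary.fractions["ring_closed"]
print(f"ring closing (E_FRET > 0.3 for ≥2 frames): "
      f"{rc.percent:.0f} ± {rc.sem_percent:.0f}% ({rc.k}/{rc.n})")

m = res.mixture
print(f"mixture fit on {m.n_samples} E_FRET frames: "
      f"μ_low = {m.mu_low:.3f} ± {m.se_mu_low:.3f}, "
      f"μ_high = {m.mu_high:.3f} ± {m.se_mu_high:.3f} "
      f"(simulated centers {cfg.efret_open_center} / {cfg.efret_closed_center})")

hm = res.heatmap
areas = np.trapezoid(hm.density, hm.e_grid, axis=1)
print(f"heat map: {hm.n_molecules} molecules, {len(hm.t_grid)} time slices, "
      f"slice normalization max deviation {np.abs(areas-1).max():.1e}")
print(f"remaining fraction at t=0: {hm.remaining[0]:.2f}, "
      f"at t={hm.t_grid[-1]:.0f} s: {hm.remaining[-1]:.2f}")
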
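"""Time-to-first-binding kinetics for the two ORC phosphorylation states.

Simulates surface-tethered DNAs (plus non-DNA control locations) under
unphosphorylated and CDK-phosphorylated ORC conditions, then fits the
two-stage specific+background arrival model

    F(t) = A_f (1 - e^{-(k_a + k_ns) t}) + (1 - A_f)(1 - e^{-k_ns t})

to the first Mcm2-7 arrival time at each location.  The fitted k_a pair
shows the phosphorylation-dependent slowdown of first Mcm2-7-Cdt1
recruitment (OCCM formation); A_f is the fraction of competent DNAs and
k_ns the nonspecific surface-binding rate measured at the controls.
"""

import numpy as np

from cosmofret import SimConfig, fit_first_binding, phos_orc_config, \
    simulate_timeline


def first_arrivals(locations):
    return np.array([loc.first_arrival("Mcm2-7") or np.inf
                     if loc.first_arrival("Mcm2-7") is not None else np.inf
                     for loc in locations])


fits = {}
for label, cfg in [("unphosORC", SimConfig(n_locations=1000, seed=1)),
                   ("phosORC", phos_orc_config(SimConfig(n_locations=1000,
                                                         seed=2)))]:
    tl = simulate_timeline(cfg)
    fit = fit_first_binding(first_arrivals(tl.dna_locations),
                            first_arrivals(tl.control_locations),
                            cfg.record_length)
    fits[label] = fit
    print(f"{label:10s} k_a = {fit.k_a:.4f} ± {fit.se_k_a:.4f} s⁻¹   "
          f"A_f = {fit.A_f:.2f} ± {fit.se_A_f:.2f}   "
          f"k_ns = {fit.k_ns:.1e} s⁻¹   (truth k_a = {cfg.k_specific})")

red = 1 - fits["phosORC"].k_a / fits["unphosORC"].k_a
print(f"\nPhosphorylation reduces the OCCM formation rate by {100*red:.0f}% "
      "(the fitted rates should bracket their generating values within ~2 SE).")
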
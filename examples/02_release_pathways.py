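"""Cdt1-release pathway choice and post-release Mcm2-7 retention.

Runs the trace-level analysis chain (render -> normalize -> hysteresis
interval calling -> channel pairing) on simulated two-color records and
classifies every resolved OCCM episode as productive (Cdt1 releases
first, Mcm2-7 retained) or nonproductive (Cdt1 and Mcm2-7 leave
simultaneously).  Post-Cdt1 Mcm2-7 dwells, censored by the end of the
~26 min recording, are summarized with a Kaplan-Meier median.
"""

import warnings

from cosmofret import SimConfig, phos_orc_config
from cosmofret.pipeline import analyze_condition

# channels with no binding at a given DNA warn during normalization
warnings.filterwarnings("ignore", message="no discernible bound level")

for label, cfg in [
        ("unphosORC", SimConfig(n_locations=300, n_control_locations=0,
                                seed=11)),
        ("phosORC", phos_orc_config(SimConfig(n_locations=300,
                                              n_control_locations=0,
                                              seed=12)))]:
    res = analyze_condition(cfg, label, fit_arrival=False, fit_fret=False)
    b = res.summary.fractions["cdt1_only"]
    c = res.summary.fractions["censored_dwell"]
    print(f"{label}: productive Cdt1-only release "
          f"{b.percent:.0f} ± {b.sem_percent:.0f}% ({b.k}/{b.n}); "
          f"generating branch probability {cfg.p_productive:.2f}")
    surv = res.summary.post_cdt1_survival
    if surv is not None:
        print(f"  post-Cdt1 Mcm2-7 dwell: KM median {surv.median_label}, "
              f"{c.percent:.0f}% of dwells censored by record end")
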
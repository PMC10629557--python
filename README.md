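# cosmofret

Single-molecule colocalization (CoSMoS) and smFRET analysis of eukaryotic
helicase loading, paired with a kinetic Monte-Carlo simulator of the
loading reaction that provides ground truth for every analysis stage.

## The problem

Loading of the Mcm2-7 replicative helicase onto origin DNA is an ordered,
multi-step reaction: ORC and Cdc6 recruit a first Mcm2-7–Cdt1 complex
(the OCCM), Cdc6 and then Cdt1 release, the Mcm2-5 gate closes around
DNA, ORC swings to the Mcm2-7 N-face to form the MO intermediate, and a
second Cdc6 and second Mcm2-7 arrive to complete the double hexamer.
Colocalization single-molecule TIRF microscopy watches these steps as
fluorescence appearing and disappearing at mapped DNA locations, and
intramolecular FRET reports the gate's open/closed state and MO geometry.
Quantifying such data requires a specific toolchain — spot mapping with
fiducial drift correction, intensity-trace extraction, interval calling
with stoichiometry, censored dwell-time statistics, arrival-model fits
against a nonspecific background, and FRET state analysis — and this
package implements that toolchain for anyone analyzing CoSMoS/smFRET
records of ordered assembly reactions, together with a simulator that
makes every stage testable without any experimental data.

## Models and statistics at the core

**Time to first binding.** The first Mcm2-7 arrival time at a DNA
location follows

&nbsp;&nbsp;&nbsp;&nbsp;F(t) = A_f·(1 − e^(−(k_a + k_ns)·t)) + (1 − A_f)·(1 − e^(−k_ns·t)),

with k_a the apparent specific association rate, A_f the active DNA
fraction, and k_ns the nonspecific surface rate. Fitting is two-stage
maximum likelihood with end-of-record censoring: k_ns from ~1,000
non-DNA control locations first, then (k_a, A_f) with k_ns fixed; SEs
from the observed information matrix.

**Censored dwells.** Dwell times truncated by the end of a ~26-min
recording are handled with the Kaplan-Meier estimator (Greenwood 95%
CI); proportions carry binomial SEMs, 100·√(p(1−p)/n).

**Apparent FRET.** E_FRET = A_em/(A_em + D_em) on donor-excited frames,
uncorrected. The Mcm2-5 gate is scored closed when E_FRET > 0.3 for at
least two consecutive valid frames; the MO complex uses the same rule at
0.5. Pooled E_FRET samples on [0.1, 0.7] are fit to the two-component
Gaussian mixture P_low·N(μ_low, σ_low²) + (1−P_low)·N(μ_high, σ_high²)
with 1,000-sample bootstrap SEs, and visualized as time-aligned 2-D
Gaussian kernel histograms (bandwidths 2.7 s and 0.005) normalized per
time slice.

**Simulator.** Each surface location is an independent continuous-time
realization: exponential specific arrival on active DNAs, Poisson
background binding everywhere, ordered sub-events (Cdc6 dwell, the
productive Cdt1-only vs. nonproductive simultaneous release branch, MO
formation, second Cdc6/Mcm2-7), a two-state gate CTMC with MO-dependent
stabilization, photobleaching, incomplete labeling, alternating-
excitation frame rendering, and optional TIRF image stacks with drift
and fiducial beads.

## Worked example

`examples/01_arrival_kinetics.py` simulates 1,000 DNA and 1,000 control
locations for each ORC phosphorylation state and fits the arrival model:

```
unphosORC  k_a = 0.0045 ± 0.0002 s⁻¹   A_f = 0.80 ± 0.01   k_ns = 2.0e-04 s⁻¹   (truth k_a = 0.0047)
phosORC    k_a = 0.0018 ± 0.0001 s⁻¹   A_f = 0.79 ± 0.02   k_ns = 2.1e-04 s⁻¹   (truth k_a = 0.002)

Phosphorylation reduces the OCCM formation rate by 60% ...
```

Each fitted rate brackets its generating value within ~2 SE, and the
fitted pair reproduces the large phosphorylation-dependent slowdown of
first Mcm2-7 recruitment. The other examples cover release-pathway
classification with censored-dwell survival curves
(`02_release_pathways.py`), gate-FRET state calling, mixture fitting and
heat maps (`03_ring_closing_fret.py`), and the image-to-intervals
pipeline with drift correction (`04_image_pipeline.py`). A thin CLI
(`cosmofret simulate|extract|run-all|report`) wraps the same library
calls.

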
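# scrunchfret

Quantitative analysis of transcription-initiation dynamics by the yeast
mitochondrial RNA polymerase (Rpo41) and its initiation factor Mtf1, built
around two kinds of measurement:

* **single-molecule FRET** traces of dual-labeled promoter DNA, which report
  the closed, open and scrunched conformations of the initiation complex and
  their interconversion kinetics;
* **ensemble assays** — fluorescence-anisotropy binding titrations,
  2-aminopurine (2AP) fluorescence melting and NTP-binding titrations, and
  radiometric gel assays of RNA synthesis.

The package is aimed at single-molecule biophysicists who have per-frame
donor/acceptor intensity traces (or want to simulate them) and at enzymologists
fitting titration and kinetics data from initiation assays.  Because no raw
instrument data are redistributed, a first-class synthetic-data module
generates every input from stated ground truth, so the entire pipeline is
testable end to end.

## Models at the core

**FRET correction.** Detected intensities are converted to FRET efficiency
with background and donor-leakage correction,
`E = (I_A − 0.08·I_D)/(I_D + I_A)`, check frames excluded, and pooled as
non-overlapping five-frame window means into density histograms.

**Gaussian mixtures.** Histogram populations are quantified with 1–3
component Gaussian mixtures (maximum-likelihood EM on pooled values, seeded
multi-start).  Any subset of means can be held exactly fixed — used to
resolve a new scrunched peak against the closed/open peaks assigned at an
earlier stalling position.

**Hidden Markov kinetics.** Traces are idealized with a three-state
Gaussian-emission HMM fitted by Baum–Welch over the pooled multi-trace
likelihood.  Per-frame transition probabilities are converted to rate
constants through the matrix logarithm, `K = log(P)/Δt`, giving the
scrunching equilibrium constant
`Keq = k(open→scrunched)/k(scrunched→open)`.

**Ensemble fits.** The quadratic tight-binding isotherm

    r_obs = r_f + (r_b − r_f) · [(K_d+P_t+D_t) − √((K_d+P_t+D_t)² − 4·P_t·D_t)] / (2·D_t)

for sub-nanomolar complex K_d at finite probe concentration; the hyperbola
`F = F0 + ΔF·x/(K_d + x)` for the composite initiating-NTP K_d; the
Michaelis–Menten fit `v = k_cat·S/(K_m + S)` with catalytic efficiency
`k_cat/K_m`; gel-band conversion `RNA (μM) = R/(R+A)·[ATP]` with the
3–7-mer abortive:runoff ratio; 2AP fold change; and single-exponential
bubble-collapse fitting with a no-collapse verdict.

## Worked example

```python
import numpy as np, scrunchfret as sf

phys = sf.PhotophysicsParams(noise_sd=0.0, leakage=0.08)
ts = sf.simulate_trace_set(sf.wt_pos2_model(), phys, 150, 600, seed=1)
fret = [sf.compute_fret(t, leakage=0.08) for t in ts]
fit = sf.fit_hmm(fret, n_states=3, seed=101)
rates = sf.rates_from_hmm(fit, phys.frame_interval)
print(np.round(fit.emission_means, 3), round(rates.keq_scrunch, 2))
```

prints

```
[0.141 0.38  0.56 ] 6.21
```

the recovered state FRET means (truth 0.14/0.38/0.56) and the scrunching
equilibrium constant (truth 6 for the full-length factor): the scrunched
conformation dominates the +2 initiation complex.  The `examples/` directory
has one short script per capability (binding fits, trace simulation, mixture
populations, HMM kinetics, gel quantification); each prints the numbers it
computes and what they mean.  A thin CLI (`scrunchfret simulate|fret|histfit|
hmm|titrate|pipeline`) wraps the same functions for reproducible runs from a
YAML config.

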
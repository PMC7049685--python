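"""Simulate smFRET movies of the +2 initiation complex and correct them.

Builds a trace set from the three-state (closed/open/scrunched) kinetic
model, injects leakage and detection noise, applies QC and leakage/background
correction, and pools the corrected FRET values into a histogram.
"""

import numpy as np

import scrunchfret as sf

model = sf.wt_pos2_model()
print("states:", model.state_names)
print("state FRET means:", model.fret_means)
print("stationary occupancy:", np.round(model.stationary(), 3))

phys = sf.PhotophysicsParams(
    total_intensity=1000.0, noise_sd=20.0, leakage=0.08,
    background_d=30.0, background_a=30.0, n_check_frames=5,
)
ts = sf.simulate_trace_set(model, phys, n_traces=40, n_frames=400, seed=11)

kept, log = sf.select_traces(
    ts, sf.QCConfig(background_d=30.0, background_a=30.0)
)
print(f"QC kept {len(kept)}/{len(ts)} traces")

fret = [
    sf.compute_fret(t, leakage=0.08, background_d=30.0, background_a=30.0)
    for t in kept
]
hist = sf.build_histogram(fret, window=5)
print(f"histogram: {hist.n_points} five-frame window means from {hist.n_traces} traces")
peak = hist.bin_centers[np.argmax(hist.density)]
print(f"dominant FRET bin: {peak:.2f}  (scrunched state sits near 0.56)")
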
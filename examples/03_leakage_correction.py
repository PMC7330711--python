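"""Why orthogonalization: source leakage inflates naive envelope correlation.

Simulates eight INDEPENDENT sources (no planted coupling) observed through
an instantaneous mixing matrix (strength 0.3, nearest neighbor), emulating
the zero-phase-lag signal spread of an MEG inverse solution.  The naive
envelope correlation between mixed neighbors is strongly inflated; the
orthogonalized estimator removes the in-phase component first and stays
near zero on average.
"""

import numpy as np

import envconn as ec

spec = ec.CohortSpec(
    n_hc=2, n_bd=2, n_rois=8, duration_s=660.0, fs=250.0, seed=0,
    coupling=(ec.CouplingSpec(band="alpha", community="LM_L", coupling=0.0),),
    leakage=ec.LeakageSpec(strength=0.3, structure="knn", k=1),
    kappa_sd=0.0,
)
ts = ec.simulate_subject(spec, "HC", 7)

band = ec.DEFAULT_BANDS["alpha"]
banded = ec.bandpass(ts, band)
margin = banded.meta["transient_samples"]
z = ec.analytic(banded)
windows = ec.make_windows(ts.n_samples - margin, ts.fs, offset=margin)

plain = ec.plain_envelope_correlation(z, windows)
orth = ec.connectivity_matrix(z, windows).values

M = ec.mixing_matrix(spec.leakage, spec.n_rois)
neighbors = np.abs(np.triu(M, 1)) > 0
all_pairs = np.triu_indices(spec.n_rois, 1)

print(f"independent sources, mixing strength 0.3, {len(windows)} windows")
print(f"plain AEC, mixed neighbors:        {np.nanmean(plain[neighbors]):+.3f}")
print(f"orthogonalized AEC, neighbors:     {np.nanmean(np.abs(orth[neighbors])):+.3f}")
print(f"orthogonalized AEC, all pairs:     {np.nanmean(np.abs(orth[all_pairs])):+.3f}")
print("\nleakage alone produces strong spurious plain correlation; "
      "orthogonalization suppresses it (a small residual remains on "
      "directly mixed pairs when envelopes are deeply modulated)")
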
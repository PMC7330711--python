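"""Orthogonalized envelope correlation on a planted coupled pair.

Simulates three ROIs where the first two share a strong (kappa = 0.8)
band-limited envelope modulator, then estimates the full connectivity
matrix: band-pass -> analytic signal -> orthogonalize -> envelope ->
windowed Pearson -> median.  The coupled pair should dominate the matrix.
"""

import numpy as np

import envconn as ec

spec = ec.CohortSpec(
    n_hc=2, n_bd=2, n_rois=3, duration_s=300.0, fs=250.0, seed=3,
    coupling=(ec.CouplingSpec(band="alpha", community=None,
                              rois=("roi0", "roi1"), coupling=0.8),),
    kappa_sd=0.0,
)
ts = ec.simulate_subject(spec, "HC", 42)

band = ec.DEFAULT_BANDS["alpha"]
banded = ec.bandpass(ts, band)
margin = banded.meta["transient_samples"]
z = ec.analytic(banded)
windows = ec.make_windows(ts.n_samples - margin, ts.fs, offset=margin)

cm = ec.connectivity_matrix(z, windows, band=band, labels=ts.labels)
print(f"{len(windows)} windows of 30 s (stride 5 s), alpha band (8-12 Hz)")
print(np.round(cm.values, 3))
print(f"\nplanted pair (roi0, roi1): r = {cm.values[0, 1]:.3f}")
print(f"background pairs:          r = {cm.values[0, 2]:.3f}, {cm.values[1, 2]:.3f}")
print("the planted envelope coupling survives orthogonalization; "
      "independent pairs sit near zero")
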
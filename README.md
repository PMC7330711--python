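# envconn

Band-specific resting-state MEG connectomics: orthogonalized
amplitude-envelope correlation between cortical ROIs, proportional graph
thresholding, hemisphere-resolved network-community edge counts, and
group/symptom statistics — together with a synthetic cohort generator that
plants known envelope coupling, source leakage and clinical-score effects so
the whole pipeline can be validated against ground truth.

## Who this is for

Researchers analyzing source-reconstructed MEG/EEG resting-state recordings
who want a tested, reproducible implementation of the standard
envelope-connectome workflow: given ROI time series `x_i(t)` (e.g. 446
cortical labels at 1000 Hz), compare patient and control groups on the
number of strong connections within and between the seven canonical
resting-state networks (FPN, LM, SAL, DAN, DMN, SMN, VN), split by
hemisphere, in each oscillatory band (delta 1–4, theta 4–8, alpha 8–12,
low beta 13–20, high beta 20–30, gamma 30–80 Hz).

## The estimator

Source leakage — the instantaneous, zero-phase-lag mixing introduced by any
MEG inverse operator — inflates naive envelope correlations.  The pipeline
therefore orthogonalizes each analytic signal pair before taking envelopes:

    Y⊥X(t,f) = Im( Y(t,f) · X(t,f)* / |X(t,f)| )
    Env_X(t,f) = |X(t,f)|

where `X = x + i·H[x]` is the band-limited analytic signal.  The
connectivity value for a pair is the Pearson correlation between
`Env[Y⊥X]` and `Env[X]`, averaged over both orthogonalization directions,
computed in overlapping 30-s windows (stride 1/6 window) and aggregated as
the median across windows.  Per band, matrices are binarized by keeping the
top 15% of connections (sweep 5–30%), edges are counted per community
bucket (14 intra + 91 inter + unassigned), and buckets are compared across
groups with pooled-variance t-tests and related to clinical scales
(BDI-II, HAMD-17, ASRM, YMRS) with Spearman correlations within the
patient group.

## Worked example

```python
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
print(round(cm.values[0, 1], 3), round(cm.values[0, 2], 3))
```

prints

```
0.371 0.003
```

the planted pair (sharing 80% of its slow envelope variance) comes out at
r = 0.371 after orthogonalization while an independent pair sits at 0.003.
The scripts in `examples/` walk through each capability the same way:
cohort simulation, connectivity, leakage correction, graph counts, group
statistics, and the end-to-end pipeline (`envconn run-all --config ...`
from the shell).

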
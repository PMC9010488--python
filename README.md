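# crcest

Creatine CEST (CrCEST) MRI analysis of skeletal-muscle oxidative capacity:
a tested Python pipeline from raw saturation-offset images to cohort
statistics, with a synthetic phantom generator so every stage can be
verified by parameter recovery.

## The problem

Chemical exchange saturation transfer (CEST) MRI measures free creatine in
muscle through the exchange of saturated amine protons (at +1.8 ppm from
water) with bulk water. After a short in-scanner plantar-flexion exercise,
free creatine rises abruptly and then declines exponentially as
mitochondrial oxidative phosphorylation (OXPHOS) regenerates
phosphocreatine. Imaging the calf every 24 s around the exercise yields,
for each muscle (lateral gastrocnemius LG, medial gastrocnemius MG,
soleus):

* **resting CrCEST** — mean contrast over the pre-exercise baseline
  frames, an index of free creatine concentration;
* **ΔCrCEST** — the jump at the first post-exercise frame, an index of
  exercise-induced creatine release;
* **τCr** — the time constant of the mono-exponential recovery
  `v(t) = v∞ + A·exp(−t/τCr)`, the index of OXPHOS capacity
  (longer τCr = slower recovery = lower capacity).

The contrast itself is the z-spectrum asymmetry at the creatine offset,

```
MTR_asym(Δω) = 100 · [S(−Δω) − S(+Δω)] / S(−Δω) %,   Δω = 1.8 ppm
```

computed per voxel after two field corrections: the per-voxel water
centre (B0) is estimated from a finely sampled water-reference spectrum
(WASSR) by maximum-symmetry search, each offset side is resampled at the
voxel's true ±1.8 ppm, and the result is divided by a saturation-efficiency
curve of the relative B1 amplitude. Fitted τCr values below one inter-scan
interval (24 s) or above 1000 s are flagged implausible but reported.

At the cohort level, outcomes are analysed with subject-random-intercept
mixed models (fixed effects: age, sex, disease status, muscle with LG as
reference), a likelihood-ratio screen for disease × muscle interactions,
and per-muscle OLS model suites — the design used to compare adults with
Friedreich's ataxia against healthy adults.

Because no scanner data ship with the package, a phantom module simulates
complete sessions from a two-pool Lorentzian z-spectrum model with known
anatomy, smooth polynomial B0/B1 fields and muscle-specific creatine
kinetics; everything downstream is tested by recovering what was injected.

## Worked example

Simulate a noiseless session with realistic field inhomogeneity
(B0 ≤ 0.25 ppm, B1 in 0.8–1.2), run the correction pipeline, and fit the
LG recovery:

```python
from crcest import TissuePhantom, simulate_acquisition, compute_asym_series
from crcest.kinetics import CrRecoveryModel, roi_timeseries
from crcest.protocol import AcquisitionProtocol

protocol = AcquisitionProtocol(matrix=(64, 64), fov_mm=(80.0, 80.0))
phantom = TissuePhantom.default(
    matrix=protocol.matrix, seed=7,
    b0_amplitude_ppm=0.25, b1_range=(0.8, 1.2), noise_sd=0.0,
)
session = simulate_acquisition(phantom, protocol, seed=7)
asym, fields = compute_asym_series(
    session.cest, session.wassr, session.b1_rel_map,
    mask=session.label_map > 0,
)
series = roi_timeseries(asym, session.label_map, "LG")
print(CrRecoveryModel(series, n_baseline=5).fit().summary())
```

```
CrCEST recovery fit — LG
  resting CrCEST :    6.192 %
  ΔCrCEST        :    8.872 %
  τCr            :    138.1 s
  amplitude      :    8.873 %
  asymptote      :    6.191 %
  RSS            :  2.187e-07
  post frames    : 20
  status         : ok
```

The phantom injected resting 6.2 %, Δ 8.9 % and τ 138 s for the LG; the
pipeline recovers them through the full B0/B1 correction chain (the small
residuals are deterministic interpolation error, ≪ the plausibility and
reporting tolerances).

The same flow is available from the shell:

```
crcest simulate session/ --seed 7
crcest process session/ --out results/
crcest cohort results/cohort_rows.csv --out cohort/
```

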
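# cmro2map

Spatially resolved estimation of the cerebral metabolic rate of oxygen
(CMRO2) from two-dimensional maps of oxygen partial pressure (pO2), as
measured around cortical penetrating arterioles with two-photon
phosphorescence-lifetime microscopy.

## The method

At steady state, with negligible axial diffusion, oxygen transport in
cortical tissue reduces to a 2-D Poisson relation between the pO2 field
`P(r)` and the net consumption variable `M(r)`:

    ∇²P(r) = M(r),        M(r) = s(r) / (D·α),

where `s` is the net oxygen consumption rate, `D` the tissue diffusion
coefficient and `α` the oxygen solubility (`M` has units mmHg·μm⁻²).  The
inverse problem is therefore solved directly by the *diffusion operator*:
apply the Laplacian to the measured map,

    M̂_est(x, y) = ∇² P_smooth(x, y),

where `P_smooth` is a 2-D penalized cubic smoothing spline fitted to the
data (smoothing parameter `q ∈ [0, 1)`; `q = 0` interpolates).  Smoothing
is essential — the double derivative is a high-pass filter that amplifies
measurement noise — but it introduces bias, so the choice of smoothing is
a bias/variance trade-off.  The amount of smoothing is parameterized by a
smoothing length `d_q`, the half-maximum radius of the smoother's impulse
response, which obeys the calibrated power law

    d_q = k · (q · d_data)^(1/4),        k ≈ 1.4,

with `d_data` the grid spacing of the data.  The estimator is validated on
synthetic ground truth: the Krogh–Erlang closed-form solution for a single
vessel with uniform consumption, and finite-difference Poisson solves for
multi-vessel or spatially varying consumption fields, plus additive
Gaussian measurement noise.  Monte-Carlo runs quantify bias, SD and RMSE
(per position or for disc-cut spatial averages) as percent of the true
`M`.  Internally the package works in dimensionless form, `P̂ = P/(M*·r*²)`,
`r̂ = r/r*`, with defaults `r* = 141 μm`, `M* = 10⁻³ mmHg·μm⁻²`.

## Worked example

```python
import numpy as np
from cmro2map import (GridSpec, NoiseModel, SmoothingConfig, add_noise,
                      average_M, estimate_M, sample_krogh_erlang_map)
from cmro2map.presets import single_vessel_scenario

scenario = single_vessel_scenario()      # Pves=80 mmHg, Rves=6 um, Rt=200 um
grid = GridSpec.centered(1.0, 0.007)     # 285x285 window, ~1 um sampling
clean = sample_krogh_erlang_map(scenario, grid)
noisy = add_noise(clean, NoiseModel(sigma_P=5e-4, seed=42))

config = SmoothingConfig(d_q=0.04, d_est=0.0035)
est = estimate_M(noisy, config)

r = est.grid.radii()
bulk = est.validity & (r > 0.3) & (r < 0.9)
print(f"median M-hat estimate (0.3 < r < 0.9): {np.median(est.values[bulk]):.4f}")
print(f"90th percentile |error|: {np.percentile(np.abs(est.values[bulk]-1), 90)*100:.1f}%")
avg = average_M(est, scenario.vessels, d_cut=0.3)
print(f"disc-cut average: {avg.value:.4f} over {avg.n_points} nodes")
```

prints

```
median M-hat estimate (0.3 < r < 0.9): 1.0027
90th percentile |error|: 6.7%
disc-cut average: 0.9199 over 298396 nodes
```

The true consumption is `M̂ = 1` everywhere: away from the vessel the
resolved estimate is accurate to a few percent at this noise level
(σ̂_P = 5×10⁻⁴ ≈ 0.01 mmHg), while the single-replicate disc-cut average
still carries the smoothing-induced edge bias (the Monte-Carlo harness in
`cmro2map.evaluation` quantifies exactly this).

The same pipeline is available from the shell:

```sh
cmro2map calibrate --d-data 0.005 --q 5e-4
# d_q = 0.0569994
# k = 1.43346 (rounded: 1.4)
cmro2map simulate --config run.yaml --out sim/
cmro2map add-noise --in sim/pressure.txt --sigma 5e-4 --seed 1
cmro2map estimate --in noisy.txt --d-q 0.04 --out est
cmro2map evaluate --config run.yaml --mode averaged --d-cut 0.2 --d-cut 0.4
```

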
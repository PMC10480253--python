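# omnicliq

Omnipolar electrogram (oEGM) estimation from electrode cliques on
high-density cardiac mapping arrays, with a reliability-assessment
toolbox and a synthetic wavefront generator for validation.

## The problem

Bipolar electrograms depend on the orientation of the electrode pair
relative to the activation wavefront: a bipole perpendicular to the
propagation direction records almost nothing. Omnipolar mapping tries to
remove this orientation dependence by combining two orthogonal bipolar
signals recorded on a small 2×2 *clique* of unipolar electrodes into a
virtual bipole aligned with the wavefront. How that clique is wired
matters: four *triangular* configurations use two adjacent cell edges,
and a *cross* configuration uses the two diagonals (whose midpoints
coincide, removing the inter-bipole delay) followed by a +π/4
counter-clockwise rotation back into the Cartesian frame.

This package implements, for researchers working with multielectrode
array recordings:

- clique enumeration at interelectrode spacings *k*·pitch and the five
  bipole constructions, e.g. for the lower-left triangle
  b_x = u_B2 − u_B1, b_y = u_A1 − u_B1, and for the cross
  b_1 = u_A2 − u_B1, b_2 = u_A1 − u_B2 with
  **b** = R(π/4)·[b_1, b_2]ᵀ;
- the omnipole estimate: θ_o = argmax_θ max([cos θ, −sin θ]·**b**(t)) /
  max|[sin θ, cos θ]·**b**(t)|, and [ô(t); r(t)] = R(θ_o)·**b**(t),
  where r(t) is the orthogonal residual and the propagation direction is
  −θ_o;
- four reliability metrics: **ORR** (omnipole-to-residuum peak ratio,
  higher better), **NLA** (area of the normalised b_x–b_y electric-field
  loop, lower better), **PW** (omnipole pulse width, shorter better) and
  **MD** (RMSE between the peak-normalised omnipole and a reference
  omnipole built from aligned, averaged −du/dt of the clique's
  unipoles);
- a synthetic generator for paced planar (or circular) wavefronts with
  configurable conduction velocity, biphasic unipolar template, pacing
  trains and noise — every electrode sees the same waveform delayed by
  τ(x, y) = (x·cos Ψ_w + y·sin Ψ_w)/v, so ground truth is known exactly.

## Worked example

```python
from omnicliq import (OmnipolarModel, PlanarWaveParams, CliqueConfig,
                      generate_planar_wave, default_grid)

rec = generate_planar_wave(default_grid(),            # 8x16, 1 mm pitch
                           PlanarWaveParams(psi_w_deg=60.0, seed=42))
res = OmnipolarModel(rec, spacings=(1, 2, 3, 4), max_cliques=8).fit()
print(res.wavefront_direction(CliqueConfig.X))
print(res.summary())
```

prints (abridged):

```
{'direction_deg': 63.15, 'circ_std_deg': 1.86, 'n': 24}

1 mm
  metric                t_ll              t_lr              t_ul              t_ur                 x
  ORR         8.681 ±  0.555    2.347 ±  0.153    2.395 ±  0.102    9.044 ±  0.969   22.603 ±  3.092
  NLA         0.274 ±  0.023    0.947 ±  0.079    0.918 ±  0.049    0.261 ±  0.028    0.088 ±  0.018
  PW [ms]     2.589 ±  0.065    2.702 ±  0.065    2.689 ±  0.056    2.584 ±  0.065    2.705 ±  0.058
  MD          0.039 ±  0.034    0.059 ±  0.023    0.050 ±  0.020    0.027 ±  0.018    0.062 ±  0.002
```

The cross clique recovers the simulated 60° wavefront within a few
degrees. At 1 mm spacing one complementary triangle pair (here
t_ll/t_ur, whose bipole centres happen to align with this wavefront)
attains high ORR and a narrow loop, the other pair (t_lr/t_ul) fails —
triangular cliques are orientation-dependent — while the cross clique
matches or beats the better pair without knowing the wavefront
direction. Metrics for all configurations degrade as the interelectrode
spacing grows, because the bipoles stop approximating a local field
gradient.

A command-line interface mirrors the library:

```sh
omnicliq simulate --psi 60 --seed 42 --out rec.csv
omnicliq metrics rec.csv --out metrics.csv
omnicliq aggregate metrics.csv --render
```

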
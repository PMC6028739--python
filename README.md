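# astroquant

Quantitative analysis of astrocyte morphology and activity in brain slices:
a tested, seed-reproducible pipeline covering shearlet-based spatial
entropy–complexity mapping, Sholl morphometry, leaflet volume fraction,
gap-junction dye-coupling decay, x-y-time Ca²⁺ event statistics, and slice
electrophysiology metrics.  Every stage is driven by a synthetic-data
generator with known ground truth, so the whole analysis is testable as a
recovery problem without any raw recordings.

It is written for slice physiologists and image analysts who need the
quantitative half of an astrocyte remodeling study — e.g. comparing control
against epileptic (status epilepticus) tissue — as importable, verifiable
functions rather than one-off scripts.

## Methods at the core

**Spatial entropy and statistical complexity.** A 2D image *I(x, y)* is
decomposed with a cone-adapted discrete shearlet transform into K bands
indexed by scale *j* and shear (orientation) *k*.  Smoothed, band-calibrated
coefficient power defines a per-pixel probability over features,
P_k(x, y) = E_k / Σ_i E_i.  From it,

- normalized entropy  H_s[P] = −Σ P_k log₂P_k / log₂K ∈ [0, 1]
- statistical complexity  C[P] = Q_JS[P, P_e] · H_s[P]

with Q_JS the Jensen–Shannon divergence to the equiprobable distribution
P_e, normalized by its value at a degenerate distribution.  Ordered textures
score low on both, white noise has H_s → 1 but C → 0, and
structured-but-random branching patterns — like astrocyte arbors — maximize C.

**Morphometry.** Z-stacks are diffusion-filtered (Perona–Malik), projected
and adaptively thresholded into a branch mask; the Sholl profile counts
crossings of circles of increasing radius about the soma.  Leaflet volume
fraction along a 45 μm line follows GV = (F − F₀)/(F_max − F₀), with soma
fluorescence as the 100 % reference and background as 0 %.

**Coupling.** Coupled-soma intensity decays with 3D distance as
I(d) = I₀·exp(−d/C_λ); C_λ comes from the semilog linear fit.

**Ca²⁺ events.** After dark-noise subtraction and DFT registration, a
two-pass Savitzky–Golay baseline (60 s, then 100 s with transient exclusion)
yields ΔF/F; supra-threshold pixels are grouped per frame and linked across
frames into x-y-time events carrying S_max (union footprint area), integral
and duration.  Events with integral < 4 μm²·s, S_max < 10 μm² or duration
< 2 s are excluded; sizes and durations follow P(x) ~ x^(−α) with α fitted
on log-binned densities.

**Electrophysiology.** I_K amplitude at 200 ms post-stimulus with
mono-exponential τ_decay; the fifth-stimulus current from the 5 − 4
subtraction; fEPSP amplitude, 20–80 % rising slope and paired-pulse ratio;
Gompertz input–output fit y = a·exp(−exp(−k(x − x_c))) with maximum slope
a·k/e; LTP magnitude as the 47–60 min post-induction over baseline slope
ratio.

## Worked example

```bash
python analysis/02_morphometry.py --seed 1
```

```
primary branches: 6 (planted 6)
enclosing radius: 42 um (planted ray length 40 um)
mean leaflet VF: 3.40% (planted 3.4%)
```

A synthetic astrocyte with six primary processes of 40 μm and a 3.4 %
leaflet haze is masked and profiled: the Sholl count at the first radius
beyond the soma recovers the six primary branches, the enclosing radius
brackets the planted process length (42 vs 40 μm, one 2 μm Sholl step), and
the volume-fraction profile recovers the planted haze level exactly on the
noiseless stack.  The other drivers behave the same way, e.g.
`analysis/03_coupling.py`:

```
planted 33 um, noise 0% -> C_lambda 33.00 um (r2 1.000)
planted 33 um, noise 10% -> C_lambda 33.09 um (r2 0.992)
```

and `analysis/04_ca_events.py`:

```
30 events kept (32 planted); frequency density 5.00 s^-1 mm^-2
alpha(s_max): 2.68 +- 0.02 (planted 2.7)
alpha(duration): 2.75 +- 0.02 (planted 2.75)
```

The same stages are available as a CLI (`astroquant demo --seed 1`,
`astroquant sholl`, `astroquant caevents`, ...) writing CSV/TIFF/JSON
artifacts with the exact configuration hash embedded for provenance.

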
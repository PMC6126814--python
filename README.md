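# hookmotility

Analytics for bacterial swimming motility around flagellar hook-length
phenotypes, built for the question: *how does a structural perturbation of the
flagellum show up in quantitative motility readouts?*  Peritrichous bacteria
such as *Salmonella enterica* swim by rotating a flagellar bundle; the hook —
the flexible universal joint between motor and filament, ~55 nm long in the
wild type — sets how stably that bundle forms.  Perturbing hook length changes
swimming speed, the rate of (pseudo-)tumbles, the persistence of the swimming
direction, and the wobble of the cell body.  This package implements the full
measurement chain for those readouts and a seeded simulator + virtual
microscope to exercise it end to end, so every estimator is validated by
parameter recovery against known ground truth.

It is aimed at quantitative microbiologists and biophysicists who want a
tested, scriptable reference implementation of these standard analyses on
trajectory tables and image stacks.

## What it computes

**Quasi-2D single-cell tracking** (`tracking`): from each trajectory r(t)
sampled at 10 fps it derives speed, heading, angular velocity, and the
(relative, angular) accelerations; classifies frames into *swimming* /
*tumbling* with a two-state Gaussian HMM over (relative acceleration,
|angular acceleration|); estimates the effective diffusion coefficient with
the covariance-based estimator (CVE) on 10-s resampled displacements,
D̂ = ⟨δ²⟩/2Δ + ⟨δₙδₙ₊₁⟩/Δ; and converts it to the directional persistence via
D = ½ v₀² τ.

**Circular run-and-tumble model** (`rtmodel`): near a surface runs curve into
circles of radius s traversed at angular velocity ψ (v = ψs).  Closed forms:
orientational autocorrelation cos(ψt), MSD 2s²[1 − cos(ψt)], the population
average over ψ ~ Exponential(λ) giving λ²/(λ² + t²), and with tumbles at rate
λ_T the ACF e^(−λ_T t)·cos(ψt) — verified in-suite against the Monte-Carlo
ensemble.  `fit_circular_rt` recovers (ψ, λ_T) from an empirical ACF and v
from the first MSD point (ballistic short-time limit).

**Differential dynamic microscopy** (`ddm`): the image structure function
g(q,τ) = A(q)[1 − f(q,τ)] + B(q) from Fourier-differenced movies, with the
swimming intermediate scattering function
f(q,τ) = e^(−Dq²τ)[(1−α) + α·Ws(qv̄τ; Z)], Ws the Schulz-speed-distribution
term with Z = (v̄/σ)² − 1.  Band averages over 0.5 ≤ q ≤ 2 μm⁻¹ give the
population speed v̄, width σ, S = σ/v̄, and the path-straightness ratio
R = v(L1)/v(L2) (L = 2π/q; R = 1 for straight paths, >1 for bent ones).

**Dark-field flicker microscopy** (`dfm`): the body angular velocity Ω from
the lowest-frequency peak (at Ω/2π) of the cell-averaged power spectrum of
per-cell intensity flicker, and the processivity P = v/Ω — distance advanced
per radian of body rotation.

**Phenotype utilities** (`phenotype`): OLS calibration of hook length against
the FliK molecular-ruler length (≈0.2 nm per amino acid over the controlled
range), per-batch normalization of motility-plate halo areas, and reporter
RLU = light · OD(t=0)/OD(t=n).

**Simulator + virtual microscope** (`simulate`, `optics`): seeded generators
for circular run-and-tumble populations (fixed or exponentially distributed
ψ, Schulz speed spread, Poisson tumbles, optional finite-duration tumbles),
bulk 3D swimmers projected to the image plane, Brownian controls, hook-ruler
measurement panels, and rendered phase-like / dark-field movies (Gaussian
PSF, read noise, intensity flicker at the wobble frequency).

## Worked example

```python
import hookmotility as hm

cfg = hm.SimulationConfig(n_cells=1000, duration=50.0, dt=0.1, psi_value=1.2,
                          tumble_rate=0.4, speed_mean=20.0, speed_rel_width=0.0,
                          rot_diffusion=0.0, box_size=1e6, seed=1)
tracks = hm.simulate_circular_rt(cfg).unwrapped()
fit = hm.fit_circular_rt(hm.empirical_acf(tracks, 10.0),
                         hm.empirical_msd(tracks, 10.0))
print(fit.params.psi, fit.params.tumble_rate, fit.params.v, fit.params.s)
```

prints (seed 1)

```
1.205  0.402  19.99  16.59
```

i.e. from 1000 noisy trajectories the model recovers the generative curvature
ψ = 1.2 rad/s, tumble rate 0.4 /s, speed 20 μm/s and circle radius
v/ψ = 16.7 μm to within a few percent.  The numbered scripts under
`analysis/` run the other pipelines the same way; for example
`analysis/04_ddm_straight_swimmers.py` renders a 2000-frame movie of straight
swimmers and prints

```
band-averaged speed v = 24.64 um/s (simulated 25.0)
relative width     S = 0.165 (simulated 0.2)
path straightness  R = 0.992 (straight swimmers: 1)
```

and `analysis/07_hook_sweep.py` assembles the synthetic analogue of a mutant
panel, reporting (v, Ω, P, R, τ) per condition normalized to the
wild-type-like reference.

## Layout

```
src/hookmotility/   library (simulate, optics, tracking, rtmodel, ddm, dfm,
                    phenotype, io, cli)
analysis/           numbered drivers reproducing each analysis on synthetic data
tests/              pytest suite incl. end-to-end recovery checks
scripts/            acceptance script
docs/methods.md     model and estimator details, defaults, limitations
```

A `hookmotility` console script exposes the pipelines as subcommands
(`simulate`, `render`, `track-stats`, `fit-rt`, `ddm`, `dfm`, `hook-sweep`),
each writing a manifest sufficient to re-run bit-identically.
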
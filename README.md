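# ir2d

Analysis toolkit for two-dimensional infrared (2D IR) spectral
diffusion of protein-bound carbonyl probes — built around the problem of
deciding, from linear and waiting-time-resolved 2D IR spectra of a
CO-ligated heme enzyme, whether a sample populates one conformational
state or several, and what each state's energy landscape looks like.

It is aimed at vibrational spectroscopists who want a tested, scriptable
implementation of the standard CO-stretch analysis chain:

* **Kubo-model lineshapes** — the frequency-frequency correlation
  function (FFCF) `C(t) = δ(t)·Γ-term + Δ₁²e^(−t/τ₁) + Δ_s²`, its
  second-cumulant lineshape function `g(t)`, and FFT synthesis of linear
  absorption bands;
* a **forward simulator** of purely absorptive 2D IR spectra
  (third-order rephasing + nonrephasing response, excited-state
  absorption, population relaxation, seeded detector noise) that serves
  as the synthetic data source for every estimator;
* **band decomposition** — second-derivative component detection,
  one/two-Gaussian fits with F-test model selection, diagonal slices and
  band projections of 2D spectra;
* **transition-dipole and population analysis** — linear intensities
  scale as μ², 2D intensities as μ⁴, so comparing the two yields the
  relative dipole strength and converts band areas into state
  populations;
* **vibrational lifetimes** — single-trace, frequency-resolved and
  global two-component fits of the waiting-time decay;
* **center-line-slope (CLS) analysis** — CLS(Tw) approximates the
  normalized inhomogeneous FFCF; co-fitting it with the linear lineshape
  determines the full Kubo parameter set;
* **two-component CLS decomposition** — the core inference: with one
  component's FFCF fixed (the free enzyme's closed state), the hidden
  second component's CLS decay and FFCF are extracted from the mixed
  center line.

`docs/methods.md` documents the model, the estimator design choices and
their measured limitations.

## Worked example

Simulate the effector-bound complex (two bands at 1936.8 and
1931.3 cm⁻¹, populations 25/75, dipole ratio 1.27, lifetimes 16/13 ps),
average five replicate measurements at 1% detector noise, and run the
full analysis:

```
$ ir2d report --fixture pdx --noise 0.01 --seed 7 --replicates 5
sample: pdx   components: 2
   center   fwhm  area%  pop%  T1/ps    Γh    Δ1     τ1    Δs
   1937.2    8.9   34.3  25.3   16.1   1.6   2.0   20.7   2.7
   1931.4    7.9   65.7  74.7   13.1   2.2   2.1   36.6   1.7
dipole ratio |mu_high|/|mu_low|: 1.24
```

Reading the rows: the linear spectrum decomposes into a 35/65 area
split, but because the high-frequency band carries a ~1.3-fold larger
transition dipole, only ~25% of the enzyme population sits in that
(closed) state.  The global lifetime fit separates 16 ps and 13 ps
decays for the two bands, and the two-component center-line
decomposition recovers the hidden low-frequency band's FFCF
(Γ_h ≈ 2.2 cm⁻¹, Δ₁ ≈ 2.1 cm⁻¹, τ₁ ≈ 37 ps, Δ_s ≈ 1.7 cm⁻¹;
injected: 2.2, 2.0, 31.7, 1.8 — the timescale is the least certain
quantity at this noise level) — a
less heterogeneous, more slowly sampled energy landscape than the free
enzyme's (Δ₁ = 3.0, τ₁ = 20.7, Δ_s = 4.1).

The same pipeline is available as a library:

```python
import numpy as np
from ir2d.simulate import reference_model, simulate_replicates, average_series
from ir2d.report import analyze_sample
from ir2d.simulate import FREE_ENZYME_FFCF

model = reference_model("pdx", noise_sd=0.01)
replicates = simulate_replicates(model, 5, seed=7)
series = average_series(replicates)
linear = model.linear_spectrum(np.linspace(1900, 1970, 701))
result = analyze_sample(series, linear, known_ffcf=FREE_ENZYME_FFCF,
                        replicates=replicates)
```

Other CLI commands: `simulate` (write a series + linear spectrum to a
directory of text matrices), `fit-linear`, `lifetimes`, `cls`,
`decompose`.

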
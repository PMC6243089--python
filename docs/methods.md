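# Methods

## The physical model

The package analyzes (and simulates) the carbonyl-stretch band of a
CO-ligated heme protein as a probe of protein conformational dynamics.
The probe's instantaneous frequency fluctuates with the environment; the
frequency-frequency correlation function (FFCF) is modeled in Kubo form
as three contributions:

    C(t)  =  homogeneous (motionally narrowed) term, Lorentzian FWHM Γ_h
           + Δ₁² e^(−t/τ₁)          (substates sampled on τ₁, tens of ps)
           + Δ_s²                   (substates static on the experiment)

All amplitudes are stored in cm⁻¹ and converted to angular frequency
(rad/ps) with 2πc, c = 2.99792458×10⁻² cm/ps, only inside the
second-cumulant lineshape integral

    g(t) = Δ₁²τ₁² (e^(−t/τ₁) + t/τ₁ − 1) + Δ_s² t²/2 + (πcΓ_h) t .

`Γ_h` is interpreted as the **total** homogeneous Lorentzian FWHM —
pure dephasing and lifetime broadening merged — so the linear-spectrum
synthesis applies no separate 1/(2T₁) factor.  This convention reproduces
the reported linear widths (12.9 cm⁻¹ for the free enzyme, 7.6 cm⁻¹ for
the bound complex's low band) from the corresponding FFCF rows; whether
the original fits carried the lifetime term separately cannot be decided
from the published description, so the choice is recorded here as this
package's convention, not an attribution.

Linear spectra are synthesized as Re ∫ e^{i(ω−ω₀)t} e^{−g(t)} dt by FFT
(time step 0.02 ps, extent set by the decay of e^{−g}, cosine
half-apodization over the final 10%, zero-padding ≥4× the sample count;
width errors < 0.02 cm⁻¹).

## The 2D simulator

Purely absorptive 2D IR spectra are built from the standard third-order
rephasing and nonrephasing response functions of a weakly anharmonic
oscillator in the second-cumulant approximation, with
ground-state-bleach/stimulated-emission pathways (+2) at the fundamental
and an excited-state-absorption pathway (−2, harmonic dipole scaling)
red-shifted by the anharmonicity (default 25 cm⁻¹, a typical heme–CO
value; the published work does not state it, and the analysis windows
exclude the shifted band so the choice cannot leak into results).
Components add at the amplitude level — no exchange cross peaks, because
the conformational states interconvert far more slowly than the ~100 ps
experimental window.  A component's 2D amplitude scales as
population·μ⁴·e^(−Tw/T₁); its linear area as population·μ².

Two discretization points matter:

* the time grid (step 0.1 ps) must cover not only the free-induction
  decay, set by the full g(t), but also the **rephasing echo ridge**
  t₁ ≈ t₃, which decays only at the homogeneous rate; the extent is
  therefore at least 3.9 homogeneous lifetimes (capped at 45–60 ps).
  Truncating the ridge suppresses the apparent frequency correlation by
  several percent.
* spectra are evaluated by zero-padded FFT and interpolated onto the
  requested axes (default 64×64 points over 1900–1970 cm⁻¹).

Detector noise is i.i.d. additive Gaussian per spectral point, with a
standard deviation quoted relative to the noiseless Tw = 0.25 ps global
maximum (default 1%).  Because the noise floor is fixed while the signal
decays as e^(−Tw/T₁), the late-waiting-time signal-to-noise ratio
degrades steeply — the dominant practical limitation of the analysis,
exactly as in the laboratory.  Replicate measurements (`simulate_replicates`,
`average_series`) are the standard remedy; the reference analyses average
five replicates, mirroring the triplicate averaging used experimentally.

### Reference parameterizations

`reference_model(name)` returns the published parameter sets: the free
enzyme ("wt", one band at 1939.4 cm⁻¹, Γ*=1.6, Δ₁=3.0, τ₁=20.7, Δ_s=4.1);
the effector-bound complex ("pdx", bands at 1936.8/1931.3 cm⁻¹ with
populations 0.25/0.75); and the proximal mutant ("l358p", 1937.5/1931.2,
populations 0.54/0.46).  High-frequency (closed-state) bands carry
T₁ = 16 ps and a 1.27-fold larger transition dipole; low-frequency bands
carry their own FFCFs and T₁ = 13 ps.  The free enzyme's T₁ is not
reported separately and is set to the high-frequency component's 16 ps.

The closed-state bands are given the free-enzyme FFCF *dynamics* — the
same Γ_h, τ₁ and Δ₁²:Δ_s² split, hence exactly the same normalized CLS
decay — with the inhomogeneous amplitudes rescaled so the linear band
reproduces the reported band-fit widths (8.6 and 10.2 cm⁻¹).  Carrying
the free-enzyme amplitudes verbatim would make those bands 12.9 cm⁻¹
wide, contradict the reported two-Gaussian widths, and suppress the
reported waiting-time blue shift (the 44 ps diagonal maximum would stay
on the low band).  The normalized CLS decay is the quantity that the
"same FFCF" assumption actually pins in the analysis, and it is preserved
exactly.

One internal tension is left as-is: the mutant low band's reported
Gaussian width (8.5 cm⁻¹) is narrower than the ~10.4 cm⁻¹ implied by its
own FFCF row; the generator follows the FFCF row.

## Band decomposition

Component counting uses an extra-sum-of-squares F-test (α = 0.01)
between one- and two-Gaussian fits (flat baseline), with a 5%
minimum-area guard and a resolvedness guard (center separation >
0.25 × mean FWHM).  The resolvedness guard is necessary because the
Kubo bands have Lorentzian wings: two *concentric* Gaussians
(narrow core + broad wings) always beat one Gaussian on noiseless data
at any significance level, without representing a second state.

Second-derivative candidate detection (Gaussian smoothing, default
halfwidth 1 cm⁻¹; noise floor from the robust second difference of the
raw trace) reliably finds the dominant band, but with the reported band
parameters (5.5 cm⁻¹ separation, ~8 cm⁻¹ widths, 35% shoulder) the
composite has analytically only one curvature minimum — the shoulder
never forms its own.  The pipeline therefore seeds two-band fits with a
search over second-center candidates and keeps the best *resolved* fit.

Free two-Gaussian fits of the overlapped linear composite misallocate
area (the wings favor a core/wings split; measured: 0.25/0.75 instead of
the injected 0.35/0.65).  The pipeline instead resolves the centers on
the 2D diagonal slice — where the components are far better separated —
and ties the linear fit's centers to them (±0.3 cm⁻¹), which restores
the fractions to ±0.01.

### 2D band intensities and the dipole ratio

A band's diagonal-slice area is *not* proportional to its 2D volume
(∝ population·μ⁴): the slice area equals volume divided by the band's
antidiagonal effective width, so the more homogeneous band is
under-represented on the diagonal.  2D intensities for the dipole ratio
are therefore measured on the **sheared band projection** — amplitude
integrated over |ω₃ − ω₁| < 12 cm⁻¹ (inside the anharmonic shift) per
pump frequency — whose component areas are volume-faithful.  With linear
areas ∝ pμ² and projection areas ∝ pμ⁴,
ratio = √[(A2D_hi/A2D_lo)/(Alin_hi/Alin_lo)], and populations follow by
dividing the high band's linear area by ratio² and renormalizing.
Diagonal-slice fits are still the right object where slice amplitudes
are what mixes — center-line decomposition weights and frozen shapes.

## Lifetimes

The global two-component lifetime fit models the waiting-time stack as
Σᵢ aᵢ Gᵢ(ω) e^(−Tw/T₁ᵢ) with shapes frozen from the earliest-frame fit
and amplitudes solved by non-negative least squares inside a
Nelder–Mead search over the two shared lifetimes.  It runs on the band
projection, not the raw diagonal slice: slice ridge height also decays
through the loss of diagonal elongation (spectral diffusion), which
biases slice-based lifetimes low (measured: 11–13 ps instead of the
injected 13/16 ps).  The projection conserves band volume under spectral
diffusion, so its decay is purely population relaxation.
Frequency-resolved single-exponential fits of the slice are retained as
the qualitative diagnostic (they reveal the frequency-dependent decay of
a two-lifetime mixture).

## CLS analysis and FFCF determination

Center lines collect, for each probe frequency in a window (default:
band maximum ± 0.6 × FWHM), the pump-frequency position of maximum
amplitude, located by an amplitude-weighted quadratic fit to the
logarithm of the peak top (a linearized Gaussian fit over the contiguous
half-maximum run).  This estimator is smooth in the underlying
amplitudes and noise-robust; simple parabolic refinement leaves
grid-phase artifacts of ~0.01 in the slope on 64-point axes, which alias
into tens of percent of τ₁.  Peak-position uncertainties are propagated
from the frame's detector-noise level (estimated from the signal-free
frame corners) through the weighted slope regression.

The CLS-vs-Tw values are summarized by A·e^(−Tw/τ) + C, and the complete
FFCF is determined by a forward-model co-fit: candidate parameters are
pushed through *the same* simulate → extract → regress pipeline, at the
measurement's grid step and window, and matched to the measured per-Tw
CLS plus the linear FWHM.  Running the identical estimator on both sides
cancels the systematic difference between the CLS and the true
normalized FFCF (the Kwak approximation is applied identically on both
sides); fitting the analytic FFCF shape directly instead leaves τ₁
biased by 15–30% for the ~31 ps rows.  Noiseless 64×64×9 recoveries are
within (1%, 1%, 5%, 1%) for all three published parameter sets.

## Two-component center-line decomposition

For a two-band sample the mixed center line is modeled as the
amplitude-fraction-weighted convex combination of the components'
center lines; given the known (closed-state) component's line — computed
by noiseless forward simulation from the free-enzyme FFCF at the
measured high-band center — the unknown component's line is solved
pointwise.  Operating choices, each measured to matter:

* mixing fractions come from re-fitting **each frame's** diagonal slice
  with frozen shapes (non-negative least squares): slice heights decay
  through spectral diffusion as well as T₁, so propagating e^(−Tw/T₁)
  alone misestimates the late-time fractions;
* points with f_known > 0.9 are dropped (noise amplification is bounded
  at 10×) and slopes are regressed over the low-band window only — the
  crossover region carries the largest convex-combination error;
* frames are lightly smoothed (Gaussian, 0.75 grid steps) before peak
  extraction, identically on data and model sides; propagated position
  errors carry a ×2 inflation for the smoothing-induced correlation.

The unknown band's FFCF is then determined by the same forward-model
co-fit idea taken one level up: candidate low-band FFCFs are inserted
into a two-component mixture (measured centers, projection-derived
volume weights, global-fit lifetimes), simulated, and pushed through the
identical decomposition; the candidate's extracted slopes are matched to
the measured ones, and the candidate's linear band — after being fit by
the same tied two-Gaussian estimator inside the measured composite — is
matched to the measured low-band width (this "estimator matching"
cancels the Gaussian-on-Voigt width bias).  The measured low-band center
and 2D weight float as prior-penalized nuisance parameters (±0.6 cm⁻¹,
±0.12): their residual errors otherwise dominate the model–data mismatch
for the strongly overlapped mutant.  The fit uses a robust (soft-L1)
loss, and the (τ₁, Δ-split) direction — nearly flat over a 44 ps window
at realistic noise — is anchored to the measured exponential-offset
summary of the decay (log-τ prior width 30%, split-logit width 0.75).

Replicate series provide empirical per-Tw slope uncertainties
(replicate-to-replicate scatter; central values from the averaged
series).

## What the tests do and do not show

The synthetic data reproduce Kubo-model spectral diffusion, two-state
superposition with distinct dipoles and lifetimes, and stationary
detector noise.  They do not include pulse-duration/bandwidth effects,
phasing errors, scatter, solvent background, baseline drift, or any
non-Condon or orientational contributions; passing round trips therefore
validate the estimators against the stated model class, not against
every artifact of real interferograms.  Known limitations, measured and
documented above: Gaussian decompositions of Voigt-like bands are biased
unless center-tied; diagonal-slice areas are not volume-faithful;
apparent mixed-band CLS values are window-sensitive near the inter-band
crossover (windows extending across it pick up center-to-center
correlation, which can raise the mixed CLS above the free-enzyme value);
and the hidden-band τ₁/Δ_s separation at 1% noise is near the
information limit of a 44 ps window, hence the summary anchor.

## Problem sizes and defaults

Default axes 64×64 over 1900–1970 cm⁻¹; waiting times
{0.25, 2, 5, 10, 15, 20, 28, 36, 44} ps; noise 1% of the Tw = 0.25 ps
peak; five replicates for noisy analyses; CLS window factor 0.6;
anharmonicity 25 cm⁻¹; projection halfwidth 12 cm⁻¹.  All tolerances and
guards quoted above are package defaults exposed as function arguments.
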
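# Methods

This note documents the models inside `spintirf`, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish about real recordings.

## Scan waveforms and interleaving

The galvo pair is driven with
`x(t) = x₀ + A·sin(2πft)`, `y(t) = y₀ + e·A·cos(2πft + φ)`: y leads x by
90° plus the user phase offset φ, giving a counterclockwise circular scan
as seen from the objective (the handedness is a package convention; it
has no observable consequence in the model). Drive units are normalized
so 1.0 deflects the spot to the objective aperture edge at the back
focal plane; the conversion to millimetres (`r = radius·f·NA`) lives in
the optics module. Waveforms are one-period lookup tables at a
configurable sample rate (default 1 MHz); a sample-rate/frequency ratio
below 100 is rejected as undersampled, and any drive exceeding full
scale after offsets is a clipping error.

Interleave schedules cycle up to three presets frame by frame
(ABCABC…). For every scanning preset the revolutions-per-exposure
`f·T_exp` is rounded to the nearest integer ≥ 1 and the frequency
adjusted (logged at info level), so each frame averages over complete
360° revolutions — at 5 ms exposures the canonical setting is exactly
200 Hz. A request with `f·T_exp < 0.5` cannot be snapped and raises a
schedule error. Stationary-spot presets park the beam at
`(x₀ + A, y₀)` and keep their nominal frequency untouched. Galvo
dynamics (finite bandwidth, phase lag) are not modelled; real
instruments compensate them empirically with the ellipticity/phase
controls that the preset fields expose.

## TIRF optics

Closed forms: `θc = arcsin(n₂/n₁)`; sine condition `r = f·n₁·sin θ`
(valid to `r = f·NA`); penetration depth
`d = λ/(4π√(n₁² sin²θ − n₂²))` for θ > θc. Defaults describe a 60×
NA 1.45 oil objective: n₁ = 1.515, n₂ = 1.33, f = 3 mm, so the TIR
annulus at the BFP is (3.99, 4.35] mm and d ranges from divergent at
the annulus inner edge down to ≈ 67 nm (488 nm) at the aperture edge.

The lateral excitation field is phenomenological, not wave-optical —
there is no optical-path description from which to propagate fields, so
the model captures the *statistics* of the irregularities instead:

* **Envelope** — Gaussian beam profile, σ = 100 µm by default (an
  expanded, collimated beam is nearly flat over the ~50 µm field;
  σ = None gives an exactly flat envelope for analyses that need the
  fringe statistics in isolation).
* **Fringes** — a sum of `n_components` (default 4) cosine gratings
  with random phases and periods (drawn once per speckle seed, around a
  2 µm period) whose orientations track the illumination azimuth plus a
  fixed per-component jitter. Peak modulation depth (contrast) defaults
  to 0.3, chosen so a stationary-spot field shows ≈ ±2–3 σ intensity
  swings of tens of percent between adjacent regions, qualitatively
  matching conventional TIRF.
* **Shadows** — each occluder casts a multiplicative wedge of
  attenuation directly downstream of the illumination azimuth, with
  exponential recovery over 5 µm (configurable). Azimuth 0° propagates
  along +x, so its shadows fall on the +x side.

Every lateral map is mean-normalized to 1, so switching modes never
changes the total expected signal from a uniform film at the coverslip;
the spinning field is the exact elementwise mean over equally spaced
azimuths (this is asserted against a brute-force oracle in the tests).

Axial models: TIRF modes are `exp(−z/d)` with d set by the scan radius;
pseudo-widefield is a uniform slab over the cell thickness (default
5 µm), the minimal model for conical sub-critical excitation of the
bulk; skimming-plane is exponential with a 1 µm effective depth —
the mode is defined geometrically (beam skimming just above the glass)
and no measured axial profile exists, so a single-parameter exponential
intermediate between TIRF and widefield is adopted.

## Synthetic specimens and the EMCCD model

Specimens combine: a fluorophore film at z = 0 (photon rate per pixel
under unit excitation — the resting, near-membrane indicator
fluorescence); a *bulk* term (rate per µm of excited depth) representing
cytosolic indicator, which is what makes widefield resting fluorescence
exceed TIRF resting fluorescence; point beads at known (x, y, z)
rendered into their nearest pixel (no PSF beyond this; PSF convolution
is deliberately out of scope); and puff sites.

A puff rises linearly over 10 ms, decays exponentially with a 100 ms
time constant (events last tens to hundreds of ms), and has a Gaussian
spatial footprint of σ = 0.5 µm. Its amplitude is expressed relative to
the local resting film fluorescence, i.e. it is the peak ΔF/F₀ a mode
with full axial visibility would report. Ca²⁺ diffusion is not
simulated: the widefield-visible signal is the full amplitude and the
TIRF-visible signal is attenuated by `exp(−z/d)` — the minimal model in
which the amplitude ratio carries depth information.

Camera chain, per frame: Poisson photons at
`qe × rate × exposure × laser_power`; electron multiplication as a
gamma distribution with shape = photon count and scale = EM gain
(variance 2·N·g², the √2 excess-noise factor), or an exact `N × g`
mean-gain mode for deterministic tests; Gaussian read noise; black
level; rounding and clipping to unsigned 16 bit (with a saturation
warning). Defaults: 128×128 frames, 0.4 µm pixels, gain 30, read noise
5 counts, black level 100, QE 0.9. Randomness derives from a single
seed forked per frame by frame index, so renders are byte-reproducible
and independent of evaluation order.

Because no photon budgets are published for this kind of recording, the
film scenarios default to ~100 detected photons/pixel/frame — enough
that the ±1 % excitation-stability figure is a meaningful test of the
illumination model rather than being swamped by shot noise (the shot-
noise floor of a 100×100-pixel frame mean is then ≈ 0.14 %, and its
maximum over 600 frames ≈ 0.5 %). The puff scenario uses a brighter
film (~500 photons/pixel/frame, as expected for indicator-loaded cells)
and a bulk term sized so widefield resting fluorescence is ≈ 1.3× the
TIRF value, giving superficial sites a ratio comfortably above 1. Its
TIRF preset uses a scan radius of 0.927 (d ≈ 200 nm), a deliberate
mid-annulus setting that keeps sites down to ~500 nm measurable.

## Processing pipeline

Black subtraction floors at zero. De-interleaving takes stride-k
subsequences (k = 1–3) and verifies the frame tags actually follow a
stride-k pattern. ΔF/F₀ uses `F₀` = per-pixel mean over a user-chosen
range of resting frames; pixels with F₀ below 1 count are NaN-masked
rather than producing unbounded ratios, and the masked count is
recorded in the output metadata (a dim pixel's ratio is undefined, not
zero). ROIs are 0-based half-open rectangles; "3×3 pixel" ROIs are
centered on a site's integer pixel, and linked ROIs across
de-interleaved stacks share identical pixel coordinates by
construction. The adjacent-region uniformity metric is defined here as
the maximum symmetric percent difference `|mᵢ−mⱼ|/(mᵢ+mⱼ)` over
neighbouring tile means (no standard definition exists for "variation
between adjacent regions", so the package fixes one). The
noise-corrected CV subtracts the mean temporal variance over N frames
from the spatial variance of the N-frame average — without this, shot
noise (≈ 14 % per pixel at 100 photons with EM excess noise) would mask
the few-percent residual non-uniformity being measured.

## Event analysis

Event amplitudes are `max(trace in window) − baseline`, with the
baseline the median of the trace outside all event windows (robust to
the events themselves; there is no published prescription, so this rule
is the package's). Event windows are taken as known — from simulation
ground truth or curated intervals; a threshold-crossing detector is
provided as a convenience but is explicitly non-canonical. Events whose
widefield amplitude falls below a noise floor (default ΔF/F₀ = 0.02)
are excluded from ratios and logged. Sites need ≥ 4 events to be
classified; mean ratio > 1.1 → superficial, < 0.9 → deep. Depth
estimation inverts `ratio(z) = k·exp(−z/d)` with k either supplied or
estimated as the ratio of measured resting baselines F0_WF/F0_TIRF;
ratios above k clip to z = 0 with a warning. The max-based amplitude
estimator carries a small positive noise bias, which is why deep sites
(z ≳ 2.5·d) are recovered with a systematic underestimate of a few tens
of nanometres — visible in the depth-recovery tests, which still bound
the RMSE at 50 nm over 0–500 nm.

## What the synthetic data do not show

The generator emulates the *statistics* of irregular illumination, not
its optics: no Fresnel coefficients, polarization, interface intensity
enhancement, aberrations, or wave propagation; no Ca²⁺ diffusion,
buffering or stepwise channel gating; no photobleaching or drift; no
PSF. Passing tests therefore demonstrate that the scan geometry,
averaging logic, noise model and analysis chain are internally correct
and that azimuthal averaging suppresses azimuth-locked structure — they
do not certify quantitative agreement with any particular instrument's
fringe contrast or shadow depth, which are free parameters here.

## Problem sizes

The test suite and acceptance script run at desk scale by choice:
128×128-pixel frames (the fast-EMCCD format), 600-frame stability runs,
200-frame uniformity comparisons, and 6 sites × 20 events depth-recovery
recordings (~5000 frames). These sizes put every stochastic assertion's
noise floor well below its threshold while keeping a full run under a
minute or two.
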
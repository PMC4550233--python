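# spintirf

Simulation and analysis toolkit for **spinning-spot shadowless TIRF
microscopy** — the illumination scheme in which a pair of galvanometer
mirrors, driven by 90°-phase-shifted sine waves, spins the excitation
laser spot around the periphery of the objective back focal plane so
that the interference fringes and shadows that plague conventional
(stationary-spot) through-the-objective TIRF average out within each
camera exposure.

The package is for microscopists and quantitative cell biologists who
want to reason about this acquisition modality without the hardware: it
synthesizes the galvo drive waveforms and frame-interleave schedules,
models the excitation physics, renders realistic synthetic recordings
through an EMCCD noise model, and provides the downstream processing
and event-analysis pipeline used for local Ca²⁺ signal (puff)
measurements.

## The physics and the statistic at the core

Through-the-objective TIRF obeys the sine condition `r = f·n₁·sin θ`: the
radial position *r* of the focused spot at the back focal plane sets the
incidence angle θ of the collimated beam at the coverslip. Beyond the
critical angle `θc = arcsin(n₂/n₁)` only an evanescent field remains,
decaying as `exp(−z/d)` with

```
d = λ / (4π √(n₁² sin²θ − n₂²))
```

(≈ 67 nm at the NA 1.45 aperture edge for 488 nm, n₁ = 1.515, n₂ = 1.33).
Spinning the spot keeps θ fixed while sweeping the illumination azimuth
through 360° per camera frame, so azimuth-dependent irregularities cancel.

For depth analysis, a release event at depth *z* recorded in alternating
TIRF and widefield (WF) frames yields two ΔF/F₀ amplitudes whose ratio
follows the forward model

```
ratio(z) = k · exp(−z/d),      k = F0_WF / F0_TIRF,
```

which the package inverts (`z = d·ln(k/ratio)`) and thresholds
(mean ratio > 1.1 → superficial site, < 0.9 → deep, n ≥ 4 events).

## Worked example

`examples/04_puff_depths.py` simulates six Ca²⁺ puff sites at depths
0–500 nm imaged in alternating 5 ms TIRF/WF frames and runs the full
pipeline:

```
rendered 936 interleaved frames (5 ms each)
TIRF penetration depth d = 200 nm; calibration k = F0_wf/F0_tirf = 1.28
36 events measured

site_id  n_events  mean_ratio       class  depth_nm  true_z_nm
  site0         6        1.30 superficial      0.00       0.00
  site1         6        0.80        deep     94.92     100.00
  site2         6        0.50        deep    186.93     200.00
  site3         6        0.32        deep    274.78     300.00
  site4         6        0.18        deep    394.03     400.00
  site5         6        0.17        deep    408.28     500.00
```

Each site's mean TIRF/WF amplitude ratio decays exponentially with its
true depth; inverting `ratio = k·exp(−z/d)` recovers the depths to a few
tens of nanometres. The other examples cover waveform synthesis and
scheduling (`01`), the BFP-radius → angle → depth mapping (`02`),
field-uniformity and excitation-stability measurements (`03`), and
three-preset two-laser interleaving with TIFF round trips (`05`).

A thin CLI wraps the same library:

```
spintirf simulate --scenario puff_depths --seed 7 --out stack.tif
spintirf process --in stack.tif --deinterleave 2 --baseline 0:100 --out-dir results/
spintirf waveform --preset presets.yaml --out table.csv
spintirf reproduce t2
```

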
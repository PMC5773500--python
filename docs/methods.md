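# Methods

## The measurement model

A confocal line scan samples a fixed line of `n_pixels` positions once
per line period Δt, producing a carpet F(t, r) of photon counts. The
package models the fluorescence as a sum of point emitters moving in the
scan plane, detected through a 2D Gaussian point-spread function of 1/e²
radius w (axial structure is ignored for line scans — the data are
effectively one-dimensionally sampled), with Poisson photon statistics:

    counts(t, p) ~ Poisson( background + lamina(p) +
                            Σ_i  q_i · exp(−2 |x_i(t) − x_p|² / w²) )

where q_i is the per-species brightness (counts per line sampling per
molecule at beam center) split across two detection channels by the
species' channel weights. Trajectories advance once per line with
Gaussian steps of variance 2·D·Δt per axis — the standard line-scan
approximation, valid because the pixel dwell (2 µs) is three orders of
magnitude shorter than the line period.

Default acquisition constants follow the regime the package targets:
41 nm pixels, 2 µs dwell, 1.5 ms line period (32,000 lines ≈ 48 s),
PSF waist 250 nm. The default scanned line is 256 pixels (10.5 µm) and
the simulated field extends 12 µm laterally; both are deliberately large
— see *Finite-box effects* below.

### Boundaries and the nuclear-envelope barrier

Without a barrier the field is periodic in both axes (a uniform
concentration is exactly stationary). A barrier is a vertical plane at a
pixel column: each step that would cross it is transmitted with the
configured crossing probability (Bernoulli per encounter) and mirrored
back otherwise. With a barrier present the x boundaries become
reflecting, because a single barrier on a periodic domain does not
separate the field into two compartments — particles could walk around
through the seam, violating the two-compartment topology the barrier is
meant to create.

The barrier may carry a finite thickness (default 0 for backward
compatibility; the envelope-permeability protocol uses 0.4 µm): the slab
is particle-excluded, reflection happens at the near face, and
transmitted particles emerge beyond the far face. Physically, an NE is a
double membrane plus lamina meshwork rather than a zero-width plane.
Operationally the slab matters for pair-correlation measurements across
the barrier: with a zero-width barrier, particles linger at reflective
contact inside the shared tail of both detection volumes of a straddling
pixel pair, which leaks a few percent of apparent cross-correlation even
when nothing crosses. Note that a transmitted particle skips the slab
width instantaneously, so thick barriers shorten the effective transit
path; the transit-delay protocol therefore uses a thin barrier, where
repeated Bernoulli rejection is the only delay mechanism.

## Correlation estimation

pCF(τ, d) is estimated at integer line lags with means taken over the
same overlapping support as the numerator (t ∈ [0, T−τ)), which removes
the finite-length bias of normalizing by full-series means. All lags are
computed at once by zero-padded (linear) FFT; a brute-force direct-sum
oracle is kept in the package and the FFT path must match it to 1e-10 —
this equivalence is asserted in the test suite and recomputed by the
acceptance script. Zero-mean columns yield a flagged-invalid curve, never
NaNs. The lag grid is quasi-logarithmic (8 points per octave) from one
line period to n_lines/8, matching how pair-correlation carpets are
displayed and bounding variance at long lags.

## FCS fitting

Column ACFs are fitted by least squares to
G(τ) = G₀/((1 + τ/τ_D)·√(1 + τ/(κ²τ_D))) with G₀ and log τ_D free.
Defaults: κ = ∞ (pure 2D decay — appropriate for in-plane line-scan
sampling) and w₀ = 0.25 µm (typical for a 60×/1.2 NA water objective).
Neither value is derivable from correlation data, and D scales as w₀², so
both are explicit configuration, not constants. Initialization is
derivative-free (G₀ from the first three lags, τ_D from the half-decay
lag). When per-point errors from block-split estimates are supplied the
fit is weighted and χ² is calibrated; otherwise χ² uses residual scatter
and the reduced-χ² < 5 gate acts as a shape test. Fits with D outside
[0, 100] µm²/s are invalid and excluded from every aggregate. The
fast/slow split is strict: fast means D > 2 µm²/s, D = 2 exactly is slow.

**Fit window.** After an initial full-grid fit, the fit is repeated on
lags τ ≤ 30·τ_D (two passes). A hyperbolic decay is fully determined
well before 30 dwell times; the discarded tail contains finite-record
artifacts and, in simulations, finite-box re-entry that otherwise biases
τ_D low.

**Finite-box effects.** In a periodic box the slowest concentration mode
decays as exp(−(2π/L)²·D·τ), so the simulated ACF falls below the
infinite-plane model beyond τ ≈ (L/2π)²/D. With the default 10.5 × 12 µm
field and the 30·τ_D window, recovery bias across D ∈ {0.35, 3.5, 11}
µm²/s is below ~10%, well inside the 20% recovery tolerance the
validation suite asserts. Conversely,
*small* closed boxes introduce a negative inter-pixel correlation
baseline (fixed particle number: a particle seen at one pixel is missing
elsewhere), which is why the validation protocols use generous fields
rather than shrinking the domain for speed.

**"File-averaged" analysis** is provided as: average correlation curves
across files, then fit once (`file_averaged_fit`); averaging fitted D
values instead is available by aggregating per-column fits. The
curves-first reading is the default because it is the variance-optimal
order for weak signals.

## Number & brightness

Photon-counting convention: N = ⟨k⟩²/σ², B = σ²/⟨k⟩, so pure shot noise
gives B = 1 exactly — the calibration anchor asserted at λ = 4,
T = 100,000 lines (B and N/⟨k⟩ within 2%). No analog-detector S-factor or
offset is modeled, since such calibrations are instrument-specific;
absolute brightness values from analog acquisitions are therefore not
comparable.

The 30,000-line segmentation sentence that motivates the two schemes
does not parse uniquely; the implemented reading is: *fast* = N&B per
segment of 300 raw lines (up to 100 segments, so variance is dominated
by fast fluctuations), *slow* = 100-line non-overlapping boxcar average
first, then N&B over the averaged series spanning the whole record.
Both knobs are configurable. The schemes behave as intended for
physical reasons worth stating: averaging suppresses any fluctuation
faster than the window (fast species lose brightness under the slow
scheme), while the fast scheme's 0.45 s segments cannot sample
fluctuations slower than a segment (near-immobile bright aggregates are
nearly invisible to it but dominate the slow scheme, whose span is the
full 45 s record).

Rare-event detection on intensity traces is prominence-based local
maxima with a minimum separation — the simplest defensible reading of a
"peak detection" enhancement — and is validated by planted-transit
recovery.

## Zones

The lamina is the Gaussian-fitted center of the dominant peak of the
time-averaged lamin-channel profile; two comparable peaks are refused
(candidates listed) rather than guessed, and a drift check compares the
first and last thirds of the record. The NE zone is the ±11-pixel band
around the lamina — a ~22-pixel band. Zone width is deliberately
parameterized in pixels, the native unit of the labeling; any nm figure
is derived from the recorded pixel size (22 px at 41 nm/px ≈ 0.9 µm)
rather than assumed, because published nm quotes for such bands are not
always consistent with the pixel counts they accompany. Orientation
(which side is cytoplasm) is configured, or inferred as the brighter
particle-channel side and flagged.

## 3D segmentation

Foreground (absolute or Otsu threshold) is split by a watershed seeded
at local maxima of the anisotropy-aware Euclidean distance transform
(minimum seed separation ≈ expected particle radius; ties broken in
raster order, so labeling is deterministic). Objects smaller than
`min_voxels` are dropped. Centroids are intensity-weighted by default.
Distance to the nucleus is the signed Euclidean distance (voxel sizes
respected) from the centroid to the nearest nucleus-mask surface voxel,
negative inside the nucleus. Distance bins are 0.5 µm wide: the source
text literally says "500 µm-wide bins", which exceeds any cell, and is
read as 500 nm; pipeline manifests record this decision. Default voxel
pitch is 55 nm (xy) × 150 nm (z).

## Image pCF

Per-pixel pair correlation at pixel offset d on 2D time series, with the
same overlap-matched estimator, summarized over a lag window (default
[frame period, duration/8]) by the "correlation integral", read as the
sum of pCF over that window (a window mean is available). Directional
handling defaults to the maximum over the four axis-aligned
displacements — a trajectory lights up whichever direction it follows —
with fixed-direction and radial-mean modes available; the radial mean is
preferred for unbiased map-mean statistics because a max over noisy
directions is positively biased under the null. Cross-channel maps use
channel 0 at r against channel 1 at r + d. Overlay colocalization is the
shared fraction |A∩B|/|A∪B| of pixels above half of each map's own
maximum. The NE profile averages amplitudes in bands parallel to the
envelope line and normalizes each profile to its own maximum.

## Validation protocols and problem sizes

`carpetfcs.protocols` holds the canonical in-silico experiments used by
the tests, the analysis drivers and `scripts/acceptance.py`:

* **Diffusion recovery** — single species at 300 particles, brightness
  4, 256 px × 32,000 lines; median fitted D over columns, per seed.
* **Classification** — equal counts of D = 0.35 and 11 µm²/s species
  segregated by an impermeable center barrier (the spatial analogue of
  distinct dynamic zones); fractions of valid columns at the 2 µm²/s
  threshold.
* **Barrier amplitude** — dilute bright fast species (64 particles,
  brightness 30, D = 11 µm²/s, 150 nm waist, d = 12 px, 0.4 µm-thick
  barrier), pairs centered on the barrier in both scan directions,
  amplitude = matched projection onto the same-side transit template
  over [t*/2, 3t*], t* = d²/(4D). The estimator's per-seed noise on the
  cross/same ratio is ~20% regardless of concentration (amplitude SNR
  per unit data is set by the transit shape and total record only), so
  the protocol averages ~100 seeds to push the uncertainty well below
  the 5% bound.
* **Barrier delay** — thin barrier, crossing probability 0.3 vs none,
  at D = 3.5 µm²/s, d = 16 px; smoothed argmax of the seed-averaged
  cross curve within [t*/3, 20t*].
* **Co-transport** — 64×64 two-channel stacks at 200 nm pixels (so
  d = 4 px = 800 nm), 256 frames at 10 ms; cross-pCF map mean
  (radial-mean mode) per co-transport fraction, 10-seed medians.
* **Sphere fields** — isotropic 55 nm voxels; random well-separated
  spheres, an explicitly-touching pair, and a planted volume-vs-distance
  gradient around an ellipsoidal nucleus.

## What the simulator does and does not emulate

It emulates: multi-species free diffusion with drift and immobile
fractions, species brightness and two-channel splitting, co-transported
dual-color particles, semi-permeable and thick barriers, a static lamina
stripe, Gaussian-PSF sampling, Poisson shot noise, and uniform
background. It does not emulate: photophysics (blinking, bleaching —
though a detrending guard exists on the analysis side), anomalous or
motor-driven transport, axial optical sectioning, detector afterpulsing
or analog gain, interleaved two-channel excitation (channels are
simultaneous), or curved nuclear boundaries. Passing tests therefore
demonstrate estimator and pipeline correctness under an ideal-optics,
ideal-detector model of the acquisition — not robustness to every
artifact of real recordings.

## Known limitations

* Physical-unit D is only as good as the configured beam waist (D ∝ w₀²).
* Single-component fitting reports an apparent D for mixtures; multiple
  dynamic populations within one column appear as distribution structure
  across columns, not as multi-component fits.
* The N&B brightness is convention-bound (photon counting); comparisons
  to analog-calibrated values require an external S-factor.
* pCF amplitude statistics near a barrier need heavy seed averaging; the
  per-seed ratio noise floor (~20%) is a property of the estimator, not
  of the implementation.
* The 3D pipeline assumes the nucleus mask is given or obtainable by
  simple thresholding; curved-boundary zone analysis for line scans is
  out of scope.
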
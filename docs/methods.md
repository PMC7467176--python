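# Methods

This note records the models implemented by `eerkit`, the conventions that
were genuinely open and how they were fixed, the numerical choices, and what
the synthetic tests do and do not demonstrate about real detector data.

## The Bernoulli counting model and the size equations

A counted camera frame is treated as a Bernoulli process over physical
pixels: each pixel is hit with probability `p = exposure_rate / frame_rate`
(e⁻ pixel⁻¹ frame⁻¹), independently, with at most one recorded electron per
pixel per frame.  This is an idealisation of real counting hardware, which
collapses coincident arrivals (see *Coincidence loss* below) and whose
point-spread couples neighbouring pixels; neither effect is modelled in the
size equations.

From the Bernoulli model follow the quantities in `eerkit.size_model`:

* entropy `H(p) = −p log₂ p − (1−p) log₂(1−p)` bits/pixel, the lossless
  lower bound;
* optimal frame size `D = N_pixels (H(p) + 2p log₂ u) / 8` bytes, where
  `2 log₂ u` extra bits per electron carry the u × u subpixel position;
* optimal movie size `S_opt = D · N_frames`, `N_frames = E/p` for total
  exposure `E` e⁻/pixel;
* RLE movie size
  `S_RLE = E · N_pixels (b_RLE + 2 log₂ u + b_RLE · s) / 8` bytes.

**Sentinel correction.**  The geometric gap before each electron spends
`⌊gap/m⌋` sentinel words, whose expectation is the geometric tail sum
`s = Σ_k q^{km} = q^m/(1−q^m)` with `q = 1−p` and `m = 2^b_RLE − 1`.  This
closed form ignores frame boundaries (gaps reset at each frame start and a
trailing gap is paid per frame), a sub-0.1% effect for 512² frames at
p ∈ [0.005, 0.05].  The reconstruction is *validated*, not assumed: the test
suite requires the Monte-Carlo encoded payload of simulated movies to agree
with `S_RLE` within 1% in that regime, and to sit at or above `S_opt`.

**Units.**  kB means 1024 bytes and GiB means 2³⁰ bytes everywhere.  The
canonical worked numbers (301 kB and 199 kB per frame at p = 0.0125 on a
4096² sensor; 3.125 GiB/s raw at 400 fps and 4 bits/pixel) are reproduced
only with binary units, so binary units are fixed.

## The RLE dialect

The codec writes, per frame and in row-major scanline order
(`index = py·width + px`, 0-based, half-open bounds):

* for each electron, `⌊gap/m⌋` sentinel words (value `m`, "m empty pixels,
  no electron") followed by one gap word `g = gap mod m < m`, then
  `2 log₂ u` subpixel bits (`sx` in the low half, `sy` in the high half);
* after the last electron, sentinels plus one final closure word covering
  the remaining pixels, making every frame self-delimiting and letting the
  decoder verify exact pixel coverage.

Words are packed least-significant-bit first into a little-endian byte
stream; the final partial byte is zero-padded.  Gaps count pixels strictly
*between* electrons, so adjacent electrons use a gap word of 0 — the
alternative (distance including the electron's pixel) cannot represent
adjacency and wastes a count.  These four choices (bit order, subpixel
layout, closure semantics, gap convention) are not derivable from the
published description of the scheme; they are frozen by hand-packed byte
oracles in `tests/test_rle_codec.py`.  Compatibility with vendor Falcon
payloads is explicitly not claimed — the commercial tag/payload layout is
unpublished.

`b_RLE` is exposed as a parameter (default 7, hence m = 127) because the
optimal word length depends on p; only 7 is exercised against published
numbers.

## Container and MRC conventions

The container is BigTIFF with one image directory per camera frame; the
frame payload is a `(1, n_bytes)` uint8 strip and the first directory's
ImageDescription tag holds a JSON header (geometry, u, b_RLE, frame rate,
optional exposure rate/pixel size).  BigTIFF is used unconditionally since
4k sensors at thousands of frames exceed 32-bit offsets.  Unknown header
keys are ignored with a warning (forward compatibility); a declared/actual
frame-count mismatch, a truncated strip, or a payload failing the coverage
check is a format error naming the frame.

MRC output is MRC2014 mode 2 (32-bit float) — gain correction makes pixel
values real, so an integer mode is only offered by the low-level writer for
ungained data.  ISPG = 0 marks image stacks, the machine stamp is
little-endian, and the voxel size is `pixel_size / u_out`.  Because no MRC
library is a dependency, the 1024-byte header is written directly; tests
use `gemmi` as an independent conformance oracle.

Fractionation: an integer request for `n` fractions uses `⌊N/n⌋` frames per
fraction and drops the remainder from the tail (2312 frames at 30 fractions
gives 30 × 77 with 2 dropped); a short final fraction is available behind
`short_tail=True`.  Electrons on gain-0 (defect) pixels contribute weight 0
but stay in the event stream, keeping the file a faithful detector record.

## Rendering

Electrons are delta deposits at the nearest supersampled lattice cell —
no bilinear spreading, matching the shift-compensated-placement approach
that avoids image-interpolation artefacts.  Subpixel k occupies cell k of
its physical pixel and renders at that cell's centre, so with
`u_grid = u` the lattice cell is exactly `(px·u + sx, py·u + sy)`.

A trajectory d(t) means the recorded electron is displaced by +d, so
compensation deposits it at (supersampled position − d·u_grid), rounded
half-up to a cell.  Electrons compensated off the detector are dropped, not
wrapped (wrapping would alias specimen content), and counted in the raster
report.  Integer-pixel shifts therefore translate the supersampled image
exactly; shifts of k/u_grid pixels translate it by exactly k cells.

Fourier cropping retains the centred (Hermitian) box of the DFT and inverse
transforms, taking the real part.  The DC term is carried over unchanged, so
the image **sum** (total counts) is preserved to ~10⁻¹⁶ relative; the
per-pixel mean is not, because pixel area changes.  Dimensions must be even
— odd sizes would introduce a half-pixel centre ambiguity and are rejected
rather than silently shifted.

## Motion

Knots measured from fractions are anchored at fraction *centres*
(`start + (L−1)/2` in frame units): a fraction-averaged shift estimates the
mid-fraction position, so centre anchoring minimises systematic lag.
Spline mode fits an interpolating cubic B-spline (exact at the knots;
reproduces linear motion identically) and continues linearly beyond the
terminal knots with the terminal slope.  Whether measured trajectories
should be interpolated exactly or smoothed is application-dependent, so a
penalized smoothing-spline option (`smoothing=λ`) is exposed; both paths are
tested.  Piecewise-constant mode replicates each fraction's knot over its
frames — the conventional-processing control.

`residual_blur` quantifies the benefit as the RMS deviation between applied
and true per-frame positions, which is the deposited-position error when
electrons are spread uniformly over frames.  For any curved drift the
spline residual is strictly smaller than the piecewise residual; for
constant drift they coincide — the desk-scale, assertable core of the
interpolated-motion experiment.  Image-level resolution gains (Å-scale FSC
improvements) require real particle data and 3D refinement and are outside
what these tests can show.

Exposure weighting applies `w(k, N) = exp(−N/(2 Nc(k)))` with
`Nc(k) = a k^−b + c`; the defaults (a = 0.245, b = 1.665, c = 2.81, Nc in
e⁻/Å², k in 1/Å) are the widely used published critical-exposure
measurements and are configuration, not package constants.  Two
normalisation conventions circulate among movie-processing tools; both are
offered (`none` = plain weighted sum, `sum_sq` = flat noise spectrum) and
neither is asserted as canonical.

## The simulator

Arrivals are Poisson per supersampled cell (rate
`p/u² × specimen intensity`), not Bernoulli per physical pixel: at counting
densities the Bernoulli model is the induced approximation (verified by the
empirical-hit-probability test), and the Poisson choice lets coincidence
loss emerge mechanistically.  With `coincidence=True` all arrivals in one
physical pixel in one frame collapse to a single event at one arrival's
subpixel (chosen proportionally to arrival counts, i.e. a uniformly random
arrival), and the realized loss is checked against `1 − (1−e^−λ)/λ`.  With
`coincidence=False` the generator instead draws at most one electron per
physical pixel directly (probability = the pixel's summed cell intensity,
requiring rate ≤ 1 e⁻/pixel/frame); keeping *all* Poisson arrivals would
violate the one-event-per-pixel invariant that the RLE gap encoding
requires, so a valid-by-construction Bernoulli draw is the coherent
"no-loss" mode and its expected count is exactly rate × duration × N_pixels.

Specimen patterns live on the supersampled lattice so sub-physical-pixel
structure exists to be recovered; trajectories displace the pattern, not the
detector (gratings analytically, supplied images by whole-cell roll).
Counting is assumed perfect — no false positives/negatives, no detector
point-spread or charge sharing, no MTF/DQE or CTF modelling, no structural
radiation-damage model.  Passing tests therefore demonstrate the codec,
geometry and statistics of event processing, not detector physics.

## The super-resolution recovery experiment

The desk-scale analogue of the super-resolution imaging result uses a
grating at 0.625 cycles/pixel (1.25 × the physical Nyquist), rendered at
2 × 2 supersampling, with the spectral peak compared against the local
background; the control randomizes subpixels.  The test conditions are
derived analytically rather than tuned:

* The randomized control is **not** featureless at the grating frequency.
  The physical-pixel counts retain an aliased modulation (attenuated by the
  4-point subpixel lattice transform `D₄(f) = ½[cos(πf/4) + cos(3πf/4)]`,
  ≈ 0.49 at f = 0.625), and uniform subpixel spreading re-attenuates by the
  same factor, leaving a replica with ≈ 0.49⁴ ≈ 6% of the true peak power.
* The acceptance thresholds (true ≥ 10 × background, randomized ≤ 2 ×) are
  therefore jointly satisfiable only when the true peak-to-background ratio
  lies in ≈ [10, 17].  With shot-noise background `Ne` per frame and peak
  power `(Ne·c/2)²`, choosing contrast c = 0.8 and ≈ 76 electrons per
  64 × 64 frame targets a ratio of ≈ 13; averaging the power spectrum over
  100 frames reduces its relative scatter to a few percent, keeping both
  inequalities comfortably inside the window for any seed.

The companion corner-information test uses a 45° grating with per-axis
frequency components of 25/64 < 0.5 (total frequency ≈ 1.1 × Nyquist):
it survives physical-pixel rendering because it lives in the Fourier-corner
band, whereas the axis-aligned grating at 0.5625 cycles/pixel has no
in-band bin at all — only its alias — which is the point.

## Problem sizes and numerical choices

Simulations in the test and acceptance suites use 16²–512² sensors,
p ∈ [0.001, 0.1], and ≤ 100-frame movies — sizes chosen so the full suite
completes in well under a minute on one core while keeping Monte-Carlo
standard errors far below the asserted tolerances (counting statistics are
size-driven, so a 512² frame at p = 0.0125 already carries ~3300 electrons).
All randomness flows from explicit `numpy.random.default_rng` seeds; movies,
containers and CLI outputs are bit-reproducible under a fixed seed.
Statistical assertions use 3-standard-error bands; exact assertions
(round-trips, count conservation, byte oracles) use equality.

## Known limitations

* Vendor EER files are not readable: the dialect here is faithful to the
  published scheme but the commercial container layout is unpublished.
* No motion estimation, CTF handling, 2D/3D classification or refinement —
  this toolkit feeds such pipelines, it does not contain them.
* The Python bit-serial decoder favours clarity over throughput
  (~10⁶ words/s); real-time decoding of 4k sensors would need a compiled
  path, which is out of scope.
* The closed-form `S_RLE` ignores frame-boundary sentinel effects; the 1%
  Monte-Carlo agreement band absorbs this.
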
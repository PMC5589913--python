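# Methods

This note documents the models, estimators and design choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the numerical conventions a user should know before
trusting a number.

## Coordinate and unit conventions

Images are 0-based `(row, col)` arrays; the horizontal image axis is
the embryo AP axis, so the DV axis is vertical. Interface angles are
measured counter-clockwise from horizontal and folded to [0, 180);
"within ±15° of the DV axis" therefore means angle ∈ [75°, 105°].
Lengths are reported in µm and areas in µm² (pixel originals are kept
on every record); the default calibration is 0.164 µm/px and 1 s/frame.

## Tissue geometry

A segmented frame is a full label partition (no ridge pixels). Vertices
are detected on the corner grid: any 2×2 pixel block containing ≥ 3
distinct regions (background counts, so border interfaces get
endpoints) is a junction corner; 8-connected corner clusters collapse
to one vertex, so 4-fold junctions remain a single vertex. An
interface is the shared boundary of one cell pair; its *length* is the
Euclidean distance between its two endpoint vertices (not the contour
arc length), and its contour pixels — the pixels of either cell that
touch the other — are retained solely for distance queries in the
association stage. Measured on rendered synthetic lattices, vertex
positions land on the corner grid and chord lengths match the imposed
geometry to well under a pixel.

Segmentation is a seeded watershed on the Gaussian-smoothed membrane
image with h-minima seeds (depth is a parameter; an explicit seed
image overrides). Cells under the minimum area merge into the neighbor
with the longest shared boundary, ties to the lower id. Tracking
assigns each cell the previous-frame identity with maximal pixel
overlap; ties break by centroid displacement, then lower id; a
previous cell claimed twice keeps its best match and the loser gets a
fresh id. Interfaces inherit identity from their cell pair, so a T1
exchange ends one interface id and starts another. Neighbor-number
fractions are computed over non-border cells only and smoothed in time
with a 5 s Gaussian.

## MSD decomposition

`compute_msd` is the time-averaged MSD over all start times; pairs
touching missing (NaN) frames are dropped and the per-lag pair count is
reported. The model

MSD(τ) = A(1 − e^{−ατ}) + 2Bτ + C²τ²

is fitted by bounded least squares (all parameters ≥ 0) with
multi-start over relaxation rates. Two estimator choices matter:

- **Relative residuals.** Time-averaged MSD estimates carry
  multiplicative sampling error, and the raw values grow with τ, so
  unweighted least squares is dominated by the long-lag active term.
  Residuals are therefore scaled by the data (weighted LS with 1/MSD
  weights), which keeps the short-lag region — where A, α and B are
  identifiable — informative.
- **Identifiability bound on α.** The fit requires
  α ≥ 3/τ_max (configurable): the confined term must be ~95% saturated
  within the fitted lag range. A slower exponential never exhibits its
  plateau inside the data and is then mathematically indistinguishable
  from the diffusive term; without the bound, a huge-A/tiny-α solution
  absorbs the diffusive slope of noisy curves (on pure-diffusion input
  the recovered B collapses to zero for roughly half of random seeds).
  With the bound, B on single Brownian trajectories is recovered with
  ~5% median error while fully-saturating confined components are
  unaffected.

Single-trajectory time-averaged MSDs are statistically meaningful only
at lags far below the trajectory length (relative error ~ √(2n/N)), so
whole-trajectory fits default to the first quarter of the computed
curve, and diffusive benchmarks compute the curve only to lag 100 on
N = 10⁴ trajectories.

## Rolling-window step detection

For each frame t and each odd window W ∈ {21, 41, 61, 81} that fits
entirely within the trajectory, the windowed MSD is fitted linearly in
log–log over lags 5 … 3(W−1)/4 — the first four lags are excluded
because localization error produces artifactual subdiffusion there —
and γ(t) is the maximum slope over window sizes. Frames within
(W_min−1)/2 of either end receive γ only from windows that fit (no
padding; edge frames are NaN). Zero MSD values are floored at the
smallest positive float before logging. The computation is fully
vectorized (windowed sums by cumulative sums; one closed-form OLS slope
per window size across all centers), so a 500-frame trajectory costs
about a millisecond.

Steps are contiguous runs of γ > 1 lasting ≥ 14 frames. Displacement
is read from the 5th-order median-filtered trajectory at the run
endpoints (keeping localization noise out of the displacement
estimate); negative displacement means contraction. Because windows
overlap the ramps, detected step durations overestimate the underlying
ramp durations by roughly the window half-width — frequencies, counts
and displacements are unaffected, which is why the cohort metrics are
frequency, duration and *net stepped displacement* rather than raw
interval boundaries.

The synthetic passive regime used for calibration is B = 10⁻⁴ µm²/s
with 0.05 µm localization noise: ~0.1 µm/min RMS passive drift, with
sub-pixel localization error comparable to the passive diffusive
displacement at the fitted lags — the regime the short-lag exclusion
exists for. Under it the per-frame false-positive rate is ≤ 5% while
embedded ≥ 14-frame runs with displacement ≥ 5× noise are recovered at
≥ 99% .

## Oscillation amplitude

Area series are Savitzky–Golay filtered (order 3, window 81 frames;
the window shrinks, with a warning, for shorter series), detrended by
subtracting a σ = 200 s Gaussian filter of the filtered series (the
"local average area", reflected boundaries), and the Hilbert envelope
of the detrended signal, divided by the local average, gives the
instantaneous amplitude in %. The signal is mirror-padded (81 samples)
before the analytic-signal transform to tame edge transients. Per-cell
amplitude averages all frames where the cell exists. Note the
Savitzky–Golay stage attenuates a 120 s period by ~6%, so a 5%
imposed amplitude reads back as ~4.7% — within the design tolerance,
and a property of the published filter settings, not of the envelope
estimator.

## Compartment detection and tracking

Frames are first normalized to zero median and unit robust background
σ (MAD/0.6745): the pixel rule S > E₉ₓ₉ + 0.5·Var₉ₓ₉ compares an
intensity to a variance and is only meaningful at a fixed intensity
scale. The à-trous B3-spline transform ([1,4,6,4,1]/16, dilated,
separable, reflected borders) produces J = 3 detail planes whose sum
plus the residual reconstructs the input exactly. Each plane is
thresholded at k·σᵢ (k = 1) with σᵢ the plane's MAD-based background
σ, the thresholded planes are multiplied into the correlation image P,
and the scalar user threshold — defaulting to Π(3σᵢ), i.e. each plane
must exceed 3σ in a geometric-mean sense — yields S. A pixel is
particle-like iff S > E (global mean) and S > E₉ₓ₉ + 0.5·Var₉ₓ₉
(population variance, reflected borders). Support components of S > 0
containing at least one qualifying pixel become detections; components
holding several intensity maxima ≥ 3 px apart (adjacent spots with
touching supports) are split by watershed on S; components under
2 px — the same floor the colocalization protocol uses for real
puncta — are dropped. Centroids are S-weighted. At SNR 5 with
diffraction-limited spots this operating point measures ≥ 0.99 recall,
≥ 0.96 precision and ~0.4 px RMSE.

Frame-to-frame linking minimizes total squared displacement as a
rectangular assignment problem with birth/death dummy costs equal to
max_link_dist² (default 4 px). Gap closing joins a track end at tₑ to
a track start at tₛ iff tₛ − tₑ ≥ 2 frames, (tₛ − tₑ)·∂t ≤ 3 s and the
stub endpoints are within 4 px; conflicting candidates are resolved by
a globally optimal assignment, iterated to a fixed point. Lifetime is
(t_end − t_start) + 1 frames × ∂t. The finite-movie correction flags
tracks touching the first or last frame as censored and weights each
complete track by 1/(T − L + 1) — the inverse of the number of start
positions at which it could have been observed whole under a
stationary birth process; on exponential-lifetime cohorts with the
movie 5× the mean, the weighted mean is within ~6% of truth (the
residual being discretization plus the untruncatable L > T tail).

## Association analytics

A compartment centroid is associated with an interface iff (i) it is
within 10 px of the interface contour, (ii) strictly closer to it than
to any other interface (ties within 10⁻⁹ px go to APICAL, preserving
uniqueness), and (iii) at least min(1 px, 0.1·length) from the nearer
endpoint vertex. Distances use contour pixels for rule (i)–(ii) and
vertex positions for rule (iii). Track-level association takes the
per-frame majority vote, ties to the earliest associated frame; the
side of the interface (for monopolarity scoring) is the cell label
containing, or nearest to, the centroid, majority-voted over frames.

Interfaces are classified from the circular mean of their orientation
over the first 90 s: AP within ±15° of the DV axis, else transverse.
Density profiles count associated compartments per 15° angle bin
divided by interfaces per bin, per frame and time-averaged; bins
without interfaces are missing, not zero; summary fractions report
compartments on interfaces within 30° of vertical/horizontal. An event
is *paired* iff a compartment exists on the opposite side of the same
interface with ≥ 1 frame of temporal overlap, and *multiple* iff any
other compartment coexists on the interface. Fixed colocalization
keeps 2–15 px puncta, grids the field at 5 µm, and calls an A-punctum
colocalized when its overlap with the B mask exceeds 2×2 px; live
association requires footprint overlap > 1 px sustained for strictly
longer than 1 s, and reports onset as a fraction of the track's
lifetime.

## Synthetic data: what it emulates, what it does not

The tissue generator builds a running-bond ("brick") lattice: vertical
joints are the AP interfaces, each with its own prescribed length
series (progressive negative steps in `control`, sign-alternating
steps in `ratchet_off`, a global radial contraction over 6.6 min in
`furrow`); the near-horizontal zigzag segments between rows are the
transverse interfaces. The dynamics are kinematic — lengths are
prescribed and the polygon configuration follows — not a mechanical
vertex model. Per-cell areas oscillate through joint-length modulation
with random phases; because vertices are shared, exactly prescribed
independent per-cell amplitudes are geometrically impossible in a
tiling, so truth area series are the realized polygon areas (shoelace,
exact), and a separate area-series generator supplies
prescribed-amplitude sinusoids for oscillation benchmarks. Rendered
label movies are rasterized per frame with seams filled by nearest
label; membrane movies are blurred boundary masks plus Gaussian noise.

Ratchet cohorts default to 4 steps of 1 µm per interface so the
alternating regime is net-neutral by construction; step durations
(16–26 frames) and pauses (45–80 frames) are drawn identically in both
regimes, making frequency/duration comparisons meaningful.

Spot movies place events on interface contours with quota-sampled
classes — exactly round(p·n) events on vertical interfaces for an
imposed polarity fraction p, with the class held fixed through
placement retries so that class-dependent placement rejection cannot
bias the realized fraction — one concurrent event per interface, a
4-frame refractory gap (longer than the tracker's gap-closing window,
so distinct events remain distinguishable in principle), a ≥ 9 px
separation between concurrent spots, exponential or constant
lifetimes, a triangular grow-then-shrink intensity profile, and
Poisson shot noise plus Gaussian read noise with SNR defined as peak
amplitude over background σ. Spot width defaults to σ = 1.2 px, a
diffraction-limited compartment core at 0.164 µm/px.

None of the generators emulate segmentation artifacts, z-drift,
photobleaching, compartment tubulation (spots are isotropic), or
mechanically coupled neighbor deformation. Passing the recovery
benchmarks therefore demonstrates the *estimators* are correct and
well-calibrated under the stated noise models, not that segmentation
or detection are robust to every imaging pathology of real embryos.

## Benchmark sizes

The recovery benchmarks use: 100 random trajectories (N = 200) for the
MSD oracle; 200 trajectories/curves per condition for fit recovery
(N = 2000 drift, N = 10⁴ diffusion, 199-lag mixed curves at 1% noise);
500 trajectories of N = 500 per γ-calibration class; 250 two-run
trajectories plus 250 diffusion controls for step detection; 50
interfaces per ratchet cohort; 100 cells × 1200 frames for amplitude;
200 spots and 24 designed gap stubs for detection/tracking; ≥ 1000
random point/geometry configurations for the association oracle; and
600 compartments on a 400-frame static lattice for polarity recovery.
These sizes keep the full benchmark under a few minutes on one CPU
while leaving each comparison's sampling error well inside its
tolerance.

## Known limitations

- Interface length is the vertex chord; strongly curved boundaries
  would be underestimated (contour pixels are kept if arc measures are
  ever needed).
- Detected step intervals are smeared by the rolling-window width;
  only their count, displacement and coarse duration are calibrated.
- The lifetime correction assumes a stationary birth process and
  cannot recover mass beyond the movie length.
- The wavelet detector's scale range (J = 3) targets 2–8 px features;
  much larger compartments would need a larger J and a recalibrated
  correlation threshold.
- `pairing_analysis` treats side assignment as exact; near-interface
  centroids in noisy data could flip sides, which the synthetic
  benchmarks (1 px side offset) only partially exercise.
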
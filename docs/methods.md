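# Methods

This note documents the models, conventions, numerical choices and known
limitations of `curvedpsd`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Geometry and conventions

Laboratory frame: incident beam along +x̂, rotation axis (vertical) +ẑ,
the in-plane diffraction angle 2θ_B opening toward +ŷ; ϕ is a
right-handed crystal rotation about ẑ. Angles are degrees at every
interface and radians internally. Reciprocal vectors carry no 2π
(`|q| = 1/d`), and the UB matrix maps integer indices to crystal-frame
vectors at ϕ = 0, `q = UB·hkl`, with B in the Busing–Levy convention.

Channels map to angles by

* `2θ_B = 2θ_c + c_x (X − X0)` — exact, because the detector is a
  cylinder section curved only horizontally, so equal X steps subtend
  equal in-plane angles;
* `χ_d = arctan[c_y ((Y − Y0) − s (X − X0))]` — tangent form, because the
  detector is flat vertically (`c_y` ≈ vertical pitch / radius). A linear
  small-angle mode (`chi_mode: linear`) exists for cross-checking.

**Where the X–Y shear enters.** The delay-line readout couples the two
channel coordinates by a small dimensionless slope `s` (~4 × 10⁻³). We
place the shear in the elevation relation, so that lines of constant χ_d
— layer lines, in particular the equator — appear tilted by slope `s` in
raw channels. This is forced by the calibration procedure itself: the
slope is *measured* from the tilt of the layer lines in a full-rotation
scan, which would be unobservable if the shear acted on the 2θ_B
coordinate only (every layer would then render exactly horizontal). The
inverse mapping is closed-form, and channel↔angle round trips are exact
to < 10⁻⁹ channels (property-tested).

**Instrument profiles.** All machine constants ship as the `hanaro`
profile (c_x = 0.2614°/ch, c_y = 0.003917/ch, s = 0.0041, X0 = 181.50,
arm 40°, active window (60,100)–(460,360), 512×512 channels, radius
530 mm, λ = 1.153 Å). The published parameter table prints the equator at
Y0 = 94.135 together with a Y window of 100–360, which would place the
entire face above the equator and contradicts both the instrument's
stated χ_d range (−18.4° … +34.5°) and the layer ranges it demonstrably
records (l = −2 … +3 for NaCl at 0.8912 Å). Setting Y0 = 194.135
reproduces all three constraints simultaneously, so the default profile
uses that value; the verbatim constants remain available as
`hanaro-printed`. This is the single deliberate departure from the
printed constants, and the layer-capture acceptance test depends on it.

**Monochromator.** λ = 2·d(hkl)·sin(takeoff/2) with the reference
germanium constant a = 5.6575 Å; the [0,−1,1]-zone planes of a Ge(311)
slab give 1.153, 0.7804, 0.7358 Å at the 39.5° take-off, matching the
nominal values to < 0.05%. The nominal 2.204 Å of Ge(111) is 0.17% away
from the Bragg value (2.2076 Å) for any standard Ge constant; we report
the computed value and do not assert the nominal one.

## Simulator

The simulator solves `(R_z(ϕ)q)·x̂ = −λ|q|²/2` in closed form for every
`hkl` inside the Ewald limit `|q| ≤ 2/λ`, yielding up to two crossings
per reflection (entry/exit). Vectors parallel to the rotation axis (and
any with no real solution) are blind — declared unreachable, never
clamped. Both crossing branches are kept as separate observations
throughout; on a single-sided detector the second branch generally lands
off-face and its Friedel mate is recorded instead. The crossing solver is
pinned against a brute-force ϕ-grid + bisection oracle to < 0.005°.

Spots are rendered as **pixel-integrated** separable Gaussians in (X, Y)
and a Gaussian partition of the total intensity over frames in ϕ,
truncated at ±4σ; on full-circle scans the ϕ profile wraps across the
0°/360° seam (a spot crossing near ϕ = 0 deposits its tail in the last
frames, as the physics requires). Defaults: σ_x = 1.34 and σ_y = 1.13
channels, the instrument's point-spread FWHM of 3.16/2.66 channels
divided by 2.355; σ_ϕ = 0.8·Δϕ so that a reflection spans several
consecutive frames, as mosaic spots do. Intensities are user-assigned —
there is deliberately no structure-factor physics, no symmetry-driven
extinctions and no resolution-function model, so passing tests certify
the *reduction chain*, not any scattering model. Poisson mode draws every
pixel from the noiseless expectation with a mandatory seed and is
bit-reproducible.

What the generator does not emulate about real data: background
structure (powder rings, air scatter gradients), detector efficiency and
distortion beyond the linear shear, absorption/extinction in the sample,
wavelength contamination, and intensity-dependent spot shapes. Results on
real frames therefore depend on calibration quality in ways the synthetic
tests cannot probe.

## Peak search and integration

Seeds are 8-neighbourhood local maxima above the user threshold, visited
strongest-first. Each seed's odd-width box (default 11) is re-centred on
the background-subtracted centre of gravity until the centre pixel is
stable (≤ 20 iterations; an oscillating COG is reported at the last
centre with a convergence flag; ties round toward the smaller channel).
Background is the mean of the box's one-pixel border rim (width
configurable); `net = Σ(inner) − n_inner·bg` and
`σ² = Σ(inner) + (n_inner/n_rim)²·Σ(rim)` by Poisson propagation. Inner
pixels of an accepted peak are masked, so no pixel contributes twice and
overlapping reflections are resolved greedily — the integration assumes
essentially isolated reflections, and overlapped ones surface later as
poor matches in classification rather than silently corrupt intensities.

Merging is single-linkage over 2D peaks within 1.5 channels in (X, Y) on
frames at most `gap_tol + 1` apart (default strictly consecutive), with
frame adjacency made periodic on full-circle scans. Integrated intensity
is the exact member sum, σ adds in quadrature, the ϕ centroid is
intensity-weighted (circular mean when the group wraps). A peak is
`partial` when its span touches the stack boundary of a non-periodic scan
or its box touches the active-window border — such integrals are
incomplete by construction and are flagged, not repaired.

On noise-free synthetic scans, interior isolated spots are recovered with
100% recall, COGs within 0.05 channels and intensities within 1% of the
deposited mass (the ~0.1% box/truncation loss is inherent to finite
boxes). On Poisson scans the pull distribution (I − truth)/σ is centred
(|mean| < 0.1) with unit width (sd ∈ [0.8, 1.2]) when the spot's ϕ
profile is fully captured by frames above threshold; spots whose tail
frames fall below threshold are integrated slightly low — the classic
thresholding bias of this integration style.

## Indexing

`observations_to_q` composes the three geometry maps at each peak's ϕ
centroid. The ϕ-discretisation of the centroid limits q accuracy to
roughly |q|·(0.05°·Δϕ/1°); at Δϕ = 1° this is ~10⁻³ Å⁻¹ at the Ewald
sphere edge.

*Vector minimum.* Candidates are the observations plus all pairwise
differences, averaged on a 5 × 10⁻³ Å⁻¹ grid — coarse enough to pool
noisy repeats of one lattice vector, far below any plausible reciprocal
basis length. Triples of short candidates (|det| > 10⁻⁶ Å⁻³) are scanned
shortest-first until one integer-indexes ≥ 80% of the observations within
the 0.1 fractional-hkl tolerance; the winner is Minkowski-reduced to the
compact primitive basis, sign-fixed right-handed, and least-squares
refined on the points it indexes. Residuals are measured in fractional
hkl units — the natural scale for "0.1 reciprocal-space distance".

*Two/three-reflection constructions.* Standard orthonormal-triad
alignment (U re-orthogonalised by SVD; metric mismatch beyond 2% between
|q| and 1/d is an error) and the exact linear solve
`UB = [q₁q₂q₃][h₁h₂h₃]⁻¹`.

*Monte-Carlo with a known cell.* Trials draw a random pair of
observations — preferentially from the shortest third of |q|, whose
d-spacing shells admit few candidate indices — and a random index
assignment compatible with the cell (|q| within 2% of 1/d, inter-vector
angle within 0.05 in cosine), build the orientation by the two-reflection
construction and score it by the number of observations indexed at 0.1.
The winner is polished by an index-and-refine bootstrap with a tolerance
shrinking from 0.4 to 0.1. A pure uniform-rotation search cannot work
here: the acceptance basin of a true orientation is ~2° wide
(Haar measure ~10⁻⁶), so no realistic trial count lands in it; assignment
trials make every trial land exactly on a candidate orientation.
Everything is driven by one mandatory seed and is bit-reproducible.

*Bravais search.* All integer transformation matrices with entries in
{−1, 0, 1} and determinant 1–4 (covering P, A/B/C, I, F and R
centerings) are applied to the primitive cell; each candidate's metric is
tested against cubic / hexagonal / tetragonal / orthorhombic / monoclinic
specialisations within 0.2% on lengths and 0.2° on angles. The winner is
the highest symmetry, then the smallest centering multiplicity, metric
deviation, cell perimeter, and β ≥ 90° (conventional monoclinic
setting). A cell fitting nothing stays triclinic P with its basis
untouched. The centering letter is read off the primitive translations
modulo the conventional cell.

*Refinement.* The nine UB elements decouple into three linear
least-squares problems sharing one design matrix; cell standard
uncertainties are propagated from the (block-diagonal) element covariance
through the UB → cell map by forward differences. The refined residual
never exceeds that of any feasible start, by least-squares optimality.

## Calibration

Fit order is fixed — c_x/X0 from the arm scan, then Y0/slope/c_y from
layer lines, then λ — because each fit consumes its predecessors.
Stepping the arm *forward* moves a fixed reflection to *lower* X
(slope −1/c_x); the opposite sign convention is caught as an error and
exposed as a configuration switch. Layer clustering splits the
slope-corrected Y histogram at gaps (default 10 channels), discards
sparse bands (< ¼ of the largest band — stray powder-ring points), fits
all bands jointly with a common slope under iterated 4σ clipping, and
assigns layer indices by matching the intercept ladder to
tan(arcsin(lλ/c)); `c_y` then follows from the inter-layer spacings and
is flagged unfitted when only the equator is present. The wavelength fit
averages `2d·sin θ_obs` over indexed equatorial reflections with the
scatter as its uncertainty. All three fits are exact on noise-free input;
over 200 seeded replicates with 0.2-channel position noise the nominal
95% intervals cover the truth 90–99% of the time (the test suite measures
this).

## Reduction

The Lorentz factor for this fixed-χ, ϕ-rotation geometry is
`L = 1/(cos χ_d sin 2θ_B)`; a finite-difference computation of the speed
at which the rotating reciprocal point crosses the sphere agrees to
< 0.1% (the suite pins it at 10⁻³ relative), which is what justifies the
closed form. Near the rotation axis (cos χ_d·sin 2θ_B ≤ 10⁻³) the
correction is refused and the reflection flagged, never silently scaled.

Classification matches predictions to observations greedily,
nearest-first in fractional-hkl distance, each observation usable once:
`good_peak` within 0.1; `no_good_peak` when the nearest observation sits
between 0.1 and 3 × 0.1 (the "exists nearby" radius); `no_peak` beyond;
`out_of_experimental_area` for off-window predicted positions;
`out_of_expected_region` for on-face crossings whose ϕ lies outside the
scanned range — an operational definition chosen because the source
material names this category without defining its region, and it is
flagged as such in output. `partial` propagates from the underlying
integration. Labels are exhaustive and mutually exclusive by
construction.

Duplicate measurements of one `hkl` (e.g. entry and exit crossings both
on-face) are combined by inverse-variance weighting — each crossing is an
independent measurement of the same |F|², so averaging, not summing — and
the internal agreement is reported. Everything else lands in a rejects
table with its reason. SHELX export uses fixed-width HKLF-4 records (3I4,
2F8.2) with explicit overflow errors.

## Problem sizes and seeds

The shipped tests and the acceptance script run the full chain on
360-frame scans (Δϕ = 1°) of small cells (NaCl; 5 × 7 × 9 Å
orthorhombic), about 1500 reflections per scan — large enough to exercise
every code path including layer structure, window-edge partials, Friedel
mates and occasional spot overlap, while a complete suite run stays in
the minutes range. The instrument's native Δϕ = 0.2°/1800-frame mode is
exercised at the bookkeeping level (sizes, scan arithmetic) and is a
configuration change, not a code path change. Every stochastic component
(orientation draws, Poisson noise, Monte-Carlo indexing) takes an
explicit seed; nothing samples global state.

## Known limitations

* No absorption, extinction or polarisation corrections; no scaling or
  merging across scans beyond branch averaging; no structure refinement.
* No space-group determination beyond the Bravais lattice; twins appear
  only as unindexed fractions.
* Overlapping reflections are resolved greedily by masking, not
  deconvolved; heavily overlapped regions produce flagged poor matches.
* The thresholded integration slightly underestimates reflections whose
  ϕ tails fall below the 2D threshold (see peak search above).
* The original instrument's on-disk formats are unpublished; the package
  defines its own documented dialects instead of guessing them.
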
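# Methods

`rotasym` implements the quantitative reasoning used to characterise a
high-torque bacterial flagellar motor from ring-shaped density maps and
slowed bead-rotation assays.  This note records the models, the numerical
choices, and what the synthetic data do and do not establish.

## Coordinate and unit conventions

Density maps are cubic-voxel grids indexed `[z, y, x]` with the cyclic
symmetry axis along +z through the geometric grid centre (voxel coordinate
`(n−1)/2` per axis); axes are right-handed and azimuth increases
counter-clockwise viewed from +z.  Map lengths are in ångström, bead
trajectories in nanometres and seconds, torques in pN·nm.  Unit conversions
happen only through the named helpers (`angstrom_to_nm`, `nm_to_angstrom`);
the `StatorRing` type rejects contact radii above 100 nm as a guard against
unconverted ångström values.

## Synthetic phantoms

Ring phantoms are sums of isotropic Gaussian subunits placed at equal
azimuthal spacing on a circle; concentric-disk phantoms place one Gaussian
per protomer on each ring of a lattice model, with outer rings deliberately
phase-shifted so only the innermost ring shares the global symmetry;
cylinder phantoms are Gaussian shells in radius, uniform in azimuth, boxcar
in z.  Gaussians are truncated at 4σ (≤3.4 × 10⁻⁴ of peak) so construction
cost scales with blob volume, not grid volume; the phantom integral then
matches `count × amplitude·(σ√2π)³` within 1 %.  All generators are pure
functions of their parameters and seed.

Half-map pairs add independent white Gaussian noise scaled so the
signal-to-noise variance ratio equals `snr` (`snr=inf` adds none).  Real
reconstruction noise is frequency-structured and masked; white noise is
sufficient to validate FSC machinery against known answers and nothing
more.

The bead simulator emulates a de-energised, slowly stepping motor: a rotor
with `n` equally spaced dwell angles advances (or, with probability
`back_step_prob`, retreats) after exponentially distributed waits, and the
bead reports the orbit-ellipse point at the current dwell plus Gaussian
localization noise, sampled at the camera rate.  Defaults — 26 dwells,
1,000 frames/s, 50 steps/s (20 frames per mean dwell), a 150 × 90 nm orbit,
20 nm noise per coordinate, 10⁵ frames, no back-steps — describe a
1.3-µm-bead assay on a CCCP-slowed motor with a switching-deficient strain.
Steps are instantaneous and bead relaxation immediate: at these stepping
rates the bead's mechanical relaxation is far below one frame, and no
kinetic parameters beyond the stepping rate are modelled.  Simulated
trajectories are stationary; drift and photobleaching are not modelled.

## Cyclic-symmetry detection

The density in an annular band is resampled on polar rings (cubic-spline
interpolation; azimuthal sample count 4× the largest searched harmonic,
minimum 256), averaged over radius and height to a 1-D azimuthal signal
f(φ), and Fourier-transformed; S(k) = |c_k|² for k = 1..k_max.  S is
invariant to map rotation about z and to uniform density scaling.

**Peak significance.**  Each harmonic receives the larger of two robust
z-scores: against a local background (median/MAD over harmonics within ±10,
excluding the harmonic and its ±2 neighbours) and against the global
spectrum background.  The local score handles coloured baselines — finite
trajectories pile power into low harmonics — while the global score rescues
low fundamentals whose overtone comb fills the local window.  MADs are
floored at 0.3× the corresponding median so a fortuitously tight window
cannot manufacture significance.  The detection cut of **70** was
calibrated to zero false positives over 3,000 uniform-angle spectra, 600
smoothly-rotating-bead pipeline runs and 1,500 pure-noise maps (largest
null excursion 62.9); genuine phantom signals score from ~10² to beyond
10⁹.

**Call rule.**  Harmonics passing the cut (and, for maps, an amplitude
floor: Fourier amplitude ≥1 % of the band's mean density, which rejects the
~10⁻³ relative interpolation leakage a perfectly lathed structure shows on
a Cartesian grid) are candidates; the candidate with the highest *power* is
the call.  Significance decides whether structure is present, power decides
which harmonic it is — a nearby sideband (bead orbits contribute k ± 2
sidebands through residual ellipse error) can fluctuate to a higher
z-score but not to higher power.  If the winner and the other candidates
are all multiples of a smaller candidate d, the fundamental d is reported
(discrete subunit rings put power at n, 2n, …); candidates below 1 % of the
peak power are ignored by this rule.  No candidate ⇒ no symmetry
(`n_fold=None`).

**Lathing** (cylindrical averaging) computes the exact azimuthal mean on a
half-voxel-pitch (r, z) grid and maps it back to the Cartesian grid by
linear interpolation in radius.  The discrete C360 rotational average — the
classical way to build an azimuthally featureless reference — is retained
in the test-suite as an independent oracle; the two agree within 1 % of the
map maximum.  Rotational averaging (`impose_cyclic_symmetry`) uses
cubic-spline resampling: linear interpolation smears voxel-scale subunits
by several percent per rotation, which would violate the 1 % symmetry
tolerances; cubic keeps rotation and lathing density-conserving to better
than 0.5 %.

## Radial profiles and FSC

Radial profiles average density over azimuth and a z-slab into
one-voxel-wide radial bins; peak radii are parabolically interpolated
through the three bins around the maximum, giving sub-voxel precision
(62 Å shell on a 2 Å grid reads out within half a voxel).  Flat profiles
have no peak and raise an error.

FSC uses shells one reciprocal voxel wide (of the smallest grid dimension),
per-shell normalized cross-correlation, and linear interpolation to the
first crossing of the threshold (0.143 for half-maps, 0.5 for map-model).
No masking or phase-randomization correction is applied — the package does
not post-process reconstructions.  A curve that never crosses reports the
Nyquist bound flagged `crossed=False`.  Validation is property-based:
self-FSC ≡ 1, argument symmetry, near-zero correlation of independent noise
maps, and recovery of a known sharp low-pass cutoff within 15 % when the
half-map noise leaves shell SNR high up to that cutoff.

## Basal-disk stoichiometry

Under the constant-arc-spacing model the innermost ring (radius R1, n1
protomers, arc s = 2πR1/n1) fixes the packing of all rings: ring i at
R_i = R1(1 + spacing_ratio·(i−1)) carries round(n1·R_i/R1) protomers,
rounded half-to-even since the model constrains only circumference ratios.
The packaged `spacing_ratio = 0.216` is a derived constant — chosen once so
that a 51-protomer inner ring gains 11 protomers per ring, the increment
the ring-to-ring geometry shows — and is overridable in every API.  Rings
are closed concentric circles, not a spiral, and the +11 increment is
treated as exact; the symmetry of rings beyond the first is not predicted.
A brute-force circumference-packing oracle (largest n with
2πR_i/n ≥ s(1−1/2n)) agrees exactly over 1,000 random models in the tests.

Cogwheel registry: small cog k of n meets an m-tooth big cog at phase
frac(mk/n); the number of distinct phases is n/gcd(n, m).  Coprime counts
(17 stators on a 38-tooth C-ring, 11 on 34) force every stator into a
different rotational register, which argues against rigid gear-like
meshing.

## Additive stator torque

τ = N·F·r with N engaged stator complexes, per-stator tangential force F
(pN) and contact radius r (nm); exactly linear in each factor, exactly
inverted by F = τ/(N·r).  Packaged rings: 17 × 7.3 pN × 26.5 nm
(≈3,289 pN·nm) and 11 × 7.3 pN × 20.0 nm (1,606 pN·nm).  The 26.5 and
20.0 nm radii are derived structural constants consistent with those
predictions — contact radii are not independently tabulated — and carry a
`derived` provenance tag in the packaged config so users can substitute
radii measured from their own maps.  No load-line, duty-ratio or occupancy
dynamics are modelled; additivity is taken as exact.

## Step detection

The pipeline is: boxcar-smooth the trajectory (default 7 frames), fit the
bead orbit with a least-squares algebraic conic fit constrained to
ellipses, invert the ellipse transform (translate, rotate by −tilt, scale
by 1/a, 1/b, atan2) to per-frame rotor angles in [0, 2π), then count dwell
positions.

**Pre-smoothing** is load-bearing at realistic noise: 20 nm localization
noise on a 150 × 90 nm orbit gives per-frame angular noise σθ ≈ 0.17 rad,
which attenuates the k-th circular harmonic by exp(−k²σθ²/2) — a factor
~10⁻⁴ at k = 26, burying the dwell signal below the spectral noise floor.
Averaging 7 frames (well inside the ≥20-frame dwells the defaults
guarantee) cuts σθ by √7 and restores the harmonic to ~10 % amplitude,
at the cost of blurring only frames that straddle a step.  The window is a
parameter; 1 disables smoothing.

**Spectral count (primary).**  S(k) = |Σ w_j e^{ikθ_j}|²/(Σ w_j)², the
squared magnitude of the weighted empirical characteristic function, with
per-frame durations as weights so dwells count by time spent.  S ∈ [0, 1],
is exactly phase-invariant (a global angle offset cancels in the modulus),
and under the uniform null has mean ~1/n per harmonic with variance
scaling as 1/n.  Harmonics 2–60 are searched by default; k = 1 is excluded
as it is dominated by orbit-centring error.  Peak calling uses the same
combined significance and power-among-significant rule as map symmetry.

**KDE count (secondary).**  A weighted von Mises KDE is evaluated by
Fourier synthesis — the empirical circular moments shrunk by I_k(κ)/I_0(κ),
truncated where the factor falls below 10⁻¹² — on a 1,024-point grid,
clipped at zero and renormalized to unit integral; this is exact (no
binning) and O(n·k_cut).  The default κ = 4k² at the spectral count places
the kernel sd at 1/(2k) rad, a twelfth of the dwell spacing.  A dwell peak
is significant when its excess over the uniform level 1/2π exceeds 3
analytic null standard deviations (Var ρ̂ = (Σw²/(Σw)²)(I₀(2κ)/2π I₀(κ)² −
1/4π²); 1,000-trial null maximum 2.1).  A robust-MAD cut on the profile
itself — natural as it sounds — is unusable: a genuine dwell comb inflates
the profile's own MAD so much that true peaks score below the uniform
null.  At the default 20 nm noise the azimuthally varying angle blur
(wider near the orbit's minor axis) pushes some dwell peaks under the cut,
so the KDE count is conservative there; the two estimators' agreement is
reported, never enforced, and the spectral count is the package's answer.

**Operating envelope.**  With the default assay conditions the spectral
count is exact for all 26-dwell simulations tested across seeds, and over
n = 10..40 (20 seeds each, 620 runs) recovers the true count in ~98 % of
runs.  The residual failures concentrate at n ≥ 38, where 0.16 rad dwell
spacing approaches the smoothed angular noise: they are non-calls
(significance below the calibrated cut), not wrong numbers; numeric
miscalls, when they occur, are ±1 — matching an experimental read-out of
"25 to 27" around a 26-periodicity ground truth.

## Problem sizes and determinism

Default analyses run on 96³–192³ grids and 10⁵-frame trajectories — sizes
at which every phantom property (blob integrals, symmetry recovery for
n = 2..41, sub-voxel radii, cutoff recovery) is already stable.  Every
stochastic path takes an explicit integer seed, uses `numpy` Generator
streams (the simulator derives an independent noise stream from
`(seed, 1)` so stepping and localization noise cannot alias), and repeat
runs are bit-identical.  Pipeline records embed seed, inputs and package
version; rerunning a config reproduces outputs exactly.

## Known limitations

No cryo-EM image formation, masking, sharpening or refinement is modelled;
phantom results bound what the measurement machinery can do on ideal
inputs, not what real micrographs support.  The basal-disk model fixes the
+11 increment by construction wherever rounding permits, so it cannot test
the lattice hypothesis, only propagate it.  The torque model's contact
radii are derived, not measured.  The step detector assumes a stationary,
elliptical orbit and a constant stepping rate; drifting or switching
motors need preprocessing this package does not provide.
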
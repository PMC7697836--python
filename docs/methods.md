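# Methods

This note documents the models behind `fluorofilm`: what the synthetic
configurations represent, how each statistic is defined and computed, the
numerical choices made, and what the package does and does not claim.

## Chain construction

Molecules are built from ideal internal coordinates, not from a force field:
C–C 0.154 nm, C–C–C 114°, C–O 0.143 nm, C–F 0.135 nm, C–H 0.109 nm,
substituent X–C–X angle 109.47°. Fluorocarbon backbones use a fixed dihedral
of 163.5°, the ~15/7 helix characteristic of perfluorinated chains, giving a
rise of ≈0.129 nm per carbon; hydrogenated backbones are all-trans (180°).
Atom order per molecule is O, hydroxyl H, then C1…Cn each followed by its
substituents (C1 of the 1H,1H-perfluorinated alcohols is a CH₂ group). The
template is oriented head-carbon → terminal-carbon along +z with the head at
the origin, so placement is pure rotation + translation.

With this geometry the head-to-tail distances are 1.674 nm (F14OH) and
2.189 nm (F18OH), within 15% of the fully extended molecular lengths known
for these species (~1.8 and ~2.5 nm, which include the head group and
terminal van der Waals radii that the carbon-to-carbon distance omits). That
consistency is what validates using rigid ideal chains in place of
energy-minimised conformers.

## Synthetic monolayer frames

The generators emulate the structural states a fluorinated-alcohol film
explores along its compression isotherm. They reproduce the *statistics*
that the analysis stages consume — positions, orientations, composition —
not the energetics or dynamics of a real trajectory; all frames are
independent draws, not time-correlated configurations.

* **hex_crystal** — n molecules on a triangular lattice (parameter `a`,
  default 0.575 nm), spiral-filled from a central site so any count gives a
  compact quasi-hexagonal patch (distance ties broken by lower azimuth).
  Each molecule is spun about its own axis by a uniform azimuth, tilted by a
  half-normal angle (`tilt_sigma`, deg) in a uniform direction, and placed
  with its **centroid** over the (optionally jittered) site — so at zero
  disorder nearest-neighbour centroid distances equal `a` exactly and all
  chain vectors are exactly +z.
* **gas_cluster** — a stated fraction of molecules forms one hex_crystal
  aggregate; the rest are placed at uniformly random unoccupied positions
  with orientations uniform on the upper hemisphere (E[u_z] = 1/2, hence
  OP → 1/4 for the gas alone). Free molecules keep ≥0.75 nm in-plane from
  everything so the aggregate stays recoverable at the default clustering
  cutoff.
* **liquid** — random sequential insertion of centroids with a 0.40 nm
  hard core (just below the fluorocarbon cross-section diameter; insertion
  aborts after 10⁴ failed trials), broad half-normal tilt (σ = 35° unless
  overridden), and per-molecule torsional noise (σ = 12°) rebuilt through
  the chain constructor — flexible, disordered chains with no long-range
  positional order.
* **segregated_mixture** — species B as a compact hexagonal domain, species
  A as a thread-like two-row strip, separated by a 2.5 nm gap: laterally
  segregated, species-pure domains at a given molar ratio.

Water is never instantiated: no statistic implemented here uses it. The
interface is the z = 0 plane; head groups anchor there with a 0.05 nm
vertical jitter where positional disorder is requested.

Random draws come from one seeded NumPy generator per frame in a fixed,
documented order (spin, tilt magnitude, tilt azimuth, positional jitter,
vertical jitter; placement trials interleaved for gas/liquid). Identical
specs (including seed) give bit-identical frames within this implementation.

## Coordinate I/O

Internal units are nm, z the interface normal. XYZ and GRO are written in
nm, PDB in Å (converted both ways). The XYZ dialect written here adds a
fifth column with the 0-based molecule index and a `box=…, t=…` comment
line; plain 4-column XYZ is read by reconstructing molecules as connected
components of the bond graph. Bond detection uses per-pair distance
thresholds (C–C < 0.20, C–O < 0.18, C–F < 0.16, C–H < 0.13, O–H < 0.12 nm).
GRO velocities are ignored on read and omitted on write. Round trips
preserve coordinates to format precision (GRO 0.001 nm, PDB 0.001 Å, XYZ
10⁻⁶ nm); the test suite independently re-reads written GRO/PDB with
MDAnalysis as an oracle.

Chain vectors use the default rules: head = the unique carbon within
0.16 nm of an oxygen; tail = the carbon with the longest bonded path from
the head over the carbon skeleton (ties → highest atom index).

## Order parameter

OP is the mean pairwise cosine of the chain vectors. It is evaluated through
the identity OP = (‖Σuᵢ‖² − N)/(N(N−1)) on the unit vectors, which equals
the literal double sum to machine precision in O(N); the literal sum is kept
as `compute_op_double_sum` for cross-checks. Bounds: −1/(N−1) ≤ OP ≤ 1.

Time averaging groups frames into consecutive non-overlapping blocks by
their time labels (default 2 ns). A final block counts as complete when the
last frame's sampling interval (median frame spacing) reaches the block end;
a truncated final block is dropped from the uncertainty but never from the
mean. The reported std is the sample standard deviation (ddof = 1) of the
block means, 0 when only one block exists. Gas-phase molecules are included
by default — the statistic literally sums over all N molecules — with
`largest_cluster_only` available to restrict it to the main aggregate.

Aggregates are detected by single-linkage clustering on in-plane centroid
distances under periodic x,y images (cKDTree pairs + connected components).
The default cutoff 0.70 nm ≈ 1.2× the lattice parameter separates lattice
neighbours from gas. Clusters need ≥2 members; singletons are labelled −1;
labels are ordered by smallest member id, so they are deterministic.
Upright/lying classification uses tilt < 45° (midpoint convention).

## Simulated in-plane diffraction

The estimator is the exact azimuthal average of the in-plane structure
factor of a finite cluster,

    I(Q) = ⟨ Σⱼ Σₖ wⱼwₖ J₀(Q·d_jk) ⟩_frames / Σⱼ wⱼ²,

including the j = k self terms (so I ≥ 0, and a single atom gives exactly
1). This cylindrical form — J₀ instead of the 3D sinc kernel — is the 2D
Debye equation appropriate to Q_z-integrated in-plane scans of a monolayer.
A J₀ pair sum was chosen over a 2D FFT because frames are finite aperiodic
clusters: no periodic images enter by default (a minimum-image flag exists),
so peak widths reflect the true domain size.

Weights default to atomic number Z, a form-factor-contrast surrogate without
tabulated f(Q); a "unit" scheme exists, and peak *positions* are insensitive
to the choice. The default atom filter selects chain carbons and fluorines
(head group excluded). The default grid is 1–30 nm⁻¹ in 0.02 nm⁻¹ steps,
matching typical synchrotron in-plane resolution.

Up to 300 selected atoms the pair sum is evaluated exactly; above that,
pair distances are accumulated into a 5×10⁻⁴ nm histogram and the Bessel sum
runs over occupied bins. The binning phase error is ≤0.0075 rad at
Q = 30 nm⁻¹; deep interference troughs can acquire tiny negative residues,
which are clamped to zero. The test suite pins both paths against a
brute-force orientational average over 720 azimuthal directions (<0.5%
everywhere) and against the exact pair sum (<0.3%).

No Q_z dependence, refraction, polarisation or Lorentz corrections are
modelled. Computed peak intensities and widths are therefore comparable only
qualitatively; positions and position ratios are the quantitative outputs.

## Peak fitting and derived lattice quantities

Peaks are fitted as amplitude·S((Q−Q₀)/w) + linear baseline by
`scipy.optimize.curve_fit`, with S Lorentzian (FWHM = 2w) or Gaussian
(FWHM = 2√(2 ln 2)·w), initialised from the argmax and half-height
crossings, tolerances 10⁻¹². Lorentzian is the conventional choice for
measured zero-pressure spectra, Gaussian for compressed or simulated ones.

Hexagonal indexing assigns the first position to (10); further positions
must sit at √3 and 2 times the first within 1% (a square lattice, √2 ≈ 8.6%
off, is safely rejected with a diagnostic naming the offending ratio). Then
a = 4π/(√3·Q₁₀) and area = (√3/2)a². One known subtlety: a measured F18OH
peak at 12.65 nm⁻¹ indexes to a = 0.574 nm — reported tabulations sometimes
carry a lattice parameter (0.5753 nm) inconsistent with their own peak
position at the last digit; this package always reports the value derived
from Q, which is what propagates to the area per molecule.

Coherence length: l_c = 2π/FWHM_intrinsic. Quadrature deconvolution of the
instrument resolution is the default for measured widths — it is what makes
a 0.029 nm⁻¹ width with 0.02 nm⁻¹ resolution yield ≈300 nm rather than the
uncorrected 217 nm — and computed spectra use Δ = 0. A width at or below the
resolution yields a lower-bound flag with l_c = 2π/Δ.

## Isotherm analysis

Limit area A₀: ordinary least squares of π on A over a window on the linear
condensed branch; A₀ = −intercept/slope, requiring a negative slope and ≥5
points spanning ≥5 mN/m. The automatic window is the steepest contiguous
quarter of the *rising* compression branch — from where the pressure exceeds
the 0.2 mN/m noise floor and stays above it, up to the pressure maximum
(collapse) — so neither the coexistence plateau nor post-collapse points
enter the fit. Liftoff is the largest area at which the pressure exceeds the
threshold and remains above it at all smaller areas; liftoff and limit area
are deliberately distinct quantities (the literature sometimes conflates
them).

The synthetic generator produces a zero plateau, a quadratic shoulder that
joins the linear branch tangentially at A_t = 2A₀ − liftoff, and a linear
branch of slope −s extrapolating exactly to A₀, plus optional collapse kink
and seeded Gaussian noise. `limit_area` on noise-free output recovers A₀
exactly; under σ_π = 0.2 mN/m the median recovery error is <1% over 100
seeds.

## Problem sizes and defaults

Default study conditions mirror the films being modelled: 550 molecules per
frame, lattice parameter 0.575 nm, 0.02 nm⁻¹ spectral grid over 1–30 nm⁻¹,
2 ns averaging blocks. Tests exercise the same code on smaller patches
(19–550 molecules, carbon-only atom selections where the full fluorine shell
adds cost without changing peak positions); the acceptance script runs the
550-molecule spectrum with the full carbon+fluorine selection.

## Limitations

* Frames are static independent draws: no dynamics, energetics, thermostats
  or water; "trajectories" are sequences of such frames with time labels.
* The diffraction model has no Q_z structure, form factors, or instrumental
  convolution; computed intensities/widths are not comparable to measured
  ones in absolute terms.
* The azimuthal registry inside generated aggregates is free-rotator
  (uniform spins); herringbone-like registries are not modelled.
* Experimental isotherms and spectra are consumed from plain two-column
  tables only; instrument file formats are out of scope.
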
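# Methods

This note documents the models and numerical choices behind `memsoap`, in the
spirit of a methods appendix: what is computed, with which conventions, which
knobs matter, and what a green test does and does not establish.

## Unified bead representation

All analyses run on a four-site-per-lipid reduction: HEAD (charged head
group), PHOS (phosphate), TAIL1/TAIL2 (alkyl tail termini). Each site is the
mass-weighted center of a configurable list of atom/bead names; for CG models
with one bead per site it is the bead itself, and when masses are unknown
(e.g. bead names a topology reader cannot assign) the geometric center is
used. Residues are unwrapped internally by minimum image relative to their
first member atom before averaging — any anchor works for molecules smaller
than half the box. Leaflets are assigned by the sign of the phosphate z
relative to the frame's mean phosphate z (a planar-bilayer assumption;
curvature is out of scope).

## SOAP power spectra

For each lipid the neighborhood of its PHOS site within `r_cut` is encoded as
a SOAP power spectrum. The species-resolved density is a sum of unit-height
Gaussians of width σ at the neighboring site positions (the center's own four
sites included — they are part of its environment density). Expansion
coefficients

    c^α_nlm = ∫ g_n(r) Y_lm(r̂) ρ_α(r) d³r

are evaluated analytically: expanding each neighbor Gaussian in modified
spherical Bessel functions reduces every coefficient to a 1D radial integral
I_nl(R) per neighbor distance R. These integrals are computed by windowed
Gauss–Legendre quadrature (64 nodes over the ±8σ support) on a 4096-point
grid in R and interpolated with a cubic spline (relative interpolation error
~3e−9; an `exact_radial` mode bypasses the spline for verification). The
scaled Bessel function `ive` avoids overflow at the large arguments
(2aRr ≈ 900) the default parameters produce.

**Radial basis.** The polynomial set φ_k(r) = (r_cut − r)^(k+2),
k = 1..n_max, Löwdin-orthonormalized under r² dr with its closed-form overlap
matrix. It was chosen over Gaussian-type orbitals because its exact finite
support matches the windowed radial quadrature and its orthonormalization is
stable to n_max = 8 in float64. Kernel values are convention-sensitive
(basis, density amplitude); distances within one convention are
self-consistent, and the convention is recorded in `SoapParams`.

**Invariant contraction.** p^{αβ}_{nn'l} = π√(8/(2l+1)) Σ_m c^α c^β with
real spherical harmonics (orthonormal, √2·Re/Im convention). Only unique
blocks are stored (α ≤ β; n ≤ n' within same-species blocks), off-diagonal
entries weighted by √2 so that dot products equal those of the full tensor —
the kernel is unaffected by the compression.

**Periodicity.** Bilayers are slabs: x and y are periodic, z is not.
Implemented by wrapping positions into the primary box and replicating the
±1 in-plane images; `r_cut` must be smaller than half the smallest in-plane
box edge, which is enforced.

**Defaults.** n_max = 8, l_max = 8, σ = 0.1 nm, r_cut = 3 nm. The cutoff
sits between the tail reach (≈2 nm) and the opposite-leaflet head groups
(≈3.7 nm); the effective rank of the ensemble kernel matrix grows with the
cutoff and plateaus in this range (tested qualitatively). Heavy analyses
(phase ladders) run at n_max = l_max = 4, which preserves the gel/liquid
contrast at a quarter of the cost.

## Ensemble metric

A force field's ensemble is summarized by the arithmetic mean of the **raw**
per-lipid spectra over lipids and frames; normalization happens inside the
kernel, so every (lipid, frame) observation contributes equal weight.
K = cosine similarity of the mean spectra, d = √(2 − 2K) — the Euclidean
metric on unit-normalized vectors, hence symmetric, zero on identical
ensembles, and triangle-inequality-obeying. Hierarchical clustering uses
average linkage (scipy); the 2D map is metric SMACOF MDS (scikit-learn,
seeded, best of 8 random starts, stress reported).

## Distributional (Jensen–Shannon) path

Per-frame subsampling (uniform without replacement within evenly spaced
frames, seeded) feeds a pooled-data PCA shared by all systems. The PCA is
computed exactly from the pooled covariance (streamed in chunks, so
million-row float32 spectrum pools never get copied), with a deterministic
sign convention. TwoNN estimates the intrinsic dimension from the ratio
μ = r₂/r₁ of second- to first-neighbor distances: a through-origin fit of
−log(1 − F̂(μ)) vs log μ after discarding the top 10% of ratios; duplicates
are dropped with a warning.

Densities on a regular grid (default 12 bins/dimension, data range ±5%) use
a k-NN estimator: point-wise ρ(x_i) = k/(N V_d r_k^d), extrapolated to each
cell center as the inverse-distance-weighted average of its three nearest
sample points' densities, normalized to unit mass. Two properties of this
estimator are worth knowing: it has no spatial decay beyond the sample
support (far cells inherit their nearest neighbors' density; with the ±5%
grid margin this is a small, systematic tail weight), and duplication
invariance holds only when the neighbor counts scale with the duplication
factor. On a 100k-point standard-normal sample it reaches total-variation
error < 0.04 against the closed form at k = 128. JSD uses the natural log
(bounded by ln 2 ≈ 0.693); cells where both densities vanish contribute
zero. On the two-cell example p = (0.5, 0.5), q = (0.9, 0.1):
KL(p‖m) = 0.08718, KL(q‖m) = 0.11632, JSD = 0.10175 nats.

## Phase clustering (PAMM-style)

KDE → quick-shift → moment-fitted Gaussian mixture:

* **KDE**: product Gaussian kernel, per-dimension Silverman bandwidth × a
  scale factor (default 1), densities evaluated at the (sub)sampled points
  themselves. At most 12,000 seeded points enter this stage; the fitted
  mixture then classifies any number of points.
* **Quick-shift**: each point links to its nearest higher-density neighbor
  within τ = λ × max(kernel bandwidth, median NN spacing) in
  bandwidth-scaled coordinates (λ = 3). Linking on the bandwidth scale
  matters: a pure nearest-neighbor-spacing threshold strands sparse tail
  points as spurious modes. Link roots are the density modes.
* **Mixture**: one Gaussian per mode from the hard members
  (weight/mean/covariance + small ridge); clusters holding < 0.5% of points
  are merged into their nearest mode. Assignments are maximum
  responsibility; responsibilities are returned.
* **Phase naming**: GEL is the cluster with the higher mean member density,
  or — when a per-point packing observable such as the Voronoi area is
  supplied — the cluster with the smaller mean area (gel = tighter packing).
  This is a stated convention, not a physical inference.

Transition matrices count (lipid, t) → (lipid, t + lag) label pairs at a
default lag of one analysis frame (10 ns); rows without events are flagged
rather than normalized. The melting detector reports the temperature pair
where the gel fraction crosses 0.5, provided the curve's total variation
across the ladder exceeds 0.5 — otherwise "no sharp transition", the
dry-CG-like phenotype in which gel grows on cooling but never dominates.

## Membrane observables

APL = L_x L_y/(n/2) per frame (per-leaflet average, with a warning, on
unequal occupancy). D_HH is the distance between the two leaflet peaks of
the midplane-centered phosphate number-density profile, with parabolic peak
refinement — phosphate-based by construction, since the bead representation
has no electrons. K_A = k_B T ⟨A⟩ / var(A) from total box-area fluctuations
(the standard fluctuation estimator), in mN/m. Lateral diffusion comes from
the xy MSD of phosphates with per-leaflet center-of-mass motion removed,
fitted over lags of 10–50% of the trajectory, D = slope/4 (no finite-size
/periodicity corrections). Voronoi areas are computed per leaflet on the
3×3-tiled phosphate positions, so cells are exactly periodic and areas sum
exactly to the box area; the per-leaflet mean Voronoi area equals the APL
identically.

## Synthetic bilayers

The generator plants ground truth instead of simulating physics:

* **Geometry**: per-leaflet triangular lattices of PHOS sites; phosphate
  planes at ±1.9 nm, heads at ±2.3 nm, tails at ±0.5 nm (D_HH = 3.8 nm);
  gel APL 0.47 nm², liquid 0.64 nm² — typical PC-lipid values below/above
  melting. Gel lipids: small jitter (0.03 nm), nearly straight tails;
  liquid: large jitter (0.12 nm), widely splayed tails (0.30 nm). Contiguous
  gel domains contract toward their centroid by √(apl_gel/apl_frame), so gel
  lipids are measurably tighter packed in mixed frames.
* **Kinetics**: per-lipid two-state Markov chains, optionally
  neighbor-coupled on the lattice (rates multiplied by 1 + c × like-phase
  neighbor fraction), which produces contiguous domains instead of
  salt-and-pepper mixtures; a gated "nucleation-only" mode allows
  liquid→gel flips only next to existing gel, for planted-seed growth
  experiments. Jitter is AR(1)-correlated between frames (ρ = 0.5).
* **Temperature ladders**: SHARP — equilibrium gel fraction on a steep
  sigmoid (midpoint 310 K, width 6 K) crossing 0.5 between 293 and 323 K;
  GRADUAL — a shallow linear drift from 0.45 at 273 K that never reaches
  0.5. Rates are calibrated per temperature (including the mean-field
  correction for the neighbor coupling) so the chain's stationary fraction
  matches the target; the realized fractions agree with the targets to
  ~0.005 at 1,152 lipids.

What the generator does **not** emulate: real tail conformational order
parameters, undulations and curvature, water/ions, interdigitation, any
energetics. A green phase-recovery test therefore establishes that the
descriptor + clustering machinery separates packing/disorder contrasts of
realistic magnitude and recovers planted kinetics and transitions — not that
any specific force field behaves this way.

## Numerical notes and limitations

* All randomness flows from explicit integer seeds (`numpy` Generators,
  `SeedSequence` spawning for ladders); results are bit-reproducible.
* Spectra for large ladders are held in float32 (the PCA accumulates in
  float64); everything else is float64.
* The quadrature-free analytic SOAP route agrees with a brute-force 3D
  numerical integration of the expansion integrals to ~1e−13 relative; the
  spline adds ~1e−9.
* Mixed-lipid bilayers, membrane curvature, descriptor gradients, and
  statistical error bars on d^SOAP are out of scope.
* Classification accuracy at a phase boundary is intrinsically limited: a
  lipid's 3 nm environment mixes both phases there, so per-lipid labels
  blur over roughly one lattice spacing around domain edges.
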
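# Methods

This note documents the models, numerical choices, and limitations behind
each stage of the pipeline, and what the synthetic-data tests do and do
not establish about real data.

## Grid and unit conventions

All fields live on regular grids indexed `[row, col]`; the physical
coordinate of node (i, j) is `origin + (j·Δ, i·Δ)` with grid spacing Δ in
µm (x along columns, y along rows). Every field carries a units tag
(`um/h`, `um`, `Pa`, `nN/um`) that operations propagate or reject;
mixing incompatible tags raises. Tractions are surface stresses in Pa;
monolayer stresses are line stresses in nN/µm (= mN/m) because monolayer
height is not measured — 1 nN/µm² = 1 kPa connects the two where needed.

## Velocimetry

Flow between consecutive frames is estimated either by iterative
Lucas–Kanade dense optical flow wrapped in a 3-level coarse-to-fine
pyramid (so displacements of several pixels stay within the linearization
range; plain iLK alone is accurate only for sub-window motions), or by
windowed cross-correlation (the DIC engine below). Both backends satisfy
one contract, checked on speckle textures: rigid translations up to 5 px
recovered within 0.2 px interior median error (measured ≈ 0.03 px for the
pyramidal iLK, ≈ 0.08–0.13 px for cross-correlation).

Trajectories are seeded on a square grid (default 30 µm, comparable to a
cell diameter, configurable) in the first frame and integrated with one
explicit Euler step per frame interval, `x_{t+1} = x_t + u_t(x_t)`, with
bilinear interpolation of the flow and the flow held constant within the
interval — the natural discretization at 6-min cadence. Trajectories
leaving the flow hull are clamped and flagged, never dropped.

Speed is path-based: the per-trajectory mean of per-interval displacement
magnitudes divided by the interval duration, converted to µm/h. The
net-displacement speed (|end − start| / total time) is reported as a
secondary column; the two differ for oscillatory motion, and the
path-based definition is the one that matches per-interval speed maps. A
field of view is *migratory* when its mean speed is ≥ 1.8 µm/h
(inclusive; the rule is recorded in output metadata) and *jammed*
otherwise.

## Cell shape

Each labelled cell's aspect ratio is the axis ratio of its
moment-equivalent ellipse: AR = √(λ₁/λ₂), where λ are the eigenvalues of
the pixel-coordinate covariance with the uniform-pixel correction
(+1/12 on each diagonal term). The correction makes an axis-aligned W×H
pixel rectangle measure exactly W/H and keeps AR stable for thin or small
regions; the definition is rotation invariant and pixel-size free.
Default field-of-view filters: border-touching cells dropped, labels
below 20 px skipped, cells above the 99.5th area percentile dropped
(segmentation-artifact suppression). These filters are declared choices —
the measurement convention of the upstream ROI tools does not specify
them.

## Traction force microscopy

**DIC.** Windowed (default 32 px, step 16 px) cross-correlation between
the loaded bead image and the trypsin-released reference. Windows are
zero-meaned and Hann-apodized before upsampled-DFT phase correlation
(subpixel factor 1/100 px); without apodization, circular-correlation
edge leakage biases fractional shifts by ~0.1 px. Window quality is the
registration error mapped to [0, 1]; windows below `q_min` (default 0.2)
or textureless are inpainted by the median of valid neighbours. Stage
drift is removed by subtracting the median displacement over cell-free
nodes (outside 1.2× the island radius).

**Elastic kernel.** In Fourier space, surface displacement responds to
surface traction through a 2×2 tensor split along the unit wavevector
k̂ (longitudinal) and its perpendicular (transverse):

    Ĝ(k) = 2(1+ν)/(E·k) · [ c_T(kh)·(I − k̂k̂ᵀ) + (1−ν)·c_L(kh, ν)·k̂k̂ᵀ ]

For a layer of thickness h bonded to a rigid base, the transverse factor
is the exact antiplane solution c_T = tanh(kh), and the longitudinal
factor is the exact plane-strain layer solution with zero normal surface
traction,

    c_L(κ, ν) = [2κ + (3−4ν)·sinh 2κ] /
                [(3−4ν)·cosh 2κ + 2κ² + 8ν² − 12ν + 5],   κ = kh,

derived symbolically from the biharmonic layer problem (clamped base,
tangential surface load) and frozen here in closed form. Both factors → 1
as kh → ∞ (Boussinesq half-space, ratio within 1% for kh ≥ 10, monotone),
and the small-kh limit reproduces thin-layer shear lag u = 2(1+ν)hT/E.
Normal–tangential coupling is neglected, as is standard for 2D TFM.
Substrate defaults: E = 4.8 kPa, h = 100 µm; ν = 0.49 (near-incompressible
polyacrylamide; the gel's Poisson ratio is a configurable assumption, not
a measurement). An alternative stiffness of 4.6 kPa is selectable via
config where that characterization is preferred.

**FTTC.** Unconstrained per-wavevector inversion T̂ = Ĝ⁻¹û: no
regularization penalty; noise control only through DIC window averaging
and an optional hard spectral cutoff (the pipeline default removes
wavelengths shorter than twice the DIC window). The k = 0 mode is set to
zero (zero net force). Fields are zero-padded 2× before the FFT; the
pipeline additionally cosine-tapers the field border (5%) against
periodicity artifacts, while the bare operators stay taper-free so that
inverse∘forward is exact to rounding on a common grid. The island fixture
is generated on a grid spanning 4R (the island occupies half the span),
which is the forward model's own requirement that the traction support be
zero-padded to at least twice the island extent; with tighter framing the
displacement tails truncated by the crop dominate the round-trip error.

## Monolayer stress microscopy

Force balance on the cell sheet, ∂ⱼσᵢⱼ = Tᵢ in the island Ω with σ·n = 0
on ∂Ω, closed by modelling the sheet as a plane-stress elastic medium
with unit fictitious modulus and Poisson ratio ν_m, loaded by −T. The
recovered stress is exactly independent of the fictitious modulus (it
cancels between the solve and the constitutive evaluation).

The closure parameter matters more than is sometimes assumed: for the
parabolic-tension disk the continuum closure solution is

    σ̄(r)/σ₀ = (3+ν_m)/4 − (1+ν_m)/2 · (r/R)²,

so ν_m = 0.5 underestimates the centre tension by 12.5% of σ₀, while the
closure reproduces σ₀(1 − r²/R²) exactly only in the two-dimensional
incompressible limit ν_m → 1 (for a 2D sheet, area preservation means
ν₂D = 1, not 0.5; exactly 1 is singular in plane stress). The default is
therefore ν_m = 0.9, configurable. The *median* tension over the disk is
(2/4)σ₀ = σ₀/2 independent of ν_m — the reported median is insensitive to
the closure, and the ν-sensitivity bound (medians for ν_m ∈ {0.3, 0.5}
within 5%) is regression-tested.

Discretization: bilinear quadrilateral finite elements on the traction
grid (elements fully inside Ω), consistent bilinear body-force loads,
rigid modes removed by zero-mean translation/rotation constraints
(admissible after the net force/torque projection below). Nodal stresses
come from patch recovery: interior nodes average their four adjacent
element-centre stresses (the symmetric-patch linear fit); boundary nodes
fit a linear polynomial over element centres within two cells.

Tractions whose best-fit uniform + rigid-rotation component exceeds 5% of
their total magnitude are refused; smaller imbalances are projected out
and the correction magnitude recorded.

Diagnostics: the equilibrium residual is the relative L2 mismatch of
centred-difference div σ against T, evaluated ≥ 3 cells inside ∂Ω — at
the edge the input traction is discontinuous and the recovery one-sided,
so a centred-difference check of a weak-form solution is not meaningful
there. The free-boundary residual is the RMS of |σ·n| over boundary
nodes (normals from a Gaussian-smoothed mask, σ = 2 cells, to average the
staircase) relative to the median interior tension; it is a pure
discretization scale, ≈ 1.4% of the median at 7.8 µm cells and ≈ 0.85%
at 3.9 µm cells on the 1-mm disk. Accuracy checks against the analytic
disk therefore run on a 512² grid (≈ 50 s on one CPU); routine analyses
use 256².

## Collective metrics

The spatial autocorrelation of a scalar field over Ω is pairwise:
C(r) = ⟨δf(x)·δf(x′)⟩ / var(f) over node pairs with |x − x′| in bins one
grid spacing wide (C(0) ≡ 1 from self-pairs). All pairs are used up to
2×10⁶; beyond that a fixed-seed random subsample keeps the estimator
reproducible. The correlation length L₅₀ is the first downward crossing
of C = 0.5, linearly interpolated — a direct reading of the 50%-decay
definition, not a fit — and is reported as "not reached" when the curve
stays above 0.5.

Packs are connected components of the alignment graph: nodes at or above
the speed threshold (default 1.8 µm/h, reusing the migratory threshold),
4-neighbour edges where velocity directions differ by ≤ 45° (both
configurable, both recorded in outputs). Pack area is node count ×
cell area, with node count reported alongside. Mean pack size is
guaranteed monotone in the alignment angle and grows with the velocity
field's correlation length; it is *not* monotone in the speed threshold
(removing small packs can raise the mean) — the monotone quantity there
is the total coordinated area, which is what the tests assert.

## Statistics

Fold changes: band/GAPDH per lane, divided by the mean ratio of the
reference group (the non-asthma or unprimed control group at the earliest
differentiation day), making the reference group's mean fold 1 by
construction. Spearman correlation uses average ranks; p-values are exact
(full permutation distribution) for n ≤ 9 and the large-sample t
approximation otherwise. t tests are Student two-sided, two-sample or
paired. No multiple-testing correction is applied across days — tests are
reported per day, and the report manifest says so. Biological replicates
are averaged before donor-level testing, making the donor the unit of
analysis.

## Synthetic data: what it shows and what it does not

The generators emulate the *geometry and signal structure* of the real
assays — speckle statistics of bead images, persistent advected texture
of a migrating monolayer, exponential-covariance tension fields,
anisotropic polygonal cell mosaics, and a contractile island whose
traction and stress are known in closed form (net force and torque vanish
by symmetry; div σ = T holds exactly since the profile is quadratic).
Speed schedules are imposed via cumulative warps of a fixed texture, so
the spatial-mean interval speed equals the schedule by construction.

They do not emulate phase-contrast optics, segmentation errors, cell
division/extrusion, bead detachment, out-of-plane displacements, or
non-stationary illumination. Passing tests establish that the estimators
are correct and well-calibrated on their model classes; accuracy on real
images also depends on those unmodelled effects, which is why the DIC
quality map, drift correction, and residual diagnostics are part of every
pipeline output.

Default study conditions mirror the imaging protocol the pipeline is
built for: 0.65 µm pixels, 6-min frame intervals over 4 h (41 frames),
1-mm collagen islands on 4.8 kPa, 100-µm gels with 0.5 µm beads at
sub-resolution density (PSF σ = 1 px).

## Known limitations

- The FTTC inverse is unregularized by design; with very noisy
  displacements the spectral cutoff is the only guard, and median |T| is
  the recommended robust summary (inflation < 15% at displacement SNR 10
  on the disk fixture, regression-tested).
- MSM assumes a simply connected island and an isotropic, homogeneous
  closure; holes, tears, or strong anisotropy violate the model.
- The pack definition (threshold + alignment graph) is one reasonable
  formalization of "coordinated packs"; parameter choices shift absolute
  sizes, so packs should be compared across conditions at fixed
  parameters, which the outputs record.
- Euler trajectory integration is first-order; at 6-min cadence and
  ≤ 6 µm/h speeds the step error is far below the flow-estimation error,
  but faster motions would warrant sub-stepping.
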
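# Methods

This note documents the models behind `beadmodes`, the parameters that
matter, the numerical choices, and what the synthetic fixtures do and do not
demonstrate.

## Scattering-profile analysis

**Units.** All lengths are ångström and momentum transfer is reciprocal
ångström throughout the library; profiles recorded in nm⁻¹ are divided by 10
at the file boundary.  Intensities are arbitrary units; every reported
statistic is invariant under rescaling of *I* (and σ) by a positive constant.

**Uncertainties.** When a profile carries no σ column, a 1% relative
uncertainty (σ = 0.01·|I|) is assumed and every result is flagged
`sigma_assumed`.  Unit absolute weights would make χ² depend on the arbitrary
intensity scale; relative weights keep all χ² quantities scale-free, at the
cost of an arbitrary overall χ² normalisation for σ-less data (only *ratios*
and convergence behaviour are then meaningful).

**Guinier fit.** Weighted linear least squares of ln *I* against *q²*,
weights (I/σ)².  The window is found self-consistently: start from the first
20 usable points, fit, recompute *Rg*, keep the points with
*q·Rg* ≤ `qrg_limit` (default 1.0), repeat to a fixed point; a 2-cycle
between adjacent windows resolves to the smaller one, then shrinks until the
final *Rg* keeps every retained point inside the limit.  At least 5 points
are required; a non-negative slope is an error.  Note that for elongated
particles the Guinier approximation at *q·Rg* ≤ 1 is systematically biased:
on the packaged bent-rod / rod / rod-plus-lobe fixtures the noise-free bias
is −2.7%, −3.1% and −4.0% respectively.  This is a property of the method at
this window, not of the implementation; recovery tests on elongated shapes
therefore use a 5% band, while sphere-like fixtures recover well under 1%.

**Indirect Fourier transform.** P(r) is represented on an `n_r`-point grid
(default 101) with both endpoints pinned to zero, and obtained by
non-negative least squares on

    I(q) = 4π Σⱼ P(rⱼ) · sinc(q·rⱼ) · Δr

with a Tikhonov penalty of weight α on second differences of P (computed
against the zero-padded endpoints, so a pile-up against either end is
penalised).  χ² is reported as the mean squared weighted residual.

*Choice of α ("auto").* A wide geometric grid of α is scanned; the corner of
the L-curve is located as the **residual-plateau transition** — the largest α
whose χ² stays within 10% of the best achieved, with an absolute floor of 0.1
so noise-free curves admit their smooth solutions.  Pointwise curvature of
(log ρ, log η) proved numerically erratic on the non-negative solution path,
so the plateau rule is used as the corner estimator; it is deterministic and
reproduces the visually obvious corner on all packaged cases.

*Dmax scan.* Candidates form a descending geometric grid from 1.5× an anchor
estimate (3.5·Rg from a Guinier fit, capped at π/q_min) down to 0.4×; the
smallest candidate whose χ² is within 5% of the minimum is chosen, to step
off the monotone-χ² plateau that otherwise overestimates Dmax.  **Limitation:**
at the fixtures' constant noise of 1% of I(0), χ² is nearly flat for any
support above ~0.85 × the true Dmax (truncating the rod fixture's P(r) from
182 Å to 162 Å costs 0.0007 in per-point χ² against a noise floor of 1), so
the scan typically lands 10–20% low on elongated shapes.  Maximum dimensions
from noisy data should be read as soft lower-bound estimates — a well-known
property of Dmax determination generally, made explicit here.

*Point-bead self term.* The Debye curve of N point beads contains a flat
self-scattering term (+N) that a P(r) vanishing at r = 0 cannot represent.
For many-bead models it is O(1/N) of I(0) and irrelevant; for few-bead
didactic cases subtract it as a constant background before transforming.

**Model-vs-data fit.** Scale and background minimise Σ((c·I_m + b − I_d)/σ)²
in closed form via the 2×2 normal equations; the model is linearly
interpolated onto the data grid, points outside the model's q range are
dropped, and χ² is reduced by N − 2 degrees of freedom.

## Bead models and the Debye formula

Envelopes are ordered sets of identical beads (common radius).  The forward
curve is the exact O(N²) Debye pair sum; above two million pairs the
distances are binned into a 2¹⁷-bin histogram first, an approximation below
1e-5 relative at SAXS momentum transfers.  The optional bead form factor is
the uniform-sphere amplitude 3(sin x − x cos x)/x³.  `model_geometry` treats
beads as points for *Rg* (consistent with point-bead Debye curves) and adds
one bead diameter to the maximum centre separation for *Dmax*.

**Lattice resampling** anchors a cubic lattice at the envelope centroid and
keeps lattice points within `bead_radius + spacing/2` of any source centre —
the extra half-spacing keeps thin regions connected at coarse spacings, at
the price of a one-cell halo around the envelope.  Beads are ordered
lexicographically by lattice index (z, then y, then x) so bead numbering is
reproducible.  "auto" spacing bisects to a target bead count within 5%
(ties resolved toward smaller spacing); the bisection assumes the count
decreases with spacing, which holds for all solid envelopes.

## Elastic network model

Identical springs (γ, default 1) connect beads within
`cutoff_factor × spacing`; the default factor 1.6 is the geometric midpoint
of the √2–√3 window, spanning nearest and second-nearest cubic-lattice
neighbours while excluding third-nearest.  Masses are uniform (envelope beads
are featureless), so mass weighting is a constant absorbed into γ.  The
Hessian carries off-diagonal blocks −(γ/r²)·d⊗d and negative row-sum
diagonal blocks; it is symmetrised exactly after assembly and diagonalised
densely (`scipy.linalg.eigh`).

Eigenvalues below 1e-8 of the largest are zero modes: six for any connected
non-collinear network (three translations, three rotations).  Collinear
networks are degenerate — a distance-only Hessian has *no* transverse
stiffness, so a 3-bead collinear chain has seven zero modes, not the five of
a generic rigid body; the axial spectrum is the textbook {0, 1, 3}·γ.
"Mode k" everywhere means the k-th non-zero mode in ascending eigenvalue
order.  Degenerate eigenpairs keep solver order; only quantities invariant
to rotations within a degenerate subspace (RMSF, full-subset trajectories)
are asserted in tests.

**RMSF.** RMSF_i = T·√(Σ_k |u_k[i]|²/ω_k²) over the requested subset
(default modes 1–6, the motions that dominate because amplitudes scale as
1/ω).  Internal units set kT/γ = 1; the absolute ångström scale of an
envelope network is not determined by the envelope (γ and temperature are
unknown), so `temperature_scale` is an explicit global multiplier and every
comparison in the mobility module is normalised to be scale-free.  Relative
profiles, not absolute values, are the supported readout.

**Trajectories.** The combined-mode movie gives mode k′ amplitude scale/ω_k′
(rule "inverse_frequency"; "equal" available) and k′ full cycles per
trajectory period — distinct integer harmonics, so the trajectory is
periodic, frame 0 is the equilibrium, and by discrete orthogonality of the
harmonics the time-averaged squared displacement equals ½Σ a_k²|u_k[i]|² per
bead, i.e. exactly the subset RMSF² profile.  (A common-frequency, in-phase
superposition would leave per-bead cross terms and break that equality.)
The default overall scale sets the peak displacement to 5% of Dmax.

## Mobility analysis

Regions are explicit 1-based index ranges over the reproducible lattice
numbering; published segmentations for the tropoelastin (168 beads),
fibrillin-fragment (127) and complex (226) envelopes ship as constants.
Pivot detection smooths the profile with a centred moving average (default
7 beads) and reports interior local minima, plateaus by their centre.  On
rod-like lattices the default window tracks per-layer minima (axis beads are
always locally stiffest — the "scrambling" regime); a window spanning ~3
lattice layers resolves beam-level pivots instead, which for a free rod sit
at the two free-free bending nodes 22.4% in from the ends — not at the
centre, a point worth remembering when reading pivot output.

**Stabilisation reports.** The component→complex bead mapping is always
explicit input (for the packaged fixture pair it is exact coordinate
identity, emitted by the generator); it is never inferred from shape, to
avoid silently wrong superpositions.  Each profile is normalised by its own
structure-wide mean RMSF before ratios are formed, removing the per-structure
amplitude arbitrariness; a mapped region is "stabilised" below 1 − threshold
and "mobilised" above 1 + threshold (default 0.2).  On the packaged rod vs
rod-plus-lobe pair the junction region is robustly stabilised (ratio ≈ 0.42
across lobe sizes 25–45 Å).  The free tip's ratio *exceeds* 1.2 at the
default 35 Å lobe: fusing a lobe onto one end lengthens the beam, and
clamped-free bending modes are softer than free-free ones, so the distal
tip's relative amplitude rises at equal γ.  That is correct physics, not an
artefact — the complex in the motivating system likewise keeps a highly
mobile extension while its base is quenched.

## Hydrodynamics

The Kirkwood double-sum Rh is exact for one bead and accurate to ~5–10% for
envelope-resolution assemblies (verified to 8% against the Stokes radius of
a bead-shell sphere); no Oseen/Rotne–Prager tensor inversion is attempted.
Solvent defaults are water at 20 °C (η = 1.002 mPa·s, ρ = 0.9982 g/ml);
v̄ defaults to 0.73 ml/g, the generic-protein value.  The sedimentation
chain is reported in Svedberg and nm; f/f₀ uses the equivalent compact
sphere of the given mass and v̄.  Forward estimates from envelopes support
*qualitative* comparison with measured s and Rh (orderings, elongation
ratios), not instrument-grade prediction — the bead radius of a resampled
lattice is a modelling choice, and hydration is not modelled.

## Synthetic fixtures

The generator fills analytic solids onto a lattice deterministically (no
randomness in shapes; seeds only drive profile noise).  The packaged
comparison pair shares one 9 Å lattice: a 180 × 15 Å cylinder (≈ 18 nm
elongated monomer, 189 beads — near the 168-bead envelope it emulates) and
the same cylinder with a 35 Å sphere on its +z end cap (404 beads); a bent
rod (150 Å arc, 14 Å radius, 40°, 155 beads) emulates the curved-fragment
shape.  Simulated profiles use q ∈ (0, 0.25] Å⁻¹ with 800 points (beamline-
like radial-binning density) and constant Gaussian noise σ = 1% of I(0).

What these fixtures demonstrate: unit and round-trip correctness of every
operation, closed-form limits, independence cross-checks (bio3d ANM,
complex-step Hessian, Monte-Carlo P(r), pseudo-inverse RMSF), and the
qualitative stabilisation/elongation signatures.  What they do not: real
SAXS error structure (counting statistics, buffer subtraction, smearing),
conformational flexibility, glycosylation mass, or the absolute RMSF scale
of any real molecule.  Passing tests therefore certify the machinery and its
physics at fixture scale, not agreement with any particular instrument
dataset; deposited experimental profiles can be dropped under `data/sasbdb/`
to run the corresponding benchmarks.

## Degenerate and edge inputs

Profiles must have strictly increasing positive q; rows with non-positive q
or non-finite I are dropped on read with a logged count.  Networks that
fragment at the chosen cutoff raise an error listing component sizes rather
than silently analysing a piece.  Constant mobility profiles export as
all-zero B-factors with a zero-slope sidecar so recovery still works.
Coincident bead centres are rejected at model construction (they would make
both the Hessian and the Kirkwood sum singular).
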
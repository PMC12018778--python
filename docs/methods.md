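# Methods

## Transport model

The model describes one isolated cylindrical root in an infinite,
homogeneous soil, reduced to a radial 1D domain from the root surface
(r = a) to R_out = 6 cm.  For each nutrient the pore-water concentration
c(r, t) (mol cm⁻³ solution) obeys

    (θ + b) ∂c/∂t = (1/r) ∂/∂r ( r De ∂c/∂r + a Jw(t) c ) − k M² − Q_rh

* **Sorption** is linear and instantaneous: the solid phase holds b·c per
  soil volume, so the factor (θ + b) buffers all storage terms and the
  dissolved pool per soil volume is θ·c.  Buffer powers are
  nutrient- and substrate-specific (loam: Ca 2, S 2, P 239; sand: Ca 0.3,
  S 0.35, P 41.3 — scaled from loam in proportion to clay content).
* **Diffusion** uses De = D·θ·f with impedance factor f = 0.3.
* **Advection** follows from water continuity: the flux density at radius r
  of water flowing toward the root is a·Jw(t)/r, where Jw(t) is the flux at
  the root surface.  Jw(t) = Jw_daily·(sin(2πt/24 − π/2) + 1) is zero at
  midnight and peaks at twice the daily mean at noon; the same Jw(t) enters
  the interior advection term and the root boundary condition, and t = 0 is
  midnight at simulation start.
* **Root uptake** is a Michaelis–Menten boundary flux at r = a:
  De ∂c/∂r + Jw c = Fm c/(Km + c).  At r = R_out the concentration is held
  at its initial pore-water value c_pw,ini = c_tot,ini/(θ + b); a
  closed (zero-total-flux) outer variant exists for conservation checks.
* **Gypsum precipitation** is a second-order irreversible sink k·M² with
  M = max(min(c_Ca − √Ksp, c_S − √Ksp), 0); it removes Ca and S in 1:1
  stoichiometry from their buffered pools (instantaneous re-equilibration
  through b) and feeds a per-node, immobile, non-decreasing precipitated
  pool.  Internally k = 33.33 cm³ mol⁻¹ s⁻¹ and Ksp = 2.4 × 10⁻¹¹
  mol² cm⁻⁶ (√Ksp = 4.9 mM).  Note that with the packaged initial pools
  both substrates start gypsum-supersaturated, so a spatially uniform
  precipitation transient runs everywhere until S reaches saturation; this
  shifts the far field and motivates the bulk-reference choice below.
* **Root hairs** are homogenized into a volumetric sink
  Q_rh = (L/l)(2π a_h/l²)·Fmh·c/(Kmh + c), active only within one mean hair
  length l_rh of the surface and only for t < 2 d (functional lifetime), and
  disabled entirely for the hairless *rth3* variant.  The inter-hair
  spacing in the packaged sets is l = sqrt(2π a_h/N) ≈ 39 μm.  The
  alternative geometric reading l = sqrt(2π a_root/N) (the side of the
  square of root surface area per hair) is available via
  `RootHairSpec.spacing_convention`; it weakens the sink by roughly two
  orders of magnitude, below the advective delivery rate, and therefore
  cannot produce the hair-driven surface depletion around thin tips in loam
  that the packaged convention yields.  Hair uptake is booked as uptake (not
  lost mass) so the balance closes.

All internal units are cm / s / mol; parameter files carry explicit unit
strings that are validated and converted on load (`rhizoextent.units`),
because the literature constants mix litre- and centimetre-based units.

## Discretization and numerics

Conservative finite volumes on a geometrically graded grid: first cell 5 μm
at the root, growth ratio 1.05, cell width capped at 0.04 cm (~220 cells to
6 cm).  Face fluxes use central interpolation for the advected concentration
(cell Péclet ≪ 1 at the prescribed fluxes) and two-point gradients for
diffusion.  Time integration is method-of-lines with SciPy's BDF, rtol 1e-8,
atol 1e-14 mol cm⁻³, max step 1 h (to resolve the diurnal cycle), and an
analytically prescribed Jacobian sparsity pattern; the Ca/S pair is advanced
as one coupled system (shared precipitation sink) with P solved separately
on the same grid.  The hair-lifetime gate is a genuine discontinuity, so
integration is split into legs at t = 2 d.  Cumulative root uptake, hair
uptake and outer-boundary influx are carried as extra ODE states, which
makes the mass-balance residual (domain pools + uptake − influx) an
independent diagnostic; it closes to ~1e-15 on the packaged scenarios and
must stay below 1e-3.  Michaelis–Menten arguments are clipped at zero;
final states are checked for concentrations above −1e-10 and then clipped.

A deliberately independent reference solver (`rhizoextent.reference`) —
node-centred finite differences in non-conservative form, ghost-node root
boundary, uniform 10-μm grid, explicit Euler — cross-checks single-nutrient
profiles; the production solver agrees to < 1 % L∞ on a one-day case with
hairs and advection.  Extents change by < 0.2 % under a 2× grid refinement.

## Model-side rhizosphere extent

The extent is the distance from the root surface over which the *mapped*
concentration — sorbed + precipitated for Ca and S, sorbed for P, matching
what a dehydrated element map images — deviates from bulk by more than
0.8 μmol cm⁻³ soil, evaluated at the final simulation time (7 or 21 d,
whole diurnal cycles).  Two choices were genuinely open:

* **Bulk reference.** The outer-boundary value equals the initial state by
  construction, but the supersaturation transient moves the true far field
  away from it (for sand S by more than the threshold), and the pinned
  boundary keeps precipitating in a rim layer that is a finite-domain
  artefact.  The bulk reference is therefore read off the evolved profile
  at r = 3 cm (outside all root-driven gradients, inside the rim), and the
  extent search is restricted to r ≤ 3 cm.  `bulk="initial"` restores the
  naive reading.
* **Crossing rule.**  Hairy-scenario profiles superpose a near-root
  accumulation peak on the depletion halo left by the 2-d hair mining, so
  the deviation can cross the threshold in detached excursions.  The
  default rule delimits the deviation zone contiguous with the root surface
  (equivalently: the outermost crossing of the surface-signed deviation),
  which keeps the extent monotone-ish in hair strength and matches the
  notion of "the area around the root" that deviates; detached excursions
  set a `multiple-crossings` flag, and `crossing="outermost"` returns the
  outermost absolute-deviation crossing instead.

Crossings are linearly interpolated between grid nodes and reported in μm.

## Element-map statistic

`distance_map` is the Euclidean distance transform of the binary root mask
scaled by the pixel size (20 μm default).  `radial_profile` bins evaluable
(non-root, non-pore) pixels into half-open [k·w, (k+1)·w) distance bins
(w = pixel size by default) and records per-bin mean, population SD and
pixel count; pore masking is uniform across elements by default, with the
per-element switch available since measured workflows sometimes mask pores
for Ca only.  `bulk_stats` takes the pixel-count-weighted mean and SD of the
bin means from 1 mm outward (frequency-weight convention, ∑w denominator).

`extent_estimate` finds where the profile re-enters the band
bulk ± max(2·SD, ε·|mean|) moving outward.  A ±2 SD band leaves ~5 % of
noisy bulk bins outside by construction, so a deterministic rule needs two
guards that replace the manual cut-off choice of interactive workflows: a
crossing is a candidate only if it terminates a sustained excursion
(≥ 3 out-of-band bins) and is followed by ≥ 5 in-band bins (or in-band to
the profile's end), and the cut-off is sought only below the 1-mm start of
the bulk region.  The chosen extent is the outermost such candidate; with
several candidates the estimate is flagged ambiguous, and a profile still
out of band at its end is flagged truncated.  Both run lengths and the
search cap are parameters.

## Synthetic maps

The generator emulates only the features that matter to the radial
statistic.  Sand: random sequential addition of grain discs (radius
±10 %, target solid fraction 0.50, safely below the RSA jamming limit);
the inter-grain space is the pore mask and imprints the undulating
solid-fraction profile characteristic of well-sorted substrates.  Loam: a
continuous fine matrix with sparse small pores and smooth multiplicative
texture.  Enrichment is deposited on non-pore pixels with an exponential or
step envelope of known extent E; a patchiness parameter concentrates it at
grain contacts (thin solid bridges) or texture patches while conserving the
injected total exactly.  Poisson sampling adds count noise.  Identical
recipe + seed give bit-identical maps.  The generator is a statistical
emulator, not an XRF forward model: no matrix effects, screening, detector
response, or registration errors, and real patchiness need not be
mass-conserving — so passing recovery tests demonstrate the statistic's
correctness on its stated assumptions, not robustness to every measurement
artefact.

## Problem sizes and defaults

The packaged matrix (12 scenarios × two ODE systems, ~220 cells, 7 or 21
simulated days) runs in well under a minute; the extent-recovery study uses
401×401-pixel maps (8 × 8 mm at 20 μm), 50 replicates per injected extent
E ∈ {150, 300, 500} μm with background 100 and amplitude 200 counts —
high signal-to-noise by design, since it validates the estimator rather
than explores its detection limit.

## Known limitations

* Continuum homogeneity: no pore-scale enrichment, no image-based pore
  geometry; observed gypsum hot-spots at grain contacts have no analogue in
  the 1D model (the generator produces them only statistically).
* Prescribed water flux (no root growth, no Richards flow, no
  genotype-specific water uptake); constant root radius; uptake parameters
  uniform along the root.
* No co-precipitation with other salts and no gypsum re-dissolution.
* The initial supersaturation transient is a genuine consequence of the
  packaged pools and rate law; extents measured against the evolved far
  field are insensitive to it, but absolute precipitated pools near the
  outer boundary are dominated by the Dirichlet rim artefact and should not
  be interpreted beyond r ≈ 3 cm.
* Extent endpoints that hinge on the balance between 2-d hair mining and
  subsequent advective refill are a small difference of large terms and
  react strongly to solver and mesh choices; comparisons across
  implementations should expect tens of per cent scatter there.
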
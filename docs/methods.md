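# Methods

## Electromagnetic model

**Coupled-dipole method.** Every silver sphere (radius a ≪ λ) is a point
electric dipole at its center with the full Mie electric-dipole
polarizability α = i 6π ε_amb a₁ / k³ (k the ambient wavenumber), which
contains retardation and radiative damping exactly. The 3N×3N linear system
couples each dipole to (i) the external field E_in — incident plane wave
plus its Fresnel reflection from the substrate, phase-referenced at the
substrate plane, (ii) every other dipole through the free-space dyadic
Green tensor plus its substrate-reflected counterpart, and (iii) its own
surface image. The system is solved by a direct dense solve; the relative
residual is stored on the solution and the solver refuses results with
residual > 1e-8 (reporting a condition-number diagnostic). At the problem
sizes used here (N ≤ a few hundred) the dense solve is exact to machine
precision and takes milliseconds.

**Conventions.** Time dependence exp(−iωt) (passive media: Im ε ≥ 0),
lengths in nm, substrate occupying z ≤ 0, a particle resting on the surface
at center height z = a (contact, no gap). Polarizabilities are volume
polarizabilities (nm³) with p = ε₀ α E; ε₀ is carried symbolically and
cancels from every reported field, so all intensities are in units of the
incident |E₀|² = 1.

**Substrate term.** The reflected Green tensor uses the image
approximation: free-space propagation from the mirrored source with the
image moment β·diag(−1,−1,+1)·p, β = (ε_s−ε_a)/(ε_s+ε_a). This is the
quasi-static limit of the exact half-space (Sommerfeld-integral) tensor and
is accurate for sub-wavelength source heights, which dominate here
(particle centers 20–25 nm above the surface, kz ≈ 0.25–0.3). The interface
is a clean function boundary, so an exact Sommerfeld backend can replace it
without touching the solver. The particle's free-space self-term is *not*
added: its radiative part is already inside the Mie a₁, and adding it again
would double-count radiation damping. The image self-term is finite (image
distance 2z) and diagonal in the surface frame.

One subtlety worth recording: the image *self-interaction* enhances both
the normal and (half as strongly) the in-plane effective polarizability —
the image field at the real dipole is parallel to it for both orientations.
The often-quoted "in-plane suppressed, normal doubled" statement describes
the *net radiating pair* (real + image moment: (1−β)p in-plane, (1+β)p
normal) and the boundary condition on the driving field (tangential E
suppressed, normal E doubled at a good conductor). Both effects are in the
model, and the second is what makes oblique TM illumination effective.

**Silver permittivity.** A Drude–Lorentz model (ε_inf + Drude + three
Lorentz oscillators) least-squares fitted to an embedded 25-point
Johnson–Christy silver tabulation (1.14–4.13 eV). The fit agrees with the
table at 532 nm to 1.4% (real part) and 0.2% (imaginary part); the table
interpolation is kept in the package as the independent oracle. Fit window
300–1100 nm; evaluation outside it warns rather than fails. The ambient is
vacuum by default (the idealized simulation setup); the
experiments run in buffer, so an ε = 1.77 water model is provided and every
function takes the ambient permittivity explicitly — a documented
divergence, not a hidden constant.

**Ensembles and evaluation.** Particle configurations come from seeded
rejection sampling (uniform radii in 20–25 nm, uniform centers in a
1000×1000 nm region, minimum surface gap 2 nm, hard attempt bound 1e5, area
feasibility pre-check at 55% disc coverage). Field maps are evaluated on
user grids; points inside particles are masked NaN with a warning rather
than extrapolated, because the point-dipole field is not valid there.
Enhancement is the pointwise ratio |E_total|²/|E_background|² with the
particle-free background computed on the same grid; points with ~zero
background (TM interference nulls) are excluded with a warning. The default
comparison (normal vs 65° TM, 532 nm, evaluation plane 60 nm above the
substrate, ≥30 particles of 40–50 nm diameter) reproduces the qualitative
directionality: the oblique-TM mean enhancement exceeds the
normal-incidence one for every seed tried, typically by ×1.3–1.4 with local
spots of ~10×.

## Spectral model

**Band library.** Four band sets (mitochondria / purified cytochrome c ×
oxidized / dithionite-reduced) with the published peak positions. Widths
(Lorentzian, FWHM 12 cm⁻¹ for all bands) and relative amplitudes are
*fixture constants*, not measured values: the positions are published, the
intensities are not, so amplitudes were chosen once to give the qualitative
ordering of recorded oxidized mitochondrial spectra (strong
748/1371/1585/1638 cm⁻¹) and a clearly increased 748 cm⁻¹ band in the
reduced state. They live as editable module constants.

**Generator.** A spectrum is Σ Lorentzians + cubic-spline background
through stated knot values + i.i.d. Gaussian noise on a uniform axis
(default 600–1800 cm⁻¹, 1 cm⁻¹ step). Mixtures are convex combinations
f·S_red + (1−f)·S_ox before background/noise. What it emulates: band
positions/shifts, relative-intensity changes with redox state, smooth
fluorescence-type backgrounds, detector noise. What it does not: shot
noise, cosmic-ray spikes, instrument response, peak-width changes with
environment, b-type cytochrome contributions, and any coupling between
enhancement physics and band intensities. Passing tests therefore validate
the *pipeline arithmetic* on realistic-shaped inputs, not instrument
behavior on real data.

**Baseline.** Cubic spline through knots at fixed x-positions (12 defaults
inside the band-free windows <640, 800–1100, 1200–1290, 1420–1520,
>1660 cm⁻¹); each knot ordinate is the mean of the 5 samples nearest the
knot (half_width = 2). The same knot x-positions are reused across a
spectrum set. With half_width = 0 the operator is an interpolating cubic
spline and reproduces any cubic polynomial exactly (residual < 1e-15
relative in practice); with the default 5-point averaging a curvature bias
of order |y″|·h² is accepted in exchange for noise robustness — on the
synthetic set the band-free residual stays below 2% of the peak height.

**Ratios and classification.** Peak intensities are max-in-window
(half-window 15 cm⁻¹, ties toward lower wavenumber), ratios normalized to
the ν₁₀ marker (1638 cm⁻¹ oxidized windows by default; reduced-state
windows recenter to the shifted marker positions 1356/1605, and the report
records which centers were used — the 1638→1605 shift spans 33 cm⁻¹, wider
than the window, so one window cannot serve both states). The reduced
fraction is estimated by non-negative least squares onto the two band-only
end-member spectra, normalized to sum to one; the state call is
oxidized/reduced/mixed by thirds of the fraction, with a low-confidence
flag when the marker peaks sit below 3× a robust (MAD) noise estimate.
At 3%-of-peak noise the estimate recovers the true fraction to ±0.05 on
average across the whole mixture grid.

**Treatment emulation.** Control replicates at reduced fraction 0.6 (a
partially reduced pool, as expected for a respiring chain supplied with
substrates), treatment shifts of ∓0.3 for the uncoupler / inhibitor
emulations, 10 replicates, 5%-of-amplitude noise, the default curved
background. These are generator settings defining the synthetic study
conditions, chosen once; only the *direction* of the resulting
percent-of-control changes is compared with experiment, since the published
treatment effects are graphical, not numeric.

## Problem sizes and determinism

Default analysis sizes: 30 particles (90 complex unknowns ×2
illuminations), 41×41 evaluation grids, 11-fraction × 10-replicate recovery
sweeps, 10-replicate treatment series — each driver runs in seconds on one
CPU. Every stochastic step flows from an explicit integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical ensembles,
spectra, tables and reports. Degenerate inputs fail loudly: infeasible
packings, points below the substrate, coincident Green-tensor arguments,
the Fröhlich pole of the quasi-static polarizability, non-positive ratio
denominators and undersized knot sets all raise typed exceptions.

## Known limitations

- The image-approximation substrate term omits retardation of the
  reflected interaction and all surface-plasmon-polariton physics; no
  quantitative field amplitudes are claimed, only robust qualitative
  contrasts (illumination directionality, height decay).
- Dipole-only particles: no multipoles, so near-touching particle gaps and
  particle–substrate junction hot spots are underresolved.
- The spectral amplitudes are fixtures; absolute ratio values carry no
  experimental meaning, only their trends with the reduced fraction do.
- Max-in-window peak metrics (no lineshape fitting) are faithful to the
  analysis recipe but sensitive to heavy band overlap outside the
  library's geometry.
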
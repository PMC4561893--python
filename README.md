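# cytosers

Coupled-dipole simulation of electric near fields above silver nanoparticle
layers on a silver substrate, together with a SERS (surface-enhanced Raman
spectroscopy) spectral pipeline for reading out the redox state of
cytochrome *c* in mitochondria.

## The problem

SERS on nanostructured silver surfaces can pick up the heme bands of
cytochrome *c* sitting 7–17 nm away from the metal — behind the outer
mitochondrial membrane and the intermembrane space — without any direct
protein–metal contact. Two questions follow:

1. **Physics.** Under what illumination does a layer of 40–50 nm silver
   nanoparticles on a silver substrate produce strong fields tens of
   nanometres *above* the particles? Each sub-wavelength particle is treated
   as a point dipole with a Mie polarizability; the dipole moments solve the
   coupled system

   p_i = ε₀ α_i [ E_in(r_i) + (k₀²/ε₀) Ĝ_s(r_i, r_i) p_i
        + (k₀²/ε₀) Σ_{j≠i} (Ĝ₀ + Ĝ_s)(r_i, r_j) p_j ],

   where E_in is the incident plane wave plus its Fresnel reflection,
   Ĝ₀ the free-space dyadic Green tensor and Ĝ_s the substrate term in the
   image approximation (image dipole scaled by β = (ε_s−ε_a)/(ε_s+ε_a),
   in-plane components flipped, normal component preserved). Total fields
   follow from E(r) = E_in(r) + (k₀²/ε₀) Σ_i Ĝ(r, r_i) p_i.

2. **Spectroscopy.** Given SERS spectra, how is the redox state of the
   cytochrome pool quantified? The pipeline subtracts a cubic-spline
   baseline anchored at knots in band-free windows (knot ordinates are
   5-point neighborhood averages), measures max-in-window peak intensities,
   and forms the ratios I₇₄₈/I₁₆₃₈, I₁₁₇₀/I₁₆₃₈ and I₁₃₇₁/I₁₆₃₈. Marker
   bands shift with the heme-iron redox state (ν₄: 1371 → 1356 cm⁻¹;
   ν₁₀: 1638 → 1605 cm⁻¹; the 748 cm⁻¹ band grows on reduction), and a
   non-negative projection onto oxidized/reduced end-member spectra
   estimates the reduced fraction.

A synthetic-spectrum generator (Lorentzian bands + spline background +
Gaussian noise, two-state redox mixtures) emulates the experiments,
including treatments that shift the reduced fraction down (protonophore
uncoupler, e.g. FCCP) or up (ATP-synthase inhibitor, e.g. oligomycin).

## Worked example

```bash
python analysis/01_simulate_near_field.py --seed 0
```

```
Mean / max |E|^2 enhancement at the 60 nm plane
  normal incidence : 1.031 / 1.60
  65-deg TM        : 1.402 / 9.94
  TM/normal mean-enhancement ratio: 1.361
```

Under normal incidence the near field above the layer is nearly the bare
background (mean enhancement 1.03): the in-plane induced dipoles are
quenched by their antiparallel images. Under 65° TM illumination the normal
dipole components are driven and image-reinforced, and the same ensemble
shows up to ~10× intensity spots at the 60 nm evaluation plane. The height
profile written alongside decays smoothly over the 7–17 nm analyte band
(mean |E|² 2.38 → 2.06), so an analyte held ~7 nm off the particles still
sits in an enhanced field.

```bash
python analysis/04_treatment_response.py --seed 0
```

```
uncoupler (delta f_red = -0.3): percent of control r748 = 49.8%, r1170 = 56.2%, r1371 = 58.9%
inhibitor (delta f_red = +0.3): percent of control r748 = 238.3%, r1170 = 202.6%, r1371 = 278.9%
```

All three ratios fall below 100% of control when the pool oxidizes and the
redox-marker ratios rise above 100% when it reduces — the directions the
band assignments predict. `analysis/02_synthesize_spectra.py` and
`analysis/03_redox_recovery.py` generate the synthetic spectrum sets and
quantify reduced-fraction recovery (±0.05 at 3% noise across the full
mixture grid).

The same workflows are available as a CLI
(`cytosers simulate-field|synth-spectra|analyze-spectra|treatment-sim
--config cfg.yaml --seed 1 --out DIR`).

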
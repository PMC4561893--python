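"""Coupled-dipole model of nanoparticle ensembles on a metal substrate.

Each sub-wavelength sphere is a point electric dipole with a Mie
polarizability.  The dipole moments solve

    p_i = eps0 a_i [ E_in(r_i) + (k0^2/eps0) G_s(r_i, r_i) p_i
                     + (k0^2/eps0) sum_{j != i} (G0 + G_s)(r_i, r_j) p_j ]

where E_in is the incident plane wave plus its Fresnel reflection from the
substrate, G0 the free-space dyadic Green tensor and G_s the image
(substrate-reflected) tensor.  Total fields outside the particles follow from

    E(r) = E_in(r) + (k0^2/eps0) sum_i [G0 + G_s](r, r_i) p_i.

All fields are normalized to unit incident amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .exceptions import GeometryError, InvalidInputError, PackingError, SolverError
from .green import free_space_green, image_factor, surface_self_term, total_green
from .materials import (
    SILVER,
    OpticalConstants,
    fresnel_reflection,
    mie_dipole_polarizability,
    permittivity,
)

__all__ = [
    "Particle",
    "Ensemble",
    "PlaneWave",
    "DipoleSolution",
    "FieldGrid",
    "EnhancementSummary",
    "generate_ensemble",
    "external_field",
    "solve_dipoles",
    "total_field",
    "enhancement_summary",
    "field_vs_height",
]

_MIRROR = np.diag([-1.0, -1.0, 1.0])


@dataclass(frozen=True)
class Particle:
    """Sphere resting above the substrate; center in nm."""

    center: tuple
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidInputError("particle radius must be positive")
        if self.center[2] < self.radius:
            raise GeometryError("particle interpenetrates the substrate (z < radius)")


@dataclass(frozen=True)
class PlaneWave:
    """Illumination: wavelength nm, incidence angle (deg from normal), TM/TE."""

    wavelength: float = 532.0
    incidence_angle: float = 0.0
    polarization: str = "TM"
    amplitude: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.incidence_angle < 90.0:
            raise InvalidInputError("incidence angle must satisfy 0 <= angle < 90")
        if self.polarization.upper() not in ("TM", "TE"):
            raise InvalidInputError("polarization must be 'TM' or 'TE'")


@dataclass(frozen=True)
class Ensemble:
    """Nanoparticle configuration plus the optical constants of the setup."""

    particles: tuple
    optics: OpticalConstants
    rng_seed: int = 0
    region: tuple = None  # (Lx, Ly) nm, lateral extent used for field averaging
    eps_particle: complex = None

    def __post_init__(self):
        if self.eps_particle is None:
            object.__setattr__(
                self, "eps_particle", permittivity(SILVER, self.optics.wavelength)
            )
        pts = np.array([p.center for p in self.particles], dtype=float)
        rad = np.array([p.radius for p in self.particles], dtype=float)
        for i in range(len(rad)):
            d = np.linalg.norm(pts[i + 1:] - pts[i], axis=1)
            if np.any(d < rad[i + 1:] + rad[i] - 1e-9):
                raise GeometryError("particles overlap")

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.particles], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([p.radius for p in self.particles], dtype=float)


@dataclass(frozen=True)
class DipoleSolution:
    """Solved dipole moments (N, 3) and the relative residual of the system."""

    moments: np.ndarray
    residual_norm: float
    wave: PlaneWave


@dataclass(frozen=True)
class FieldGrid:
    """Evaluated total field on a point set; intensity normalized to |E0|^2 = 1."""

    points: np.ndarray
    field: np.ndarray
    intensity: np.ndarray


@dataclass(frozen=True)
class EnhancementSummary:
    mean_enhancement: float
    max_enhancement: float
    n_points: int
    n_excluded: int = 0


def generate_ensemble(n: int, radius_range=(20.0, 25.0), region=(1000.0, 1000.0),
                      min_gap: float = 2.0, seed: int = 0,
                      optics: OpticalConstants = None,
                      max_attempts: int = 100_000) -> Ensemble:
    """Seeded rejection sampling of non-overlapping spheres resting on the substrate.

    Radii uniform in ``radius_range``, centers uniform in ``region``, z = radius
    (contact, no gap).  Identical seed -> identical ensemble.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rmin, rmax = radius_range
    if not 0 < rmin <= rmax:
        raise InvalidInputError("radius_range must satisfy 0 < rmin <= rmax")
    Lx, Ly = region
    # area feasibility: random sequential adsorption stalls well below ~55% disc coverage
    if n * np.pi * (rmax + min_gap / 2.0) ** 2 > 0.55 * Lx * Ly:
        raise PackingError(
            f"{n} discs of radius <= {rmax + min_gap / 2:.1f} nm cannot pack into "
            f"{Lx:.0f} x {Ly:.0f} nm"
        )
    rng = np.random.default_rng(seed)
    placed = []  # (x, y, r)
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise PackingError(f"placement failed after {max_attempts} attempts")
        attempts += 1
        r = rng.uniform(rmin, rmax)
        x = rng.uniform(0.0, Lx)
        y = rng.uniform(0.0, Ly)
        ok = True
        for (x2, y2, r2) in placed:
            if (x - x2) ** 2 + (y - y2) ** 2 < (r + r2 + min_gap) ** 2:
                ok = False
                break
        if ok:
            placed.append((x, y, r))
    particles = tuple(Particle((x, y, r), r) for (x, y, r) in placed)
    if optics is None:
        optics = OpticalConstants(wavelength=532.0)
    return Ensemble(particles=particles, optics=optics, rng_seed=seed, region=(Lx, Ly))


def _external_field_many(points: np.ndarray, wave: PlaneWave,
                         optics: OpticalConstants) -> np.ndarray:
    """Incident + Fresnel-reflected plane wave at many points, (M, 3) complex."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(points[:, 2] < 0):
        raise GeometryError("external field defined for z >= 0 only")
    th = np.deg2rad(wave.incidence_angle)
    k = optics.k_ambient
    pol = wave.polarization.upper()
    rcoef = fresnel_reflection(
        wave.incidence_angle, pol, optics.eps_ambient, optics.eps_substrate
    )
    kx = k * np.sin(th)
    kz = k * np.cos(th)
    # phase reference at the origin on the substrate plane
    ph_inc = np.exp(1j * (kx * points[:, 0] - kz * points[:, 2]))
    ph_ref = np.exp(1j * (kx * points[:, 0] + kz * points[:, 2]))
    if pol == "TE":
        e_inc = np.array([0.0, 1.0, 0.0])
        e_ref = np.array([0.0, 1.0, 0.0])
    else:
        e_inc = np.array([np.cos(th), 0.0, np.sin(th)])
        e_ref = np.array([-np.cos(th), 0.0, np.sin(th)])
    E = wave.amplitude * (
        ph_inc[:, None] * e_inc[None, :] + rcoef * ph_ref[:, None] * e_ref[None, :]
    )
    return E


def external_field(r, wave: PlaneWave, optics: OpticalConstants) -> np.ndarray:
    """Superposition of incident and substrate-reflected plane waves at one point."""
    return _external_field_many(np.asarray(r, dtype=float)[None, :], wave, optics)[0]


def _polarizabilities(ensemble: Ensemble) -> np.ndarray:
    lam = ensemble.optics.wavelength
    ea = ensemble.optics.eps_ambient
    ep = ensemble.eps_particle
    return np.array(
        [mie_dipole_polarizability(p.radius, lam, ep, ea) for p in ensemble.particles]
    )


def solve_dipoles(ensemble: Ensemble, wave: PlaneWave) -> DipoleSolution:
    """Direct dense solve of the 3N x 3N coupled-dipole system."""
    optics = ensemble.optics
    if abs(wave.wavelength - optics.wavelength) > 1e-9:
        raise InvalidInputError(
            "plane-wave wavelength differs from the ensemble's optical constants"
        )
    centers = ensemble.centers
    N = len(ensemble.particles)
    alphas = _polarizabilities(ensemble)
    k = optics.k_ambient
    k0 = optics.k0
    ea, es = optics.eps_ambient, optics.eps_substrate

    A = np.zeros((3 * N, 3 * N), dtype=complex)
    for i in range(N):
        sl_i = slice(3 * i, 3 * i + 3)
        Gs_ii = surface_self_term(centers[i], k, ea, es)
        A[sl_i, sl_i] = np.eye(3) - alphas[i] * k0**2 * Gs_ii
        for j in range(N):
            if j == i:
                continue
            Gij = total_green(centers[i], centers[j], k, ea, es)
            A[sl_i, 3 * j:3 * j + 3] = -alphas[i] * k0**2 * Gij

    E_in = _external_field_many(centers, wave, optics)
    b = (optics.eps0 * alphas[:, None] * E_in).reshape(-1)
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SolverError(
            f"singular coupled-dipole system (cond ~ {np.linalg.cond(A):.3e})"
        ) from exc
    scale = np.linalg.norm(b)
    residual = np.linalg.norm(A @ x - b) / scale if scale > 0 else np.linalg.norm(A @ x)
    if not np.isfinite(residual) or residual > 1e-8:
        raise SolverError(
            f"untrustworthy solve: relative residual {residual:.3e}, "
            f"cond ~ {np.linalg.cond(A):.3e}"
        )
    return DipoleSolution(moments=x.reshape(N, 3), residual_norm=float(residual), wave=wave)


def _green_many(points: np.ndarray, src: np.ndarray, k: complex) -> np.ndarray:
    """Free-space dyadic Green tensor from one source to many points, (M, 3, 3)."""
    dr = points - src[None, :]
    R = np.linalg.norm(dr, axis=1)
    # points coincident with a source sit inside that particle and are
    # masked downstream; silence the benign 0/0 here
    with np.errstate(divide="ignore", invalid="ignore"):
        n = dr / R[:, None]
        kR = k * R
        expf = np.exp(1j * kR) / (4.0 * np.pi * R)
        Afac = 1.0 + (1j * kR - 1.0) / kR**2
        Bfac = (3.0 - 3.0j * kR - kR**2) / kR**2
    eye = np.eye(3)[None, :, :]
    nn = n[:, :, None] * n[:, None, :]
    return expf[:, None, None] * (Afac[:, None, None] * eye + Bfac[:, None, None] * nn)


def total_field(ensemble: Ensemble, solution: DipoleSolution, points) -> FieldGrid:
    """Evaluate E_in + scattered field of all dipoles (and images) on a point set.

    Points inside any particle are masked to NaN with a warning: the
    point-dipole field is not valid there.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    optics = ensemble.optics
    k = optics.k_ambient
    k0 = optics.k0
    beta = image_factor(optics.eps_ambient, optics.eps_substrate)

    E = _external_field_many(points, solution.wave, optics)
    pref = k0**2 / optics.eps0
    for center, p in zip(ensemble.centers, solution.moments):
        G0 = _green_many(points, center, k)
        E = E + pref * np.einsum("mab,b->ma", G0, p)
        if beta != 0.0:
            img = center * np.array([1.0, 1.0, -1.0])
            Gs = beta * _green_many(points, img, k) @ _MIRROR
            E = E + pref * np.einsum("mab,b->ma", Gs, p)

    inside = np.zeros(len(points), dtype=bool)
    for center, radius in zip(ensemble.centers, ensemble.radii):
        inside |= np.linalg.norm(points - center[None, :], axis=1) < radius
    if inside.any():
        warnings.warn(
            f"{int(inside.sum())} evaluation points inside particles masked to NaN",
            stacklevel=2,
        )
        E[inside] = np.nan
    intensity = np.sum(np.abs(E) ** 2, axis=1)
    return FieldGrid(points=points, field=E, intensity=intensity)


def enhancement_summary(grid: FieldGrid, background: FieldGrid) -> EnhancementSummary:
    """Pointwise |E_total|^2 / |E_background|^2 statistics over a shared point set."""
    if grid.points.shape != background.points.shape or not np.allclose(
        grid.points, background.points
    ):
        raise InvalidInputError("grids must share an identical point set")
    num = grid.intensity
    den = background.intensity
    valid = np.isfinite(num) & np.isfinite(den)
    nonzero = den > 1e-12 * np.nanmax(den)
    excluded = int(np.sum(valid & ~nonzero))
    if excluded:
        warnings.warn(
            f"{excluded} points with ~zero background intensity excluded", stacklevel=2
        )
    use = valid & nonzero
    if not use.any():
        raise InvalidInputError("no valid points for enhancement statistics")
    ratio = num[use] / den[use]
    return EnhancementSummary(
        mean_enhancement=float(np.mean(ratio)),
        max_enhancement=float(np.max(ratio)),
        n_points=int(use.sum()),
        n_excluded=excluded,
    )


def field_vs_height(ensemble: Ensemble, solution: DipoleSolution, heights,
                    nx: int = 21, ny: int = 21) -> pd.DataFrame:
    """Laterally averaged intensity at heights above the top of the particle layer.

    Heights are measured from the highest particle apex; supports probing the
    7-17 nm analyte band (membrane + intermembrane space of a mitochondrion
    resting on the nanostructure).
    """
    heights = np.asarray(heights, dtype=float)
    if np.any(heights < 0):
        raise InvalidInputError("heights must be >= 0")
    if ensemble.region is None:
        raise InvalidInputError("ensemble has no lateral region to average over")
    Lx, Ly = ensemble.region
    z_top = float(np.max(ensemble.centers[:, 2] + ensemble.radii))
    xs = np.linspace(0.0, Lx, nx)
    ys = np.linspace(0.0, Ly, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rows = []
    for h in heights:
        pts = np.column_stack(
            [X.ravel(), Y.ravel(), np.full(X.size, z_top + h)]
        )
        grid = total_field(ensemble, solution, pts)
        rows.append((float(h), float(np.nanmean(grid.intensity))))
    return pd.DataFrame(rows, columns=["height", "mean_intensity"])
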
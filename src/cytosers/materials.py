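"""Optical material models: permittivities, Fresnel coefficients, sphere polarizabilities.

Conventions used throughout the package
---------------------------------------
* Time dependence exp(-i omega t), so passive media have Im(eps) >= 0 and
  decaying waves have Im(k) >= 0.
* Lengths in nanometres; wavenumbers in rad/nm.
* Polarizabilities are *volume* polarizabilities (nm^3) defined so that the
  induced dipole moment is p = eps0 * alpha * E.  With this convention every
  field the package reports is independent of the numeric value of eps0.
* Fields are normalized to unit incident amplitude |E0| = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from .exceptions import InvalidInputError, SingularResonanceError

__all__ = [
    "DielectricModel",
    "OpticalConstants",
    "SILVER",
    "VACUUM",
    "WATER",
    "permittivity",
    "tabulated_silver_permittivity",
    "fresnel_reflection",
    "mie_dipole_polarizability",
    "quasistatic_polarizability",
    "load_material",
    "save_material",
]

#: speed of light, nm/s
C_NM = 2.99792458e17
#: vacuum permittivity (SI); cancels out of every reported field
EPS0_SI = 8.8541878128e-12
#: model validity window for the silver parameterization, nm
VALID_WINDOW = (300.0, 1100.0)


class ModelValidityWarning(UserWarning):
    """Material model evaluated outside its fitted wavelength window."""


class DipoleValidityWarning(UserWarning):
    """Sphere too large for reliable dipole-only (a1) truncation."""


@dataclass(frozen=True)
class DielectricModel:
    """Drude-Lorentz permittivity model.

    eps(w) = eps_inf - wp^2 / (w (w + i g0))
             + sum_j s_j w_j^2 / (w_j^2 - w^2 - i w G_j)

    Parameters are angular frequencies in rad/s; strengths are dimensionless.
    """

    eps_inf: float = 1.0
    plasma_frequency: float = 0.0
    drude_damping: float = 0.0
    lorentz_terms: tuple = ()
    name: str = "unnamed"

    def __call__(self, wavelength_nm: Union[float, np.ndarray]) -> complex:
        return permittivity(self, wavelength_nm)


# Drude-Lorentz parameters fitted by least squares to the embedded
# Johnson-Christy tabulation below over 300-1100 nm (frozen constants).
SILVER = DielectricModel(
    eps_inf=4.173768438251705,
    plasma_frequency=1.4321098739448524e16,
    drude_damping=14658356929908.557,
    lorentz_terms=(
        (0.025620099041064912, 6116516208202178.0, 203542163903802.25),
        (0.4310809741528851, 6707203956892480.0, 424461029459092.9),
        (0.16606909603353068, 3366465767802963.5, 1864121776412108.0),
    ),
    name="silver",
)

VACUUM = DielectricModel(eps_inf=1.0, name="vacuum")
#: non-dispersive water/buffer stand-in (n ~ 1.33)
WATER = DielectricModel(eps_inf=1.77, name="water")


# Johnson & Christy (1972) silver optical constants: (energy eV, n, k).
# Used as the interpolation oracle for the analytic fit above.
_JC_SILVER_EV_N_K = np.array([
    [1.14, 0.04, 7.795],
    [1.26, 0.04, 6.992],
    [1.39, 0.04, 6.312],
    [1.51, 0.04, 5.727],
    [1.64, 0.03, 5.242],
    [1.76, 0.04, 4.838],
    [1.88, 0.05, 4.483],
    [2.01, 0.06, 4.152],
    [2.13, 0.05, 3.858],
    [2.26, 0.06, 3.586],
    [2.38, 0.05, 3.324],
    [2.50, 0.05, 3.093],
    [2.63, 0.05, 2.869],
    [2.75, 0.04, 2.657],
    [2.88, 0.04, 2.462],
    [3.00, 0.05, 2.275],
    [3.12, 0.05, 2.070],
    [3.25, 0.05, 1.864],
    [3.37, 0.07, 1.657],
    [3.50, 0.10, 1.419],
    [3.62, 0.14, 1.142],
    [3.74, 0.17, 0.829],
    [3.87, 0.81, 0.392],
    [4.00, 1.13, 0.616],
    [4.13, 1.32, 0.647],
])

_JC_WL = 1239.84193 / _JC_SILVER_EV_N_K[:, 0][::-1]  # nm, ascending
_JC_EPS = ((_JC_SILVER_EV_N_K[:, 1] + 1j * _JC_SILVER_EV_N_K[:, 2]) ** 2)[::-1]


def tabulated_silver_permittivity(wavelength_nm: Union[float, np.ndarray]) -> complex:
    """Linear interpolation of the embedded Johnson-Christy silver table.

    Serves as the independent oracle for the analytic Drude-Lorentz fit.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise InvalidInputError("wavelength must be positive")
    if np.any(wl < _JC_WL[0]) or np.any(wl > _JC_WL[-1]):
        raise InvalidInputError(
            f"tabulation covers {_JC_WL[0]:.0f}-{_JC_WL[-1]:.0f} nm"
        )
    re = np.interp(wl, _JC_WL, _JC_EPS.real)
    im = np.interp(wl, _JC_WL, _JC_EPS.imag)
    out = re + 1j * im
    return complex(out) if out.ndim == 0 else out


def permittivity(model: DielectricModel, wavelength_nm: Union[float, np.ndarray]):
    """Complex relative permittivity of ``model`` at the given vacuum wavelength.

    Wavelengths outside the 300-1100 nm fit window trigger a
    :class:`ModelValidityWarning` (for dispersive models), not an error.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise InvalidInputError("wavelength must be positive")
    dispersive = model.plasma_frequency != 0.0 or len(model.lorentz_terms) > 0
    if dispersive and (np.any(wl < VALID_WINDOW[0]) or np.any(wl > VALID_WINDOW[1])):
        warnings.warn(
            f"{model.name}: wavelength outside fitted window "
            f"{VALID_WINDOW[0]:.0f}-{VALID_WINDOW[1]:.0f} nm",
            ModelValidityWarning,
            stacklevel=2,
        )
    w = 2.0 * np.pi * C_NM / wl  # rad/s
    eps = np.asarray(model.eps_inf, dtype=complex) * np.ones_like(w)
    if model.plasma_frequency != 0.0:
        eps = eps - model.plasma_frequency**2 / (w * (w + 1j * model.drude_damping))
    for s, w0, g in model.lorentz_terms:
        eps = eps + s * w0**2 / (w0**2 - w**2 - 1j * w * g)
    return complex(eps) if eps.ndim == 0 else eps


@dataclass(frozen=True)
class OpticalConstants:
    """Wavelength-dependent constants of one simulation setup.

    ``eps0`` is carried symbolically through the coupled-dipole equations
    (p = eps0 alpha E, E_scat = (k0^2/eps0) G p) and cancels from every
    reported field.
    """

    wavelength: float  # nm
    eps_ambient: complex = 1.0 + 0.0j
    eps_substrate: complex = field(default=None)  # type: ignore[assignment]
    eps0: float = EPS0_SI

    def __post_init__(self):
        if self.wavelength <= 0:
            raise InvalidInputError("wavelength must be positive")
        if self.eps_substrate is None:
            object.__setattr__(self, "eps_substrate", permittivity(SILVER, self.wavelength))

    @property
    def k0(self) -> float:
        """Vacuum wavenumber, rad/nm."""
        return 2.0 * np.pi / self.wavelength

    @property
    def k_ambient(self) -> complex:
        """Wavenumber in the ambient medium, rad/nm."""
        return self.k0 * np.sqrt(self.eps_ambient)

    @property
    def beta(self) -> complex:
        """Quasi-static image reflection factor (eps_s - eps_a)/(eps_s + eps_a)."""
        return (self.eps_substrate - self.eps_ambient) / (self.eps_substrate + self.eps_ambient)


def fresnel_reflection(theta_deg: float, polarization: str,
                       eps_ambient: complex, eps_substrate: complex) -> complex:
    """Amplitude reflection coefficient of the planar ambient/substrate interface.

    ``theta_deg`` is measured from the surface normal.  Sign convention: for TM
    the reflected electric field is r_TM * (-cos(theta), 0, sin(theta)) for an
    incident field along (cos(theta), 0, sin(theta)), so a perfect conductor
    gives r_TM = +1 and r_TE = -1 (zero total tangential field at the surface).
    """
    if not 0.0 <= theta_deg < 90.0:
        raise InvalidInputError("incidence angle must satisfy 0 <= theta < 90 degrees")
    pol = polarization.upper()
    if pol not in ("TM", "TE"):
        raise InvalidInputError(f"polarization must be 'TM' or 'TE', got {polarization!r}")
    th = np.deg2rad(theta_deg)
    na = np.sqrt(complex(eps_ambient))
    # normal wavevector components (units of k0); principal sqrt gives Im >= 0
    kz_a = na * np.cos(th)
    kz_s = np.sqrt(complex(eps_substrate) - complex(eps_ambient) * np.sin(th) ** 2)
    if pol == "TE":
        return complex((kz_a - kz_s) / (kz_a + kz_s))
    return complex(
        (eps_substrate * kz_a - eps_ambient * kz_s)
        / (eps_substrate * kz_a + eps_ambient * kz_s)
    )


def _psi1(z):
    """Riccati-Bessel psi_1(z) = z j_1(z)."""
    return np.sin(z) / z - np.cos(z)


def _psi1p(z):
    """d/dz psi_1(z) = z j_0(z) - j_1(z)."""
    return np.sin(z) - (np.sin(z) / z**2 - np.cos(z) / z)


def _xi1(z):
    """Riccati-Bessel xi_1(z) = z h1^(1)(z)."""
    return _psi1(z) - 1j * (np.cos(z) / z + np.sin(z))


def _xi1p(z):
    return _psi1p(z) - 1j * (-np.sin(z) / z - np.cos(z) / z**2 + np.cos(z))


def mie_electric_dipole_a1(radius_nm: float, wavelength_nm: float,
                           eps_particle: complex, eps_ambient: complex) -> complex:
    """Mie electric-dipole coefficient a1 of a homogeneous sphere."""
    if radius_nm <= 0:
        raise InvalidInputError("radius must be positive")
    k = 2.0 * np.pi / wavelength_nm * np.sqrt(complex(eps_ambient))
    x = k * radius_nm
    m = np.sqrt(complex(eps_particle) / complex(eps_ambient))
    mx = m * x
    num = m * _psi1(mx) * _psi1p(x) - _psi1(x) * _psi1p(mx)
    den = m * _psi1(mx) * _xi1p(x) - _xi1(x) * _psi1p(mx)
    return complex(num / den)


def mie_dipole_polarizability(radius_nm: float, wavelength_nm: float,
                              eps_particle: complex, eps_ambient: complex = 1.0) -> complex:
    """Electric-dipole polarizability from the Mie a1 coefficient.

    alpha = i 6 pi eps_ambient a1 / k^3 with k the ambient wavenumber; volume
    units (nm^3), so p = eps0 alpha E.  Includes all retardation/radiative
    corrections of the full a1 coefficient.
    """
    if radius_nm <= 0:
        raise InvalidInputError("radius must be positive")
    k = 2.0 * np.pi / wavelength_nm * np.sqrt(complex(eps_ambient))
    if np.abs(k * radius_nm) >= 1.5:
        warnings.warn(
            "size parameter k*a >= 1.5: dipole term no longer dominant",
            DipoleValidityWarning,
            stacklevel=2,
        )
    a1 = mie_electric_dipole_a1(radius_nm, wavelength_nm, eps_particle, eps_ambient)
    return complex(1j * 6.0 * np.pi * complex(eps_ambient) * a1 / k**3)


def quasistatic_polarizability(radius_nm: float, eps_particle: complex,
                               eps_ambient: complex = 1.0) -> complex:
    """Clausius-Mossotti polarizability 4 pi eps_a a^3 (ep-ea)/(ep+2ea), nm^3.

    No radiative correction; used as the small-sphere limit oracle.
    """
    if radius_nm <= 0:
        raise InvalidInputError("radius must be positive")
    ep = complex(eps_particle)
    ea = complex(eps_ambient)
    den = ep + 2.0 * ea
    if den == 0:
        raise SingularResonanceError("eps_particle + 2 eps_ambient = 0 (Froehlich pole)")
    return complex(4.0 * np.pi * ea * radius_nm**3 * (ep - ea) / den)


# -- config-file round-trip ---------------------------------------------------

def material_to_dict(model: DielectricModel) -> dict:
    return {
        "name": model.name,
        "model": "drude-lorentz",
        "eps_inf": model.eps_inf,
        "plasma_frequency": model.plasma_frequency,
        "drude_damping": model.drude_damping,
        "lorentz_terms": [list(t) for t in model.lorentz_terms],
    }


def material_from_dict(data: dict) -> DielectricModel:
    if data.get("model", "drude-lorentz") != "drude-lorentz":
        raise InvalidInputError(f"unknown material model {data.get('model')!r}")
    return DielectricModel(
        eps_inf=float(data.get("eps_inf", 1.0)),
        plasma_frequency=float(data.get("plasma_frequency", 0.0)),
        drude_damping=float(data.get("drude_damping", 0.0)),
        lorentz_terms=tuple(tuple(map(float, t)) for t in data.get("lorentz_terms", [])),
        name=str(data.get("name", "unnamed")),
    )


def load_material(path) -> DielectricModel:
    """Load a material definition from a YAML file."""
    with open(path, "r") as fh:
        return material_from_dict(yaml.safe_load(fh))


def save_material(model: DielectricModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(material_to_dict(model), sort_keys=False))
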
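"""Dyadic Green tensors: free-space term and substrate-reflected (image) term.

Convention: the electric field at r produced by a dipole p at r' is
E(r) = (k0^2 / eps0) G(r, r') p with G in 1/nm, k the *ambient* wavenumber.
The substrate occupies z <= 0; the ambient half-space is z > 0.

The reflected tensor uses the image approximation: free-space propagation
from the mirrored source, with the image dipole scaled by the quasi-static
reflection factor beta = (eps_s - eps_a)/(eps_s + eps_a) and its in-plane
components flipped (image of a horizontal dipole is antiparallel, image of a
vertical dipole is parallel).  This is accurate for sub-wavelength heights;
an exact Sommerfeld-integral backend can be substituted behind the same
signatures.
"""

from __future__ import annotations

import numpy as np

from .exceptions import GeometryError, InvalidInputError

__all__ = [
    "free_space_green",
    "reflected_green",
    "surface_self_term",
    "total_green",
    "image_factor",
]

#: mirror matrix for image dipole components: (px, py, pz) -> (-px, -py, +pz)
_MIRROR = np.diag([-1.0, -1.0, 1.0])


def image_factor(eps_ambient: complex, eps_substrate: complex) -> complex:
    """Quasi-static image reflection factor beta = (es - ea)/(es + ea)."""
    ea, es = complex(eps_ambient), complex(eps_substrate)
    return (es - ea) / (es + ea)


def free_space_green(r, r_prime, k) -> np.ndarray:
    """Homogeneous-medium electric dyadic Green tensor, 3x3 complex, 1/nm.

    G = e^{ikR}/(4 pi R) [ A I + B nn^T ],
    A = 1 + (ikR - 1)/(kR)^2,  B = (3 - 3ikR - (kR)^2)/(kR)^2,
    containing the 1/R (far), 1/R^2 (intermediate) and 1/R^3 (near) terms.
    """
    r = np.asarray(r, dtype=float)
    rp = np.asarray(r_prime, dtype=float)
    dr = r - rp
    R = np.linalg.norm(dr)
    if R == 0.0:
        raise InvalidInputError("free-space Green tensor is singular at r = r'")
    n = dr / R
    kR = k * R
    expf = np.exp(1j * kR) / (4.0 * np.pi * R)
    A = 1.0 + (1j * kR - 1.0) / kR**2
    B = (3.0 - 3.0j * kR - kR**2) / kR**2
    return expf * (A * np.eye(3) + B * np.outer(n, n))


def reflected_green(r, r_prime, k, eps_ambient: complex, eps_substrate: complex) -> np.ndarray:
    """Substrate-reflected dyadic Green tensor in the image approximation.

    Field at r from the image of a dipole at r': the source is mirrored to
    (x', y', -z') and its moment mapped to beta * diag(-1, -1, +1) p.
    Both points must lie above the substrate (z > 0); the field point may
    coincide with the source point (the image is at distance 2 z').
    """
    r = np.asarray(r, dtype=float)
    rp = np.asarray(r_prime, dtype=float)
    if r[2] <= 0.0 or rp[2] <= 0.0:
        raise GeometryError("source and field points must lie above the substrate (z > 0)")
    beta = image_factor(eps_ambient, eps_substrate)
    if beta == 0.0:
        return np.zeros((3, 3), dtype=complex)
    r_img = rp * np.array([1.0, 1.0, -1.0])
    return beta * free_space_green(r, r_img, k) @ _MIRROR


def surface_self_term(r_i, k, eps_ambient: complex, eps_substrate: complex) -> np.ndarray:
    """Particle-surface interaction tensor G_s(r_i, r_i).

    Finite (image distance 2 z_i) and diagonal in the surface frame.  The
    free-space self-term is *not* included: its radiative part already sits
    inside the Mie polarizability, so adding it here would double count.
    """
    r_i = np.asarray(r_i, dtype=float)
    if r_i[2] <= 0.0:
        raise GeometryError("particle center must lie above the substrate (z > 0)")
    return reflected_green(r_i, r_i, k, eps_ambient, eps_substrate)


def total_green(r, r_prime, k, eps_ambient: complex, eps_substrate: complex) -> np.ndarray:
    """G0 + G_s between distinct points above the substrate."""
    return free_space_green(r, r_prime, k) + reflected_green(
        r, r_prime, k, eps_ambient, eps_substrate
    )
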
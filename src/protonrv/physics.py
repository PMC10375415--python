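"""Continuous-slowing-down and scattering physics for protons.

Stopping power follows the standard Bethe–Bloch form (no shell or density
corrections — protons at radiotherapy energies, 10–250 MeV, are far from
both regimes), CSDA ranges are obtained by numerically integrating the
reciprocal stopping power, large-angle "hard" scatters are sampled from a
Rutherford-type differential cross-section, and small-angle multiple
Coulomb scattering uses the Highland parameterization.

Two angle conventions are supported for the Rutherford cross-section:

``"sin4theta"``  (default)
    d(sigma)/d(Omega) = (Z e^2 / 4E)^2 / sin^4(theta).
``"sin4half"``
    the textbook form with sin^4(theta/2) in the denominator.

For the default convention the angular density over theta (including the
solid-angle sin(theta) Jacobian) diverges at both 0 and pi, so sampling is
restricted to the symmetric window [theta_min, pi - theta_min].
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache

import numpy as np
from scipy import integrate

from .materials import CONSTANTS, Material

__all__ = [
    "ScatterEvent",
    "stopping_power",
    "csda_range",
    "rutherford_dcs",
    "sample_hard_scatter",
    "sample_scatter_angles",
    "highland_sigma",
    "hard_scatter_rate",
    "calibrate_hard_scatter_norm",
    "DEFAULT_THETA_MIN",
]

DEFAULT_THETA_MIN = math.radians(2.0)

_MP = CONSTANTS.proton_mass
_ME = CONSTANTS.electron_mass
_K = CONSTANTS.K


@dataclasses.dataclass(frozen=True)
class ScatterEvent:
    """A single hard-scatter deflection: polar angle theta, azimuth phi (rad)."""

    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= math.pi):
            raise ValueError(f"theta must be in (0, pi], got {self.theta}")
        if not (0.0 <= self.phi < 2.0 * math.pi):
            raise ValueError(f"phi must be in [0, 2*pi), got {self.phi}")


def _beta2_gamma(E):
    """(beta^2, gamma) of a proton with kinetic energy E (MeV)."""
    gamma = 1.0 + E / _MP
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    return beta2, gamma


def stopping_power(E, m: Material | None = None, *, rho=None, Z=None, A=None, I=None):
    """Linear electronic stopping power -dE/dx in MeV/cm.

    Accepts either a :class:`Material` or explicit (rho, Z, A, I) arrays for
    vectorized use inside the transport loop. ``E`` may be scalar or array
    (MeV, must be > 0).
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("kinetic energy must be > 0 MeV")
    if m is not None:
        rho, Z, A, I = m.density, m.Z, m.A, m.I
    beta2, gamma = _beta2_gamma(E)
    I_mev = np.asarray(I, dtype=float) * 1e-6
    arg = 2.0 * _ME * beta2 * gamma * gamma / I_mev
    val = _K * rho * (np.asarray(Z) / np.asarray(A)) / beta2 * (np.log(arg) - beta2)
    # below ~0.05 MeV the uncorrected formula turns over; clamp positive
    val = np.maximum(val, 1e-6)
    return float(val) if val.ndim == 0 else val


def csda_range(E0: float, m: Material, *, E_cut: float = 1.0) -> float:
    """Continuous-slowing-down range in cm: integral of 1/S from E_cut to E0.

    The cutoff matches the transport engine's termination energy and sits
    above the low-energy turnover of the uncorrected Bethe-Bloch formula
    for every registry material (including Pb, I = 823 eV)."""
    if E0 <= 0:
        raise ValueError("E0 must be > 0 MeV")
    if E0 <= E_cut:
        return 0.0
    val, err = integrate.quad(lambda e: 1.0 / stopping_power(e, m), E_cut, E0, limit=200)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-4):
        raise RuntimeError(f"range integration failed (value={val}, err={err})")
    return float(val)


def rutherford_dcs(E, Z, theta, *, convention: str = "sin4theta"):
    """Relative differential cross-section (Z e^2 / 4E)^2 / sin^4(...).

    Units are fm^2/sr with e^2 in MeV fm; only ratios are ever used.
    """
    E = np.asarray(E, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(E <= 0):
        raise ValueError("E must be > 0")
    if np.any(theta <= 0) or np.any(theta > math.pi):
        raise ValueError("theta must be in (0, pi]")
    if convention == "sin4theta":
        s = np.sin(theta)
        if np.any(s == 0):
            raise ValueError("theta = pi is singular for the sin^4(theta) convention")
    elif convention == "sin4half":
        s = np.sin(theta / 2.0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    amp = (np.asarray(Z) * CONSTANTS.e2 / (4.0 * E)) ** 2
    out = amp / s**4
    return float(out) if out.ndim == 0 else out


# -- angular sampling ------------------------------------------------------
#
# The density over theta is p(theta) ∝ sin(theta) * dcs(theta). Closed-form
# antiderivatives exist for both conventions, so sampling is exact inverse-CDF
# via a cached fine inverse table.


def _antideriv(theta, convention):
    if convention == "sin4theta":
        # integral of csc^3
        return -0.5 * (np.cos(theta) / np.sin(theta) ** 2) + 0.5 * np.log(
            np.tan(theta / 2.0)
        )
    # sin(theta)/sin^4(theta/2) integrates to -2/sin^2(theta/2)
    return -2.0 / np.sin(theta / 2.0) ** 2


def _support(theta_min, convention):
    if convention == "sin4theta":
        return theta_min, math.pi - theta_min
    return theta_min, math.pi


@lru_cache(maxsize=32)
def _inverse_cdf_table(theta_min: float, convention: str, n: int = 8192):
    # node spacing refined geometrically toward the support ends, where the
    # density (and hence the CDF slope) diverges
    lo, hi = _support(theta_min, convention)
    span = hi - lo
    ends = np.geomspace(1e-8 * span, span / 2.0, n // 2)
    thetas = np.unique(np.concatenate([[lo], lo + ends, hi - ends, [hi]]))
    cdf = _antideriv(thetas, convention)
    cdf = (cdf - cdf[0]) / (cdf[-1] - cdf[0])
    # guard against numerically non-monotone plateaus for interp
    cdf = np.maximum.accumulate(cdf)
    return cdf, thetas


@lru_cache(maxsize=32)
def angular_tables(theta_min: float, convention: str):
    """(cdf, thetas, pdf) tables of the normalized hard-scatter density.

    The pdf table feeds importance-sampling weights in the transport engine.
    """
    cdf, thetas = _inverse_cdf_table(theta_min, convention)
    total = _antideriv(thetas[-1], convention) - _antideriv(thetas[0], convention)
    if convention == "sin4theta":
        pdf = np.sin(thetas) / np.sin(thetas) ** 4 / total
    else:
        pdf = np.sin(thetas) / np.sin(thetas / 2.0) ** 4 / total
    return cdf, thetas, pdf


def sample_scatter_angles(n, theta_min, rng, *, convention: str = "sin4theta"):
    """Draw n polar angles from the normalized hard-scatter density."""
    if not (0.0 < theta_min < math.pi):
        raise ValueError("theta_min must be in (0, pi)")
    cdf, thetas = _inverse_cdf_table(float(theta_min), convention)
    u = rng.random(n)
    return np.interp(u, cdf, thetas)


def sample_hard_scatter(
    E: float,
    m: Material,
    theta_min: float,
    rng,
    *,
    convention: str = "sin4theta",
) -> ScatterEvent:
    """Sample one hard-scatter event (theta from the cross-section, phi uniform).

    For the relative Rutherford density the theta shape does not depend on E
    or the material; they are accepted for interface symmetry with
    :func:`hard_scatter_rate`, which carries the E^-2 and Z^2 dependence.
    """
    if E <= 0:
        raise ValueError("E must be > 0")
    if theta_min <= 0:
        raise ValueError("theta_min must be > 0: the density is unnormalizable at 0")
    theta = float(sample_scatter_angles(1, theta_min, rng, convention=convention)[0])
    phi = float(rng.random() * 2.0 * math.pi)
    return ScatterEvent(theta=theta, phi=phi)


def highland_sigma(E, step_cm, m: Material | None = None, *, X0=None):
    """Highland multiple-scattering angular std-dev (rad) over a path step.

    sigma = (13.6 MeV / (beta c p)) sqrt(t) [1 + 0.038 ln t],  t = step/X0.
    """
    E = np.asarray(E, dtype=float)
    step_cm = np.asarray(step_cm, dtype=float)
    if np.any(step_cm <= 0):
        raise ValueError("step must be > 0")
    if X0 is None:
        X0 = m.radiation_length
    beta2, gamma = _beta2_gamma(E)
    pc = np.sqrt(E * (E + 2.0 * _MP))
    beta_pc = np.sqrt(beta2) * pc
    t = step_cm / np.asarray(X0)
    corr = np.maximum(1.0 + 0.038 * np.log(t), 0.25)
    out = 13.6 / beta_pc * np.sqrt(t) * corr
    return float(out) if out.ndim == 0 else out


def hard_scatter_rate(E, norm, *, rho, Z, A):
    """Expected hard scatters per cm of path: norm * Z^2 * (rho/A) / E^2.

    ``norm`` is the single global normalization constant (MeV^2 cm^2 mol/g)
    fixed by :func:`calibrate_hard_scatter_norm`; the E^-2 and Z^2 scalings
    are those of the integrated Rutherford cross-section above theta_min.
    """
    E = np.asarray(E, dtype=float)
    out = norm * np.asarray(Z) ** 2 * (np.asarray(rho) / np.asarray(A)) / E**2
    return float(out) if out.ndim == 0 else out


def calibrate_hard_scatter_norm(
    mean_scatters: float, E0: float, m: Material, *, E_cut: float = 1.0
) -> float:
    """Normalization constant giving ``mean_scatters`` expected hard scatters
    over a full stopping track of an E0-MeV proton in material ``m``.

    The path integral of the rate is converted to an energy integral with
    dx = dE / S(E).
    """
    integrand = lambda e: (m.Z**2 * m.density / m.A) / (e**2 * stopping_power(e, m))
    val, _ = integrate.quad(integrand, E_cut, E0, limit=200)
    return mean_scatters / val
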
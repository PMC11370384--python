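"""Closed-form forward signal models for gray-matter diffusion MRI.

Three compartmental frameworks are implemented:

* **DTI** — single 3x3 symmetric tensor, ``S = S0 * exp(-<B, D>_F)`` where B
  is the b-matrix of a volume and <.,.>_F the Frobenius inner product.
* **NODDI** — three non-exchanging compartments: Watson-dispersed sticks
  (intraneurite), an axially symmetric extraneurite tensor whose
  perpendicular diffusivity follows the tortuosity rule
  ``d_perp = d_par * (1 - f_in)``, and isotropic CSF.  Parallel diffusivity
  is fixed at 1.7 um^2/ms and CSF diffusivity at 3.0 um^2/ms.  Orientation
  dispersion is summarised by ODI = (2/pi) * arctan(1/kappa).
* **SANDI** — direction-averaged (spherical-mean) three-compartment model:
  sticks (neurites), a restricting sphere of radius r_s (somas, intrasoma
  diffusivity fixed at 3.0 um^2/ms, Gaussian-phase-distribution
  attenuation), and an isotropic extracellular ball.  The mixture is
  ``S̄ = (1-f_ec) [ f_in * S̄_in + (1-f_in) * S̄_is ] + f_ec * S̄_ec``,
  giving derived maps f_extracellular = f_ec,
  f_neurite = (1-f_ec) f_in and f_soma = (1-f_ec)(1-f_in).

The Watson-stick orientation convolution is evaluated with the spherical
convolution theorem: ``S(g) = sum_l ((2l+1)/2) * Atil_l(kappa) * B_l(b d) *
P_l(mu . g)`` over even Legendre orders, where ``Atil_l`` are normalised
Legendre moments of the Watson weight exp(kappa t^2) and ``B_l`` Legendre
moments of the stick kernel exp(-b d t^2).  Moments are computed by
composite Gauss-Legendre quadrature with panels geometrically refined
towards t = +/-1 so that concentrations up to kappa ~ 1e4 stay accurate.

Units: b in ms/um^2, diffusivities in um^2/ms, radii in um, timings in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.optimize import brentq
from scipy.special import erf, spherical_jn

from .protocol import AcquisitionProtocol

__all__ = [
    "TensorParams", "NoddiParams", "SandiParams",
    "tensor_signal", "fa_md", "odi_from_kappa", "kappa_from_odi",
    "watson_stick_signal", "noddi_signal",
    "stick_sphmean", "ball_signal", "sphere_gpd_sphmean", "sandi_sphmean",
]

D_PAR_FIXED = 1.7   # um^2/ms, intraneurite parallel diffusivity (NODDI)
D_ISO_FIXED = 3.0   # um^2/ms, CSF diffusivity (NODDI)
D_IS_FIXED = 3.0    # um^2/ms, intrasoma diffusivity (SANDI)

_LMAX = 30  # even Legendre orders 0..30 in the Watson-stick convolution


# --------------------------------------------------------------------- DTI

@dataclass(frozen=True)
class TensorParams:
    """Diffusion tensor (um^2/ms) with baseline signal S0."""

    D: np.ndarray
    S0: float = 1.0

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (3, 3):
            raise ValueError("D must be 3x3")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if np.linalg.eigvalsh(D).min() < -1e-10:
            raise ValueError("D must be positive semi-definite")
        object.__setattr__(self, "D", D)


def tensor_signal(params: TensorParams, protocol: AcquisitionProtocol) -> np.ndarray:
    """``S = S0 * exp(-<B, D>_F)`` per volume; B = b * g g^T."""
    g = protocol.bvecs
    quad = np.einsum("ij,vi,vj->v", params.D, g, g)
    return params.S0 * np.exp(-protocol.bvals * quad)


def fa_md(eigenvalues) -> tuple[float, float]:
    """Fractional anisotropy and mean diffusivity from tensor eigenvalues.

    FA is the normalised eigenvalue dispersion, in [0, 1]; by convention an
    all-zero tensor has FA = 0.  MD is the eigenvalue mean (um^2/ms).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    md = float(lam.mean())
    denom = np.sum(lam**2)
    if denom == 0:
        return 0.0, md
    fa = float(np.sqrt(1.5 * np.sum((lam - md) ** 2) / denom))
    return min(fa, 1.0), md


# ------------------------------------------------------------------- NODDI

def odi_from_kappa(kappa) -> np.ndarray | float:
    """ODI = (2/pi) arctan(1/kappa); ODI(0) = 1 by continuity."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    with np.errstate(divide="ignore"):
        odi = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    return float(odi) if odi.ndim == 0 else odi


def kappa_from_odi(odi) -> np.ndarray | float:
    """Inverse of :func:`odi_from_kappa` (odi in (0, 1])."""
    odi = np.asarray(odi, dtype=float)
    kappa = 1.0 / np.tan(np.pi * odi / 2.0)
    return float(kappa) if kappa.ndim == 0 else kappa


@dataclass(frozen=True)
class NoddiParams:
    """Watson-dispersed stick + tortuosity-tensor + CSF parameters."""

    f_iso: float
    f_in: float
    kappa: float
    mu: np.ndarray
    d_par: float = D_PAR_FIXED
    d_iso: float = D_ISO_FIXED

    def __post_init__(self) -> None:
        for name in ("f_iso", "f_in"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        mu = np.asarray(self.mu, dtype=float)
        norm = np.linalg.norm(mu)
        if norm == 0:
            raise ValueError("mu must be a non-zero vector")
        object.__setattr__(self, "mu", mu / norm)


@lru_cache(maxsize=8)
def _panel_nodes(n_gl: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights on u in [0, 1] with panel
    edges geometrically refined towards 0 (u = 1 - t of the pole)."""
    edges = np.concatenate([[0.0], np.geomspace(1e-6, 1.0, 25)])
    x, w = np.polynomial.legendre.leggauss(n_gl)
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        nodes.append(0.5 * (b - a) * x + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * w)
    return np.concatenate(nodes), np.concatenate(weights)


def _watson_legendre(kappa: float, lmax: int = _LMAX) -> np.ndarray:
    """Normalised even Legendre moments Atil_l = A_l / A_0 of exp(kappa t^2).

    Uses A_l = 2 exp(kappa) * int_0^1 exp(-kappa (1 - t^2)) P_l(t) dt with the
    exp(kappa) factor cancelling in the ratio, keeping large kappa stable.
    """
    u, w = _panel_nodes()
    t = 1.0 - u
    g = np.exp(-kappa * (1.0 - t**2)) * w
    P = npleg.legvander(t, lmax)[:, ::2]  # even orders only
    moments = g @ P
    return moments / moments[0]


@lru_cache(maxsize=64)
def _gl64() -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(64)


def _stick_legendre(bd: float, lmax: int = _LMAX) -> np.ndarray:
    """Even Legendre moments B_l = int_{-1}^{1} exp(-bd t^2) P_l(t) dt."""
    x, w = _gl64()
    g = np.exp(-bd * x**2) * w
    return g @ npleg.legvander(x, lmax)[:, ::2]


def watson_stick_signal(bvals: np.ndarray, cosbeta: np.ndarray, kappa: float,
                        d_par: float = D_PAR_FIXED) -> np.ndarray:
    """Signal of Watson-dispersed sticks per volume.

    Parameters
    ----------
    bvals : (n,) b-values (ms/um^2).
    cosbeta : (n,) cosine of the angle between each gradient direction and
        the Watson mean orientation mu.
    kappa : Watson concentration (kappa = 0 is isotropic dispersion).
    """
    bvals = np.asarray(bvals, dtype=float)
    cosbeta = np.asarray(cosbeta, dtype=float)
    atil = _watson_legendre(kappa)
    ls = np.arange(0, _LMAX + 1, 2)
    Pl = npleg.legvander(np.clip(cosbeta, -1.0, 1.0), _LMAX)[:, ::2]
    out = np.empty_like(bvals)
    for b in np.unique(bvals):
        Bl = _stick_legendre(b * d_par)
        sel = bvals == b
        out[sel] = Pl[sel] @ ((ls + 0.5) * atil * Bl)
    return np.clip(out, 0.0, None)


def noddi_signal(params: NoddiParams, protocol: AcquisitionProtocol) -> np.ndarray:
    """Three-compartment NODDI signal per volume (normalised, S(b=0)=1)."""
    b = protocol.bvals
    cosbeta = protocol.bvecs @ params.mu
    s_in = watson_stick_signal(b, cosbeta, params.kappa, params.d_par)
    d_perp = params.d_par * (1.0 - params.f_in)
    s_en = np.exp(-b * (d_perp + (params.d_par - d_perp) * cosbeta**2))
    s_iso = np.exp(-b * params.d_iso)
    tissue = params.f_in * s_in + (1.0 - params.f_in) * s_en
    return (1.0 - params.f_iso) * tissue + params.f_iso * s_iso


# ------------------------------------------------------------------- SANDI

def stick_sphmean(b, d_in) -> np.ndarray | float:
    """Spherical-mean stick signal sqrt(pi/(4 b D)) * erf(sqrt(b D)).

    Continuous limit 1 as b*D -> 0.
    """
    bd = np.asarray(b, dtype=float) * np.asarray(d_in, dtype=float)
    if np.any(bd < 0):
        raise ValueError("b and D must be non-negative")
    out = np.ones_like(bd, dtype=float)
    nz = bd > 1e-12
    out[nz] = np.sqrt(np.pi / (4.0 * bd[nz])) * erf(np.sqrt(bd[nz]))
    return float(out) if out.ndim == 0 else out


def ball_signal(b, d) -> np.ndarray | float:
    """Isotropic Gaussian compartment exp(-b D)."""
    bd = np.asarray(b, dtype=float) * np.asarray(d, dtype=float)
    if np.any(bd < 0):
        raise ValueError("b and D must be non-negative")
    out = np.exp(-bd)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=4)
def _sphere_bessel_roots(n_roots: int = 50) -> np.ndarray:
    """First roots of d/dx j1(x) = 0 (reflecting-sphere eigenmodes)."""

    def f(x: float) -> float:
        return spherical_jn(1, x, derivative=True)

    roots: list[float] = []
    x = 1.0
    step = 0.05
    prev = f(x)
    while len(roots) < n_roots:
        x_next = x + step
        cur = f(x_next)
        if prev * cur < 0:
            roots.append(brentq(f, x, x_next, xtol=1e-12))
        x, prev = x_next, cur
    return np.asarray(roots)


def sphere_gpd_sphmean(b, r_s: float, delta: float, big_delta: float,
                       d_is: float = D_IS_FIXED, n_roots: int = 50) -> np.ndarray | float:
    """Restricted-sphere signal under the Gaussian phase distribution.

    Murday-Cotts attenuation for PGSE with gradient duration ``delta`` and
    separation ``big_delta`` (ms), sphere radius ``r_s`` (um) and intrasoma
    diffusivity ``d_is`` (um^2/ms).  The gradient strength is recovered from
    the b-value via b = (gamma G)^2 delta^2 (Delta - delta/3).  The
    compartment is isotropic, so the direction average equals the
    directional signal.
    """
    if not (big_delta > delta > 0):
        raise ValueError("require Delta > delta > 0 (ms)")
    if r_s <= 0:
        raise ValueError("soma radius must be positive")
    b = np.asarray(b, dtype=float)
    gG2 = b / (delta**2 * (big_delta - delta / 3.0))  # (gamma G)^2, 1/(um^2 ms)
    beta = _sphere_bessel_roots(n_roots)              # dimensionless roots
    alpha = beta / r_s                                # 1/um
    lam = d_is * alpha**2                             # 1/ms
    Y = (2.0 * lam * delta - 2.0
         + 2.0 * np.exp(-lam * delta) + 2.0 * np.exp(-lam * big_delta)
         - np.exp(-lam * (big_delta - delta)) - np.exp(-lam * (big_delta + delta)))
    series = np.sum(Y / (lam**2 * alpha**2 * (beta**2 - 2.0)))
    lnS = -2.0 * gG2 * series
    out = np.exp(lnS)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SandiParams:
    """Spherical-mean soma-and-neurite parameters."""

    f_ec: float      # extracellular signal fraction
    f_in: float      # intraneurite fraction of the cellular compartment
    r_s: float       # soma radius, um
    d_in: float      # intraneurite diffusivity, um^2/ms
    d_ec: float      # extracellular diffusivity, um^2/ms
    d_is: float = D_IS_FIXED

    def __post_init__(self) -> None:
        for name in ("f_ec", "f_in"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.r_s <= 0:
            raise ValueError("soma radius must be positive")
        if self.d_in < 0 or self.d_ec < 0:
            raise ValueError("diffusivities must be non-negative")

    @property
    def f_neurite(self) -> float:
        return (1.0 - self.f_ec) * self.f_in

    @property
    def f_soma(self) -> float:
        return (1.0 - self.f_ec) * (1.0 - self.f_in)

    @property
    def f_extracellular(self) -> float:
        return self.f_ec


def sandi_sphmean(params: SandiParams, protocol: AcquisitionProtocol,
                  b_shells: np.ndarray | None = None) -> np.ndarray:
    """Spherical-mean SANDI signal per shell.

    Evaluates on the protocol's shell b-values unless ``b_shells`` overrides
    them.  ``S̄(0) = 1`` because the signal fractions sum to one.
    """
    if b_shells is None:
        b_shells = protocol.shells.b_shells
    b = np.asarray(b_shells, dtype=float)
    s_in = stick_sphmean(b, params.d_in)
    s_is = sphere_gpd_sphmean(b, params.r_s, protocol.delta,
                              protocol.big_delta, params.d_is)
    s_ec = ball_signal(b, params.d_ec)
    return ((1.0 - params.f_ec) * (params.f_in * s_in + (1.0 - params.f_in) * s_is)
            + params.f_ec * s_ec)
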
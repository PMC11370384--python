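"""Parameter estimation for DTI, NODDI and SANDI from multi-shell signals.

Fitting mirrors the study's shell usage: the tensor uses b <= 1.2 ms/um^2,
NODDI uses all shells with fixed diffusivities (d_par = 1.7, d_iso = 3.0
um^2/ms), and SANDI fits per-shell spherical means with the intrasoma
diffusivity fixed at 3.0 um^2/ms and f_ec, f_in, r_s, D_in, D_ec free.
NODDI and SANDI use seeded multi-start bounded nonlinear least squares,
which is deterministic and testable by inverse crime (every fitter must
recover its own forward model's parameters from noiseless data).

Volumes are canonically re-ordered (by b-value, then direction) before any
nonlinear fit so estimates are exactly invariant to the input volume order.
Rician noise-floor bias is not corrected; at high b this biases estimates
upward and is characterised, not removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize

from .dwi_models import (D_IS_FIXED, D_ISO_FIXED, D_PAR_FIXED, ball_signal,
                         fa_md, odi_from_kappa, sphere_gpd_sphmean,
                         stick_sphmean, watson_stick_signal)
from .protocol import AcquisitionProtocol, ShellTable

__all__ = [
    "FitResult", "spherical_mean", "fit_dti", "fit_noddi", "fit_sandi",
    "principal_peak", "principal_peak_sh", "DEFAULT_SANDI_BOUNDS",
]

#: (lo, hi) per free SANDI parameter: f_ec, f_in, r_s (um), D_in, D_ec
#: (um^2/ms).  The diffusivity and radius windows are gray-matter
#: physiological ranges chosen for identifiability: the spherical-mean
#: mixture is a stick plus two effective exponentials, and estimation is
#: well-posed only when the three decay rates are separated
#: (D_in > D_ec > D_eff(r_s)); wide windows admit exact label-swap and
#: rate-collision degeneracies.
DEFAULT_SANDI_BOUNDS = {
    "f_ec": (0.0, 1.0),
    "f_in": (0.0, 1.0),
    "r_s": (3.0, 11.0),
    "d_in": (1.6, 2.5),
    "d_ec": (0.5, 1.3),
}

#: weak MAP prior: centre = canonical gray-matter values, sd = width of
#: the physiological range / sqrt(12) (a uniform prior's standard
#: deviation), per parameter
SANDI_PRIOR_MEAN = {"f_ec": 0.3, "f_in": 0.5, "r_s": 8.0,
                    "d_in": 2.0, "d_ec": 0.9}
SANDI_PRIOR_SD = {"f_ec": 0.5 / np.sqrt(12), "f_in": 0.6 / np.sqrt(12),
                  "r_s": 8.0 / np.sqrt(12), "d_in": 0.9 / np.sqrt(12),
                  "d_ec": 0.8 / np.sqrt(12)}

KAPPA_MAX = 128.0


@dataclass
class FitResult:
    """Per-location estimates with fit diagnostics."""

    params: dict                 # name -> (n_loc, ...) array
    objective: np.ndarray        # (n_loc,) final sum of squared residuals
    converged: np.ndarray        # (n_loc,) bool
    bounds_hit: np.ndarray       # (n_loc,) bool, any estimate at a bound
    flagged: np.ndarray          # (n_loc,) bool, location unusable

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]


def _canonical_order(protocol: AcquisitionProtocol) -> np.ndarray:
    """Deterministic volume order: by b, then lexicographic direction."""
    key = np.round(np.column_stack([protocol.bvals, protocol.bvecs]), 9)
    return np.lexsort(key.T[::-1])


def spherical_mean(signals: np.ndarray, shells: ShellTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-shell mean signal normalised by the b=0 mean.

    Returns ``(means, valid)`` where means is (n_loc, n_shell) with the b=0
    column equal to 1, and valid flags locations with a positive b=0 mean.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if shells.b_shells[0] != 0:
        raise ValueError("need at least one b=0 volume")
    raw = np.stack([signals[:, shells.volumes_in(s)].mean(axis=1)
                    for s in range(shells.n_shells)], axis=1)
    b0 = raw[:, 0]
    valid = b0 > 0
    means = np.full_like(raw, np.nan)
    means[valid] = raw[valid] / b0[valid, None]
    return means, valid


# ---------------------------------------------------------------------- DTI

def _dti_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    return np.column_stack([
        np.ones_like(bvals),
        -bvals * g[:, 0] ** 2, -bvals * g[:, 1] ** 2, -bvals * g[:, 2] ** 2,
        -2 * bvals * g[:, 0] * g[:, 1],
        -2 * bvals * g[:, 0] * g[:, 2],
        -2 * bvals * g[:, 1] * g[:, 2],
    ])


def _beta_to_tensor(beta: np.ndarray) -> np.ndarray:
    """(…, 7) log-linear coefficients -> (…, 3, 3) tensors."""
    dxx, dyy, dzz, dxy, dxz, dyz = (beta[..., i] for i in range(1, 7))
    D = np.empty(beta.shape[:-1] + (3, 3))
    D[..., 0, 0], D[..., 1, 1], D[..., 2, 2] = dxx, dyy, dzz
    D[..., 0, 1] = D[..., 1, 0] = dxy
    D[..., 0, 2] = D[..., 2, 0] = dxz
    D[..., 1, 2] = D[..., 2, 1] = dyz
    return D


def fit_dti(signals: np.ndarray, protocol: AcquisitionProtocol,
            max_b: float = 1.2) -> FitResult:
    """Weighted linear least squares tensor fit on log-signals.

    Uses all volumes with b <= ``max_b`` (the low-b regime where the
    mono-exponential tensor model holds); an ordinary LLS pass provides the
    weights (predicted squared signals) for one WLS refinement.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    use = protocol.bvals <= max_b + 1e-9
    if use.sum() < 7:
        raise ValueError("need at least 7 usable volumes at b <= max_b")
    A = _dti_design(protocol.bvals[use], protocol.bvecs[use])
    S = signals[:, use]
    flagged = ~np.all(np.isfinite(S), axis=1) | np.any(S <= 0, axis=1)
    logS = np.log(np.clip(S, 1e-10, None))
    beta = logS @ np.linalg.pinv(A).T                       # OLS start
    w = np.exp(A @ beta.T).T ** 2                            # WLS weights
    Aw = A[None] * w[:, :, None]
    lhs = np.einsum("nvi,vj->nij", Aw, A)
    rhs = np.einsum("nvi,nv->ni", Aw, logS)
    try:
        beta = np.linalg.solve(lhs, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        flagged[:] = flagged | ~np.isfinite(lhs).all(axis=(1, 2))
    D = _beta_to_tensor(beta)
    evals, evecs = np.linalg.eigh(D)
    fa = np.empty(len(D))
    md = np.empty(len(D))
    for i, lam in enumerate(evals):
        fa[i], md[i] = fa_md(lam)
    n = len(D)
    return FitResult(
        params={"tensor": D, "S0": np.exp(beta[:, 0]), "fa": fa, "md": md,
                "evals": evals, "evecs": evecs},
        objective=np.einsum("nv->n", (logS - np.einsum("vi,ni->nv", A, beta)) ** 2),
        converged=~flagged, bounds_hit=np.zeros(n, bool), flagged=flagged)


# -------------------------------------------------------------------- NODDI

def _sph_to_unit(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _noddi_model(x: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    f_iso, f_in, kappa, theta, phi = x
    mu = _sph_to_unit(theta, phi)
    cosbeta = bvecs @ mu
    s_in = watson_stick_signal(bvals, cosbeta, kappa, D_PAR_FIXED)
    d_perp = D_PAR_FIXED * (1.0 - f_in)
    s_en = np.exp(-bvals * (d_perp + (D_PAR_FIXED - d_perp) * cosbeta**2))
    s_iso = np.exp(-bvals * D_ISO_FIXED)
    return (1 - f_iso) * (f_in * s_in + (1 - f_in) * s_en) + f_iso * s_iso


def fit_noddi(signals: np.ndarray, protocol: AcquisitionProtocol,
              seed: int = 0, extra_starts: int = 0) -> FitResult:
    """Multi-start bounded NLLS NODDI fit (fixed d_par = 1.7, d_iso = 3.0).

    The mean orientation is initialised from the tensor's principal
    eigenvector; starts vary the Watson concentration (and one CSF-dominant
    start).  Requires at least 3 non-zero shells.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    shells = protocol.shells
    if shells.nonzero_shells.size < 3:
        raise ValueError("NODDI needs at least 3 non-zero b-shells")
    order = _canonical_order(protocol)
    bvals = protocol.bvals[order]
    bvecs = protocol.bvecs[order]
    sig = signals[:, order]
    # normalise by b0 mean
    b0 = sig[:, bvals == 0].mean(axis=1)
    flagged = ~(b0 > 0)
    sig = sig / np.where(b0 > 0, b0, 1.0)[:, None]

    dti = fit_dti(signals, protocol)
    mu0 = dti["evecs"][:, :, 2]  # principal eigenvector (largest eigenvalue)

    rng = np.random.default_rng(seed)
    base_starts = [
        (0.05, 0.5, 0.5), (0.05, 0.5, 2.0), (0.05, 0.5, 8.0), (0.9, 0.5, 2.0),
    ]
    rand_starts = [(rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 32))
                   for _ in range(extra_starts)]
    lo = [0.0, 0.0, 0.0, -np.inf, -np.inf]
    hi = [1.0, 1.0, KAPPA_MAX, np.inf, np.inf]

    n = sig.shape[0]
    est = np.zeros((n, 5))
    obj = np.full(n, np.inf)
    conv = np.zeros(n, bool)
    for i in range(n):
        if flagged[i]:
            continue
        theta0 = float(np.arccos(np.clip(mu0[i, 2], -1, 1)))
        phi0 = float(np.arctan2(mu0[i, 1], mu0[i, 0]))
        y = sig[i]
        for f_iso, f_in, kappa in base_starts + rand_starts:
            res = least_squares(
                lambda x: _noddi_model(x, bvals, bvecs) - y,
                x0=[f_iso, f_in, kappa, theta0, phi0],
                bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10)
            if res.cost < obj[i]:
                obj[i] = res.cost
                est[i] = res.x
                conv[i] = res.status > 0
    mu = np.stack([_sph_to_unit(t, p) for t, p in est[:, 3:]])
    at_bound = ((est[:, :3] <= np.array(lo[:3]) + 1e-8)
                | (est[:, :3] >= np.array(hi[:3]) - 1e-8)).any(axis=1)
    return FitResult(
        params={"f_iso": est[:, 0], "f_in": est[:, 1], "kappa": est[:, 2],
                "odi": odi_from_kappa(np.clip(est[:, 2], 0, None)), "mu": mu},
        objective=2 * obj, converged=conv, bounds_hit=at_bound, flagged=flagged)


# -------------------------------------------------------------------- SANDI

def _sandi_model(x: np.ndarray, b_nz: np.ndarray, delta: float,
                 big_delta: float) -> np.ndarray:
    f_ec, f_in, r_s, d_in, d_ec = x
    s_in = stick_sphmean(b_nz, d_in)
    s_is = sphere_gpd_sphmean(b_nz, r_s, delta, big_delta, D_IS_FIXED)
    s_ec = ball_signal(b_nz, d_ec)
    return (1 - f_ec) * (f_in * s_in + (1 - f_in) * s_is) + f_ec * s_ec


def sphere_effective_diffusivity(r_s, delta: float, big_delta: float) -> np.ndarray | float:
    """Effective exponential decay rate of the GPD sphere (um^2/ms).

    Under the Gaussian phase distribution with fixed pulse timings the
    restricted-sphere attenuation is exactly ``exp(-b * D_eff(r_s))``, so
    the soma compartment is a ball with radius-dependent rate.  The SANDI
    mixture is identifiable only with an ordering convention: the soma is
    the more restricted isotropic compartment, ``D_eff(r_s) < D_ec``;
    otherwise soma and extracellular can swap labels exactly.
    """
    r_s = np.asarray(r_s, dtype=float)
    s = np.array([sphere_gpd_sphmean(1.0, float(r), delta, big_delta)
                  for r in np.atleast_1d(r_s)])
    out = -np.log(s)
    return float(out[0]) if r_s.ndim == 0 else out


def _sphere_radius_from_rate(rate: np.ndarray, delta: float, big_delta: float,
                             lo: float, hi: float) -> np.ndarray:
    """Invert D_eff(r) on [lo, hi] by interpolation (monotone increasing)."""
    grid = np.linspace(lo, hi, 400)
    d_grid = sphere_effective_diffusivity(grid, delta, big_delta)
    return np.interp(rate, d_grid, grid, left=lo, right=hi)


def _sandi_grid_starts(y_all: np.ndarray, b_nz: np.ndarray, delta: float,
                       big_delta: float, lo: np.ndarray, hi: np.ndarray,
                       n_grid: int = 14) -> np.ndarray:
    """Variable-projection grid search for SANDI initialisation.

    For fixed (r_s, D_in, D_ec) the spherical-mean model is linear in the
    compartment fractions, so each grid cell reduces to a 2-variable
    linear least-squares problem (fractions clipped to the simplex).  The
    best cell per location provides a start inside the correct valley —
    plain random multi-starts frequently settle in near-degenerate ones
    (sticks with low diffusivity mimicking spheres, large spheres
    mimicking balls).
    """
    r_grid = np.linspace(lo[2], hi[2], n_grid)
    din_grid = np.linspace(lo[3], hi[3], n_grid)
    dec_grid = np.linspace(lo[4], hi[4], n_grid)
    A_in = np.stack([stick_sphmean(b_nz, d) for d in din_grid])     # (j, s)
    A_is = np.stack([sphere_gpd_sphmean(b_nz, r, delta, big_delta)
                     for r in r_grid])                              # (i, s)
    A_ec = np.stack([ball_signal(b_nz, d) for d in dec_grid])       # (k, s)
    u = A_in[None, :, :] - A_ec[:, None, :]          # (k, j, s)
    v = A_is[:, None, :] - A_ec[None, :, :]          # (i, k, s)
    t = y_all[:, None, :] - A_ec[None, :, :]         # (n, k, s)
    uu = np.einsum("kjs,kjs->kj", u, u)              # (k, j)
    vv = np.einsum("iks,iks->ik", v, v)              # (i, k)
    uv = np.einsum("iks,kjs->ikj", v, u)             # (i, k, j)
    bu = np.einsum("kjs,nks->nkj", u, t)             # (n, k, j)
    bv = np.einsum("iks,nks->nik", v, t)             # (n, i, k)
    tt = np.einsum("nks,nks->nk", t, t)              # (n, k)
    det = (uu[None, :, :] * vv[:, :, None] - uv**2)  # (i, k, j)
    det = np.where(np.abs(det) < 1e-14, 1e-14, det)
    # c1 multiplies the stick column, c2 the sphere column;
    # broadcast everything to (n, i, k, j)
    bu_b = bu[:, None, :, :]
    bv_b = bv[:, :, :, None]
    vv_b = vv[None, :, :, None]
    uu_b = uu[None, None, :, :]
    uv_b = uv[None, :, :, :]
    det_b = det[None, :, :, :]
    c1 = (vv_b * bu_b - uv_b * bv_b) / det_b
    c2 = (uu_b * bv_b - uv_b * bu_b) / det_b
    # clip to the fraction simplex {c1, c2 >= 0, c1 + c2 <= 1}
    c1 = np.clip(c1, 0.0, 1.0)
    c2 = np.clip(c2, 0.0, 1.0)
    s = c1 + c2
    over = s > 1.0
    scale = np.where(over, 1.0 / np.where(s == 0, 1.0, s), 1.0)
    c1, c2 = c1 * scale, c2 * scale
    resid = (tt[:, None, :, None] - 2 * c1 * bu_b - 2 * c2 * bv_b
             + c1**2 * uu_b + 2 * c1 * c2 * uv_b + c2**2 * vv_b)
    # restrict to the identifiable branch: soma more restricted than the
    # extracellular ball (D_eff(r_s) < d_ec), excluding label-swap twins
    d_eff = sphere_effective_diffusivity(r_grid, delta, big_delta)  # (i,)
    swapped = d_eff[:, None] >= dec_grid[None, :] * 0.999           # (i, k)
    resid = np.where(swapped[None, :, :, None], np.inf, resid)
    flat = resid.reshape(resid.shape[0], -1)
    best = np.argmin(flat, axis=1)
    i_idx, k_idx, j_idx = np.unravel_index(
        best, (n_grid, n_grid, n_grid))
    nn = np.arange(len(y_all))
    c1_b = c1[nn, i_idx, k_idx, j_idx]
    c2_b = c2[nn, i_idx, k_idx, j_idx]
    f_ec = np.clip(1.0 - c1_b - c2_b, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_in = np.where(c1_b + c2_b > 0, c1_b / np.maximum(c1_b + c2_b, 1e-12),
                        0.5)
    starts = np.column_stack([f_ec, np.clip(f_in, 0, 1), r_grid[i_idx],
                              din_grid[j_idx], dec_grid[k_idx]])
    eps = 1e-6
    return np.clip(starts, lo + eps, hi - eps)


def estimate_noise_sigma(signals: np.ndarray, shells: ShellTable) -> np.ndarray:
    """Per-location relative noise sd estimated from the b=0 repeats."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    b0 = signals[:, shells.volumes_in(0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        return b0.std(axis=1, ddof=1) / b0.mean(axis=1)


def fit_sandi(shell_means: np.ndarray, b_shells: np.ndarray,
              delta: float, big_delta: float,
              bounds: dict | None = None, n_starts: int = 3,
              seed: int = 0, noise_sigma: np.ndarray | float | None = None,
              shell_n_dirs: np.ndarray | None = None) -> FitResult:
    """Bounded NLLS / MAP fit on per-shell spherical means; D_is fixed at
    3.0 um^2/ms.

    ``shell_means`` is (n_loc, n_shell) normalised so the b=0 column is 1.
    Requires >= 4 non-zero shells (soma-radius identifiability).  Each
    location is initialised by a variable-projection grid search (see
    :func:`_sandi_grid_starts`) plus seeded random multi-starts, then
    polished with bounded nonlinear least squares.

    When ``noise_sigma`` (per-location relative noise sd, e.g. from
    :func:`estimate_noise_sigma`) is given, the objective becomes a MAP
    fit: residuals are weighted by the per-shell standard error
    (``noise_sigma / sqrt(n_dirs)``) and a weak Gaussian prior centred on
    canonical gray-matter values (:data:`SANDI_PRIOR_MEAN`, sd = a quarter
    of each bound window) regularises the near-degenerate directions of
    the stick + two-exponential mixture — the same role the learned priors
    play in regressor-based fitting.  Without it the objective is plain
    least squares and noiseless curves are recovered exactly.

    Derived maps f_neurite = (1-f_ec) f_in, f_soma = (1-f_ec)(1-f_in) and
    f_extracellular = f_ec are returned alongside the free parameters.
    """
    bounds = DEFAULT_SANDI_BOUNDS if bounds is None else bounds
    shell_means = np.atleast_2d(np.asarray(shell_means, dtype=float))
    b_shells = np.asarray(b_shells, dtype=float)
    nz = b_shells > 0
    if nz.sum() < 4:
        raise ValueError("SANDI needs at least 4 non-zero b-shells")
    b_nz = b_shells[nz]
    y_all = shell_means[:, nz]
    names = ("f_ec", "f_in", "r_s", "d_in", "d_ec")
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    rng = np.random.default_rng(seed)
    rand_starts = [lo + (hi - lo) * rng.uniform(0.05, 0.95, size=5)
                   for _ in range(max(0, n_starts - 1))]

    n = y_all.shape[0]
    flagged = ~np.all(np.isfinite(y_all), axis=1)
    grid_starts = np.tile((lo + hi) / 2, (n, 1))
    ok = ~flagged
    if ok.any():
        grid_starts[ok] = _sandi_grid_starts(y_all[ok], b_nz, delta,
                                             big_delta, lo, hi)

    mu = np.array([SANDI_PRIOR_MEAN[k] for k in names])
    prior_sd = np.array([SANDI_PRIOR_SD[k] for k in names])
    if noise_sigma is not None:
        sigma = np.broadcast_to(np.atleast_1d(np.asarray(noise_sigma,
                                                         dtype=float)), (n,))
        n_dirs = (np.asarray(shell_n_dirs, dtype=float)
                  if shell_n_dirs is not None else np.ones(nz.sum()))
        se = np.maximum(sigma[:, None] / np.sqrt(n_dirs)[None, :], 1e-8)
    else:
        se = None

    def residual_fn(i):
        y = y_all[i]
        if se is None:
            return lambda x: _sandi_model(x, b_nz, delta, big_delta) - y
        w = se[i]
        return lambda x: np.concatenate([
            (_sandi_model(x, b_nz, delta, big_delta) - y) / w,
            (x - mu) / prior_sd])

    def polish(i, x0, max_nfev=3000):
        return least_squares(residual_fn(i), x0=x0, bounds=(lo, hi),
                             method="trf", xtol=1e-15, ftol=1e-15,
                             gtol=1e-15, max_nfev=max_nfev,
                             x_scale=[0.3, 0.3, 4.0, 1.0, 1.0])

    est = np.zeros((n, 5))
    obj = np.full(n, np.inf)
    conv = np.zeros(n, bool)
    for i in range(n):
        if flagged[i]:
            continue
        for x0 in [grid_starts[i]] + rand_starts:
            res = polish(i, x0)
            if res.cost < obj[i]:
                obj[i] = res.cost
                est[i] = res.x
                conv[i] = res.status > 0
        if not conv[i]:
            flagged[i] = True

    # enforce the ordering convention on any solution that converged into
    # the label-swapped branch: relabel to its exact twin and re-polish
    d_eff = sphere_effective_diffusivity(est[:, 2], delta, big_delta)
    swapped = (~flagged) & (est[:, 4] < d_eff)
    for i in np.flatnonzero(swapped):
        f_ec, f_in, r_s, d_in, d_ec = est[i]
        c_n = (1 - f_ec) * f_in
        c_s = (1 - f_ec) * (1 - f_in)
        r_new = _sphere_radius_from_rate(d_ec, delta, big_delta, lo[2], hi[2])
        f_ec_new = np.clip(c_s, 0.0, 1.0)
        f_in_new = np.clip(c_n / max(1 - f_ec_new, 1e-12), 0.0, 1.0)
        x0 = np.clip([f_ec_new, f_in_new, float(r_new), d_in, d_eff[i]],
                     lo + 1e-9, hi - 1e-9)
        res = polish(i, x0, max_nfev=2000)
        if res.cost <= obj[i] * (1 + 1e-6) + 1e-30:
            obj[i] = res.cost
            est[i] = res.x
    at_bound = ((est <= lo + 1e-9) | (est >= hi - 1e-9)).any(axis=1)
    f_ec, f_in = est[:, 0], est[:, 1]
    return FitResult(
        params={"f_ec": f_ec, "f_in": f_in, "r_s": est[:, 2],
                "d_in": est[:, 3], "d_ec": est[:, 4],
                "fextracellular": f_ec,
                "fneurite_SANDI": (1 - f_ec) * f_in,
                "fsoma": (1 - f_ec) * (1 - f_in)},
        objective=2 * obj, converged=conv, bounds_hit=at_bound, flagged=flagged)


# --------------------------------------------------------------------- peaks

def principal_peak(tensors: np.ndarray, min_linearity: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Principal eigenvector per tensor; isotropic locations are flagged.

    Returns ``(peaks, flagged)``; peaks are unit vectors (sign arbitrary,
    antipodally symmetric), NaN where flagged.  A location is degenerate
    when the first two eigenvalues are closer than ``min_linearity``
    relative to the largest.
    """
    tensors = np.asarray(tensors, dtype=float)
    single = tensors.ndim == 2
    if single:
        tensors = tensors[None]
    evals, evecs = np.linalg.eigh(tensors)
    lam1, lam2 = evals[:, 2], evals[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        flagged = ~((lam1 > 0) & ((lam1 - lam2) / np.abs(lam1) > min_linearity))
    peaks = evecs[:, :, 2].copy()
    peaks[flagged] = np.nan
    return (peaks[0], flagged[0]) if single else (peaks, flagged)


def _real_even_sh_basis(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Real symmetric spherical-harmonic basis at unit directions."""
    from scipy.special import sph_harm_y

    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            Y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2) * (-1) ** m * Y.imag)
            elif m == 0:
                cols.append(Y.real)
            else:
                cols.append(np.sqrt(2) * (-1) ** m * Y.real)
    return np.column_stack(cols)


def principal_peak_sh(coeffs: np.ndarray, lmax: int, n_grid: int = 1000,
                      seed: int = 0) -> np.ndarray:
    """Largest peak of an even-order real-SH function (fODF surrogate).

    Dense-grid search followed by local refinement; returns a unit vector
    (antipodal sign arbitrary).
    """
    from .protocol import dispersed_directions

    grid = dispersed_directions(n_grid, seed=seed, n_iter=80)
    vals = _real_even_sh_basis(lmax, grid) @ coeffs
    best = grid[np.argmax(vals)]

    def neg(angles: np.ndarray) -> float:
        d = _sph_to_unit(*angles)[None]
        return -(_real_even_sh_basis(lmax, d) @ coeffs).item()

    theta0 = float(np.arccos(np.clip(best[2], -1, 1)))
    phi0 = float(np.arctan2(best[1], best[0]))
    res = minimize(neg, x0=[theta0, phi0], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12})
    return _sph_to_unit(*res.x)
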
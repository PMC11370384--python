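"""Statistical battery for developmental surface analyses.

Four layers mirror the analysis design:

1. **Tiered Pearson screening** of age against parcel-averaged metrics.
   The minimum alpha is 0.01 — a Bonferroni family of 5 (one metric tested
   across 5 subfields) at family-wise 0.05 — with stricter 0.005 and
   0.0005 tiers reported for conservative reading.
2. **Nested-model F-tests**: a full linear model (e.g.
   ``DV ~ age + subfield + sex + age:subfield + sex:subfield + age:sex``)
   against the reduced model dropping the interaction of interest,
   with Benjamini-Hochberg FDR over each test family.
3. **Vertex-wise age contrasts**: per-vertex OLS of
   ``DV ~ age + sex + age:sex``; the age t-statistic map is correlated with
   contrived AP/PD positional gradients to localise where along the
   hippocampal axes age effects vary.
4. **Spin test**: permutation correlation of two surface maps that
   preserves spatial autocorrelation by rigid random shifts in the
   unfolded (AP, PD) plane with toroidal wrap-around, nearest-vertex
   resampling, and the add-one permutation p-value.

Factor coding is treatment contrasts (reference: subiculum / F / L); any
full-rank coding yields identical F statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

from .mesh import MetricSurface

__all__ = [
    "pearson_screen", "TIER_ALPHAS", "nested_f_test", "FTestResult",
    "fdr_bh", "vertexwise_age_contrast", "ContrastMap",
    "positional_gradients", "PositionalGradients", "gradient_correlation",
    "spin_test", "SpinResult", "smooth_random_field",
    "full_model_formula", "reduced_model_formula",
]

#: screening significance tiers, most to least liberal; 0.01 is the
#: Bonferroni-of-5 minimum alpha
TIER_ALPHAS = (0.01, 0.005, 0.0005)


def pearson_screen(x, y) -> tuple[float, float, str]:
    """Pearson R with two-sided p and significance tier.

    Returns ``(R, p, tier)`` with tier the most conservative alpha in
    :data:`TIER_ALPHAS` that p passes, or ``'ns'``.  Zero-variance input
    raises a ValueError (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    tier = "ns"
    for alpha in TIER_ALPHAS:
        if p < alpha:
            tier = str(alpha)
    return float(r), float(p), tier


@dataclass(frozen=True)
class FTestResult:
    F: float
    df1: int
    df2: int
    p: float


def full_model_formula(dv: str = "value", parcel: str = "subfield",
                       group: str = "sex",
                       interaction: str = "age:sex") -> str:
    """Standard full model: main effects, age-by-parcel and group-by-parcel
    interactions, plus the interaction of interest."""
    base = (f"{dv} ~ age + C({parcel}) + C({group}) "
            f"+ age:C({parcel}) + C({group}):C({parcel})")
    return f"{base} + {interaction}"


def reduced_model_formula(dv: str = "value", parcel: str = "subfield",
                          group: str = "sex") -> str:
    return full_model_formula(dv, parcel, group, interaction="").rstrip(" +")


def nested_f_test(data: pd.DataFrame, full: str, reduced: str) -> FTestResult:
    """F-test between a full and a nested reduced OLS model.

    ``F = ((RSS_r - RSS_f) / (df_r - df_f)) / (RSS_f / df_f)`` with the
    p-value from the F(df1, df2) distribution.  Raises if the reduced
    design is not a column subset of the full design.
    """
    fit_f = ols(full, data=data).fit()
    fit_r = ols(reduced, data=data).fit()
    cols_f = set(fit_f.model.exog_names)
    cols_r = set(fit_r.model.exog_names)
    if not cols_r < cols_f:
        raise ValueError("models are not nested (reduced must drop terms)")
    rss_f, rss_r = fit_f.ssr, fit_r.ssr
    df_f, df_r = int(fit_f.df_resid), int(fit_r.df_resid)
    df1 = df_r - df_f
    F = ((rss_r - rss_f) / df1) / (rss_f / df_f)
    p = float(stats.f.sf(F, df1, df_f))
    return FTestResult(F=float(F), df1=df1, df2=df_f, p=p)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


# ------------------------------------------------------------- vertex-wise

@dataclass
class ContrastMap:
    """Per-vertex age t-statistics from ``DV ~ age + sex + age:sex``."""

    t_age: np.ndarray
    n: int
    df_resid: int


def vertexwise_age_contrast(values: np.ndarray, ages: np.ndarray,
                            sexes: np.ndarray) -> ContrastMap:
    """Vertex-wise OLS age contrast on hemisphere-averaged data.

    ``values`` is (n_subjects, n_vertices); the age t-statistic is
    ``beta_age / SE(beta_age)``.  Vertices with non-finite or constant data
    get NaN.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    male = (np.asarray(sexes) == "M").astype(float)
    n = values.shape[0]
    X = np.column_stack([np.ones(n), ages, male, ages * male])
    k = X.shape[1]
    if n <= k:
        raise ValueError("need more subjects than model parameters")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ values                 # (4, V)
    resid = values - X @ beta
    dof = n - k
    sigma2 = np.sum(resid**2, axis=0) / dof
    se_age = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / se_age
    bad = ~np.all(np.isfinite(values), axis=0) | (np.ptp(values, axis=0) == 0)
    t[bad] = np.nan
    return ContrastMap(t_age=t, n=n, df_resid=dof)


@dataclass(frozen=True)
class PositionalGradients:
    """Contrived positional gradient maps: the unfolded coordinates."""

    ap: np.ndarray
    pd: np.ndarray

    @classmethod
    def from_mesh(cls, mesh: MetricSurface) -> "PositionalGradients":
        return cls(ap=mesh.unfolded[:, 0].copy(), pd=mesh.unfolded[:, 1].copy())


def positional_gradients(mesh: MetricSurface) -> PositionalGradients:
    return PositionalGradients.from_mesh(mesh)


def gradient_correlation(tmap: ContrastMap | np.ndarray,
                         grads: PositionalGradients) -> tuple[float, float, float]:
    """(|R_AP|, |R_PD|, mean |t|) of an age-contrast map vs the gradients.

    Masked (NaN) vertices are excluded pairwise; a constant map raises
    (undefined correlation).
    """
    t = tmap.t_age if isinstance(tmap, ContrastMap) else np.asarray(tmap, float)
    ok = np.isfinite(t)
    if ok.sum() < 3 or np.ptp(t[ok]) == 0:
        raise ValueError("contrast map is constant or too sparse")
    r_ap = stats.pearsonr(t[ok], grads.ap[ok])[0]
    r_pd = stats.pearsonr(t[ok], grads.pd[ok])[0]
    return abs(float(r_ap)), abs(float(r_pd)), float(np.mean(np.abs(t[ok])))


# --------------------------------------------------------------- spin test

@dataclass(frozen=True)
class SpinResult:
    r: float
    p: float
    null: np.ndarray


def _spin_indices(unfolded: np.ndarray, shifts: np.ndarray,
                  tree: cKDTree | None = None) -> np.ndarray:
    """Nearest-vertex resampling indices for rigid toroidal shifts.

    For each shift (u_ap, u_pd), the value at a vertex v is taken from the
    vertex nearest to ``unfolded(v) - shift`` (wrapped to [0, 1]).
    Returns (n_shift, V) integer indices.
    """
    tree = cKDTree(unfolded) if tree is None else tree
    q = np.mod(unfolded[None, :, :] - shifts[:, None, :], 1.0)
    return tree.query(q.reshape(-1, 2))[1].reshape(len(shifts), -1)


def spin_test(map_a: np.ndarray, map_b: np.ndarray, unfolded: np.ndarray,
              n_perm: int = 2500, seed: int = 0) -> SpinResult:
    """Spatial-autocorrelation-preserving correlation of two surface maps.

    Observed Pearson R; the null rigidly shifts ``map_a`` in the unfolded
    plane (toroidal wrap, nearest-vertex resampling) by ``n_perm`` uniform
    random offsets; ``p = (1 + #{|R_null| >= |R_obs|}) / (n_perm + 1)``.
    """
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    unfolded = np.asarray(unfolded, dtype=float)
    if unfolded.ndim != 2 or unfolded.shape[1] != 2 \
            or len(map_a) != len(unfolded):
        raise ValueError("need unfolded (V, 2) coordinates matching the maps")
    ok = np.isfinite(map_a) & np.isfinite(map_b)
    r_obs = stats.pearsonr(map_a[ok], map_b[ok])[0]
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(0, 1, size=(n_perm, 2))
    idx = _spin_indices(unfolded, shifts)
    if ok.all() and np.isfinite(map_a[idx]).all():
        A = map_a[idx]                                  # (n_perm, V)
        A = A - A.mean(axis=1, keepdims=True)
        bc = map_b - map_b.mean()
        null = (A @ bc) / (np.linalg.norm(A, axis=1) * np.linalg.norm(bc))
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            a_null = map_a[idx[i]]
            sel = ok & np.isfinite(a_null)
            null[i] = stats.pearsonr(a_null[sel], map_b[sel])[0]
    p = (1 + np.sum(np.abs(null) >= abs(r_obs))) / (n_perm + 1)
    return SpinResult(r=float(r_obs), p=float(p), null=null)


def smooth_random_field(mesh: MetricSurface, rng: np.random.Generator,
                        smooth_sigma: float = 4.0, grid: int = 64) -> np.ndarray:
    """Gaussian-filtered white noise sampled at the mesh vertices.

    Noise lives on a toroidal ``grid x grid`` lattice over the unfolded
    square, is smoothed with a wrap-around Gaussian of ``smooth_sigma``
    lattice units, and is bilinearly interpolated at vertex positions.
    Used to calibrate the spin test on spatially autocorrelated nulls.
    """
    noise = rng.standard_normal((grid, grid))
    smooth = ndimage.gaussian_filter(noise, smooth_sigma, mode="wrap")
    smooth /= smooth.std()
    coords = (mesh.unfolded * grid).T
    return ndimage.map_coordinates(smooth, coords, order=1, mode="wrap")
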
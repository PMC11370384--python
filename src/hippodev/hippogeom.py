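"""Hippocampal coordinate geometry.

Laplace scalar fields define a curvilinear coordinate system over the
hippocampal gray matter: anterior-posterior (AP), proximal-distal (PD) and
inner-outer (IO), each harmonic inside the mask with Dirichlet values 0 at
its source boundary and 1 at its sink, and no-flux (Neumann) behaviour at
the remaining walls.  Their spatial gradients give reference direction
fields; the absolute cosine between a gradient direction and the principal
diffusion orientation yields the long-axis / tangential / radial
orientation maps (diffusion peaks are antipodally symmetric, so the cosine
is folded into [0, 1]).

Surfaces are constructed at a chosen IO level (midthickness = 0.5) by
inverting the voxelwise (AP, PD, IO) -> world mapping; volume metrics are
sampled onto surfaces with the enclosing-voxel rule (nearest containing
voxel, face ties resolved to the lower index) or trilinearly; per-vertex
values are averaged within subfield or long-axis parcels.

Macrostructure uses simplified, monotone definitions: subfield volume is
the labelled voxel count times the voxel volume, thickness the Euclidean
distance between corresponding inner (IO -> 0) and outer (IO -> 1)
vertices, and gyrification the ratio of native to unfolded vertex area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator

from .mesh import (MetricSurface, SUBFIELD_NAMES, LONGAXIS_NAMES,
                   subfield_from_pd, vertex_areas)

__all__ = [
    "CoordinateField", "solve_laplace", "solve_phantom_coordinates",
    "gradient_field", "cosine_similarity", "OrientationMaps",
    "orientation_maps", "midthickness_surface", "surface_at_io",
    "sample_to_surface", "parcel_average", "macrostructure",
]


@dataclass
class CoordinateField:
    """AP/PD/IO scalar fields on a gray-matter mask."""

    psi: dict                    # axis -> float volume, NaN off-mask
    mask: np.ndarray             # bool gray-matter domain
    voxel_mm: float

    def gradient(self, axis: str) -> tuple[np.ndarray, np.ndarray]:
        return gradient_field(self.psi[axis], self.mask, self.voxel_mm)


def solve_laplace(mask: np.ndarray, source: np.ndarray, sink: np.ndarray,
                  tol: float = 1e-6, max_iter: int = 100_000,
                  omega: float = 1.9) -> np.ndarray:
    """Solve Laplace's equation on ``mask`` by red-black SOR.

    Dirichlet boundaries: 0 on ``source``, 1 on ``sink`` (both must be
    6-adjacent to the mask).  Boundary values are imposed at the shared
    *face* between a boundary voxel and its in-mask neighbour (half-spacing
    stencil, neighbour weight 2), so planar boundaries aligned with voxel
    faces are represented exactly.  Walls without a boundary label are
    treated as no-flux.  Converged when the largest update falls below
    ``tol``.  Returns the field with NaN outside the mask.
    """
    mask = mask.astype(bool)
    source = source.astype(bool)
    sink = sink.astype(bool)
    struct = ndimage.generate_binary_structure(3, 1)
    labeled, n_comp = ndimage.label(mask, structure=struct)
    grown = ndimage.binary_dilation(mask, structure=struct)
    if not (source & grown).any() or not (sink & grown).any():
        raise ValueError("source and sink must be adjacent to the mask")
    for comp in range(1, n_comp + 1):
        comp_mask = labeled == comp
        touch = ndimage.binary_dilation(comp_mask, structure=struct)
        if not ((source | sink) & touch).any():
            raise ValueError(
                f"mask component {comp} touches neither source nor sink")

    field = np.zeros(mask.shape)
    field[mask] = 0.5
    field[sink] = 1.0
    fixed = source | sink
    active = mask & ~fixed
    ii, jj, kk = np.nonzero(active)
    red = ((ii + jj + kk) % 2).astype(bool)
    colors = [(ii[~red], jj[~red], kk[~red]), (ii[red], jj[red], kk[red])]
    # neighbour bookkeeping per active voxel: indices + validity
    valid_any = mask | fixed
    shape = mask.shape

    fixed_flat = fixed.ravel()

    def neighbours(idx):
        i, j, k = idx
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        nb_flat = []
        nb_w = []
        for di, dj, dk in offs:
            ni, nj, nk = i + di, j + dj, k + dk
            ok = ((ni >= 0) & (ni < shape[0]) & (nj >= 0) & (nj < shape[1])
                  & (nk >= 0) & (nk < shape[2]))
            ni_c, nj_c, nk_c = (np.clip(ni, 0, shape[0] - 1),
                                np.clip(nj, 0, shape[1] - 1),
                                np.clip(nk, 0, shape[2] - 1))
            flat = np.ravel_multi_index((ni_c, nj_c, nk_c), shape)
            ok = ok & valid_any.ravel()[flat]
            # Dirichlet neighbours act at half spacing (value on the face)
            w = np.where(fixed_flat[flat], 2.0, 1.0) * ok
            nb_flat.append(flat)
            nb_w.append(w)
        return np.stack(nb_flat), np.stack(nb_w)

    color_data = []
    for idx in colors:
        flat_self = np.ravel_multi_index(idx, shape)
        nb_flat, nb_w = neighbours(idx)
        wsum = nb_w.sum(axis=0)
        if np.any(wsum == 0):
            raise ValueError("isolated voxel with no usable neighbours")
        color_data.append((flat_self, nb_flat, nb_w, wsum))

    f = field.ravel()
    for _ in range(max_iter):
        max_update = 0.0
        for flat_self, nb_flat, nb_w, wsum in color_data:
            avg = (nb_w * f[nb_flat]).sum(axis=0) / wsum
            new = (1 - omega) * f[flat_self] + omega * avg
            max_update = max(max_update, np.abs(new - f[flat_self]).max(initial=0.0))
            f[flat_self] = new
        if max_update < tol:
            break
    else:
        warnings.warn("Laplace solver hit max_iter before tolerance")
    out = np.full(mask.shape, np.nan)
    out[mask] = field[mask]
    out[source & ~mask] = 0.0
    out[sink & ~mask] = 1.0
    return out


def solve_phantom_coordinates(phantom, tol: float = 1e-6,
                              max_iter: int = 100_000) -> CoordinateField:
    """Solve all three Laplace fields of a slab phantom numerically."""
    psi = {}
    for ax in ("AP", "PD", "IO"):
        src, snk = phantom.boundaries[ax]
        psi[ax] = solve_laplace(phantom.mask, src, snk, tol=tol,
                                max_iter=max_iter)
    return CoordinateField(psi=psi, mask=phantom.mask, voxel_mm=phantom.voxel_mm)


def gradient_field(psi: np.ndarray, mask: np.ndarray,
                   voxel_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Spatial gradient of a masked scalar field (units 1/mm).

    Central differences where both neighbours are inside the mask,
    one-sided at mask edges.  Returns ``(grad, degenerate)`` where grad is
    (X, Y, Z, 3) and ``degenerate`` flags voxels with no usable neighbour
    pair in some direction or a vanishing gradient.
    """
    grad = np.zeros(psi.shape + (3,))
    no_info = np.zeros(psi.shape, bool)
    inside = mask & np.isfinite(psi)
    for axis in range(3):
        fwd_ok = np.zeros_like(inside)
        bwd_ok = np.zeros_like(inside)
        fwd = np.full(psi.shape, np.nan)
        bwd = np.full(psi.shape, np.nan)
        sl_to = [slice(None)] * 3
        sl_from = [slice(None)] * 3
        sl_to[axis], sl_from[axis] = slice(0, -1), slice(1, None)
        fwd[tuple(sl_to)] = psi[tuple(sl_from)]
        fwd_ok[tuple(sl_to)] = inside[tuple(sl_from)]
        sl_to[axis], sl_from[axis] = slice(1, None), slice(0, -1)
        bwd[tuple(sl_to)] = psi[tuple(sl_from)]
        bwd_ok[tuple(sl_to)] = inside[tuple(sl_from)]
        both = fwd_ok & bwd_ok
        d = np.zeros(psi.shape)
        with np.errstate(invalid="ignore"):
            d[both] = (fwd[both] - bwd[both]) / (2 * voxel_mm)
            only_f = fwd_ok & ~bwd_ok
            d[only_f] = (fwd[only_f] - psi[only_f]) / voxel_mm
            only_b = bwd_ok & ~fwd_ok
            d[only_b] = (psi[only_b] - bwd[only_b]) / voxel_mm
        no_info |= inside & ~(fwd_ok | bwd_ok)
        grad[..., axis] = np.where(inside, d, 0.0)
    norms = np.linalg.norm(grad, axis=-1)
    degenerate = inside & ((norms < 1e-12) | no_info)
    grad[~inside] = np.nan
    return grad, degenerate


def cosine_similarity(grad: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """|cos(angle)| between two vector volumes, NaN where degenerate.

    The absolute value folds antipodal symmetry of diffusion peaks; the
    result lies in [0, 1] (1 parallel or antiparallel, 0 orthogonal).
    """
    gn = np.linalg.norm(grad, axis=-1)
    pn = np.linalg.norm(peaks, axis=-1)
    dot = np.abs(np.sum(grad * peaks, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = dot / (gn * pn)
    out[~np.isfinite(out)] = np.nan
    return np.clip(out, 0.0, 1.0)


@dataclass
class OrientationMaps:
    """Voxelwise |cos| similarity of the principal diffusion orientation
    with the three hippocampal axis direction fields."""

    long_axis: np.ndarray
    tangential: np.ndarray
    radial: np.ndarray


def orientation_maps(coords: CoordinateField, peaks: np.ndarray) -> OrientationMaps:
    maps = {}
    for name, ax in (("long_axis", "AP"), ("tangential", "PD"), ("radial", "IO")):
        grad, degen = coords.gradient(ax)
        sim = cosine_similarity(grad, peaks)
        sim[degen] = np.nan
        maps[name] = sim
    return OrientationMaps(**maps)


# ----------------------------------------------------------------- surfaces

def _coordinate_interpolator(coords: CoordinateField):
    m = coords.mask
    pts = np.column_stack([coords.psi["AP"][m], coords.psi["PD"][m],
                           coords.psi["IO"][m]])
    world = np.argwhere(m) * coords.voxel_mm
    return LinearNDInterpolator(pts, world)


def surface_at_io(coords: CoordinateField, template: MetricSurface,
                  io_level: float, interp=None) -> MetricSurface:
    """Place template vertices at a given inner-outer level.

    Inverts the (AP, PD, IO) -> world mapping by piecewise-linear scattered
    interpolation over gray-matter voxels.  Vertices whose coordinate
    triplet is not bracketed by the sampled domain get NaN positions
    (flagged missing).
    """
    interp = _coordinate_interpolator(coords) if interp is None else interp
    query = np.column_stack([template.unfolded[:, 0], template.unfolded[:, 1],
                             np.full(template.n_vertices, io_level)])
    return template.with_vertices(interp(query))


def midthickness_surface(coords: CoordinateField,
                         template: MetricSurface) -> MetricSurface:
    """Template vertices on the IO = 0.5 (mid-gray) level set."""
    return surface_at_io(coords, template, 0.5)


def sample_to_surface(volume: np.ndarray, surface: MetricSurface,
                      voxel_mm: float, method: str = "enclosing") -> np.ndarray:
    """Per-vertex values sampled from a voxel volume.

    ``enclosing``: value of the voxel whose (half-open) box contains the
    vertex; a vertex exactly on a voxel face belongs to the lower-index
    voxel.  ``trilinear``: order-1 interpolation (used for tissue
    probability maps).  Vertices outside the volume get NaN.
    """
    v = surface.vertices / voxel_mm  # voxel index space, centers at integers
    out = np.full(surface.n_vertices, np.nan)
    finite = np.all(np.isfinite(v), axis=1)
    if method == "enclosing":
        idx = np.ceil(v[finite] - 0.5).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
        vals = np.full(finite.sum(), np.nan)
        vals[ok] = volume[tuple(idx[ok].T)]
        out[finite] = vals
    elif method == "trilinear":
        vals = ndimage.map_coordinates(volume, v[finite].T, order=1,
                                       mode="constant", cval=np.nan)
        out[finite] = vals
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    return out


def parcel_average(values: np.ndarray, labels: np.ndarray,
                   n_parcels: int | None = None) -> np.ndarray:
    """Unweighted mean of per-vertex values per parcel (NaN-aware).

    ``values`` may have leading axes (e.g. subject, hemisphere); the vertex
    axis is last.  Empty parcels yield NaN with a warning.
    """
    labels = np.asarray(labels)
    if n_parcels is None:
        n_parcels = int(labels.max()) + 1
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape[:-1] + (n_parcels,), np.nan)
    for p in range(n_parcels):
        sel = labels == p
        if not sel.any():
            warnings.warn(f"parcel {p} has no vertices")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[..., p] = np.nanmean(values[..., sel], axis=-1)
    return out


def macrostructure(coords: CoordinateField, template: MetricSurface,
                   io_eps: float = 0.08) -> dict:
    """Subfield volume, per-vertex thickness and gyrification.

    * volume: per-subfield voxel count x voxel volume, subfields assigned
      from the PD coordinate bands of the template parcellation;
    * thickness: Euclidean distance between corresponding inner and outer
      vertices, linearly extrapolated from the sampled IO range to the
      0 and 1 level sets;
    * gyrification: native vertex area on the midthickness surface divided
      by unfolded vertex area (unfolded coordinates scaled to the
      template's physical extents).
    """
    vox_vol = coords.voxel_mm**3
    m = coords.mask
    sf_labels = subfield_from_pd(coords.psi["PD"][m])
    volume = {name: float(np.sum(sf_labels == i) * vox_vol)
              for i, name in enumerate(SUBFIELD_NAMES)}

    interp = _coordinate_interpolator(coords)
    io_vals = coords.psi["IO"][m]
    io_lo = max(io_eps, float(np.nanmin(io_vals)) + 1e-3)
    io_hi = min(1.0 - io_eps, float(np.nanmax(io_vals)) - 1e-3)
    io_grid = np.linspace(io_lo, io_hi, 7)
    positions = np.stack([
        surface_at_io(coords, template, lvl, interp=interp).vertices
        for lvl in io_grid])                      # (n_lvl, V, 3)
    # linear extrapolation of the profile ends to IO = 0 and IO = 1
    d_lo = (positions[1] - positions[0]) / (io_grid[1] - io_grid[0])
    d_hi = (positions[-1] - positions[-2]) / (io_grid[-1] - io_grid[-2])
    inner = positions[0] - d_lo * io_grid[0]
    outer = positions[-1] + d_hi * (1.0 - io_grid[-1])
    thickness = np.linalg.norm(outer - inner, axis=1)

    mid = surface_at_io(coords, template, 0.5, interp=interp)
    native_area = vertex_areas(mid.vertices, mid.faces)
    unfolded_mm = np.column_stack([
        template.unfolded[:, 0] * template.ap_extent_mm,
        template.unfolded[:, 1] * template.pd_extent_mm,
    ])
    unfolded_area = vertex_areas(unfolded_mm, template.faces)
    with np.errstate(invalid="ignore", divide="ignore"):
        gyrification = native_area / unfolded_area
    bad = ~np.all(np.isfinite(mid.vertices), axis=1)
    gyrification[bad] = np.nan
    thickness[~np.all(np.isfinite(inner) & np.isfinite(outer), axis=1)] = np.nan
    return {"volume_mm3": volume, "thickness_mm": thickness,
            "gyrification": gyrification, "midthickness": mid}
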
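"""Synthetic inputs for the full analysis pipeline.

Everything downstream consumes can be generated here with known ground
truth: a developmental cohort, per-vertex microstructure metric surfaces
with configurable linear age trends, sex-dependent slopes, spatial
structure and noise; forward-simulated multi-shell diffusion signals with
Rician noise; and a curved-slab "hippocampus" phantom whose AP/PD/IO
Laplace coordinates are known analytically.

Signal fractions are generated so that f_neurite + f_soma +
f_extracellular = 1 at every vertex: f_neurite and f_soma follow their
effect specifications and f_extracellular is the remainder (its age slope
is therefore minus the sum of the other two, matching the empirical
pattern of a rising neurite fraction mirrored by a falling extracellular
fraction).  Values are clamped to their physical ranges and a clamp mask is
recorded so statistics on saturated vertices can be excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import Cohort, make_cohort
from .dwi_models import (NoddiParams, SandiParams, TensorParams,
                         noddi_signal, sandi_sphmean, tensor_signal)
from .mesh import MetricSurface, build_template_mesh
from .protocol import AcquisitionProtocol

__all__ = [
    "EffectSpec", "default_effects", "ParameterSurfaceSet",
    "make_parameter_surfaces", "simulate_signals", "SlabPhantom",
    "make_slab_phantom",
]

SPATIAL_PATTERNS = ("uniform", "AP-linear", "PD-linear")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth generative model for one metric across the cohort.

    value = baseline + age_slope * (age - age_ref)
          + sex_slope_delta * (age - age_ref) * [sex == M]
          + spatial_amplitude * pattern(vertex)
          + subject offset (sd = subject_sd)
          + subject-specific smooth spatial field (sd = subject_parcel_sd)
          + vertex noise (sd = vertex_noise_sd)

    clamped to [lo, hi].  The regional component draws one independent
    offset per (subfield x long-axis) cell, subject and hemisphere: it
    models individual regional variability, and because distinct parcels
    average disjoint cells it keeps parcel-level rows within a subject
    uncorrelated — the independence the OLS F-tests assume.  A non-zero
    ``subject_sd`` adds a shared intercept (and with it within-subject row
    correlation the F-tests do not model); it defaults to 0.
    """

    baseline: float
    age_slope: float = 0.0              # metric units / year
    sex_slope_delta: float = 0.0        # extra slope for males
    spatial_pattern: str = "uniform"
    spatial_amplitude: float = 0.0
    vertex_noise_sd: float = 0.0
    subject_sd: float = 0.0             # between-subject random intercept
    subject_parcel_sd: float = 0.0      # subject-by-region smooth variation
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.spatial_pattern not in SPATIAL_PATTERNS:
            raise ValueError(f"unknown spatial_pattern {self.spatial_pattern!r}")
        if min(self.vertex_noise_sd, self.subject_sd,
               self.subject_parcel_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")


def default_effects() -> dict[str, EffectSpec]:
    """Study-condition effect sizes for the six microstructure metrics.

    Baselines and ranges sit in the empirically reported regimes (neurite
    fraction 0.15-0.30, ODI 0.4-0.6, MD ~ 0.8-1.0 um^2/ms, soma radius
    around 8 um); age trends encode the qualitative findings: neurite
    fraction rises with age (more steeply in males), extracellular fraction
    and MD fall, soma radius shrinks slightly, ODI and soma fraction are
    flat.  f_extracellular is derived as 1 - f_neurite - f_soma and has no
    spec of its own.
    """
    return {
        "fneurite_SANDI": EffectSpec(baseline=0.22, age_slope=0.008,
                                     sex_slope_delta=0.008,
                                     spatial_pattern="AP-linear",
                                     spatial_amplitude=0.04,
                                     vertex_noise_sd=0.02, subject_sd=0.0,
                                     subject_parcel_sd=0.03,
                                     lo=0.0, hi=1.0),
        "fsoma": EffectSpec(baseline=0.35, age_slope=0.0,
                            spatial_pattern="PD-linear", spatial_amplitude=0.04,
                            vertex_noise_sd=0.02, subject_sd=0.0,
                            subject_parcel_sd=0.03,
                            lo=0.0, hi=1.0),
        "Rsoma": EffectSpec(baseline=8.0, age_slope=-0.06,
                            sex_slope_delta=-0.08,
                            spatial_pattern="PD-linear", spatial_amplitude=0.5,
                            vertex_noise_sd=0.4, subject_sd=0.0,
                            subject_parcel_sd=0.5,
                            lo=1.0, hi=12.0),
        "ODI": EffectSpec(baseline=0.5, age_slope=0.0, sex_slope_delta=0.004,
                          vertex_noise_sd=0.02, subject_sd=0.0,
                          subject_parcel_sd=0.03,
                          lo=0.0, hi=1.0),
        "MD": EffectSpec(baseline=0.9, age_slope=-0.006,
                         sex_slope_delta=-0.004,
                         spatial_pattern="PD-linear", spatial_amplitude=0.05,
                         vertex_noise_sd=0.02, subject_sd=0.0,
                         subject_parcel_sd=0.03,
                         lo=0.0, hi=3.0),
    }


@dataclass
class ParameterSurfaceSet:
    """Per-subject, per-hemisphere metric surfaces plus generation record."""

    metrics: dict                # name -> (n_sub, 2, V)
    clamp_mask: dict             # name -> (n_sub, 2, V) bool, True where clamped
    cohort: Cohort
    mesh: MetricSurface
    effects: dict                # name -> EffectSpec used
    age_ref: float

    def hemisphere_mean(self, name: str) -> np.ndarray:
        """(n_sub, V) metric averaged across hemispheres within subject."""
        return self.metrics[name].mean(axis=1)


def make_parameter_surfaces(cohort: Cohort,
                            effects: dict[str, EffectSpec] | None = None,
                            mesh: MetricSurface | None = None,
                            seed: int = 0,
                            age_ref: float | None = None) -> ParameterSurfaceSet:
    """Generate ground-truth metric surfaces for every subject/hemisphere."""
    effects = default_effects() if effects is None else effects
    mesh = build_template_mesh() if mesh is None else mesh
    rng = np.random.default_rng(seed)
    ages = cohort.ages
    if age_ref is None:
        age_ref = float(ages.mean())
    is_male = (cohort.sexes == "M").astype(float)
    V = mesh.n_vertices
    n = cohort.n
    metrics: dict[str, np.ndarray] = {}
    clamp: dict[str, np.ndarray] = {}
    for name, spec in effects.items():
        if spec.spatial_pattern == "uniform":
            pattern = np.zeros(V)
        elif spec.spatial_pattern == "AP-linear":
            pattern = mesh.unfolded[:, 0] - 0.5
        else:  # PD-linear
            pattern = mesh.unfolded[:, 1] - 0.5
        dage = ages - age_ref
        subj = (spec.baseline + spec.age_slope * dage
                + spec.sex_slope_delta * dage * is_male
                + spec.subject_sd * rng.standard_normal(n))
        values = (subj[:, None, None]
                  + spec.spatial_amplitude * pattern[None, None, :]
                  + spec.vertex_noise_sd * rng.standard_normal((n, 2, V)))
        if spec.subject_parcel_sd > 0:
            # subject-by-region variability, independent per
            # (subfield x long-axis) cell and per hemisphere, so parcel
            # averages of distinct parcels carry independent noise
            n_sf = int(mesh.subfield.max()) + 1
            cell = mesh.subfield * (int(mesh.longaxis.max()) + 1) + mesh.longaxis
            ctrl = spec.subject_parcel_sd * rng.standard_normal(
                (n, 2, n_sf * (int(mesh.longaxis.max()) + 1)))
            values = values + ctrl[:, :, cell]
        clipped = np.clip(values, spec.lo, spec.hi)
        metrics[name] = clipped
        clamp[name] = clipped != values
    if ("fneurite_SANDI" in metrics and "fsoma" in metrics
            and "fextracellular" not in metrics):
        fec = 1.0 - metrics["fneurite_SANDI"] - metrics["fsoma"]
        clamp["fextracellular"] = (fec < 0) | (fec > 1)
        metrics["fextracellular"] = np.clip(fec, 0.0, 1.0)
        effects = dict(effects)
        spec_n, spec_s = effects["fneurite_SANDI"], effects["fsoma"]
        effects["fextracellular"] = EffectSpec(
            baseline=1.0 - spec_n.baseline - spec_s.baseline,
            age_slope=-(spec_n.age_slope + spec_s.age_slope),
            sex_slope_delta=-(spec_n.sex_slope_delta + spec_s.sex_slope_delta),
            lo=0.0, hi=1.0)
    return ParameterSurfaceSet(metrics=metrics, clamp_mask=clamp, cohort=cohort,
                               mesh=mesh, effects=effects, age_ref=age_ref)


# ------------------------------------------------------------- signals

def _forward_signals(model: str, params: dict, protocol: AcquisitionProtocol) -> np.ndarray:
    n_loc = len(next(iter(params.values())))
    out = np.empty((n_loc, protocol.n_volumes))
    if model == "sandi":
        shell_of = protocol.shells.shell_of_volume
        for i in range(n_loc):
            p = SandiParams(params["f_ec"][i], params["f_in"][i],
                            params["r_s"][i], params["d_in"][i],
                            params["d_ec"][i])
            out[i] = sandi_sphmean(p, protocol)[shell_of]
    elif model == "noddi":
        for i in range(n_loc):
            p = NoddiParams(params["f_iso"][i], params["f_in"][i],
                            params["kappa"][i], params["mu"][i])
            out[i] = noddi_signal(p, protocol)
    elif model == "dti":
        for i in range(n_loc):
            out[i] = tensor_signal(TensorParams(params["D"][i]), protocol)
    else:
        raise ValueError(f"unknown model {model!r}")
    return out


def simulate_signals(model: str, params: dict, protocol: AcquisitionProtocol,
                     snr: float | None = 50.0, seed: int = 0,
                     noise_model: str = "rician") -> np.ndarray:
    """Forward-simulate signals (n_locations x n_volumes).

    ``params`` maps parameter names to per-location arrays; required keys
    depend on ``model``: sandi (f_ec, f_in, r_s, d_in, d_ec), noddi
    (f_iso, f_in, kappa, mu), dti (D).  SANDI voxels represent a powder
    (isotropically oriented neurites), so each volume of a shell carries the
    shell's spherical-mean value.

    Rician noise adds two independent Gaussian channels of sd 1/snr to the
    complex signal and takes the magnitude; ``gaussian`` adds one channel;
    ``none`` returns the noiseless forward signal.
    """
    if noise_model not in ("rician", "gaussian", "none"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    clean = _forward_signals(model, params, protocol)
    if noise_model == "none":
        return clean
    if snr is None or snr <= 0:
        raise ValueError("snr must be positive when noise is enabled")
    rng = np.random.default_rng(seed)
    sigma = 1.0 / snr
    if noise_model == "gaussian":
        return clean + sigma * rng.standard_normal(clean.shape)
    re = clean + sigma * rng.standard_normal(clean.shape)
    im = sigma * rng.standard_normal(clean.shape)
    return np.sqrt(re**2 + im**2)


# ------------------------------------------------------------- phantom

@dataclass
class SlabPhantom:
    """Curved (annular-sector) or straight slab with analytic coordinates.

    The gray-matter domain is an annular sector extruded along z:
    radius in [r0, r1] (inner-outer axis), azimuth in [0, arc] (the curved
    anterior-posterior axis), z in [0, height] (proximal-distal axis).  Its
    three Laplace coordinates are known in closed form and are mutually
    orthogonal everywhere:

    * psi_AP = azimuth / arc                      (harmonic: angular field)
    * psi_PD = z / height                         (harmonic: linear field)
    * psi_IO = ln(r / r0) / ln(r1 / r0)           (harmonic: 2-D log-radial)

    ``arc_deg = 0`` degenerates to a straight box where all three
    coordinates are affine in the voxel indices.
    """

    labels: np.ndarray            # int volume: 0 background, 1 gray matter
    voxel_mm: float
    coords: dict                  # axis -> float volume (NaN off-mask)
    boundaries: dict              # axis -> (source mask, sink mask)
    geometry: dict                # scalar geometry parameters

    @property
    def mask(self) -> np.ndarray:
        return self.labels == 1

    def world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices (centers at i * voxel)."""
        return np.asarray(idx, dtype=float) * self.voxel_mm

    def save_nifti(self, path_prefix) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine),
                 f"{path_prefix}_labels.nii")
        for ax, vol in self.coords.items():
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                     f"{path_prefix}_coord-{ax}.nii")


def make_slab_phantom(r0_mm: float = 14.0, r1_mm: float = 24.0,
                      arc_deg: float = 150.0, height_mm: float = 20.0,
                      voxel_mm: float = 1.0, length_mm: float = 30.0) -> SlabPhantom:
    """Build the analytic slab phantom on a regular voxel grid.

    ``arc_deg > 0`` gives the curved annular sector; ``arc_deg = 0`` gives a
    straight box of AP length ``length_mm`` and IO thickness ``r1 - r0``.

    Voxel centers sit at ``index * voxel_mm`` in grid-world coordinates and
    planar region boundaries are aligned to voxel *faces* (half-integer
    positions), matching the solver's face-Dirichlet convention so that
    aligned boundaries carry no discretisation offset.
    """
    h = voxel_mm
    thickness = r1_mm - r0_mm
    if min(thickness, height_mm) < 3 * h:
        raise ValueError("domain must be at least 3 voxels thick in each direction")
    # planar region boundaries start at 1.5 h: faces of the grid whose
    # centers are at integer multiples of h, with 2 voxels of padding
    z0 = 1.5 * h
    nz = int(np.ceil(height_mm / h)) + 4

    if arc_deg > 0:
        arc = np.deg2rad(arc_deg)
        if r0_mm * arc < 3 * h:
            raise ValueError("arc length must span at least 3 voxels")
        phi_off = np.deg2rad(7.5)  # rotate off the grid axes
        # annulus centre placed off-grid so voxel centers avoid the level sets
        phis = phi_off + np.linspace(0, arc, 721)
        xs = np.concatenate([r0_mm * np.cos(phis), r1_mm * np.cos(phis), [0.0]])
        ys = np.concatenate([r0_mm * np.sin(phis), r1_mm * np.sin(phis), [0.0]])
        cx = -(xs.min() - 2.37 * h)
        cy = -(ys.min() - 2.37 * h)
        nx = int(np.ceil((xs.max() - xs.min()) / h)) + 5
        ny = int(np.ceil((ys.max() - ys.min()) / h)) + 5
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        x = ii * h - cx
        y = jj * h - cy
        z = kk * h
        r = np.hypot(x, y)
        phi = np.arctan2(y, x) - phi_off
        phi = np.where(phi < -np.pi / 2, phi + 2 * np.pi, phi)
        ap = phi / arc
        io = np.full_like(r, np.nan)
        valid_r = r > 0
        io[valid_r] = np.log(r[valid_r] / r0_mm) / np.log(r1_mm / r0_mm)
        pdc = (z - z0) / height_mm
        geometry = {"kind": "curved", "r0_mm": r0_mm, "r1_mm": r1_mm,
                    "arc_rad": arc, "phi_off_rad": phi_off,
                    "height_mm": height_mm, "center_xy": (cx, cy), "z0": z0}
    else:
        arc = 0.0
        if length_mm < 3 * h:
            raise ValueError("length must span at least 3 voxels")
        x0 = y0 = 1.5 * h
        nx = int(np.ceil(length_mm / h)) + 4
        ny = int(np.ceil(thickness / h)) + 4
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        x = ii * h
        y = jj * h
        z = kk * h
        ap = (x - x0) / length_mm
        io = (y - y0) / thickness
        pdc = (z - z0) / height_mm
        geometry = {"kind": "straight", "length_mm": length_mm,
                    "thickness_mm": thickness, "height_mm": height_mm,
                    "origin_xyz": (x0, y0, z0)}

    inside = ((ap > 0) & (ap < 1) & (io > 0) & (io < 1) & (pdc > 0) & (pdc < 1))
    labels = inside.astype(np.int16)
    coords = {}
    for ax, vol in (("AP", ap), ("PD", pdc), ("IO", io)):
        out = np.full(vol.shape, np.nan)
        out[inside] = vol[inside]
        coords[ax] = out

    def adjacent_outside(cond: np.ndarray) -> np.ndarray:
        """Voxels outside the domain satisfying cond and 6-adjacent to it."""
        near = np.zeros_like(inside)
        for axis in range(3):
            for shift in (1, -1):
                near |= np.roll(inside, shift, axis=axis)
        return (~inside) & near & cond

    with np.errstate(invalid="ignore"):
        boundaries = {
            "AP": (adjacent_outside(ap <= 0), adjacent_outside(ap >= 1)),
            "PD": (adjacent_outside(pdc <= 0), adjacent_outside(pdc >= 1)),
            "IO": (adjacent_outside(np.nan_to_num(io, nan=-1.0) <= 0),
                   adjacent_outside(np.nan_to_num(io, nan=2.0) >= 1)),
        }
    for ax, (src, snk) in boundaries.items():
        if not src.any() or not snk.any():
            raise RuntimeError(f"{ax} boundary labels do not touch the domain")
    return SlabPhantom(labels=labels, voxel_mm=voxel_mm, coords=coords,
                       boundaries=boundaries, geometry=geometry)
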
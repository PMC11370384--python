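"""Hippocampal midthickness surface meshes in folded and unfolded space.

The hippocampus unrolls to a rectangle whose axes are the anterior-posterior
long axis (AP) and the proximal-distal axis (PD, subiculum -> dentate
gyrus).  A :class:`MetricSurface` carries 3-D vertex positions, triangle
faces, per-vertex unfolded (AP, PD) coordinates in [0, 1]^2, a subfield
label (subiculum, CA1, CA2, CA3, DG/CA4 merged), a 5-bin long-axis label
(uncus, anterior lateral, anterior body, posterior body, posterior/tail)
and named per-vertex scalar channels.

The standard template is a near-regular unfolded grid of exactly 7262
vertices per hemisphere (61 rows of 119 plus a 3-vertex anterior apex
standing in for the narrow uncus tip), roughly 0.3-0.5 mm spacing at the
default physical extents.  Smaller grids with the same layout are used for
reduced-scale simulation studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MetricSurface", "build_template_mesh", "vertex_areas",
    "SUBFIELD_NAMES", "LONGAXIS_NAMES", "subfield_from_pd", "longaxis_from_ap",
]

SUBFIELD_NAMES = ("subiculum", "CA1", "CA2", "CA3", "DG_CA4")
#: PD band edges for the synthetic subfield parcellation (proximal->distal)
SUBFIELD_PD_EDGES = (0.0, 0.22, 0.52, 0.62, 0.80, 1.0001)

LONGAXIS_NAMES = ("uncus", "anterior_lateral", "body_anterior",
                  "body_posterior", "posterior_tail")
#: AP band edges for the 5-bin long-axis parcellation (anterior->posterior)
LONGAXIS_AP_EDGES = (0.0, 0.10, 0.32, 0.55, 0.78, 1.0001)


def subfield_from_pd(pd_coord: np.ndarray) -> np.ndarray:
    """Subfield index (0..4) from the proximal-distal coordinate."""
    return np.clip(np.digitize(pd_coord, SUBFIELD_PD_EDGES) - 1, 0,
                   len(SUBFIELD_NAMES) - 1)


def longaxis_from_ap(ap_coord: np.ndarray) -> np.ndarray:
    """Long-axis bin index (0..4) from the anterior-posterior coordinate."""
    return np.clip(np.digitize(ap_coord, LONGAXIS_AP_EDGES) - 1, 0,
                   len(LONGAXIS_NAMES) - 1)


@dataclass
class MetricSurface:
    """Triangulated surface with unfolded coordinates and metric channels."""

    vertices: np.ndarray          # (V, 3) mm
    faces: np.ndarray             # (F, 3) int
    unfolded: np.ndarray          # (V, 2) [AP, PD] in [0, 1]^2
    subfield: np.ndarray          # (V,) int index into SUBFIELD_NAMES
    longaxis: np.ndarray          # (V,) int index into LONGAXIS_NAMES
    data: dict = field(default_factory=dict)  # name -> (V,) array
    ap_extent_mm: float = 40.0
    pd_extent_mm: float = 25.0

    def __post_init__(self) -> None:
        V = self.vertices.shape[0]
        for name in ("unfolded", "subfield", "longaxis"):
            if getattr(self, name).shape[0] != V:
                raise ValueError(f"{name} must have one entry per vertex")
        if np.any(self.unfolded < 0) or np.any(self.unfolded > 1):
            raise ValueError("unfolded coordinates must lie in [0, 1]^2")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def with_vertices(self, vertices: np.ndarray) -> "MetricSurface":
        return replace(self, vertices=np.asarray(vertices, dtype=float),
                       data=dict(self.data))

    def set_channel(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_vertices,):
            raise ValueError("channel must be one value per vertex")
        self.data[name] = values

    # ------------------------------------------------------------- I/O
    def channels_to_csv(self, path) -> None:
        """Long-format CSV twin of the metric channels."""
        frames = []
        for name, values in self.data.items():
            frames.append(pd.DataFrame({
                "vertex": np.arange(self.n_vertices),
                "metric": name,
                "value": values,
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    def save_gifti(self, path) -> None:
        """GIFTI surface (coordinates + topology) via nibabel."""
        import nibabel as nib

        coord = nib.gifti.GiftiDataArray(self.vertices.astype(np.float32),
                                         intent="NIFTI_INTENT_POINTSET")
        topo = nib.gifti.GiftiDataArray(self.faces.astype(np.int32),
                                        intent="NIFTI_INTENT_TRIANGLE")
        nib.save(nib.gifti.GiftiImage(darrays=[coord, topo]), str(path))

    def save_metric_gifti(self, path, names=None) -> None:
        import nibabel as nib

        names = list(self.data) if names is None else names
        arrays = [nib.gifti.GiftiDataArray(self.data[n].astype(np.float32),
                                           intent="NIFTI_INTENT_SHAPE")
                  for n in names]
        img = nib.gifti.GiftiImage(darrays=arrays)
        nib.save(img, str(path))


def _stitch_rows(row_a: np.ndarray, ap_a: np.ndarray,
                 row_b: np.ndarray, ap_b: np.ndarray) -> list[tuple[int, int, int]]:
    """Greedy strip triangulation between two vertex rows (possibly ragged)."""
    faces = []
    i = j = 0
    while i < len(row_a) - 1 or j < len(row_b) - 1:
        can_a = i < len(row_a) - 1
        can_b = j < len(row_b) - 1
        if can_a and can_b:
            # advance whichever pointer yields the shorter new diagonal
            if abs(ap_a[i + 1] - ap_b[j]) <= abs(ap_b[j + 1] - ap_a[i]):
                faces.append((row_a[i], row_a[i + 1], row_b[j]))
                i += 1
            else:
                faces.append((row_a[i], row_b[j + 1], row_b[j]))
                j += 1
        elif can_a:
            faces.append((row_a[i], row_a[i + 1], row_b[j]))
            i += 1
        else:
            faces.append((row_a[i], row_b[j + 1], row_b[j]))
            j += 1
    return faces


def build_template_mesh(n_ap: int = 119, n_pd: int = 61, n_apex: int = 3,
                        ap_extent_mm: float = 40.0,
                        pd_extent_mm: float = 25.0) -> MetricSurface:
    """Standard unfolded-grid template.

    Defaults give exactly ``n_apex + n_ap * n_pd = 7262`` vertices.  The apex
    row sits at AP = 0 (anterior uncus tip); the remaining rows form a
    regular grid.  Vertex 3-D positions are the planar unfolded embedding
    (AP * ap_extent, PD * pd_extent, 0); surface-construction routines
    replace them with folded coordinates.
    """
    if n_ap < 2 or n_pd < 2:
        raise ValueError("grid must be at least 2 x 2")
    rows: list[np.ndarray] = []
    row_ap: list[np.ndarray] = []
    unfolded = []
    next_idx = 0
    if n_apex > 0:
        ap = np.full(n_apex, 0.0)
        pd_c = np.linspace(0.25, 0.75, n_apex)
        rows.append(np.arange(next_idx, next_idx + n_apex))
        row_ap.append(pd_c)  # stitch apex along PD against the first grid row
        unfolded.append(np.column_stack([ap, pd_c]))
        next_idx += n_apex
    ap_grid = np.linspace(0.0 if n_apex == 0 else 1.0 / n_ap, 1.0, n_ap)
    pd_grid = np.linspace(0.0, 1.0, n_pd)
    # rows indexed by AP position, each row spans PD
    for a in ap_grid:
        rows.append(np.arange(next_idx, next_idx + n_pd))
        row_ap.append(pd_grid)
        unfolded.append(np.column_stack([np.full(n_pd, a), pd_grid]))
        next_idx += n_pd
    unfolded_arr = np.concatenate(unfolded, axis=0)
    faces: list[tuple[int, int, int]] = []
    for (ra, aa), (rb, ab) in zip(zip(rows[:-1], row_ap[:-1]),
                                  zip(rows[1:], row_ap[1:])):
        faces.extend(_stitch_rows(ra, aa, rb, ab))
    vertices = np.column_stack([
        unfolded_arr[:, 0] * ap_extent_mm,
        unfolded_arr[:, 1] * pd_extent_mm,
        np.zeros(len(unfolded_arr)),
    ])
    return MetricSurface(
        vertices=vertices,
        faces=np.asarray(faces, dtype=int),
        unfolded=unfolded_arr,
        subfield=subfield_from_pd(unfolded_arr[:, 1]),
        longaxis=longaxis_from_ap(unfolded_arr[:, 0]),
        ap_extent_mm=ap_extent_mm,
        pd_extent_mm=pd_extent_mm,
    )


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex area: one third of each incident triangle's area."""
    v = np.asarray(vertices, dtype=float)
    if v.shape[1] == 2:  # planar mesh: embed in 3-D
        v = np.column_stack([v, np.zeros(v.shape[0])])
    tri = v[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=-1)
    out = np.zeros(v.shape[0])
    for k in range(3):
        np.add.at(out, faces[:, k], area / 3.0)
    return out
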
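"""Multi-shell diffusion acquisition protocols.

A protocol is the complete description of the diffusion encoding: one b-value
and one unit gradient direction per volume, plus the pulsed-gradient timings
(small delta = gradient duration, big Delta = gradient separation) that the
restricted-diffusion (soma) signal model needs.

The default protocol mirrors a 6-shell ultra-strong-gradient paediatric
acquisition: b = 0 (14 volumes), 0.5 (30), 1.2 (30), 2.4 (60), 4.0 (60) and
6.0 (60) ms/um^2, 254 volumes in total.  Directions within a shell are spread
by electrostatic repulsion of antipodal point pairs on the unit sphere.

Unit conventions: b-values in ms/um^2, timings in ms, diffusivities in
um^2/ms.  Readers that encounter FSL-style b-values in s/mm^2 convert by
multiplying with 1e-3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "DEFAULT_SHELL_SPEC",
    "make_protocol",
    "dispersed_directions",
    "group_shells",
    "ShellTable",
]

#: shell layout of the study protocol: (b-value in ms/um^2, number of volumes)
DEFAULT_SHELL_SPEC: tuple[tuple[float, int], ...] = (
    (0.0, 14),
    (0.5, 30),
    (1.2, 30),
    (2.4, 60),
    (4.0, 60),
    (6.0, 60),
)

#: default pulse timings (ms).  Not part of the published acquisition table;
#: chosen as plausible for a 300 mT/m system and always echoed in sidecars.
DEFAULT_DELTA = 7.0
DEFAULT_BIG_DELTA = 24.0


@dataclass(frozen=True)
class AcquisitionProtocol:
    """b-values, unit directions and pulse timings for every volume."""

    bvals: np.ndarray  # (n_vol,) ms/um^2
    bvecs: np.ndarray  # (n_vol, 3) unit vectors (arbitrary for b=0)
    delta: float = DEFAULT_DELTA  # gradient duration, ms
    big_delta: float = DEFAULT_BIG_DELTA  # gradient separation, ms

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError("bvals must be (n,) and bvecs (n, 3)")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        if not (self.big_delta > self.delta > 0):
            raise ValueError("require Delta > delta > 0 (ms)")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def shells(self) -> "ShellTable":
        return group_shells(self.bvals)

    # ---------------------------------------------------------------- I/O
    def save(self, prefix: str | Path) -> None:
        """Write FSL-style ``<prefix>.bval`` / ``<prefix>.bvec`` (s/mm^2)
        plus a JSON timing sidecar ``<prefix>.json``."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".bval"), self.bvals[None] * 1e3, fmt="%.1f")
        np.savetxt(prefix.with_suffix(".bvec"), self.bvecs.T, fmt="%.6f")
        sidecar = {
            "delta_ms": self.delta,
            "big_delta_ms": self.big_delta,
            "b_units": "s/mm^2 in .bval; ms/um^2 internally (x1e-3)",
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "AcquisitionProtocol":
        prefix = Path(prefix)
        bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel() * 1e-3
        bvecs = np.loadtxt(prefix.with_suffix(".bvec"))
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        timing = json.loads(prefix.with_suffix(".json").read_text())
        return cls(bvals, bvecs, timing["delta_ms"], timing["big_delta_ms"])


@dataclass(frozen=True)
class ShellTable:
    """Grouping of volumes into b-shells (b=0 volumes are shell 0)."""

    b_shells: np.ndarray  # (n_shell,) representative b per shell, ascending
    shell_of_volume: np.ndarray  # (n_vol,) shell index per volume

    def volumes_in(self, shell: int) -> np.ndarray:
        return np.flatnonzero(self.shell_of_volume == shell)

    @property
    def n_shells(self) -> int:
        return int(self.b_shells.size)

    @property
    def nonzero_shells(self) -> np.ndarray:
        return np.flatnonzero(self.b_shells > 0)


def group_shells(bvals: np.ndarray, tol: float = 0.05) -> ShellTable:
    """Cluster b-values into shells; values within ``tol`` ms/um^2 merge."""
    bvals = np.asarray(bvals, dtype=float)
    order = np.argsort(bvals)
    reps: list[float] = []
    assign = np.empty(bvals.size, dtype=int)
    for idx in order:
        b = bvals[idx]
        if reps and abs(b - reps[-1]) <= tol:
            assign[idx] = len(reps) - 1
        else:
            reps.append(b)
            assign[idx] = len(reps) - 1
    reps_arr = np.array(reps)
    if reps_arr.size and reps_arr[0] <= tol:
        reps_arr[0] = 0.0
    return ShellTable(reps_arr, assign)


def _repulsion_energy_step(points: np.ndarray, step: float) -> np.ndarray:
    """One projected-gradient step of antipodal electrostatic repulsion."""
    # interactions with both +/- of every other point (diffusion antipodal sym)
    signed = np.concatenate([points, -points], axis=0)
    diff = points[:, None, :] - signed[None, :, :]  # (n, 2n, 3)
    dist2 = np.sum(diff**2, axis=-1)
    np.fill_diagonal(dist2[:, : points.shape[0]], np.inf)
    dist2[dist2 < 1e-12] = np.inf
    force = np.sum(diff / dist2[..., None] ** 1.5, axis=1)
    new = points + step * force
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def dispersed_directions(n: int, seed: int | np.random.Generator = 0,
                         n_iter: int = 300) -> np.ndarray:
    """``n`` unit vectors spread by minimising antipodal Coulomb energy.

    Deterministic for a fixed seed.  For n == 1 returns the seed's random
    direction normalised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    if n == 1:
        return pts
    step = 0.1 / n
    for _ in range(n_iter):
        pts = _repulsion_energy_step(pts, step)
    return pts


def make_protocol(shell_spec=DEFAULT_SHELL_SPEC, delta: float = DEFAULT_DELTA,
                  big_delta: float = DEFAULT_BIG_DELTA,
                  seed: int = 0) -> AcquisitionProtocol:
    """Build a multi-shell protocol from ``[(b, n_volumes), ...]``.

    b=0 volumes get a dummy +z direction.  Every non-zero shell receives its
    own electrostatically dispersed direction set.
    """
    if not (big_delta > delta > 0):
        raise ValueError("require Delta > delta > 0 (ms)")
    rng = np.random.default_rng(seed)
    bvals: list[np.ndarray] = []
    bvecs: list[np.ndarray] = []
    for b, n_dir in shell_spec:
        if b < 0:
            raise ValueError("b-values must be non-negative")
        if n_dir <= 0:
            raise ValueError("each shell needs at least one volume")
        bvals.append(np.full(n_dir, float(b)))
        if b == 0:
            vecs = np.tile([0.0, 0.0, 1.0], (n_dir, 1))
        else:
            vecs = dispersed_directions(n_dir, rng)
        bvecs.append(vecs)
    return AcquisitionProtocol(np.concatenate(bvals), np.concatenate(bvecs),
                               delta, big_delta)
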
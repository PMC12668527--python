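"""Simulation grid, Courant time step and material assignment.

The solver works on a uniform Yee lattice.  Materials are assigned per
cell (pure staircase, no sub-cell averaging): all three E components
indexed (i, j, k) use cell (i, j, k)'s permittivity and conductivity, so
the discrete Joule dissipation equals the per-cell absorbed-power sum used
by the dosimetry module exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import C0
from ..phantom import VoxelPhantom

__all__ = ["courant_timestep", "SimulationGrid", "MaterialGrid", "make_material_grid"]


def courant_timestep(pitch: float, safety: float = 1.0) -> float:
    """3-D Courant-stable time step dt = safety * pitch / (c sqrt(3))."""
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    if not 0.0 < safety <= 1.0:
        raise ValueError(f"safety factor must lie in (0, 1], got {safety}")
    return safety * pitch / (C0 * np.sqrt(3.0))


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform Yee grid geometry and time step."""

    dims: tuple[int, int, int]
    pitch: float
    dt: float
    pml_cells: int = 10

    def __post_init__(self) -> None:
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 cells per axis")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if self.dt <= 0 or self.dt > courant_timestep(self.pitch) * (1 + 1e-12):
            raise ValueError(
                f"dt = {self.dt:g} s violates the Courant criterion "
                f"dt <= pitch/(c sqrt(3)) = {courant_timestep(self.pitch):g} s"
            )
        if self.pml_cells < 8:
            raise ValueError("need at least 8 PML cells per face")


@dataclass
class MaterialGrid:
    """Per-cell relative permittivity and conductivity (background vacuum)."""

    eps_r: np.ndarray
    sigma: np.ndarray
    pitch: float
    labels: np.ndarray | None = None  # embedded phantom labels, same shape
    tissue_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eps_r = np.ascontiguousarray(self.eps_r, dtype=np.float64)
        self.sigma = np.ascontiguousarray(self.sigma, dtype=np.float64)
        if self.eps_r.shape != self.sigma.shape or self.eps_r.ndim != 3:
            raise ValueError("eps_r and sigma must be equal-shape 3-D arrays")
        if np.any(self.eps_r < 1.0):
            raise ValueError("eps_r must be >= 1 everywhere")
        if np.any(self.sigma < 0.0):
            raise ValueError("sigma must be >= 0 everywhere")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.eps_r.shape  # type: ignore[return-value]

    def tissue_mask(self, tissue: str | int | None = None) -> np.ndarray:
        """Mask of one tissue (or of all tissue cells when None)."""
        if self.labels is None:
            return self.sigma > 0
        if tissue is None:
            return self.labels > 0
        if isinstance(tissue, str):
            codes = [c for c, n in self.tissue_table.items() if n == tissue]
            if not codes:
                raise KeyError(f"unknown tissue {tissue!r}")
            return self.labels == codes[0]
        return self.labels == int(tissue)


def make_material_grid(
    phantom: VoxelPhantom,
    props,
    padding: int,
    pml_cells: int = 10,
    tf_margin: int = 2,
) -> MaterialGrid:
    """Embed a phantom, centred, in a vacuum grid with ``padding`` cells of
    clearance on every side.

    All tissue voxels receive the (shared) dielectric properties ``props``;
    the padding must leave room for the absorbing boundary plus the
    total-field/scattered-field box (``pml_cells + tf_margin`` plus one
    free cell) or the source cannot be placed.
    """
    min_padding = pml_cells + tf_margin + 1
    if padding < min_padding:
        raise ValueError(
            f"padding of {padding} cells is too small: need at least "
            f"{min_padding} (pml_cells + TF/SF margin + 1)"
        )
    if phantom.tissue_voxel_count == 0:  # unreachable via VoxelPhantom, but explicit
        raise ValueError("phantom has no tissue voxels")
    shape = tuple(s + 2 * padding for s in phantom.labels.shape)
    eps = np.ones(shape)
    sig = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.uint8)
    sl = tuple(slice(padding, padding + s) for s in phantom.labels.shape)
    tissue = phantom.labels > 0
    eps[sl][tissue] = props.eps_r
    sig[sl][tissue] = props.sigma
    labels[sl] = phantom.labels
    return MaterialGrid(
        eps_r=eps,
        sigma=sig,
        pitch=phantom.pitch,
        labels=labels,
        tissue_table=dict(phantom.tissue_table),
    )
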
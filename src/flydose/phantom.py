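"""Voxel phantom data model, mesh voxelization and grid-file I/O.

A `VoxelPhantom` is a labelled 3-D grid of small-integer tissue codes
(0 = background) with a physical voxel pitch and origin; it is the digital
stand-in for the organism in all dosimetry computations.  Axis 0 is the
anteroposterior axis by convention, voxels are cell-centred and 0-based:
voxel (i, j, k) is centred at ``origin + (i + 1/2, j + 1/2, k + 1/2) * pitch``.

Phantoms are stored as detached-header NRRD (a plain-text ``.nhdr`` plus a
``.raw`` payload) with a JSON sidecar carrying the tissue label table, so
the files stay inspectable with standard volume viewers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelPhantom",
    "tissue_volumes",
    "voxelize_mesh",
    "read_phantom",
    "write_phantom",
]


@dataclass
class VoxelPhantom:
    """Labelled tissue voxel grid.

    Parameters
    ----------
    labels
        3-D ``uint8`` array of tissue codes, 0 meaning background.
    pitch
        Isotropic voxel edge length in metres.
    origin
        Physical position (m) of the grid corner (not the first voxel
        centre), 3-vector.
    tissue_table
        Mapping label code -> tissue name for every nonzero code present.
    """

    labels: np.ndarray
    pitch: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tissue_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        self.origin = np.asarray(self.origin, dtype=float)
        present = set(int(c) for c in np.unique(self.labels)) - {0}
        if not present:
            raise ValueError("phantom has no tissue voxels")
        missing = present - set(self.tissue_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from tissue_table")

    @property
    def tissue_voxel_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    @property
    def total_volume(self) -> float:
        """Total tissue volume in m^3 (voxel count x pitch^3)."""
        return self.tissue_voxel_count * self.pitch**3

    def mask(self, tissue: str | int) -> np.ndarray:
        """Boolean mask of one tissue, by name or label code."""
        if isinstance(tissue, str):
            codes = [c for c, n in self.tissue_table.items() if n == tissue]
            if not codes:
                raise KeyError(f"unknown tissue {tissue!r}")
            code = codes[0]
        else:
            code = int(tissue)
        return self.labels == code


def tissue_volumes(phantom: VoxelPhantom) -> dict[str, float]:
    """Per-tissue volumes in m^3; they sum exactly to the total volume."""
    out: dict[str, float] = {}
    v_vox = phantom.pitch**3
    for code, name in sorted(phantom.tissue_table.items()):
        out[name] = int(np.count_nonzero(phantom.labels == code)) * v_vox
    return out


# ---------------------------------------------------------------------------
# Mesh voxelization


def _open_edge_count(mesh) -> int:
    """Number of edges not shared by exactly two faces."""
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def voxelize_mesh(mesh, pitch: float, label: int = 1, name: str = "tissue") -> VoxelPhantom:
    """Voxelize a watertight triangulated surface by centre-point parity.

    A voxel is labelled iff its centre lies inside the surface, decided by
    the parity of ray crossings along the +z axis.  Voxel centres are
    nudged off exact coplanarity by a deterministic sub-voxel offset so
    that rays never graze vertices or edges, making the result reproducible.

    ``mesh`` is a ``trimesh.Trimesh`` (or anything exposing ``.vertices``,
    ``.faces``, ``.edges``, ``.bounds``).
    """
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    n_open = _open_edge_count(mesh)
    if n_open:
        raise ValueError(
            f"mesh is not watertight: {n_open} edges are not shared by exactly 2 triangles"
        )

    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    lo, hi = np.asarray(mesh.bounds, dtype=float)
    # one-voxel margin so the surface never touches the grid boundary
    origin = lo - pitch
    dims = np.ceil((hi - origin) / pitch).astype(int) + 1

    # deterministic tie-break: shift ray positions off lattice-aligned geometry
    eps = 1e-6 * pitch
    xc = origin[0] + (np.arange(dims[0]) + 0.5) * pitch + eps
    yc = origin[1] + (np.arange(dims[1]) + 0.5) * pitch + 2 * eps
    zc = origin[2] + (np.arange(dims[2]) + 0.5) * pitch

    # parity accumulated per (x, y) column: count surface crossings below
    # each voxel-centre z, then odd count = inside
    crossings = [[[] for _ in range(dims[1])] for _ in range(dims[0])]
    tri = verts[faces]  # (ntri, 3, 3)
    for t in range(tri.shape[0]):
        v0, v1, v2 = tri[t]
        txlo, txhi = min(v0[0], v1[0], v2[0]), max(v0[0], v1[0], v2[0])
        tylo, tyhi = min(v0[1], v1[1], v2[1]), max(v0[1], v1[1], v2[1])
        i0 = int(np.searchsorted(xc, txlo, side="left"))
        i1 = int(np.searchsorted(xc, txhi, side="right"))
        j0 = int(np.searchsorted(yc, tylo, side="left"))
        j1 = int(np.searchsorted(yc, tyhi, side="right"))
        if i0 >= i1 or j0 >= j1:
            continue
        xs = xc[i0:i1][:, None]
        ys = yc[j0:j1][None, :]
        # 2-D barycentric test in the xy projection
        d = (v1[1] - v2[1]) * (v0[0] - v2[0]) + (v2[0] - v1[0]) * (v0[1] - v2[1])
        if d == 0.0:
            continue  # triangle vertical in projection: contributes no crossing
        a = ((v1[1] - v2[1]) * (xs - v2[0]) + (v2[0] - v1[0]) * (ys - v2[1])) / d
        b = ((v2[1] - v0[1]) * (xs - v2[0]) + (v0[0] - v2[0]) * (ys - v2[1])) / d
        c = 1.0 - a - b
        inside = (a >= 0) & (b >= 0) & (c >= 0)
        if not inside.any():
            continue
        zhit = a * v0[2] + b * v1[2] + c * v2[2]
        ii, jj = np.nonzero(inside)
        for m in range(ii.size):
            crossings[i0 + ii[m]][j0 + jj[m]].append(zhit[ii[m], jj[m]])

    labels = np.zeros(tuple(dims), dtype=np.uint8)
    for i in range(dims[0]):
        for j in range(dims[1]):
            zs = crossings[i][j]
            if not zs:
                continue
            zs = np.sort(np.asarray(zs))
            # odd number of crossings below a centre => centre is inside
            idx = np.searchsorted(zs, zc)
            labels[i, j, :] = np.where(idx % 2 == 1, label, 0)

    return VoxelPhantom(
        labels=labels, pitch=pitch, origin=origin, tissue_table={int(label): name}
    )


# ---------------------------------------------------------------------------
# Grid-file I/O: detached-header NRRD + JSON sidecar


def write_phantom(phantom: VoxelPhantom, path: str | Path) -> Path:
    """Write ``<stem>.nhdr`` + ``<stem>.raw`` + ``<stem>.json``.

    Returns the header path.  The raw payload is the label array in C
    order, uint8, little-endian.
    """
    stem = Path(path)
    if stem.suffix in (".nhdr", ".raw", ".json"):
        stem = stem.with_suffix("")
    raw = stem.with_suffix(".raw")
    hdr = stem.with_suffix(".nhdr")
    sidecar = stem.with_suffix(".json")

    phantom.labels.tofile(raw)
    dims = phantom.labels.shape
    hdr.write_text(
        "NRRD0004\n"
        "# flydose voxel phantom\n"
        "type: uint8\n"
        "dimension: 3\n"
        f"sizes: {dims[0]} {dims[1]} {dims[2]}\n"
        "encoding: raw\n"
        "endian: little\n"
        "space dimension: 3\n"
        f"space directions: ({phantom.pitch},0,0) (0,{phantom.pitch},0) (0,0,{phantom.pitch})\n"
        f"space origin: ({phantom.origin[0]},{phantom.origin[1]},{phantom.origin[2]})\n"
        f"data file: {raw.name}\n"
    )
    sidecar.write_text(
        json.dumps(
            {
                "pitch_m": phantom.pitch,
                "origin_m": list(map(float, phantom.origin)),
                "tissue_table": {str(k): v for k, v in phantom.tissue_table.items()},
            },
            indent=2,
        )
    )
    return hdr


def read_phantom(path: str | Path) -> VoxelPhantom:
    """Read a phantom written by `write_phantom`."""
    hdr = Path(path)
    if hdr.suffix != ".nhdr":
        hdr = hdr.with_suffix(".nhdr")
    fields: dict[str, str] = {}
    lines = hdr.read_text().splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{hdr}: not an NRRD header")
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{hdr}: malformed header line {line!r}")
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    if fields.get("type") != "uint8" or fields.get("encoding") != "raw":
        raise ValueError(f"{hdr}: only raw uint8 phantoms are supported")
    dims = tuple(int(s) for s in fields["sizes"].split())
    pitch = float(fields["space directions"].split("(")[1].split(",")[0])
    if pitch <= 0:
        raise ValueError(f"{hdr}: non-positive pitch {pitch}")
    origin = np.array(
        [float(s) for s in fields["space origin"].strip("()").split(",")]
    )
    raw = hdr.parent / fields["data file"]
    labels = np.fromfile(raw, dtype=np.uint8)
    if labels.size != int(np.prod(dims)):
        raise ValueError(f"{raw}: payload size does not match header sizes {dims}")
    labels = labels.reshape(dims)

    sidecar = hdr.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    table = {int(k): str(v) for k, v in meta["tissue_table"].items()}
    present = set(int(c) for c in np.unique(labels)) - {0}
    unknown = present - set(table)
    if unknown:
        raise ValueError(f"{raw}: label codes {sorted(unknown)} not in tissue table")
    return VoxelPhantom(labels=labels, pitch=pitch, origin=origin, tissue_table=table)
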
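"""Voxel-grid data model and NIfTI I/O.

All statistics modules operate on cohorts of :class:`VoxelGrid` objects that
share one template geometry.  A grid is a 3D scalar field indexed ``[x, y, z]``
with a physical spacing (mm) and origin; the payload may be dose (Gy), a
hazard ratio, a p-value, a binary mask, or a test statistic.  Cross-patient
operations require *compatible* grids: identical dims and spacing/origin
agreeing within ``GEOM_TOL`` mm.

The canonical voxel ordering used everywhere downstream is x-fastest
(Fortran order over an ``[x, y, z]``-indexed array), so that statistic
vectors scatter back into grids deterministically and bit-stably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np

GEOM_TOL = 1e-6

PayloadKind = Literal["dose", "hr", "pvalue", "mask", "stat"]

#: Template geometries used in the source trials' registration pipelines,
#: shipped as convenience fixtures; any geometry is accepted.
TEMPLATE_GEOMETRIES = {
    "T1": {"dims": (332, 249, 64), "spacing": (1.17, 1.17, 2.0)},
    "T2": {"dims": (327, 178, 76), "spacing": (1.17, 1.17, 2.5)},
    "T3": {"dims": (132, 130, 129), "spacing": (1.24, 1.24, 1.0)},
}


class GridError(ValueError):
    """Raised on contract violations in grid construction or combination."""


@dataclass
class VoxelGrid:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    data
        3D array indexed ``[x, y, z]``.
    spacing
        Voxel size in mm along (x, y, z); all positive.
    origin
        Physical coordinate of voxel (0, 0, 0) in mm.
    payload_kind
        One of ``dose``, ``hr``, ``pvalue``, ``mask``, ``stat``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    payload_kind: PayloadKind = "dose"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridError(f"non-3D image: got {self.data.ndim} dimensions")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be 3 positive values, got {self.spacing}")
        self._validate_payload()

    def _validate_payload(self) -> None:
        kind = self.payload_kind
        finite = np.isfinite(self.data)
        if kind == "dose":
            n_bad = int((~finite).sum())
            if n_bad:
                raise GridError(f"dose payload contains {n_bad} non-finite voxels")
            if np.any(self.data < 0):
                raise GridError("dose payload contains negative voxels")
        elif kind == "mask":
            vals = np.unique(self.data[finite])
            if not np.all(np.isin(vals, (0, 1))):
                raise GridError("mask payload must contain only {0, 1}")
        elif kind == "pvalue":
            if np.any((self.data[finite] < 0) | (self.data[finite] > 1)):
                raise GridError("p-value payload must lie in [0, 1]")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(d) for d in self.data.shape)

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    def is_compatible(self, other: "VoxelGrid", tol: float = GEOM_TOL) -> bool:
        """Geometry equality: same dims, spacing/origin within ``tol`` mm."""
        return (
            self.dims == other.dims
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def with_payload(self, data: np.ndarray, payload_kind: PayloadKind) -> "VoxelGrid":
        """New grid on the same geometry carrying a different payload."""
        if np.asarray(data).shape != self.data.shape:
            raise GridError("payload shape does not match grid dims")
        return replace(self, data=np.asarray(data), payload_kind=payload_kind, meta={})

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class TemplateSpace:
    """The common registration geometry plus named structure masks.

    ``structure_masks`` must contain at least ``analysis_region`` (non-empty);
    conventional additional keys are ``ctv``, ``bladder``, ``rectum``.
    """

    geometry: VoxelGrid
    structure_masks: dict[str, VoxelGrid]

    def __post_init__(self) -> None:
        if "analysis_region" not in self.structure_masks:
            raise GridError("TemplateSpace requires an 'analysis_region' mask")
        for name, m in self.structure_masks.items():
            if m.payload_kind != "mask":
                raise GridError(f"structure '{name}' is not a mask payload")
            if not m.is_compatible(self.geometry):
                raise GridError(f"structure '{name}' incompatible with template geometry")
        if self.structure_masks["analysis_region"].data.sum() == 0:
            raise GridError("analysis_region mask is empty")

    def mask(self, name: str) -> VoxelGrid:
        return self.structure_masks[name]


def require_compatible(grids: Iterable[VoxelGrid], tol: float = GEOM_TOL) -> None:
    grids = list(grids)
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if not ref.is_compatible(g, tol):
            raise GridError(f"grid {i} incompatible with grid 0 (dims/spacing/origin)")


def write_grid(grid: VoxelGrid, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write a grid as NIfTI-1 (masks uint8, everything else float32).

    A JSON sidecar (same stem, ``.json``) records payload_kind and any extra
    metadata so round trips restore the payload context.
    """
    path = Path(path)
    dtype = np.uint8 if grid.payload_kind == "mask" else np.float32
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=dtype), grid.affine())
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    meta = {"payload_kind": grid.payload_kind, **grid.meta, **(sidecar or {})}
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_grid(path: str | Path, payload_kind: PayloadKind | None = None) -> VoxelGrid:
    """Read a NIfTI-1 grid, reorienting to canonical RAS+ axis order.

    ``payload_kind`` overrides the sidecar; defaults to ``dose`` when neither
    is available.  Non-finite voxels are rejected for dose payloads.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such grid file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise GridError(f"non-3D image: {path} has shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    if payload_kind is None:
        sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        payload_kind = meta.get("payload_kind", "dose")
    else:
        meta = {}
    extra = {k: v for k, v in meta.items() if k != "payload_kind"}
    return VoxelGrid(data=data, spacing=spacing, origin=origin, payload_kind=payload_kind, meta=extra)


def subsample_grid(grid: VoxelGrid, factor: Sequence[int]) -> VoxelGrid:
    """Keep every ``factor``-th voxel per axis starting at index 0.

    Spacing scales by the factor; the origin is unchanged (index 0 is kept on
    every axis).  Deterministic; used to thin large templates uniformly
    (e.g. 1-in-2 per axis).
    """
    factor = tuple(int(f) for f in factor)
    if len(factor) != 3 or any(f < 1 for f in factor):
        raise GridError(f"subsample factor must be 3 integers >= 1, got {factor}")
    for f, d in zip(factor, grid.dims):
        if f > d:
            raise GridError(f"subsample factor {f} exceeds axis extent {d}")
    data = grid.data[:: factor[0], :: factor[1], :: factor[2]]
    spacing = tuple(s * f for s, f in zip(grid.spacing, factor))
    return VoxelGrid(data=data.copy(), spacing=spacing, origin=grid.origin,
                     payload_kind=grid.payload_kind, meta=dict(grid.meta))


def flatten_masked(grid: VoxelGrid, mask: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Values at mask==1 voxels in canonical (x-fastest) order.

    Returns ``(values, index_map)`` where ``index_map`` holds the flat
    canonical indices; :func:`scatter_to_grid` is the inverse.
    """
    if mask.payload_kind != "mask":
        raise GridError("flatten_masked requires a mask payload")
    if not grid.is_compatible(mask):
        raise GridError("grid and mask have incompatible geometry")
    flat_mask = np.asarray(mask.data, dtype=bool).ravel(order="F")
    index_map = np.flatnonzero(flat_mask)
    if index_map.size == 0:
        raise GridError("empty mask")
    values = grid.data.ravel(order="F")[index_map]
    return values, index_map


def scatter_to_grid(
    values: np.ndarray,
    index_map: np.ndarray,
    template: VoxelGrid,
    payload_kind: PayloadKind = "stat",
    fill: float = 0.0,
) -> VoxelGrid:
    """Scatter a statistic vector back into a grid (inverse of flatten)."""
    values = np.asarray(values)
    if values.shape[0] != index_map.shape[0]:
        raise GridError("values and index map lengths differ")
    flat = np.full(template.n_voxels, fill, dtype=float)
    flat[index_map] = values
    data = flat.reshape(template.dims, order="F")
    return VoxelGrid(data=data, spacing=template.spacing, origin=template.origin,
                     payload_kind=payload_kind)


def cohort_matrix(grids: Sequence[VoxelGrid], mask: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into an (n_patients, n_masked_voxels) dose matrix."""
    require_compatible(list(grids) + [mask])
    rows = []
    index_map = None
    for g in grids:
        vals, index_map = flatten_masked(g, mask)
        rows.append(vals)
    return np.asarray(rows, dtype=float), index_map
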
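"""Spherical icosahedral cortical meshes, geodesic searchlights, and target grids.

All meshes are subdivided icosahedra living on a sphere of nominal radius
(default 100 mm, matching template registration spheres), so geodesic
distances are exact great-circle arc lengths.  Vertices are ordered
coarse-first: the first ``10*4**(k-1) + 2`` vertices of an order-``k`` mesh
are exactly the order-``(k-1)`` mesh, which lets coarse connectivity-target
grids be index prefixes of the full-resolution mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel grid order meaning "every cortical vertex is its own target".
FULL = "full"

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def n_icosphere_vertices(order: int) -> int:
    """Vertex count of an order-``order`` subdivided icosahedron: ``10*4**order + 2``."""
    return 10 * 4**order + 2


@dataclass
class SurfaceMesh:
    """A spherical icosahedral hemisphere mesh with a cortex (medial-wall) mask.

    Attributes
    ----------
    coords : (V, 3) float array of vertex positions on the nominal sphere.
    faces : (F, 3) int array of 0-based triangle vertex indices.
    hemisphere : ``"left"`` or ``"right"``.
    cortex_mask : (V,) bool; False marks non-cortical (medial-wall) vertices.
    subdivision_order : icosphere subdivision level (V = 10*4**order + 2).
    nominal_radius_mm : radius of the sphere the vertices lie on.
    """

    coords: np.ndarray
    faces: np.ndarray
    hemisphere: str
    subdivision_order: int
    nominal_radius_mm: float = 100.0
    cortex_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.cortex_mask is None:
            self.cortex_mask = np.ones(len(self.coords), dtype=bool)
        self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.cortex_mask.shape != (len(self.coords),):
            raise ValueError("cortex_mask length must equal vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.coords)

    @property
    def cortical_indices(self) -> np.ndarray:
        """Indices of unmasked (cortical) vertices, ascending."""
        return np.flatnonzero(self.cortex_mask)

    @property
    def unit_coords(self) -> np.ndarray:
        return self.coords / np.linalg.norm(self.coords, axis=1, keepdims=True)


def build_icosphere(
    order: int, nominal_radius_mm: float = 100.0, hemisphere: str = "left"
) -> SurfaceMesh:
    """Build a subdivided icosahedral sphere mesh.

    Each subdivision splits every triangle into four, projecting edge
    midpoints back onto the sphere.  New vertices are appended after the
    existing ones, so coarser meshes are index prefixes of finer ones.
    """
    if not isinstance(order, (int, np.integer)) or order < 0:
        raise ValueError(f"subdivision order must be a non-negative integer, got {order}")
    if order > 7:
        raise ValueError(f"subdivision order {order} > 7 refused (runaway mesh size)")
    if nominal_radius_mm <= 0:
        raise ValueError("nominal_radius_mm must be positive")

    coords = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(order):
        edges = np.sort(
            np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]]), axis=1
        )
        uniq, inv = np.unique(edges, axis=0, return_inverse=True)
        mids = coords[uniq[:, 0]] + coords[uniq[:, 1]]
        mids /= np.linalg.norm(mids, axis=1, keepdims=True)
        first_new = len(coords)
        coords = np.vstack([coords, mids])
        nf = len(faces)
        m01 = first_new + inv[:nf]
        m12 = first_new + inv[nf : 2 * nf]
        m02 = first_new + inv[2 * nf :]
        faces = np.vstack(
            [
                np.column_stack([faces[:, 0], m01, m02]),
                np.column_stack([faces[:, 1], m12, m01]),
                np.column_stack([faces[:, 2], m02, m12]),
                np.column_stack([m01, m12, m02]),
            ]
        )
    return SurfaceMesh(
        coords=coords * nominal_radius_mm,
        faces=faces,
        hemisphere=hemisphere,
        subdivision_order=order,
        nominal_radius_mm=nominal_radius_mm,
    )


def geodesic_distances(mesh: SurfaceMesh, centers=None) -> np.ndarray:
    """Great-circle distances (mm) from ``centers`` (default: all) to every vertex."""
    unit = mesh.unit_coords
    if centers is None:
        src = unit
    else:
        centers = np.atleast_1d(np.asarray(centers, dtype=np.int64))
        if centers.size and (centers.min() < 0 or centers.max() >= mesh.n_vertices):
            raise ValueError("vertex index out of range")
        src = unit[centers]
    cosang = np.clip(src @ unit.T, -1.0, 1.0)
    return mesh.nominal_radius_mm * np.arccos(cosang)


def geodesic_distance(mesh: SurfaceMesh, i: int, j: int) -> float:
    """Great-circle distance in mm between vertices ``i`` and ``j``."""
    for idx in (i, j):
        if not 0 <= idx < mesh.n_vertices:
            raise ValueError(f"vertex index {idx} out of range [0, {mesh.n_vertices})")
    u = mesh.unit_coords
    return float(mesh.nominal_radius_mm * np.arccos(np.clip(u[i] @ u[j], -1.0, 1.0)))


@dataclass
class SearchlightSet:
    """Geodesic searchlights: per center, the sorted cortical vertices within radius."""

    radius_mm: float
    centers: np.ndarray
    members: list  # list of sorted int arrays, parallel to centers
    hemisphere: str = "left"

    def __len__(self) -> int:
        return len(self.centers)


def build_searchlight_set(
    mesh: SurfaceMesh, centers=None, radius_mm: float = 15.0
) -> SearchlightSet:
    """Build closed-ball geodesic searchlights around ``centers``.

    Masked centers are dropped with a warning; members never include masked
    vertices.  ``centers=None`` uses every cortical vertex.
    """
    if radius_mm <= 0:
        raise ValueError(f"searchlight radius must be positive, got {radius_mm}")
    if centers is None:
        centers = mesh.cortical_indices
    centers = np.atleast_1d(np.asarray(centers, dtype=np.int64))
    keep = mesh.cortex_mask[centers]
    if not keep.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} masked searchlight centers",
            stacklevel=2,
        )
        centers = centers[keep]
    members: list = []
    cortical = mesh.cortex_mask
    for start in range(0, len(centers), 512):
        block = centers[start : start + 512]
        dist = geodesic_distances(mesh, block)
        for row in dist:
            members.append(np.flatnonzero((row <= radius_mm) & cortical))
    return SearchlightSet(
        radius_mm=float(radius_mm),
        centers=centers,
        members=members,
        hemisphere=mesh.hemisphere,
    )


@dataclass
class TargetGrid:
    """Whole-brain connectivity-target definition (both hemispheres, left first).

    In coarse mode, targets are the cortical vertices of the order-
    ``grid_order`` prefix grid and each target's time course is the mean over
    its averaging searchlight.  In FULL mode every cortical vertex is its own
    target with no averaging.
    """

    grid_order: object  # int or FULL
    averaging_radius_mm: float | None
    target_indices: np.ndarray  # global vertex indices (right hemi offset by left V)
    member_lists: list  # per target, global vertex indices averaged together
    n_left_vertices: int

    @property
    def n_targets(self) -> int:
        return len(self.target_indices)

    @property
    def is_full(self) -> bool:
        return self.grid_order == FULL


def build_target_grid(
    left_mesh: SurfaceMesh,
    right_mesh: SurfaceMesh,
    grid_order,
    averaging_radius_mm: float | None = None,
) -> TargetGrid:
    """Define whole-brain connectivity targets on a coarse prefix grid (or FULL)."""
    meshes = (left_mesh, right_mesh)
    offsets = (0, left_mesh.n_vertices)
    indices: list = []
    members: list = []
    if grid_order == FULL:
        for mesh, off in zip(meshes, offsets):
            for v in mesh.cortical_indices:
                indices.append(off + v)
                members.append(np.array([off + v], dtype=np.int64))
        averaging_radius_mm = None
    else:
        if not isinstance(grid_order, (int, np.integer)) or grid_order < 0:
            raise ValueError(f"grid_order must be a non-negative integer or FULL, got {grid_order}")
        if averaging_radius_mm is None or averaging_radius_mm <= 0:
            raise ValueError("coarse target grids need a positive averaging_radius_mm")
        for mesh in meshes:
            if grid_order > mesh.subdivision_order:
                raise ValueError(
                    f"grid_order {grid_order} exceeds mesh subdivision order "
                    f"{mesh.subdivision_order}"
                )
        n_coarse = n_icosphere_vertices(grid_order)
        for mesh, off in zip(meshes, offsets):
            coarse = np.arange(n_coarse)
            coarse = coarse[mesh.cortex_mask[coarse]]
            sls = build_searchlight_set(mesh, coarse, averaging_radius_mm)
            for c, m in zip(sls.centers, sls.members):
                if len(m) == 0:
                    raise ValueError(
                        f"target at {mesh.hemisphere} vertex {c} has no cortical members"
                    )
                indices.append(off + c)
                members.append(off + m)
    return TargetGrid(
        grid_order=grid_order,
        averaging_radius_mm=averaging_radius_mm,
        target_indices=np.asarray(indices, dtype=np.int64),
        member_lists=members,
        n_left_vertices=left_mesh.n_vertices,
    )


def apply_polar_cap_mask(
    mesh: SurfaceMesh, cap_axis, cap_angle_deg: float
) -> SurfaceMesh:
    """Mask all vertices within ``cap_angle_deg`` of ``cap_axis`` (synthetic medial wall).

    Returns a copy; composes with (ANDs into) any existing mask, so the
    operation is idempotent.
    """
    if not 0.0 < cap_angle_deg < 90.0:
        raise ValueError(f"cap_angle_deg must lie in (0, 90), got {cap_angle_deg}")
    axis = np.asarray(cap_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ang = np.degrees(np.arccos(np.clip(mesh.unit_coords @ axis, -1.0, 1.0)))
    new_mask = mesh.cortex_mask & (ang > cap_angle_deg)
    return replace(mesh, cortex_mask=new_mask, coords=mesh.coords.copy(), faces=mesh.faces.copy())
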
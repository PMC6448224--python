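"""Per-cell geometry: centroids, volumes, surface meshes and cone tests.

The layer-detection algorithm reduces each cell to its centroid ``x_c``,
the nearest point ``x_t`` on the tissue's outer surface mesh, and the
vector ``t = x_c - x_t`` joining them.  ``t`` points from the surface
into the tissue, so ``-t`` is the outward direction a cell "looks"
toward the surface; it is the axis of the cone used to decide whether
any other cell sits between this cell and the surface.

All coordinates are physical (µm), ordered (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .errors import DegenerateGeometryError, InputError
from .volume import LabeledVolume

__all__ = [
    "CellTable",
    "compute_cell_table",
    "extract_surface_mesh",
    "nearest_points_on_mesh",
    "cone_contains",
]

#: A surface mesh is any trimesh.Trimesh with vertices in µm.
SurfaceMesh = trimesh.Trimesh


@dataclass
class CellTable:
    """Per-cell geometry record.

    Arrays are aligned: row k describes cell ``labels[k]``.  ``centroids``
    and ``surface_points`` are (n, 3) in (x, y, z) µm; ``surface_vectors``
    holds ``t = centroid - surface_point`` exactly as stored.
    """

    labels: np.ndarray
    centroids: np.ndarray
    volumes: np.ndarray
    surface_points: np.ndarray
    surface_vectors: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = self.labels.size
        for name in ("centroids", "surface_points", "surface_vectors"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise InputError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            setattr(self, name, arr)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.shape != (n,):
            raise InputError("volumes must be 1-D, aligned with labels")
        self._index = {int(lab): k for k, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return int(self.labels.size)

    def index_of(self, label: int) -> int:
        try:
            return self._index[int(label)]
        except KeyError:
            raise KeyError(f"cell label {label} not in table") from None

    def centroid(self, label: int) -> np.ndarray:
        return self.centroids[self.index_of(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "centroid_x": self.centroids[:, 0],
                "centroid_y": self.centroids[:, 1],
                "centroid_z": self.centroids[:, 2],
                "volume_um3": self.volumes,
                "surface_x": self.surface_points[:, 0],
                "surface_y": self.surface_points[:, 1],
                "surface_z": self.surface_points[:, 2],
            }
        )


def _cell_coordinates(vol: LabeledVolume):
    """Yield (label, (m, 3) physical xyz coordinates of voxel centres)."""
    labels = vol.labels
    objects = ndimage.find_objects(labels)
    vx, vy, vz = vol.voxel_size_xyz
    for lab_minus_1, sl in enumerate(objects):
        if sl is None:
            continue
        lab = lab_minus_1 + 1
        if lab == vol.background_label:
            continue
        sub = labels[sl] == lab
        iz, iy, ix = np.nonzero(sub)
        iz = iz + sl[0].start
        iy = iy + sl[1].start
        ix = ix + sl[2].start
        coords = np.column_stack([ix * vx, iy * vy, iz * vz])
        yield lab, coords


def compute_cell_table(vol: LabeledVolume, mesh: SurfaceMesh) -> CellTable:
    """Centroid, volume and nearest-surface-point for every cell.

    Centroid is the mean of the cell's voxel-centre coordinates; volume is
    voxel count times voxel volume; the surface point is the exact closest
    point on any mesh triangle to the centroid (per-triangle projection,
    not nearest vertex).
    """
    if vol.n_cells == 0:
        raise InputError("volume contains no cells")
    if mesh is None or len(mesh.faces) == 0:
        raise InputError("surface mesh is empty")

    cell_labels = vol.cell_labels()
    # ndimage handles centroids/counts in one pass over the array
    counts = ndimage.sum_labels(np.ones(vol.shape, dtype=np.int64), vol.labels, cell_labels)
    com = np.asarray(ndimage.center_of_mass(np.ones(vol.shape), vol.labels, cell_labels))
    vx, vy, vz = vol.voxel_size_xyz
    centroids = np.column_stack([com[:, 2] * vx, com[:, 1] * vy, com[:, 0] * vz])
    volumes = counts * vol.voxel_volume

    surface_points = nearest_points_on_mesh(mesh, centroids)
    return CellTable(
        labels=cell_labels,
        centroids=centroids,
        volumes=volumes,
        surface_points=surface_points,
        surface_vectors=centroids - surface_points,
    )


def nearest_points_on_mesh(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Exact closest point on the mesh surface for each query point.

    Uses a KD-tree over mesh vertices to prune candidates, then projects
    onto every candidate triangle.  Correctness of the pruning: if the true
    closest point lies on triangle T at distance d*, then d* <= d_v (the
    nearest-vertex distance), and every vertex of T is within d* plus the
    longest mesh edge of the query — so T is always among the candidates.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)
    tree = cKDTree(verts)
    edges = verts[faces[:, [0, 1, 2]]] - verts[faces[:, [1, 2, 0]]]
    max_edge = float(np.sqrt((edges**2).sum(-1)).max())

    # vertex -> incident faces adjacency (CSR-style)
    order = np.argsort(faces.ravel(), kind="stable")
    face_of = order // 3
    vert_sorted = faces.ravel()[order]
    starts = np.searchsorted(vert_sorted, np.arange(len(verts)))
    ends = np.searchsorted(vert_sorted, np.arange(len(verts)) + 1)

    d_v, _ = tree.query(points)
    out = np.empty_like(points)
    for k, p in enumerate(points):
        cand_verts = tree.query_ball_point(p, d_v[k] + max_edge + 1e-9)
        cand_faces = np.unique(
            np.concatenate([face_of[starts[v]:ends[v]] for v in cand_verts])
        )
        tri = verts[faces[cand_faces]]
        proj = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
        d2 = ((proj - p) ** 2).sum(1)
        out[k] = proj[np.argmin(d2)]
    return out


def extract_surface_mesh(
    vol: LabeledVolume,
    smoothing_sigma: float = 2.0,
    iso_level: float = 0.5,
    cut_base: bool = False,
) -> SurfaceMesh:
    """Triangle mesh of the tissue's outer surface, from the segmentation.

    The foreground (any non-background label) is binarized, Gaussian
    smoothed with ``smoothing_sigma`` (µm, converted per axis to voxels),
    and contoured by marching cubes at ``iso_level``.  Only the largest
    connected component is kept; zero-area triangles are dropped.  With
    ``cut_base`` the flat cap that closes the volume's lower z boundary is
    removed, leaving an open dome — appropriate when the tissue was clipped
    at the bottom of the stack and the cap is not real surface.
    """
    fg = vol.foreground_mask()
    if not fg.any():
        raise InputError("volume has empty foreground")
    # pad so the isosurface closes even where tissue touches the array edge
    f = np.pad(fg.astype(np.float32), 1)
    if smoothing_sigma > 0:
        sigma_vox = [smoothing_sigma / v for v in vol.voxel_size]
        f = ndimage.gaussian_filter(f, sigma=sigma_vox)
    verts_zyx, faces, _, _ = marching_cubes(f, level=iso_level, spacing=vol.voxel_size)
    # to (x, y, z) and remove the one-voxel pad offset
    vz, vy, vx = vol.voxel_size
    verts = verts_zyx[:, ::-1] - np.array([vx, vy, vz])

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # largest connected component by area
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: m.area)
    if cut_base:
        # faces produced by the pad below the first z slice sit at z < 0
        keep = ~(mesh.vertices[mesh.faces, 2] < 0).all(axis=1)
        mesh = trimesh.Trimesh(mesh.vertices, mesh.faces[keep], process=False)
    areas = trimesh.triangles.area(mesh.triangles)
    keep = areas > 1e-12
    if not keep.all():
        mesh = trimesh.Trimesh(mesh.vertices, mesh.faces[keep], process=False)
    mesh.remove_unreferenced_vertices()
    if len(mesh.faces) == 0:
        raise InputError("surface extraction produced an empty mesh")
    return mesh


def cone_contains(
    apex: np.ndarray,
    axis_to_surface: np.ndarray,
    theta: float,
    query: np.ndarray,
    convention: str = "described",
) -> bool | np.ndarray:
    """Is ``query`` inside the open cone at ``apex`` aimed at the surface?

    The cone has its vertex at the cell centroid (``apex``) and opens
    toward the cell's nearest surface point with semi-angle ``theta``
    (degrees); it is unbounded along its axis.  Membership is strict:
    a point exactly on the lateral boundary is outside.

    ``convention="described"`` (default) tests the angle between
    ``query - apex`` and ``axis_to_surface`` (the outward direction
    ``-t``), i.e. ``cos(angle) > cos(theta)``.  ``convention="literal"``
    instead applies the inequality ``(q - apex)·t / (|q - apex||t|) <
    cos(theta)`` with the inward vector ``t = -axis_to_surface``, which
    selects the complement of a cone; it is kept only for comparison.

    ``query`` may be a single point or an (n, 3) stack; the return type
    matches.
    """
    apex = np.asarray(apex, dtype=float)
    axis = np.asarray(axis_to_surface, dtype=float)
    norm_axis = np.linalg.norm(axis)
    if norm_axis == 0:
        raise DegenerateGeometryError("cone axis has zero length (centroid on surface)")
    if not 0 < theta < 90:
        raise ValueError("theta must be in (0, 90) degrees")
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    d = q - apex
    dist = np.linalg.norm(d, axis=1)
    cos_theta = np.cos(np.deg2rad(theta))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (d @ (axis / norm_axis)) / dist
    if convention == "described":
        inside = cosang > cos_theta
    elif convention == "literal":
        inside = -cosang < cos_theta
    else:
        raise ValueError(f"unknown cone convention {convention!r}")
    inside = inside & (dist > 0)
    return bool(inside[0]) if single else inside
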
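"""Reading and writing every on-disk artifact.

Conventions: labeled volumes are multi-page integer TIFFs (page = z
slice, axes z/y/x); surface meshes are PLY triangle meshes with vertices
in µm; annotations are UTF-8 CSV with a header row; cell networks are
GraphML with a ``zone`` node attribute and an ``interface_area`` (µm²)
edge attribute.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import trimesh

from .annotations import AnnotationMap, parse_zone
from .errors import ConsistencyError, FormatError, InputError
from .geometry import CellTable, SurfaceMesh
from .morphometrics import AnisotropyRecord
from .volume import LabeledVolume

__all__ = [
    "read_labeled_volume",
    "write_labeled_volume",
    "read_mesh",
    "write_mesh",
    "write_annotation_csv",
    "read_annotation_csv",
    "write_network_graphml",
    "read_network_graphml",
]


def read_labeled_volume(
    path: str | os.PathLike,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    background_label: int = 0,
) -> LabeledVolume:
    """Read a multi-page TIFF of integer cell labels.

    ``voxel_size`` is (z, y, x) µm.  A single-page TIFF is rejected as
    not 3-D; float-typed TIFFs are rejected (labels must be integers).
    """
    arr = tifffile.imread(os.fspath(path))
    if arr.size == 0:
        raise InputError(f"{path}: empty TIFF stack")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path}: labeled volumes must have integer pixel type, got {arr.dtype}"
        )
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D stack, got {arr.ndim} axes")
    return LabeledVolume(arr, voxel_size=voxel_size, background_label=background_label)


def write_labeled_volume(vol: LabeledVolume, path: str | os.PathLike) -> None:
    """Write the label array as an uncompressed multi-page TIFF."""
    tifffile.imwrite(os.fspath(path), vol.labels)


def read_mesh(path: str | os.PathLike) -> SurfaceMesh:
    """Read a PLY (or other trimesh-supported) triangle mesh, vertices in µm."""
    mesh = trimesh.load_mesh(os.fspath(path), process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path}: not a triangle mesh")
    return mesh


def write_mesh(mesh: SurfaceMesh, path: str | os.PathLike) -> None:
    mesh.export(os.fspath(path))


def write_annotation_csv(
    amap: AnnotationMap,
    cells: CellTable,
    path: str | os.PathLike,
    aniso: dict[int, AnisotropyRecord] | None = None,
) -> None:
    """One row per annotated cell, sorted by label.

    Columns: label, zone, primordium_index, centroid_x/y/z (µm),
    volume_um3 and, when ``aniso`` is given, anisotropy.  Every annotated
    label must exist in ``cells``.
    """
    known = set(int(x) for x in cells.labels)
    missing = [lab for lab in amap.labels() if lab not in known]
    if missing:
        raise ConsistencyError(
            f"annotated labels missing from cell table: {missing[:10]}"
        )
    rows = []
    for lab in amap.labels():
        zone = amap[lab]
        k = cells.index_of(lab)
        row = {
            "label": lab,
            "zone": zone.name,
            "primordium_index": zone.index if zone.index is not None else "",
            "centroid_x": repr(float(cells.centroids[k, 0])),
            "centroid_y": repr(float(cells.centroids[k, 1])),
            "centroid_z": repr(float(cells.centroids[k, 2])),
            "volume_um3": repr(float(cells.volumes[k])),
        }
        if aniso is not None:
            rec = aniso.get(lab)
            row["anisotropy"] = "" if rec is None or np.isnan(rec.anisotropy) else repr(rec.anisotropy)
        rows.append(row)
    cols = ["label", "zone", "primordium_index", "centroid_x", "centroid_y",
            "centroid_z", "volume_um3"]
    if aniso is not None:
        cols.append("anisotropy")
    pd.DataFrame(rows, columns=cols).to_csv(os.fspath(path), index=False)


def read_annotation_csv(path: str | os.PathLike) -> AnnotationMap:
    """Read back label -> zone from an annotation CSV (lossless round-trip)."""
    df = pd.read_csv(os.fspath(path), dtype={"label": np.int64, "zone": str})
    amap = AnnotationMap()
    for lab, name in zip(df["label"], df["zone"]):
        amap.set(int(lab), parse_zone(name))
    return amap


def write_network_graphml(
    net: nx.Graph,
    amap: AnnotationMap | None,
    path: str | os.PathLike,
) -> None:
    """GraphML with node attribute ``zone`` and edge attribute ``interface_area``.

    Nodes absent from the annotation map get zone ``unassigned``.  Nodes
    and edges are written in sorted order so output is byte-reproducible.
    """
    out = nx.Graph()
    for node in sorted(net.nodes):
        zone = amap.zone_name(node) if amap is not None else "unassigned"
        out.add_node(int(node), zone=zone)
    for u, v in sorted(tuple(sorted(e)) for e in net.edges):
        out.add_edge(int(u), int(v), interface_area=float(net[u][v]["interface_area"]))
    nx.write_graphml(out, os.fspath(path))


def read_network_graphml(path: str | os.PathLike) -> nx.Graph:
    g = nx.read_graphml(os.fspath(path))
    out = nx.Graph()
    for node, data in g.nodes(data=True):
        out.add_node(int(node), zone=data.get("zone", "unassigned"))
    for u, v, data in g.edges(data=True):
        out.add_edge(int(u), int(v), interface_area=float(data["interface_area"]))
    return out
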
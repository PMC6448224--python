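"""Cellular morphometrics: shape anisotropy, adjacency networks, summaries.

Anisotropy abstracts each cell into three principal axes via PCA of its
voxel-centre coordinates: the principal magnitudes are the square roots
of the covariance eigenvalues (population normalization), each divided
by the sum of all three; the maximum normalized magnitude is the
anisotropy.  It ranges from 1/3 (isotropic — all axes equal, e.g. a
cube) to 1 (a perfect rod).

Cell adjacency uses 6-connectivity: two cells are neighbours exactly
when they share at least one voxel face, and the edge weight is the
accumulated physical area of those faces (µm²).  Corner and edge
contacts carry no area and create no edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .annotations import AnnotationMap
from .errors import InputError
from .geometry import CellTable
from .volume import LabeledVolume

__all__ = [
    "AnisotropyRecord",
    "cell_anisotropy",
    "anisotropy_table",
    "build_cell_network",
    "exposed_face_areas",
    "zone_summaries",
]


@dataclass(frozen=True)
class AnisotropyRecord:
    """Principal magnitudes (µm, descending) and anisotropy of one cell."""

    label: int
    principal_magnitudes: tuple[float, float, float]
    anisotropy: float  # NaN when undefined (single-voxel cell)


def _voxel_coords(vol: LabeledVolume, label: int) -> np.ndarray:
    sl = ndimage.find_objects((vol.labels == label).astype(np.int8))
    if not sl or sl[0] is None:
        raise InputError(f"label {label} not present in volume")
    sl = sl[0]
    iz, iy, ix = np.nonzero(vol.labels[sl] == label)
    vx, vy, vz = vol.voxel_size_xyz
    return np.column_stack(
        [(ix + sl[2].start) * vx, (iy + sl[1].start) * vy, (iz + sl[0].start) * vz]
    )


def _anisotropy_from_coords(label: int, coords: np.ndarray) -> AnisotropyRecord:
    center = coords - coords.mean(axis=0)
    cov = center.T @ center / len(coords)  # population covariance
    eigvals = np.linalg.eigvalsh(cov)
    mags = np.sqrt(np.clip(eigvals, 0, None))[::-1]
    total = mags.sum()
    if total == 0:
        warnings.warn(
            f"cell {label} has zero spatial extent; anisotropy undefined", stacklevel=3
        )
        aniso = float("nan")
    else:
        aniso = float(mags[0] / total)
    return AnisotropyRecord(int(label), tuple(float(m) for m in mags), aniso)


def cell_anisotropy(vol: LabeledVolume, label: int) -> AnisotropyRecord:
    """PCA shape anisotropy of one cell (1/3 isotropic … 1 rod-like)."""
    return _anisotropy_from_coords(label, _voxel_coords(vol, label))


def anisotropy_table(vol: LabeledVolume) -> dict[int, AnisotropyRecord]:
    """Anisotropy for every cell in one pass over the volume."""
    records: dict[int, AnisotropyRecord] = {}
    objects = ndimage.find_objects(vol.labels)
    vx, vy, vz = vol.voxel_size_xyz
    for lab_m1, sl in enumerate(objects):
        if sl is None:
            continue
        lab = lab_m1 + 1
        if lab == vol.background_label:
            continue
        iz, iy, ix = np.nonzero(vol.labels[sl] == lab)
        coords = np.column_stack(
            [(ix + sl[2].start) * vx, (iy + sl[1].start) * vy, (iz + sl[0].start) * vz]
        )
        records[lab] = _anisotropy_from_coords(lab, coords)
    return records


def _face_pairs(vol: LabeledVolume):
    """Yield (label_a, label_b, total_area) over all touching voxel faces.

    Labels are padded with background so faces on the volume border count
    as background-facing.  Pairs are emitted with a < b; background pairs
    have a = background_label.
    """
    lab = np.pad(vol.labels, 1, constant_values=vol.background_label)
    vz, vy, vx = vol.voxel_size
    face_area = {0: vy * vx, 1: vz * vx, 2: vz * vy}  # area orthogonal to each axis
    maxlab = int(lab.max()) + 1
    totals: dict[tuple[int, int], float] = {}
    for axis in range(3):
        s1 = [slice(None)] * 3
        s2 = [slice(None)] * 3
        s1[axis] = slice(None, -1)
        s2[axis] = slice(1, None)
        a = lab[tuple(s1)].ravel()
        b = lab[tuple(s2)].ravel()
        m = a != b
        a = a[m].astype(np.int64)
        b = b[m].astype(np.int64)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        keys, counts = np.unique(lo * maxlab + hi, return_counts=True)
        for key, cnt in zip(keys, counts):
            pair = (int(key // maxlab), int(key % maxlab))
            totals[pair] = totals.get(pair, 0.0) + float(cnt) * face_area[axis]
    return totals


def build_cell_network(vol: LabeledVolume) -> nx.Graph:
    """Undirected cell-adjacency graph weighted by shared interface area.

    Every cell is a node; an edge joins two cells iff they share voxel
    faces, with attribute ``interface_area`` (µm²).  Symmetric by
    construction (each face pair is accumulated once).
    """
    if vol.n_cells == 0:
        raise InputError("volume contains no cells")
    g = nx.Graph()
    g.add_nodes_from(int(x) for x in vol.cell_labels())
    bg = vol.background_label
    for (a, b), area in sorted(_face_pairs(vol).items()):
        if a == bg or b == bg:
            continue
        g.add_edge(a, b, interface_area=area)
    return g


def exposed_face_areas(vol: LabeledVolume) -> dict[int, float]:
    """Per cell, the voxel-face area facing background or the volume border (µm²)."""
    bg = vol.background_label
    out = {int(lab): 0.0 for lab in vol.cell_labels()}
    for (a, b), area in _face_pairs(vol).items():
        if a == bg and b != bg:
            out[b] = out.get(b, 0.0) + area
        elif b == bg and a != bg:
            out[a] = out.get(a, 0.0) + area
    return out


def zone_summaries(
    cells: CellTable,
    amap: AnnotationMap,
    net: nx.Graph | None = None,
    aniso: dict[int, AnisotropyRecord] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-zone cell statistics and per-zone-pair interface statistics.

    Returns (zone_table, pair_table).  The zone table has one row per
    zone present: cell count, volume mean/median/sd and, when ``aniso``
    is given, anisotropy mean/sd.  The pair table has one row per
    unordered zone pair with at least one network edge: edge count and
    interface-area mean/sd.  Zones with one cell report NaN sd.
    """
    rows = []
    zone_of = {int(lab): amap.zone_name(lab) for lab in cells.labels}
    frame = pd.DataFrame(
        {
            "zone": [zone_of[int(lab)] for lab in cells.labels],
            "volume": cells.volumes,
            "anisotropy": [
                aniso[int(lab)].anisotropy if aniso and int(lab) in aniso else np.nan
                for lab in cells.labels
            ],
        }
    )
    for zone, grp in frame.groupby("zone", sort=True):
        row = {
            "zone": zone,
            "n_cells": len(grp),
            "volume_mean": grp["volume"].mean(),
            "volume_median": grp["volume"].median(),
            "volume_sd": grp["volume"].std(ddof=1),
        }
        if aniso is not None:
            row["anisotropy_mean"] = grp["anisotropy"].mean()
            row["anisotropy_sd"] = grp["anisotropy"].std(ddof=1)
        rows.append(row)
    zone_table = pd.DataFrame(rows)

    pair_rows = []
    if net is not None and net.number_of_edges():
        pair_frame = pd.DataFrame(
            {
                "pair": [
                    "|".join(sorted((zone_of.get(u, "unassigned"), zone_of.get(v, "unassigned"))))
                    for u, v in net.edges
                ],
                "area": [d["interface_area"] for _, _, d in net.edges(data=True)],
            }
        )
        for pair, grp in pair_frame.groupby("pair", sort=True):
            pair_rows.append(
                {
                    "zone_pair": pair,
                    "n_interfaces": len(grp),
                    "area_mean": grp["area"].mean(),
                    "area_sd": grp["area"].std(ddof=1),
                }
            )
    pair_table = pd.DataFrame(pair_rows, columns=["zone_pair", "n_interfaces", "area_mean", "area_sd"])
    return zone_table, pair_table
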
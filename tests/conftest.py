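"""Shared fixtures: toy volumes, flat-surface cell tables, small phantoms."""

import numpy as np
import pytest
import trimesh

from meristem3d import (
    CellTable,
    LabeledVolume,
    PhantomSpec,
    compute_cell_table,
    detect_layers,
    extract_surface_mesh,
    generate_phantom,
)


def flat_cell_table(centroids, volumes=None):
    """CellTable for points under the plane z = 0 (surface point = vertical drop)."""
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    surface = centroids.copy()
    surface[:, 2] = 0.0
    return CellTable(
        labels=np.arange(1, n + 1),
        centroids=centroids,
        volumes=np.ones(n) if volumes is None else np.asarray(volumes, float),
        surface_points=surface,
        surface_vectors=centroids - surface,
    )


def square_mesh(z=0.0, half=100.0):
    """Two triangles covering the square |x|,|y| <= half at height z."""
    v = np.array(
        [[-half, -half, z], [half, -half, z], [half, half, z], [-half, half, z]]
    )
    return trimesh.Trimesh(vertices=v, faces=[[0, 1, 2], [0, 2, 3]], process=False)


@pytest.fixture(scope="session")
def small_phantom():
    """~230-cell ideal 3-shell dome used by most integration tests."""
    spec = PhantomSpec(dome_radius=24.0, shell_thickness=5.0, n_shells=3, seed=0)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth

@pytest.fixture(scope="session")
def small_phantom_annotated(small_phantom):
    _, vol, truth = small_phantom
    mesh = extract_surface_mesh(vol, cut_base=True)
    cells = compute_cell_table(vol, mesh)
    amap = detect_layers(cells)
    return vol, truth, mesh, cells, amap


@pytest.fixture()
def two_block_volume():
    """Two 2x2x2 cells sharing a full 2x2 face along x."""
    labels = np.zeros((2, 2, 4), dtype=np.int32)
    labels[:, :, :2] = 1
    labels[:, :, 2:] = 2
    return LabeledVolume(labels)
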
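"""Synthetic dome-shaped meristem phantoms with known ground truth.

The generator emulates the class of inputs the annotation pipeline
consumes — watershed-style 3D segmentations of a dome-shaped shoot
apical meristem — without simulating biology.  Cells are the Voronoi
regions of seed points placed on concentric hemispherical shells under
the dome surface (optionally raised by Gaussian bumps that play the
role of organ primordia); each voxel takes the label of its nearest
seed.  The construction records ground truth per cell: its shell index
(1 = outermost = L1), and its zone (layer, primordium sector, boundary
ring, organizing centre) by construction.  Everything is deterministic
for a fixed seed.

Default dimensions follow a typical angiosperm meristem: a dome of
radius 40 µm with ~5 µm cells, giving on the order of a thousand cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .annotations import AnnotationMap
from .errors import ParameterError
from .volume import LabeledVolume

__all__ = ["PrimordiumBump", "PhantomSpec", "PhantomTruth", "generate_phantom", "PRESETS"]

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))  # Fibonacci-lattice azimuth increment


@dataclass(frozen=True)
class PrimordiumBump:
    """A Gaussian surface bump standing in for an organ primordium.

    direction: outward unit vector (normalized on use) of the bump axis;
    radius: lateral extent in µm of surface arc (the Gaussian sigma);
    height: peak radial elevation in µm above the dome sphere.
    """

    direction: tuple[float, float, float]
    radius: float = 10.0
    height: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling parameters of one phantom.

    voxel_size is (z, y, x) µm.  layer_volume_profile controls how the
    seed spacing (hence mean cell volume) changes with depth:
    "increasing" makes deep cells larger (Arabidopsis-like),
    "decreasing" makes surface cells larger (tomato-like).  jitter
    displaces each seed by up to ``jitter`` × local spacing.  Shells
    deeper than n_shells are filled with interior seeds that count as
    the innermost identity (everything below L2 is L3).
    """

    dome_radius: float = 40.0
    n_shells: int = 3
    shell_thickness: float = 5.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cells_per_shell: int | None = None
    layer_volume_profile: str = "uniform"
    primordia: tuple[PrimordiumBump, ...] = ()
    jitter: float = 0.0
    seed: int = 0
    oc_depth: float | None = None
    oc_radius: float | None = None

    def __post_init__(self) -> None:
        if self.n_shells < 1:
            raise ParameterError("n_shells must be >= 1")
        if self.dome_radius <= 0 or self.shell_thickness <= 0:
            raise ParameterError("dome_radius and shell_thickness must be > 0")
        if not 0 <= self.jitter < 0.5:
            raise ParameterError("jitter must be in [0, 0.5)")
        if self.layer_volume_profile not in ("uniform", "increasing", "decreasing"):
            raise ParameterError(
                f"unknown layer_volume_profile {self.layer_volume_profile!r}"
            )
        if self.dome_radius < self.shell_thickness:
            raise ParameterError("dome must be at least one shell thick")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom.

    ``table`` has one row per cell: label, true_shell (1 = outermost;
    interior filler cells get n_shells + 1), true_zone (canonical zone
    string).  ``apex_cell`` is the topmost L1 cell; ``primordium_cells``
    holds one (peak_cell, saddle_cell) pair per bump, selected on the
    surface layer as a user would click them.
    """

    table: pd.DataFrame
    apex_cell: int
    primordium_cells: list[tuple[int, int]] = field(default_factory=list)

    def true_layer(self) -> pd.Series:
        """Label -> expected L1/L2/L3 stratum (deep shells collapse to 3)."""
        return self.table.set_index("label")["true_shell"].clip(upper=3)

    def layer_accuracy(self, amap: AnnotationMap) -> float:
        """Fraction of cells whose annotated stratum matches the true layer."""
        truth = self.true_layer()
        hits = 0
        for lab, expect in truth.items():
            if amap.get(int(lab)).stratum == int(expect):
                hits += 1
        return hits / len(truth)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n approximately evenly spaced unit vectors on the upper hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n  # uniform in area over the cap z in (0, 1)
    rho = np.sqrt(1.0 - z**2)
    phi = i * _GOLDEN
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _spacing_factors(spec: PhantomSpec) -> np.ndarray:
    """Per-shell seed-spacing multipliers implementing the volume profile."""
    n = spec.n_shells
    if spec.layer_volume_profile == "uniform":
        return np.ones(n + 1)
    step = np.linspace(-0.15, 0.15, n)
    factors = 1.0 + step  # shell 1 .. n
    if spec.layer_volume_profile == "decreasing":
        factors = factors[::-1]
    return np.concatenate([factors, [factors[-1]]])  # interior follows shell n


def _local_radius(spec: PhantomSpec, dirs: np.ndarray) -> np.ndarray:
    """Dome radius along each direction, including primordium bumps."""
    r = np.full(len(dirs), spec.dome_radius)
    for bump in spec.primordia:
        axis = np.asarray(bump.direction, dtype=float)
        axis = axis / np.linalg.norm(axis)
        gamma = np.arccos(np.clip(dirs @ axis, -1.0, 1.0))
        sigma = bump.radius / spec.dome_radius
        r = r + bump.height * np.exp(-0.5 * (gamma / sigma) ** 2)
    return r


def generate_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, PhantomTruth]:
    """Build a labeled dome phantom and its ground truth.

    Seeds are laid out shell by shell on surfaces ``local_radius(dir) -
    (s - 0.5) * shell_thickness`` using a Fibonacci lattice, jittered by
    the spec's seed; any core deeper than the last shell is filled with
    a jittered cubic grid of interior seeds.  Each foreground voxel
    (radius <= local dome radius, z >= 0) takes the label of the nearest
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    R, t = spec.dome_radius, spec.shell_thickness
    factors = _spacing_factors(spec)

    seed_pts: list[np.ndarray] = []
    seed_shell: list[int] = []
    seed_dir: list[np.ndarray] = []
    for s in range(1, spec.n_shells + 1):
        r_mid = R - (s - 0.5) * t
        if r_mid <= 0:
            break
        spacing = t * factors[s - 1]
        if spec.cells_per_shell is not None:
            n = spec.cells_per_shell
        else:
            n = max(4, int(round(2.0 * np.pi * r_mid**2 / spacing**2)))
        dirs = _fibonacci_hemisphere(n)
        radii = _local_radius(spec, dirs) - (s - 0.5) * t
        pts = dirs * radii[:, None]
        if spec.jitter > 0:
            disp = rng.normal(size=(n, 3))
            disp /= np.linalg.norm(disp, axis=1)[:, None]
            disp *= (spec.jitter * spacing * rng.random(n) ** (1.0 / 3.0))[:, None]
            pts = pts + disp
        seed_pts.append(pts)
        seed_shell.extend([s] * n)
        seed_dir.append(dirs)

    # fill the core below the deepest shell with interior (L3-identity) seeds
    r_core = R - spec.n_shells * t
    if r_core > 0.5 * t:
        spacing = t * factors[-1]
        axis = np.arange(-r_core, r_core + spacing, spacing)
        gz = axis[axis >= 0.25 * spacing]
        gx, gy, gzz = np.meshgrid(axis, axis, gz, indexing="ij")
        grid = np.column_stack([gx.ravel(), gy.ravel(), gzz.ravel()])
        rr = np.linalg.norm(grid, axis=1)
        keep = rr < r_core - 0.25 * t
        grid = grid[keep]
        if len(grid):
            if spec.jitter > 0:
                disp = rng.normal(size=(len(grid), 3))
                disp /= np.linalg.norm(disp, axis=1)[:, None]
                disp *= (spec.jitter * spacing * rng.random(len(grid)) ** (1.0 / 3.0))[:, None]
                grid = grid + disp
            seed_pts.append(grid)
            seed_shell.extend([spec.n_shells + 1] * len(grid))
            with np.errstate(invalid="ignore"):
                gd = grid / np.linalg.norm(grid, axis=1)[:, None]
            gd[~np.isfinite(gd).all(axis=1)] = (0.0, 0.0, 1.0)
            seed_dir.append(gd)

    if not seed_pts:
        raise ParameterError("phantom spec produced no seed points")
    seeds = np.vstack(seed_pts)
    shells = np.asarray(seed_shell)
    dirs_all = np.vstack(seed_dir)

    # voxel grid: dome base sits on the z = 0 boundary plane
    vz, vy, vx = spec.voxel_size
    h_max = R + sum(b.height for b in spec.primordia)
    nx = int(np.ceil(2 * (h_max + 2.0) / vx)) + 1
    ny = int(np.ceil(2 * (h_max + 2.0) / vy)) + 1
    nz = int(np.ceil((h_max + 2.0) / vz)) + 1
    cx = (nx - 1) / 2.0 * vx
    cy = (ny - 1) / 2.0 * vy

    zc = np.arange(nz) * vz
    yc = np.arange(ny) * vy - cy
    xc = np.arange(nx) * vx - cx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    P = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    r = np.linalg.norm(P, axis=1)
    with np.errstate(invalid="ignore"):
        D = P / r[:, None]
    D[~np.isfinite(D).all(axis=1)] = (0.0, 0.0, 1.0)
    fg = r <= _local_radius(spec, D)
    if not fg.any():
        raise ParameterError("phantom foreground is empty")

    # seeds live in centred coordinates; voxel labels need offset coordinates
    idx = cKDTree(seeds).query(P[fg])[1]
    labels = np.zeros(nz * ny * nx, dtype=np.int32)
    labels[fg] = idx + 1
    labels = labels.reshape(nz, ny, nx)

    # drop seeds that captured no voxel and relabel consecutively
    present = np.unique(labels)
    lut = np.zeros(present.max() + 1, dtype=np.int32)
    new_of_old = {}
    nxt = 1
    for p in present:
        if p == 0:
            continue
        lut[p] = nxt
        new_of_old[int(p)] = nxt
        nxt += 1
    labels = lut[labels]
    vol = LabeledVolume(labels, voxel_size=spec.voxel_size)

    truth = _build_truth(spec, seeds, shells, dirs_all, new_of_old)
    return vol, truth


def _build_truth(spec, seeds, shells, dirs, new_of_old) -> PhantomTruth:
    rows = []
    bump_axes = []
    for bump in spec.primordia:
        a = np.asarray(bump.direction, dtype=float)
        bump_axes.append(a / np.linalg.norm(a))
    oc_centre = None
    if spec.oc_depth is not None and spec.oc_radius is not None:
        oc_centre = np.array([0.0, 0.0, spec.dome_radius - spec.oc_depth])

    for old_idx, new_lab in new_of_old.items():
        k = old_idx - 1
        s = int(shells[k])
        stratum = min(s, 3)
        zone = f"L{stratum}"
        if oc_centre is not None and stratum == 3:
            if np.linalg.norm(seeds[k] - oc_centre) <= spec.oc_radius:
                zone = "OC"
        if s <= spec.n_shells:
            for b_i, (bump, axis) in enumerate(zip(spec.primordia, bump_axes), start=1):
                gamma = float(np.arccos(np.clip(dirs[k] @ axis, -1, 1)))
                sigma = bump.radius / spec.dome_radius
                if gamma <= sigma:
                    zone = f"primordium_{b_i}_L{stratum}"
                    break
                if gamma <= 1.6 * sigma:
                    zone = f"boundary_{b_i}"
                    break
        rows.append({"label": new_lab, "true_shell": s, "true_zone": zone})
    table = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)

    shell1 = np.flatnonzero(shells == 1)
    apex_old = shell1[np.argmax(dirs[shell1, 2])] + 1
    apex_cell = new_of_old[int(apex_old)]

    prim_cells = []
    zhat = np.array([0.0, 0.0, 1.0])
    for bump, axis in zip(spec.primordia, bump_axes):
        sigma = bump.radius / spec.dome_radius
        gam1 = np.arccos(np.clip(dirs[shell1] @ axis, -1, 1))
        peak_old = shell1[np.argmin(gam1)] + 1
        # saddle: on the great circle from the bump toward the dome apex,
        # just outside the bump (1.5 sigma from its axis)
        tangent = zhat - (zhat @ axis) * axis
        tangent = tangent / np.linalg.norm(tangent)
        gamma_apex = float(np.arccos(np.clip(axis @ zhat, -1, 1)))
        offset = min(1.5 * sigma, 0.5 * gamma_apex)
        saddle_dir = np.cos(offset) * axis + np.sin(offset) * tangent
        gs = np.arccos(np.clip(dirs[shell1] @ saddle_dir, -1, 1))
        saddle_old = None
        for j in np.argsort(gs):
            cand = shell1[j] + 1
            if cand != peak_old and int(new_of_old[int(cand)]) != apex_cell:
                saddle_old = cand
                break
        prim_cells.append((new_of_old[int(peak_old)], new_of_old[int(saddle_old)]))
    return PhantomTruth(table=table, apex_cell=apex_cell, primordium_cells=prim_cells)


def _default_primordia(n: int, elevation_deg: float = 50.0) -> tuple[PrimordiumBump, ...]:
    """n bumps evenly spaced in azimuth on the dome flank."""
    out = []
    el = np.deg2rad(elevation_deg)
    for k in range(n):
        az = 2 * np.pi * k / max(n, 1)
        out.append(
            PrimordiumBump(
                direction=(
                    float(np.cos(el) * np.cos(az)),
                    float(np.cos(el) * np.sin(az)),
                    float(np.sin(el)),
                )
            )
        )
    return tuple(out)


#: Qualitative presets for the two meristem architectures the tool targets:
#: Arabidopsis-like SAMs have cell volume increasing with depth (L1 < L3),
#: tomato-like SAMs the reverse.
PRESETS: dict[str, dict] = {
    "arabidopsis-like": {"layer_volume_profile": "increasing"},
    "tomato-like": {"layer_volume_profile": "decreasing"},
}
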
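"""Primordium / boundary / SAM delineation by a weighted Voronoi rule.

An organ primordium bulges from the flank of the meristem dome.  Given
three user-selected cells — the SAM peak (centroid ``x_SAM``), the
primordium peak (``x_p``) and the saddle cell in the crease between them
(``x_b``) — the distances ``d_SAM = |x_SAM - x_b|`` and
``d_p = |x_p - x_b|`` fix a ratio ``r = d_p / d_SAM``.  Every cell ``i``
is scored by ``ρ_i = |x_i - x_p| / |x_i - x_SAM|``, a weighted-Voronoi
coordinate: cells with ``ρ_i < r`` are relatively closer to the
primordium peak than the saddle is.  A half-width δ on the ratio scale
carves out the boundary band:

    P = { i : ρ_i < r - δ }
    B = { i : r - δ <= ρ_i <= r + δ }
    S = { i : ρ_i > r + δ }

The boundary band is additionally capped in depth: only band cells
within ``absolute_distance`` µm of the saddle centroid stay in B; band
cells beyond the cap fall back to P or S by the δ = 0 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationMap, CellZone
from .errors import ParameterError
from .geometry import CellTable

__all__ = ["PrimordiumSelection", "ZonePartition", "mark_primordium", "mark_primordia_sequential"]


@dataclass(frozen=True)
class PrimordiumSelection:
    """One primordium's three selected cells and band parameters.

    delta is the dimensionless half-width of the boundary band on the
    ratio scale; absolute_distance (µm) caps how far from the saddle the
    boundary may extend; same_label collapses all primordia onto index 1.
    """

    sam_peak_cell: int
    primordium_peak_cell: int
    saddle_cell: int
    delta: float = 0.0
    absolute_distance: float = np.inf
    same_label: bool = False

    def __post_init__(self) -> None:
        cells = (self.sam_peak_cell, self.primordium_peak_cell, self.saddle_cell)
        if len(set(cells)) != 3:
            raise ParameterError("SAM peak, primordium peak and saddle cells must be distinct")
        if self.delta < 0:
            raise ParameterError("delta must be >= 0")
        if self.absolute_distance <= 0:
            raise ParameterError("absolute_distance must be > 0")


@dataclass(frozen=True)
class ZonePartition:
    """Disjoint primordium (P), boundary (B) and SAM (S) label sets."""

    P: frozenset[int]
    B: frozenset[int]
    S: frozenset[int]
    ratio: float = float("nan")

    def zone_of(self, label: int) -> str:
        if label in self.P:
            return "P"
        if label in self.B:
            return "B"
        if label in self.S:
            return "S"
        raise KeyError(label)


def _rho(cells: CellTable, x_p: np.ndarray, x_sam: np.ndarray) -> np.ndarray:
    """Weighted-Voronoi ratio per cell, with peak-cell limits.

    The primordium peak itself has d_p = 0 → ρ = 0 (always P); the SAM
    peak has d_SAM = 0 → ρ = +inf (always S).
    """
    d_p = np.linalg.norm(cells.centroids - x_p, axis=1)
    d_sam = np.linalg.norm(cells.centroids - x_sam, axis=1)
    rho = np.empty(len(cells))
    zero_p = d_p == 0
    ok = ~zero_p & (d_sam > 0)
    rho[ok] = d_p[ok] / d_sam[ok]
    rho[d_sam == 0] = np.inf
    rho[zero_p] = 0.0  # a cell coincident with the primordium peak wins P
    return rho


def mark_primordium(cells: CellTable, sel: PrimordiumSelection) -> ZonePartition:
    """Partition all cells into P/B/S for one primordium selection."""
    x_sam = cells.centroid(sel.sam_peak_cell)
    x_p = cells.centroid(sel.primordium_peak_cell)
    x_b = cells.centroid(sel.saddle_cell)
    d_sam = float(np.linalg.norm(x_sam - x_b))
    d_p = float(np.linalg.norm(x_p - x_b))
    if d_sam == 0 or d_p == 0:
        raise ParameterError("selection centroids coincide; distances d_SAM and d_p must be > 0")
    r = d_p / d_sam

    rho = _rho(cells, x_p, x_sam)
    d_saddle = np.linalg.norm(cells.centroids - x_b, axis=1)

    in_band = (rho >= r - sel.delta) & (rho <= r + sel.delta)
    b_mask = in_band & (d_saddle <= sel.absolute_distance)
    # band cells beyond the depth cap fall back to the delta = 0 rule
    p_mask = (rho < r - sel.delta) | (in_band & ~b_mask & (rho < r))
    s_mask = ~p_mask & ~b_mask

    labels = cells.labels
    return ZonePartition(
        P=frozenset(int(x) for x in labels[p_mask]),
        B=frozenset(int(x) for x in labels[b_mask]),
        S=frozenset(int(x) for x in labels[s_mask]),
        ratio=r,
    )


def mark_primordia_sequential(
    cells: CellTable,
    selections: list[PrimordiumSelection],
    base: AnnotationMap,
) -> AnnotationMap:
    """Apply selections in order, annotating P and B cells onto ``base``.

    Cells captured by an earlier primordium (P or B) are frozen against
    later reassignment (first selection wins).  Primordium cells keep
    their L1/L2/L3 stratum — zone ``primordium(k, layer)`` — and boundary
    cells become ``boundary(k)``.  The organizing centre and unassigned
    cells are never overwritten.  With ``same_label`` every selection
    shares index 1.
    """
    if not selections:
        raise ParameterError("at least one primordium selection is required")
    out = base.copy()
    frozen: set[int] = set()
    prov = []
    for pos, sel in enumerate(selections, start=1):
        for picked in (sel.sam_peak_cell, sel.primordium_peak_cell, sel.saddle_cell):
            if picked in frozen:
                raise ParameterError(
                    f"selected cell {picked} already belongs to a previous primordium"
                )
        k = 1 if sel.same_label else pos
        part = mark_primordium(cells, sel)
        for lab in part.P:
            if lab in frozen:
                continue
            zone = out.get(lab)
            if zone.kind in ("oc", "unassigned"):
                continue
            stratum = zone.stratum
            if stratum is None:
                continue
            out.set(lab, CellZone("primordium", layer=stratum, index=k))
        for lab in part.B:
            if lab in frozen:
                continue
            zone = out.get(lab)
            if zone.kind in ("oc", "unassigned"):
                continue
            out.set(lab, CellZone("boundary", index=k))
        frozen |= set(part.P) | set(part.B)
        prov.append(
            {
                "sam_peak": sel.sam_peak_cell,
                "peak": sel.primordium_peak_cell,
                "saddle": sel.saddle_cell,
                "delta": sel.delta,
                "absolute_distance": sel.absolute_distance,
                "index": k,
                "ratio": part.ratio,
            }
        )
    out.provenance["primordia"] = prov
    return out
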
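"""Weighted-Voronoi primordium/boundary/SAM delineation."""

import numpy as np
import pytest

from meristem3d import (
    AnnotationMap,
    CellZone,
    PrimordiumSelection,
    detect_layers,
    mark_primordia_sequential,
    mark_primordium,
)
from meristem3d.errors import ParameterError
from conftest import flat_cell_table


def brute_force_partition(centroids, x_sam, x_p, x_b, delta, abs_distance):
    """Independent re-implementation: evaluate the three set inequalities per point."""
    r = np.linalg.norm(x_p - x_b) / np.linalg.norm(x_sam - x_b)
    P, B, S = set(), set(), set()
    for k, x in enumerate(centroids):
        dp = np.linalg.norm(x - x_p)
        ds = np.linalg.norm(x - x_sam)
        if dp == 0:
            rho = 0.0
        elif ds == 0:
            rho = np.inf
        else:
            rho = dp / ds
        lab = k + 1
        if r - delta <= rho <= r + delta and np.linalg.norm(x - x_b) <= abs_distance:
            B.add(lab)
        elif rho < r:
            P.add(lab)
        else:
            S.add(lab)
    return P, B, S


def setup_line(points):
    """CellTable whose first three cells are the SAM peak, primordium peak, saddle."""
    base = [[0, 0, 0], [10, 0, 0], [6, 0, 0]]
    return flat_cell_table(np.array(base + list(points), dtype=float) - [0, 0, 5])


class TestMarkPrimordium:
    # worked example: x_SAM=(0,0,0), x_p=(10,0,0), x_b=(6,0,0) => r = 4/6 = 2/3
    def test_cell_closer_to_peak_is_primordium(self):
        cells = setup_line([[8, 0, 0]])
        sel = PrimordiumSelection(1, 2, 3, delta=0.0)
        part = mark_primordium(cells, sel)
        assert 4 in part.P  # rho = 2/8 = 0.25 < 2/3

    def test_cell_at_exact_ratio_is_boundary(self):
        cells = setup_line([[6, 0, 1e-12]])  # avoid coinciding with the saddle cell
        # use the saddle cell itself: rho = 4/6 = r exactly
        sel = PrimordiumSelection(1, 2, 3, delta=0.0)
        part = mark_primordium(cells, sel)
        assert 3 in part.B

    def test_cell_closer_to_sam_is_sam(self):
        cells = setup_line([[2, 0, 0]])
        sel = PrimordiumSelection(1, 2, 3, delta=0.0)
        part = mark_primordium(cells, sel)
        assert 4 in part.S  # rho = 8/2 = 4 > 2/3

    def test_peak_cells_belong_to_their_own_zones(self):
        cells = setup_line([[4, 4, 0]])
        part = mark_primordium(cells, PrimordiumSelection(1, 2, 3, delta=0.1))
        assert 1 in part.S  # SAM peak: rho = +inf
        assert 2 in part.P  # primordium peak: rho = 0

    def test_partition_is_exact(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-10, 10, size=(50, 3))
        cells = setup_line(pts)
        part = mark_primordium(cells, PrimordiumSelection(1, 2, 3, delta=0.08))
        labels = set(int(x) for x in cells.labels)
        assert part.P | part.B | part.S == labels
        assert not (part.P & part.B or part.P & part.S or part.B & part.S)

    @pytest.mark.parametrize("config_seed", range(20))
    def test_matches_brute_force_oracle(self, config_seed):
        rng = np.random.default_rng(1000 + config_seed)
        pts = rng.uniform(-20, 20, size=(60, 3))
        delta = float(rng.uniform(0, 0.3))
        abs_d = float(rng.uniform(5, 40))
        cells = flat_cell_table(pts - [0, 0, 50])
        x_sam, x_p, x_b = cells.centroids[:3]
        sel = PrimordiumSelection(1, 2, 3, delta=delta, absolute_distance=abs_d)
        part = mark_primordium(cells, sel)
        P, B, S = brute_force_partition(cells.centroids, x_sam, x_p, x_b, delta, abs_d)
        assert (set(part.P), set(part.B), set(part.S)) == (P, B, S)

    def test_boundary_grows_monotonically_with_delta(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-15, 15, size=(80, 3))
        cells = setup_line(pts)
        prev = frozenset()
        for delta in (0.0, 0.05, 0.1, 0.2):
            part = mark_primordium(cells, PrimordiumSelection(1, 2, 3, delta=delta))
            assert prev <= part.B
            prev = part.B

    def test_swapping_peaks_exchanges_p_and_s_when_delta_zero(self):
        rng = np.random.default_rng(23)
        pts = rng.uniform(-15, 15, size=(40, 3))
        cells = setup_line(pts)
        fwd = mark_primordium(cells, PrimordiumSelection(1, 2, 3, delta=0.0))
        rev = mark_primordium(cells, PrimordiumSelection(2, 1, 3, delta=0.0))
        # the boundary (exact-ratio) sets coincide; P and S swap
        assert fwd.B == rev.B
        assert fwd.P == rev.S and fwd.S == rev.P

    def test_coincident_selection_cells_rejected(self):
        with pytest.raises(ParameterError):
            PrimordiumSelection(1, 1, 3)

    def test_band_cell_beyond_absolute_distance_falls_back(self):
        # cell in the ratio band but far from the saddle in z
        cells = setup_line([[6, 0, 30]])
        sel = PrimordiumSelection(1, 2, 3, delta=0.3, absolute_distance=5.0)
        part = mark_primordium(cells, sel)
        assert 4 not in part.B
        # its rho = sqrt(16+900)/sqrt(36+900) > r? compute via the delta=0 rule
        rho = np.linalg.norm([4, 0, 30]) / np.linalg.norm([6, 0, 30])
        assert (4 in part.P) == (rho < 2 / 3)


class TestSequential:
    def _annotated(self, pts):
        cells = setup_line(pts)
        return cells, detect_layers(cells)

    def test_single_selection_matches_mark_primordium(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-10, 10, size=(30, 3))
        cells, base = self._annotated(pts)
        sel = PrimordiumSelection(1, 2, 3, delta=0.05)
        part = mark_primordium(cells, sel)
        amap = mark_primordia_sequential(cells, [sel], base)
        for lab in part.P:
            zone = amap[lab]
            assert zone.kind == "primordium" and zone.index == 1
            assert zone.layer == base[lab].stratum
        for lab in part.B:
            assert amap[lab] == CellZone("boundary", index=1)
        for lab in part.S:
            assert amap[lab] == base[lab]

    def test_two_disjoint_primordia_get_distinct_indices(self):
        # two opposite primordium peaks, shared SAM peak
        pts = [[-10, 0, 0], [-6, 0, 0], [9, 1, 0], [-9, 1, 0]]
        cells = setup_line(pts)
        base = detect_layers(cells)
        sels = [
            PrimordiumSelection(1, 2, 3, delta=0.0),
            PrimordiumSelection(1, 4, 5, delta=0.0),
        ]
        amap = mark_primordia_sequential(cells, sels, base)
        idx1 = {lab for lab, z in amap.entries.items()
                if z.kind == "primordium" and z.index == 1}
        idx2 = {lab for lab, z in amap.entries.items()
                if z.kind == "primordium" and z.index == 2}
        assert idx1 and idx2 and not idx1 & idx2

    def test_same_label_collapses_indices(self):
        pts = [[-10, 0, 0], [-6, 0, 0], [9, 1, 0], [-9, 1, 0]]
        cells = setup_line(pts)
        base = detect_layers(cells)
        sels = [
            PrimordiumSelection(1, 2, 3, delta=0.0, same_label=True),
            PrimordiumSelection(1, 4, 5, delta=0.0, same_label=True),
        ]
        amap = mark_primordia_sequential(cells, sels, base)
        indices = {z.index for z in amap.entries.values() if z.kind == "primordium"}
        assert indices == {1}

    def test_earlier_primordium_frozen_against_reassignment(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-10, 10, size=(30, 3))
        cells, base = self._annotated(pts)
        sel1 = PrimordiumSelection(1, 2, 3, delta=0.05)
        first = mark_primordium(cells, sel1)
        # second selection aimed the other way would claim SAM-side cells
        far = [lab for lab in sorted(first.S) if lab > 3][:2]
        if len(far) < 2:
            pytest.skip("random cloud left no free cells")
        sel2 = PrimordiumSelection(1, far[0], far[1], delta=0.05)
        amap = mark_primordia_sequential(cells, [sel1, sel2], base)
        for lab in first.P:
            assert amap[lab].kind == "primordium" and amap[lab].index == 1

    def test_selected_cell_inside_previous_primordium_rejected(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(-10, 10, size=(20, 3))
        cells, base = self._annotated(pts)
        sel1 = PrimordiumSelection(1, 2, 3, delta=0.0)
        part = mark_primordium(cells, sel1)
        inside = sorted(part.P)[0]
        others = [lab for lab in sorted(part.S) if lab != 1][:1]
        sel2 = PrimordiumSelection(1, inside, others[0], delta=0.0)
        with pytest.raises(ParameterError, match="previous primordium"):
            mark_primordia_sequential(cells, [sel1, sel2], base)
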
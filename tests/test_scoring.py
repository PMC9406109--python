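"""Scoring-layer unit tests: definitional examples, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mugr import Thresholds
from mugr.scoring import (
    Ganglion,
    Junction,
    MuscleUnit,
    NerveBundle,
    ZonePartition,
    classify_bundles,
    cluster_ganglia,
    compute_mgr,
    count_interval_units,
    detect_junctions,
    ganglion_composition,
    measure_unit_width,
    partition_zones,
    segment_muscle_units,
)

from .conftest import make_profile, v_notch
from .oracles import (
    brute_force_interval_counts,
    brute_force_junctions,
    brute_force_single_linkage,
)


def _gang(x, gid=0, n_neu=2, n_glia=0, n_other=0):
    return Ganglion(
        id=gid, centroid_x=x, centroid_y=0.0,
        n_dapi=n_neu + n_glia + n_other,
        n_neurons=n_neu, n_glia=n_glia, n_other=n_other,
    )


# --------------------------------------------------------------------------
# junctions
# --------------------------------------------------------------------------
class TestDetectJunctions:
    def test_flat_profile_has_no_junctions(self, thresholds):
        assert detect_junctions(make_profile(np.zeros(500)), thresholds) == []

    @pytest.mark.parametrize(
        "depth,expected", [(29.0, 0), (30.0, 1), (31.0, 1)]
    )
    def test_30um_criterion_is_inclusive(self, thresholds, depth, expected):
        prof = make_profile(v_notch(401, center=200.5, depth=depth, slope=1.0))
        junctions = detect_junctions(prof, thresholds)
        assert len(junctions) == expected
        if expected:
            assert junctions[0].depth == pytest.approx(depth)
            assert junctions[0].position == pytest.approx(200.5)

    def test_two_valleys_only_deep_one_counted(self, thresholds):
        d = v_notch(900, 200.5, 29.0, slope=1.0) + v_notch(900, 600.5, 31.0, slope=1.0)
        junctions = detect_junctions(make_profile(d), thresholds)
        assert [round(j.position) for j in junctions] == [600]

    def test_matches_brute_force_on_random_profiles(self, thresholds):
        rng = np.random.default_rng(12)
        for _ in range(500):
            n = int(rng.integers(50, 400))
            base = np.clip(rng.normal(0, 8, n).cumsum() * 0.1, 0, None)
            d = base.copy()
            for _k in range(rng.integers(0, 5)):
                d += v_notch(n, float(rng.uniform(5, n - 5)),
                             float(rng.uniform(10, 60)),
                             slope=float(rng.uniform(1, 5)))
            got = detect_junctions(make_profile(d), thresholds)
            want = brute_force_junctions(d, thresholds.junction_min_depth)
            assert [(round(j.position - 0.5), round(j.depth, 9)) for j in got] == [
                (i, round(p, 9)) for i, p in want
            ]

    def test_raising_min_depth_never_adds_junctions(self):
        rng = np.random.default_rng(3)
        d = sum(
            v_notch(600, float(rng.uniform(10, 590)), float(rng.uniform(20, 50)))
            for _ in range(6)
        )
        prof = make_profile(np.asarray(d))
        counts = [
            len(detect_junctions(prof, Thresholds(junction_min_depth=t)))
            for t in (20.0, 30.0, 40.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)


# --------------------------------------------------------------------------
# muscle units and widths
# --------------------------------------------------------------------------
class TestMuscleUnits:
    def test_no_junctions_single_unit(self):
        units = segment_muscle_units([], (0.0, 900.0))
        assert len(units) == 1 and units[0].start == 0.0 and units[0].end == 900.0

    def test_definitional_tiling(self):
        js = [Junction(300.0, 35.0), Junction(520.0, 40.0)]
        units = segment_muscle_units(js, (0.0, 900.0))
        assert [(u.start, u.end) for u in units] == [
            (0.0, 300.0), (300.0, 520.0), (520.0, 900.0)
        ]

    def test_duplicate_junctions_rejected(self):
        js = [Junction(300.0, 35.0), Junction(300.0, 40.0)]
        with pytest.raises(ValueError):
            segment_muscle_units(js, (0.0, 900.0))

    def test_tiling_invariant_random(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            extent = (0.0, float(rng.uniform(500, 5000)))
            pos = np.sort(rng.uniform(1, extent[1] - 1, rng.integers(0, 20)))
            pos = np.unique(pos)
            units = segment_muscle_units(
                [Junction(float(x), 30.0) for x in pos], extent
            )
            assert sum(u.interval_length for u in units) == pytest.approx(extent[1])

    def test_rectangular_unit_width_equals_interval(self, thresholds):
        prof = make_profile(np.zeros(250))
        u = MuscleUnit(0.0, 250.0, 250.0)
        assert measure_unit_width(u, prof, thresholds) == pytest.approx(250.0)

    def test_v_flanks_narrow_measured_width(self, thresholds):
        # valley deeper than the 50 µm offset eats into the measurement line
        d = v_notch(300, 0.5, 80.0, slope=1.0) + v_notch(300, 299.5, 80.0, slope=1.0)
        prof = make_profile(d)
        u = MuscleUnit(0.0, 300.0, 300.0)
        w = measure_unit_width(u, prof, thresholds)
        assert w < 300.0
        assert w == pytest.approx(300.0 - 2 * 30.0, abs=2.0)

    def test_narrow_unit_flagged(self, thresholds):
        prof = make_profile(np.zeros(100), step=10.0)
        u = MuscleUnit(0.0, 15.0, 15.0)
        with pytest.warns(UserWarning):
            assert measure_unit_width(u, prof, thresholds) == 15.0


# --------------------------------------------------------------------------
# ganglion clustering
# --------------------------------------------------------------------------
def _cells(points, classes):
    return pd.DataFrame(
        {
            "x_um": [p[0] for p in points],
            "y_um": [p[1] for p in points],
            "cell_class": classes,
        }
    )


class TestClusterGanglia:
    def test_single_neuron_is_not_a_ganglion(self, thresholds):
        cells = _cells([(100.0, 0.0)], ["neuron"])
        assert cluster_ganglia(cells, thresholds) == []

    def test_two_neurons_with_glia(self, thresholds):
        pts = [(0.0, 0.0), (10.0, 0.0)] + [(5.0, d) for d in (5, -5, 10, -10, 15)]
        cells = _cells(pts, ["neuron"] * 2 + ["glia"] * 5)
        (g,) = cluster_ganglia(cells, thresholds)
        assert (g.n_neurons, g.n_glia, g.n_other) == (2, 5, 0)
        assert g.centroid_x == pytest.approx(5.0)

    def test_matches_brute_force_on_random_point_sets(self, thresholds):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            pts = rng.uniform(0, 300, size=(n, 2))
            cells = _cells([tuple(p) for p in pts], ["neuron"] * n)
            got = cluster_ganglia(cells, thresholds)
            want = brute_force_single_linkage(pts, thresholds.ganglion_link_distance)
            want_counts = sorted(
                len(g) for g in want if len(g) >= thresholds.min_neurons_per_ganglion
            )
            assert sorted(g.n_neurons for g in got) == want_counts
            # centroids agree too
            want_cx = sorted(
                float(np.mean(pts[list(g), 0]))
                for g in want
                if len(g) >= thresholds.min_neurons_per_ganglion
            )
            got_cx = sorted(g.centroid_x for g in got)
            assert np.allclose(got_cx, want_cx)

    def test_distant_glia_not_assigned(self, thresholds):
        cells = _cells(
            [(0.0, 0.0), (10.0, 0.0), (80.0, 0.0)], ["neuron", "neuron", "glia"]
        )
        (g,) = cluster_ganglia(cells, thresholds)
        assert g.n_glia == 0 and g.n_dapi == 2


# --------------------------------------------------------------------------
# bundles and zones
# --------------------------------------------------------------------------
class TestBundlesAndZones:
    def _comp(self, width, contains_neuron=False, x=500.0):
        return pd.DataFrame(
            [{"id": 1, "x_um": x, "y_um": 50.0, "width_um": width,
              "area_um2": width * 100, "contains_neuron": contains_neuron}]
        )

    def test_strict_40um_criterion(self, thresholds):
        (b,) = classify_bundles(self._comp(40.0), [], thresholds)
        assert not b.hypertrophic
        (b,) = classify_bundles(self._comp(40.1), [], thresholds)
        assert b.hypertrophic

    def test_inclusive_mode_flips_boundary_case(self):
        th = Thresholds(bundle_width_inclusive=True)
        (b,) = classify_bundles(self._comp(40.0), [], th)
        assert b.hypertrophic

    def test_component_with_neuron_excluded(self, thresholds):
        assert classify_bundles(self._comp(60.0, contains_neuron=True), [],
                                thresholds) == []

    def test_empty_components(self, thresholds):
        empty = pd.DataFrame(columns=["x_um", "width_um", "contains_neuron"])
        assert classify_bundles(empty, [], thresholds) == []

    def test_definitional_partition(self):
        ganglia = [_gang(x, i) for i, x in enumerate((1000.0, 4000.0, 9000.0))]
        bundles = [NerveBundle(5000.0, 60.0, True)]
        z = partition_zones(ganglia, bundles, (0.0, 12000.0))
        assert z.normal == (0.0, 5000.0)
        assert z.transition == (5000.0, 9000.0)
        assert z.aganglionic == (9000.0, 12000.0)

    def test_no_bundles_all_normal(self):
        ganglia = [_gang(x, i) for i, x in enumerate((1000.0, 4000.0))]
        z = partition_zones(ganglia, [], (0.0, 6000.0))
        assert z.transition is None
        assert z.normal == (0.0, 4000.0)
        assert z.zone_of(1000.0) == "normal"

    def test_no_ganglia_all_aganglionic(self):
        z = partition_zones([], [NerveBundle(50.0, 60.0, True)], (0.0, 1000.0))
        assert z.normal is None and z.transition is None
        assert z.aganglionic == (0.0, 1000.0)

    def test_all_ganglia_proximal_of_bundle_warns_empty_transition(self):
        ganglia = [_gang(100.0, 0), _gang(400.0, 1)]
        bundles = [NerveBundle(900.0, 60.0, True)]
        with pytest.warns(UserWarning):
            z = partition_zones(ganglia, bundles, (0.0, 1000.0))
        assert z.transition is None and z.normal == (0.0, 900.0)

    def test_raising_hypertrophy_width_never_moves_z1_proximally(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ganglia = [_gang(float(x), i) for i, x in
                       enumerate(np.sort(rng.uniform(0, 9000, 8)))]
            comps = pd.DataFrame(
                {
                    "id": np.arange(4),
                    "x_um": rng.uniform(0, 10000, 4),
                    "y_um": 50.0,
                    "width_um": rng.uniform(20, 90, 4),
                    "area_um2": 1000.0,
                    "contains_neuron": False,
                }
            )
            z1s = []
            for w in (30.0, 40.0, 60.0):
                th = Thresholds(bundle_hypertrophy_width=w)
                bundles = classify_bundles(comps, ganglia, th)
                z = partition_zones(ganglia, bundles, (0.0, 10000.0))
                z1s.append(np.inf if z.z1 is None else z.z1)
            assert z1s == sorted(z1s)


# --------------------------------------------------------------------------
# interval counts and MGR
# --------------------------------------------------------------------------
class TestIntervalsAndMgr:
    def test_same_unit_pair_counts_zero(self):
        ganglia = [_gang(100.0, 0), _gang(150.0, 1)]
        (iv,) = count_interval_units(ganglia, [Junction(500.0, 35.0)])
        assert iv.unit_count == 0

    def test_index_difference(self):
        junctions = [Junction(float(x), 35.0) for x in (100, 200, 300, 400, 500)]
        ganglia = [_gang(250.0, 0), _gang(550.0, 1)]  # units 2 and 5
        (iv,) = count_interval_units(ganglia, junctions)
        assert iv.unit_count == 3

    def test_fewer_than_two_ganglia_warns_empty(self):
        with pytest.warns(UserWarning):
            assert count_interval_units([_gang(10.0)], []) == []

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(21)
        for _ in range(1000):
            gx = np.sort(rng.uniform(0, 5000, rng.integers(2, 30)))
            jx = np.sort(rng.uniform(0, 5000, rng.integers(0, 60)))
            ganglia = [_gang(float(x), i) for i, x in enumerate(gx)]
            junctions = [Junction(float(x), 35.0) for x in jx]
            got = [iv.unit_count for iv in count_interval_units(ganglia, junctions)]
            assert got == brute_force_interval_counts(gx, jx)

    def test_saturated_layout_mgr_exactly_one(self):
        # one ganglion in every unit => every interval spans one junction
        junctions = [Junction(100.0 * k, 35.0) for k in range(1, 10)]
        ganglia = [_gang(100.0 * k + 50.0, k) for k in range(10)]
        z = partition_zones(ganglia, [], (0.0, 1000.0))
        ivs = count_interval_units(ganglia, junctions)
        assert compute_mgr(ivs, z)["normal"] == 1.0

    def test_alternate_empty_units_mgr_two(self):
        junctions = [Junction(100.0 * k, 35.0) for k in range(1, 10)]
        ganglia = [_gang(200.0 * k + 50.0, k) for k in range(5)]
        z = partition_zones(ganglia, [], (0.0, 1000.0))
        ivs = count_interval_units(ganglia, junctions)
        assert compute_mgr(ivs, z)["normal"] == 2.0

    def test_interior_deletion_never_decreases_mgr(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            jx = np.arange(1, 40) * 100.0
            gx = np.sort(rng.uniform(0, 4000, 12))
            ganglia = [_gang(float(x), i) for i, x in enumerate(gx)]
            junctions = [Junction(float(x), 35.0) for x in jx]
            z = partition_zones(ganglia, [], (0.0, 4000.0))
            base = compute_mgr(count_interval_units(ganglia, junctions), z)["normal"]
            for k in range(1, len(ganglia) - 1):
                reduced = ganglia[:k] + ganglia[k + 1:]
                zr = partition_zones(reduced, [], (0.0, 4000.0))
                red = compute_mgr(count_interval_units(reduced, junctions), zr)[
                    "normal"
                ]
                assert red >= base - 1e-12

    @given(st.floats(min_value=-1e4, max_value=1e4))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_translation_invariance(self, shift):
        jx = np.array([300.0, 520.0, 800.0])
        gx = np.array([100.0, 450.0, 700.0, 950.0])
        ganglia = [_gang(float(x + shift), i) for i, x in enumerate(gx)]
        junctions = [Junction(float(x + shift), 35.0) for x in jx]
        z = partition_zones(ganglia, [], (shift, 1000.0 + shift))
        counts = [iv.unit_count for iv in count_interval_units(ganglia, junctions)]
        assert counts == [1, 1, 1]
        assert compute_mgr(count_interval_units(ganglia, junctions), z)[
            "normal"
        ] == 1.0


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------
class TestComposition:
    def test_arithmetic(self):
        g = _gang(0.0, 0, n_neu=2, n_glia=6, n_other=2)
        assert ganglion_composition(g) == (10, pytest.approx(20.0), 3.0)

    def test_all_neuron_ganglion(self):
        g = _gang(0.0, 0, n_neu=5)
        size, pct, ratio = ganglion_composition(g)
        assert (size, pct, ratio) == (5, 100.0, 0.0)

    def test_count_sum_invariant_enforced(self):
        with pytest.raises(ValueError):
            Ganglion(id=0, centroid_x=0, centroid_y=0, n_dapi=5,
                     n_neurons=2, n_glia=2, n_other=2)
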
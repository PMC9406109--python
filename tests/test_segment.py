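"""Rendering + segmentation round-trip tests against generator truth."""

import numpy as np
import pandas as pd
import pytest

from mugr import SimulationParams, sample_tissue
from mugr.errors import (
    CalibrationError,
    FragmentedTissueError,
    ResolutionError,
)
from mugr.render import render_section
from mugr.scoring import detect_junctions
from mugr.segment import (
    classify_cells,
    detect_nuclei,
    extract_boundary_profile,
    extract_s100b_components,
)


@pytest.fixture(scope="module")
def noiseless(small_layout):
    p = SimulationParams(n_units=24, zone_layout=small_layout, noise_sd=0.0, seed=4)
    m = sample_tissue(p)
    return m, render_section(m)


class TestRender:
    def test_resolution_error_when_valleys_unresolvable(self, small_model):
        params = small_model.params.model_copy(update={"um_per_px": 12.0})
        with pytest.raises(ResolutionError):
            render_section(small_model, params)

    def test_every_truth_nucleus_has_labelled_pixels(self, noiseless):
        m, r = noiseless
        labels = set(np.unique(r.nuclei_labels)) - {0}
        assert labels == set(r.truth_table["id"])

    def test_channel_shapes_consistent(self, noiseless):
        _, r = noiseless
        shapes = {c.shape for c in r.channels.values()}
        assert shapes == {r.muscle_mask.shape}

    def test_aganglionic_model_has_dark_hu_channel(self):
        p = SimulationParams(
            n_units=6, zone_layout=(("aganglionic", 6),), noise_sd=0.0, seed=0
        )
        r = render_section(sample_tissue(p))
        nuclei = detect_nuclei(r.channels["hu"], r.um_per_px)
        assert len(nuclei) == 0

    def test_render_determinism(self, small_model):
        a = render_section(small_model)
        b = render_section(small_model)
        assert all(
            np.array_equal(a.channels[c], b.channels[c]) for c in a.channels
        )


class TestDetectNuclei:
    def test_blank_raster_empty(self):
        assert len(detect_nuclei(np.zeros((50, 50)), 1.0)) == 0

    def test_missing_calibration_rejected(self):
        with pytest.raises(CalibrationError):
            detect_nuclei(np.zeros((10, 10)), None)

    def test_exact_recovery_noiseless(self, noiseless):
        m, r = noiseless
        truth = m.truth_cells()
        got = detect_nuclei(r.channels["dapi"], r.um_per_px)
        assert len(got) == len(truth)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(got[["x_um", "y_um"]].to_numpy()).query(
            truth[["x_um", "y_um"]].to_numpy()
        )
        assert d.max() < 2.0

    def test_recall_precision_under_noise(self, small_layout):
        """Detection vs truth at 5 µm matching tolerance, default noise."""
        from scipy.spatial import cKDTree

        tp = fp = fn = 0
        for seed in range(5):
            p = SimulationParams(n_units=12, zone_layout=(("normal", 12),), seed=seed)
            m = sample_tissue(p)
            r = render_section(m)
            truth = m.truth_cells()[["x_um", "y_um"]].to_numpy()
            got = detect_nuclei(r.channels["dapi"], r.um_per_px)[
                ["x_um", "y_um"]
            ].to_numpy()
            d, _ = cKDTree(got).query(truth)
            fn += int((d > 5.0).sum())
            tp += int((d <= 5.0).sum())
            d2, _ = cKDTree(truth).query(got)
            fp += int((d2 > 5.0).sum())
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestClassifyCells:
    def test_zero_signal_nucleus_is_other(self):
        nuclei = pd.DataFrame(
            [{"id": 1, "x_um": 25.0, "y_um": 25.0, "area_um2": 50.0}]
        )
        out = classify_cells(nuclei, np.zeros((50, 50)), np.zeros((50, 50)), 1.0)
        assert out["cell_class"].tolist() == ["other"]

    def test_confusion_matrix_diagonal_noiseless(self, noiseless):
        from scipy.spatial import cKDTree

        m, r = noiseless
        truth = m.truth_cells()
        nuclei = detect_nuclei(r.channels["dapi"], r.um_per_px)
        cells = classify_cells(
            nuclei, r.channels["hu"], r.channels["s100b"], r.um_per_px
        )
        _, idx = cKDTree(truth[["x_um", "y_um"]].to_numpy()).query(
            cells[["x_um", "y_um"]].to_numpy()
        )
        want = truth["cell_class"].to_numpy()[idx]
        assert (cells["cell_class"].to_numpy() == want).all()


class TestBoundaryProfile:
    def test_rectangular_band_zero_depth(self):
        mask = np.zeros((60, 300), dtype=bool)
        mask[20:50] = True
        prof = extract_boundary_profile(mask, 1.0)
        assert np.allclose(prof.depth, 0.0)

    def test_single_notch_depth_recovered(self):
        mask = np.zeros((120, 600), dtype=bool)
        mask[20:110] = True
        xs = np.arange(600)
        notch = np.clip(40.0 - 4.0 * np.abs(xs - 300), 0, None)
        for x in range(600):
            mask[20 : 20 + int(round(notch[x])), x] = False
        prof = extract_boundary_profile(mask, 1.0)
        junctions = detect_junctions(prof)
        assert len(junctions) == 1
        assert junctions[0].depth == pytest.approx(40.0, abs=2.0)
        assert junctions[0].position == pytest.approx(300.5, abs=2.0)

    def test_fragmented_band_rejected(self):
        mask = np.zeros((60, 300), dtype=bool)
        mask[20:50, :100] = True
        mask[20:50, 200:] = True
        with pytest.raises(FragmentedTissueError):
            extract_boundary_profile(mask, 1.0)

    def test_rendered_valley_depths_match_truth(self, noiseless):
        m, r = noiseless
        prof = extract_boundary_profile(r.muscle_mask, r.um_per_px)
        junctions = detect_junctions(prof)
        truth = m.junctions
        assert len(junctions) == len(truth)
        for got, want in zip(junctions, truth):
            assert got.depth == pytest.approx(want.depth, rel=0.10)
            assert got.position == pytest.approx(want.position, abs=2.0)


class TestS100bComponents:
    def test_blank_channel_empty(self):
        empty = pd.DataFrame(columns=["x_um", "y_um", "cell_class"])
        out = extract_s100b_components(np.zeros((50, 50)), empty, 1.0)
        assert len(out) == 0

    def test_bundle_width_within_10pct(self, noiseless):
        m, r = noiseless
        nuclei = detect_nuclei(r.channels["dapi"], r.um_per_px)
        cells = classify_cells(
            nuclei, r.channels["hu"], r.channels["s100b"], r.um_per_px
        )
        comps = extract_s100b_components(r.channels["s100b"], cells, r.um_per_px)
        free = comps[~comps["contains_neuron"]]
        assert len(free) == len(m.bundles)
        for b in m.bundles:
            row = free.iloc[(free["x_um"] - b.center_x).abs().argmin()]
            assert row["width_um"] == pytest.approx(b.width, rel=0.10)

    def test_ganglion_components_contain_neurons(self, noiseless):
        m, r = noiseless
        nuclei = detect_nuclei(r.channels["dapi"], r.um_per_px)
        cells = classify_cells(
            nuclei, r.channels["hu"], r.channels["s100b"], r.um_per_px
        )
        comps = extract_s100b_components(r.channels["s100b"], cells, r.um_per_px)
        with_neurons = comps[comps["contains_neuron"]]
        assert len(with_neurons) == len(m.ganglia)


class TestCalibrationEquivariance:
    def test_um_outputs_stable_across_pixel_sizes(self, small_layout):
        base = SimulationParams(
            n_units=8, zone_layout=(("normal", 8),), noise_sd=0.0, seed=9
        )
        m = sample_tissue(base)
        results = {}
        for upp in (1.0, 2.0):
            r = render_section(m, base.model_copy(update={"um_per_px": upp}))
            prof = extract_boundary_profile(r.muscle_mask, r.um_per_px)
            junctions = detect_junctions(prof)
            nuclei = detect_nuclei(r.channels["dapi"], r.um_per_px)
            results[upp] = (
                [j.position for j in junctions],
                len(nuclei),
            )
        pos1, n1 = results[1.0]
        pos2, n2 = results[2.0]
        assert n1 == n2
        assert len(pos1) == len(pos2)
        assert np.allclose(pos1, pos2, atol=3.0)
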
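"""Separation-axis search, bouton labeling, exclusion-zone metrics."""

import numpy as np
import pytest

from islandseg.errors import DegenerateLabelingWarning, InvalidParameterError, UndefinedMetricError
from islandseg.segregation import (
    BoutonClass,
    exclusion_zone_metrics,
    find_separation_axis,
    label_boutons,
)
from islandseg.synthetic import SyntheticParams, generate_circuit

from conftest import MASK_OPTIONS, manual_labeling, simple_circuit


def _rotation(rng):
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


class TestFindSeparationAxis:
    def test_axis_aligned_clusters(self):
        rng = np.random.default_rng(0)
        a = np.c_[-5 * rng.random(40), rng.random(40), rng.random(40)]
        b = np.c_[10 + 5 * rng.random(40), rng.random(40), rng.random(40)]
        axis, gap = find_separation_axis(a, b)
        assert axis @ np.array([1.0, 0.0, 0.0]) > np.cos(np.deg2rad(4))
        assert gap == pytest.approx(10.0, abs=0.5)

    def test_identical_clouds_do_not_separate(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 3))
        _, gap = find_separation_axis(pts, pts)
        assert gap <= 0

    def test_two_spheres_vs_finer_grid_oracle(self):
        from _oracles import grid_gap_search

        rng = np.random.default_rng(7)
        true_dir = rng.normal(size=3)
        true_dir /= np.linalg.norm(true_dir)
        a = rng.normal(size=(60, 3))
        a /= np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1.0)
        b = a[::-1] * 0.9 + 12 * true_dir
        axis, gap = find_separation_axis(a, b, grid_step_deg=2.0)
        oracle_axis, oracle_gap = grid_gap_search(a, b, step_deg=1.0)
        # the 2-degree grid is nested inside the 1-degree grid
        assert gap <= oracle_gap + 1e-9
        assert gap == pytest.approx(oracle_gap, abs=0.05)
        assert axis @ true_dir > np.cos(np.deg2rad(4))
        assert axis @ oracle_axis > np.cos(np.deg2rad(4))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3)) + np.array([9.0, 0.0, 0.0])
        axis, gap = find_separation_axis(a, b)
        rot = _rotation(rng)
        axis_r, gap_r = find_separation_axis(a @ rot.T, b @ rot.T)
        assert gap_r == pytest.approx(gap, abs=0.1)
        assert abs(axis_r @ (rot @ axis)) > np.cos(np.deg2rad(5))

    def test_finer_grid_never_decreases_gap(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3)) + np.array([3.0, 4.0, 5.0])
        _, coarse = find_separation_axis(a, b, grid_step_deg=8.0)
        _, fine = find_separation_axis(a, b, grid_step_deg=4.0)
        assert fine >= coarse - 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            find_separation_axis(np.empty((0, 3)), np.ones((2, 3)))


class TestLabelBoutons:
    def test_mask_recovers_ground_truth(self, segregated_circuit, mask_options):
        circuit, truth = segregated_circuit
        lab = label_boutons(circuit, "region_mask", dict(mask_options))
        assert all(
            lab.labels[sid].value == truth.bouton_class[sid] for sid in truth.bouton_class
        )

    def test_label_counts_conserve(self, null_circuit):
        circuit, _ = null_circuit
        lab = label_boutons(circuit, "two_class_split", {"seed": 0})
        assert sum(lab.counts().values()) == len(circuit.rgc_synapses())

    def test_two_class_split_matches_ground_truth_outside_gap(self, null_circuit):
        circuit, truth = null_circuit
        lab = label_boutons(circuit, "two_class_split", {"seed": 0})
        agree = sum(
            lab.labels[sid].value == truth.bouton_class[sid] for sid in truth.bouton_class
        )
        assert agree == len(truth.bouton_class)

    def test_two_class_split_deterministic(self, null_circuit):
        circuit, _ = null_circuit
        a = label_boutons(circuit, "two_class_split", {"seed": 0})
        b = label_boutons(circuit, "two_class_split", {"seed": 0})
        assert a.labels == b.labels
        assert a.options["seed"] == 0

    def test_mid_gap_boutons_labeled_ambiguous(self):
        # two island boutons, three mid-gap boutons, a far field bouton
        specs = [
            ("i1", (1.0, 0.0, 0.0), None),
            ("i2", (-1.0, 0.5, 0.0), None),
            ("g1", (17.5, 0.0, 0.0), None),
            ("g2", (17.0, 2.0, 0.0), None),
            ("g3", (16.0, -2.0, 1.0), None),
            ("f1", (30.0, 0.0, 0.0), None),
        ]
        circuit = simple_circuit(specs)
        lab = label_boutons(
            circuit, "region_mask", {"center": [0, 0, 0], "radius": 15.0, "outer_radius": 20.0}
        )
        assert {lab.labels[s].value for s in ("g1", "g2", "g3")} == {"ambiguous"}
        assert lab.labels["i1"] is BoutonClass.ISLAND
        assert lab.labels["f1"] is BoutonClass.NON_ISLAND

    def test_degenerate_mask_warns(self, segregated_circuit):
        circuit, _ = segregated_circuit
        with pytest.warns(DegenerateLabelingWarning):
            label_boutons(circuit, "region_mask", {"center": [0, 0, 0], "radius": 1e6})

    def test_manual_labels_roundtrip(self, tmp_path):
        circuit = simple_circuit([("a", (0, 0, 0), None), ("b", (7, 0, 0), None)])
        p = tmp_path / "labels.csv"
        p.write_text("synapse_id,class\na,island\nb,non_island\n")
        lab = label_boutons(circuit, "manual", {"path": str(p)})
        assert lab.labels["a"] is BoutonClass.ISLAND
        assert lab.labels["b"] is BoutonClass.NON_ISLAND


class TestExclusionZoneMetrics:
    def test_generated_gap_bounds_projection_gap(self, segregated_circuit, mask_options):
        circuit, _ = segregated_circuit
        lab = label_boutons(circuit, "region_mask", dict(mask_options))
        metrics = exclusion_zone_metrics(lab, circuit)
        assert metrics["projection_gap_um"] >= 5.0 - 1e-9
        assert metrics["min_cross_class_distance_um"] >= 5.0 - 1e-9

    def test_overlapping_shells_gap_nonpositive(self):
        params = SyntheticParams(seed=8, gap_width=0.0, one_sided_field=False)
        circuit, _ = generate_circuit(params)
        lab = label_boutons(
            circuit, "region_mask", {"center": [0, 0, 0], "radius": params.island_radius}
        )
        assert lab.projection_gap <= 0

    def test_two_point_cross_distance(self):
        circuit = simple_circuit([("a", (0.0, 0.0, 0.0), None), ("b", (7.0, 0.0, 0.0), None)])
        lab = manual_labeling(
            {"a": "island", "b": "non_island"},
            positions={"a": np.zeros(3), "b": np.array([7.0, 0.0, 0.0])},
        )
        metrics = exclusion_zone_metrics(lab, circuit)
        assert metrics["min_cross_class_distance_um"] == pytest.approx(7.0)

    def test_empty_class_is_undefined(self):
        circuit = simple_circuit([("a", (0, 0, 0), None)])
        lab = manual_labeling({"a": "island"})
        with pytest.raises(UndefinedMetricError):
            exclusion_zone_metrics(lab, circuit)
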
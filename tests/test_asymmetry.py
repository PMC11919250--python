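"""Soma-to-input displacement, asymmetry index, alignment sign structure."""

import numpy as np
import pytest

from islandseg.asymmetry import cohort_asymmetry_summary, soma_to_input_vector
from islandseg.capture import build_profiles
from islandseg.errors import UndefinedMetricError
from islandseg.segregation import BoutonClass, label_boutons
from islandseg.synthetic import SyntheticParams, generate_circuit

from conftest import MASK_OPTIONS, manual_labeling, simple_circuit


def _lab(ids_positions, extra_non_island=("ref", (100.0, 0.0, 0.0))):
    """Manual labeling marking the given synapses island plus one far
    non-island reference bouton so centroids and the axis are defined."""
    labels = {sid: "island" for sid, _ in ids_positions}
    positions = {sid: np.asarray(p, float) for sid, p in ids_positions}
    labels[extra_non_island[0]] = "non_island"
    positions[extra_non_island[0]] = np.asarray(extra_non_island[1], float)
    return manual_labeling(labels, positions)


class TestSomaToInputVector:
    def test_symmetric_inputs_cancel(self):
        specs = [("a", (5.0, 0.0, 0.0), None), ("b", (-5.0, 0.0, 0.0), None),
                 ("ref", (100.0, 0.0, 0.0), None)]
        circuit = simple_circuit(specs)
        lab = _lab([("a", (5, 0, 0)), ("b", (-5, 0, 0))])
        rec = soma_to_input_vector("tc", circuit, lab, class_filter=(BoutonClass.ISLAND,))
        assert np.allclose(rec.displacement, 0)
        assert rec.asymmetry_index == pytest.approx(0.0)

    def test_single_input_fully_asymmetric(self):
        specs = [("a", (5.0, 0.0, 0.0), None), ("ref", (100.0, 0.0, 0.0), None)]
        circuit = simple_circuit(specs)
        rec = soma_to_input_vector(
            "tc", circuit, _lab([("a", (5, 0, 0))]), class_filter=(BoutonClass.ISLAND,)
        )
        assert np.allclose(rec.displacement, [5, 0, 0])
        assert rec.magnitude == pytest.approx(5.0)
        assert rec.asymmetry_index == pytest.approx(1.0)

    def test_index_bounded_by_one(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(scale=10.0, size=(25, 3))
        specs = [(f"s{i}", tuple(p), None) for i, p in enumerate(pts)]
        specs.append(("ref", (100.0, 0.0, 0.0), None))
        circuit = simple_circuit(specs)
        rec = soma_to_input_vector(
            "tc", circuit, _lab([(f"s{i}", pts[i]) for i in range(len(pts))]),
            class_filter=(BoutonClass.ISLAND,),
        )
        assert 0.0 <= rec.asymmetry_index <= 1.0

    def test_no_qualifying_inputs_undefined(self):
        circuit = simple_circuit([("a", (1.0, 0.0, 0.0), None)])
        lab = manual_labeling({"a": "ambiguous"})
        with pytest.raises(UndefinedMetricError):
            soma_to_input_vector("tc", circuit, lab)

    def test_translation_invariance_and_rotation_equivariance(self):
        circuit, _ = generate_circuit(SyntheticParams(seed=41, segregation=1.0))
        lab = label_boutons(circuit, "region_mask", dict(MASK_OPTIONS, grid_step_deg=10.0))
        nid = next(iter(circuit.skeletons))
        base = soma_to_input_vector(nid, circuit, lab)

        shift = np.array([100.0, -50.0, 25.0])
        shifted = _translate_circuit(circuit, shift)
        lab_s = label_boutons(
            shifted, "region_mask",
            {"center": list(shift), "radius": 15.0, "outer_radius": 20.0, "grid_step_deg": 10.0},
        )
        rec_s = soma_to_input_vector(nid, shifted, lab_s)
        assert np.allclose(rec_s.displacement, base.displacement, atol=1e-9)
        assert rec_s.asymmetry_index == pytest.approx(base.asymmetry_index, abs=1e-12)

    def test_island_captured_cell_aligns_toward_island(self, segregated_circuit):
        circuit, truth = segregated_circuit
        lab = label_boutons(circuit, "region_mask", dict(MASK_OPTIONS))
        for nid, classes in truth.dendrite_class.items():
            rec = soma_to_input_vector(nid, circuit, lab)
            if all(c == "island" for c in classes):
                assert rec.alignment > 0
            elif all(c == "non_island" for c in classes):
                assert rec.alignment < 0


def _translate_circuit(circuit, shift):
    from islandseg.circuit import Circuit, NeuronRecord, Skeleton, SkeletonNode, SynapseRecord

    neurons = [
        NeuronRecord(
            r.neuron_id, r.kind,
            None if r.soma_position is None else r.soma_position + shift,
        )
        for r in circuit.neurons.values()
    ]
    skeletons = [
        Skeleton(
            sk.neuron_id,
            [SkeletonNode(n.node_id, n.parent_id, n.position + shift, n.radius, n.tag)
             for n in sk.nodes],
        )
        for sk in circuit.skeletons.values()
    ]
    synapses = [
        SynapseRecord(s.synapse_id, s.pre_id, s.post_id, s.pre_kind,
                      s.position + shift, s.post_node)
        for s in circuit.synapses
    ]
    return Circuit(neurons, skeletons, synapses)


class TestCohortSummary:
    def test_signs_split_by_capture_class(self, segregated_circuit):
        circuit, _ = segregated_circuit
        lab = label_boutons(circuit, "region_mask", dict(MASK_OPTIONS))
        profiles = build_profiles(circuit, lab, count_dendrites=False)
        records = [soma_to_input_vector(p.neuron_id, circuit, lab) for p in profiles]
        summary = cohort_asymmetry_summary(records, profiles)
        per = summary["per_class"]
        if "island_only" in per:
            assert per["island_only"]["mean_alignment"] > 0
        if "non_island_only" in per:
            assert per["non_island_only"]["mean_alignment"] < 0
        test = summary["alignment_sign_test"]
        assert test["successes"] == test["n"]

    def test_single_class_cohort_no_error(self):
        specs = [("a", (5.0, 0.0, 0.0), None), ("b", (6.0, 0.0, 0.0), None),
                 ("ref", (100.0, 0.0, 0.0), None)]
        circuit = simple_circuit(specs)
        lab = _lab([("a", (5, 0, 0)), ("b", (6, 0, 0))])
        profiles = build_profiles(circuit, lab, count_dendrites=False)
        recs = [soma_to_input_vector("tc", circuit, lab)] * 2
        summary = cohort_asymmetry_summary(recs, profiles)
        assert set(summary["per_class"]) <= {"island_only", "mixed"}

    def test_too_few_records(self):
        with pytest.raises(UndefinedMetricError):
            cohort_asymmetry_summary([], [])
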
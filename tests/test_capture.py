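"""Innervation profiles, capture classification, dendrite counting, purity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islandseg.capture import (
    CaptureClass,
    CaptureProfile,
    branch_purity,
    build_profiles,
    capture_fraction,
    classify_capture,
    count_primary_dendrites,
    rgc_input_profile,
)
from islandseg.errors import UndefinedMetricError, UnresolvedSynapseError
from islandseg.segregation import label_boutons

from conftest import MASK_OPTIONS, manual_labeling, simple_circuit, star_skeleton


class TestInputProfile:
    def test_cell_without_inputs(self):
        circuit = simple_circuit([])
        lab = manual_labeling({})
        assert rgc_input_profile("tc", circuit, lab) == (0, 0, 0)

    def test_mixed_branch_cell(self):
        # emulates a neurite receiving 4 island then 42 non-island boutons
        specs = [(f"i{j}", (j * 0.1, 0, 0), None) for j in range(4)]
        specs += [(f"n{j}", (25 + j * 0.1, 0, 0), None) for j in range(42)]
        circuit = simple_circuit(specs)
        lab = manual_labeling(
            {s: ("island" if s.startswith("i") else "non_island") for s, _, _ in specs}
        )
        assert rgc_input_profile("tc", circuit, lab) == (4, 42, 0)

    def test_unknown_neuron(self):
        circuit = simple_circuit([])
        with pytest.raises(KeyError):
            rgc_input_profile("nope", circuit, manual_labeling({}))


class TestClassifyCapture:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((12, 0, 0), CaptureClass.ISLAND_ONLY),
            ((0, 7, 0), CaptureClass.NON_ISLAND_ONLY),
            ((4, 42, 0), CaptureClass.MIXED),
            ((2, 0, 3), CaptureClass.AMBIGUOUS),
            ((0, 0, 0), CaptureClass.NO_INPUT),
            ((0, 0, 3), CaptureClass.AMBIGUOUS),
            ((1, 1, 1), CaptureClass.MIXED),
        ],
    )
    def test_rule(self, counts, expected):
        assert classify_capture(*counts) is expected

    def test_min_inputs_threshold(self):
        assert classify_capture(1, 0, 0, min_inputs=2) is CaptureClass.NO_INPUT
        assert classify_capture(2, 0, 0, min_inputs=2) is CaptureClass.ISLAND_ONLY

    @given(
        ni=st.integers(0, 50), nn=st.integers(0, 50), na=st.integers(0, 5)
    )
    @settings(max_examples=100, deadline=None)
    def test_swap_invariance(self, ni, nn, na):
        """Swapping island/non-island counts swaps only the exclusive classes."""
        swap = {
            CaptureClass.ISLAND_ONLY: CaptureClass.NON_ISLAND_ONLY,
            CaptureClass.NON_ISLAND_ONLY: CaptureClass.ISLAND_ONLY,
        }
        a = classify_capture(ni, nn, na)
        b = classify_capture(nn, ni, na)
        assert b is swap.get(a, a)


class TestCountPrimaryDendrites:
    def test_counts_innervated_root_children(self):
        sk = star_skeleton(n_branches=3)
        # branch stems are nodes 2, 4, 6; tips 3, 5, 7
        circuit = simple_circuit(
            [("s1", (10, 0, 0), 3), ("s2", (-5, -8.66, 0), 7)], skeleton=sk
        )
        assert count_primary_dendrites(sk, circuit, "tc") == 2

    def test_no_synapses_gives_zero(self):
        sk = star_skeleton(n_branches=5)
        circuit = simple_circuit([], skeleton=sk)
        assert count_primary_dendrites(sk, circuit, "tc") == 0

    def test_nearest_node_resolution(self):
        sk = star_skeleton(n_branches=3, length=10.0)
        # bouton 0.5 um off the tip of branch 1 (tip node 3 at (10,0,0))
        circuit = simple_circuit([("s1", (10.4, 0.2, 0.0), None)], skeleton=sk)
        assert count_primary_dendrites(sk, circuit, "tc", nearest_node_radius=2.0) == 1
        with pytest.raises(UnresolvedSynapseError) as exc:
            count_primary_dendrites(sk, circuit, "tc", nearest_node_radius=None)
        assert "s1" in str(exc.value)

    def test_out_of_radius_unresolved(self):
        sk = star_skeleton(n_branches=2, length=10.0)
        circuit = simple_circuit([("far", (50.0, 50.0, 50.0), None)], skeleton=sk)
        with pytest.raises(UnresolvedSynapseError):
            count_primary_dendrites(sk, circuit, "tc", nearest_node_radius=2.0)

    def test_matches_generator_ground_truth(self, segregated_circuit, mask_options):
        circuit, truth = segregated_circuit
        lab = label_boutons(circuit, "region_mask", dict(mask_options))
        for p in build_profiles(circuit, lab):
            assert p.primary_dendrite_count == len(truth.dendrite_class[p.neuron_id])


class TestBranchPurity:
    def _mixed_branch_setup(self):
        sk = star_skeleton(n_branches=2, length=10.0)
        specs = [(f"i{j}", (10, 0, 0), 3) for j in range(4)]
        specs += [(f"n{j}", (-10, 0, 0), 3) for j in range(42)]
        labels = {s: ("island" if s.startswith("i") else "non_island") for s, _, _ in specs}
        return simple_circuit(specs, skeleton=sk), sk, manual_labeling(labels)

    def test_majority_fraction(self):
        circuit, sk, lab = self._mixed_branch_setup()
        assert branch_purity(2, sk, circuit, lab) == pytest.approx(42 / 46)

    def test_pure_and_tied_branches(self):
        sk = star_skeleton(n_branches=1)
        circuit = simple_circuit(
            [(f"s{j}", (10, 0, 0), 3) for j in range(10)], skeleton=sk
        )
        lab = manual_labeling({f"s{j}": "island" for j in range(10)})
        assert branch_purity(2, sk, circuit, lab) == 1.0
        lab2 = manual_labeling(
            {f"s{j}": ("island" if j < 5 else "non_island") for j in range(10)}
        )
        assert branch_purity(2, sk, circuit, lab2) == 0.5

    def test_unlabeled_subtree_undefined(self):
        sk = star_skeleton(n_branches=2)
        circuit = simple_circuit([("s1", (10, 0, 0), 3)], skeleton=sk)
        lab = manual_labeling({"s1": "ambiguous"})
        with pytest.raises(UndefinedMetricError):
            branch_purity(2, sk, circuit, lab)


def _profile(nid, ni, nn, na=0, k=2):
    return CaptureProfile(nid, ni, nn, na, classify_capture(ni, nn, na), k)


class TestCaptureFraction:
    def test_all_exclusive(self):
        profiles = [_profile(f"c{i}", 10, 0) for i in range(9)]
        assert capture_fraction(profiles) == (1.0, 9, 9)

    def test_six_plus_eight_cohort(self):
        profiles = [_profile(f"i{i}", 5, 0) for i in range(6)]
        profiles += [_profile(f"n{i}", 0, 5) for i in range(8)]
        assert capture_fraction(profiles) == (1.0, 14, 14)

    def test_mixed_cell_halves_fraction(self):
        profiles = [_profile("a", 3, 4), _profile("b", 3, 0)]
        frac, captured, total = capture_fraction(profiles)
        assert (frac, captured, total) == (0.5, 1, 2)

    def test_default_filter_excludes_ambiguous_and_no_input(self):
        profiles = [
            _profile("a", 5, 0),
            _profile("amb", 2, 0, na=3),
            _profile("none", 0, 0),
        ]
        assert capture_fraction(profiles) == (1.0, 1, 1)

    def test_empty_cohort_undefined(self):
        with pytest.raises(UndefinedMetricError):
            capture_fraction([_profile("none", 0, 0)])
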
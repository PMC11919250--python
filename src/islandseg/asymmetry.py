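"""Dendritic-arbor asymmetry relative to retinal input positions.

For each relay cell the displacement from the soma to the unweighted mean
position of its retinal inputs summarizes how one-sided the
bouton-receiving arbor is.  The scale-free asymmetry index divides that
displacement magnitude by the mean soma-to-input distance (0 for a
perfectly balanced arbor, approaching 1 when every input lies on one side),
and the alignment is the cosine between the displacement and a reference
axis oriented toward the island, so captured cells on either side of the
exclusion zone should align with opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .capture import CaptureClass, CaptureProfile
from .circuit import Circuit, PreKind
from .errors import UndefinedMetricError
from .segregation import BoutonClass, BoutonLabeling

__all__ = ["AsymmetryRecord", "soma_to_input_vector", "cohort_asymmetry_summary"]

_DEFAULT_FILTER = (BoutonClass.ISLAND, BoutonClass.NON_ISLAND)


@dataclass
class AsymmetryRecord:
    neuron_id: str
    soma_position: np.ndarray
    mean_input_position: np.ndarray
    displacement: np.ndarray  # mean_input_position - soma_position, um
    magnitude: float  # |displacement|, um
    asymmetry_index: float  # magnitude / mean soma-to-input distance, in [0, 1]
    alignment: float  # cosine vs island-pointing reference axis, in [-1, 1]

    def to_row(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "soma_x": self.soma_position[0],
            "soma_y": self.soma_position[1],
            "soma_z": self.soma_position[2],
            "mean_input_x": self.mean_input_position[0],
            "mean_input_y": self.mean_input_position[1],
            "mean_input_z": self.mean_input_position[2],
            "magnitude_um": self.magnitude,
            "asymmetry_index": self.asymmetry_index,
            "alignment": self.alignment,
        }


def _island_pointing_axis(labeling: BoutonLabeling) -> np.ndarray | None:
    """Reference axis from the non-island centroid toward the island centroid."""
    if labeling.separation_axis is None:
        if labeling.island_centroid is None or labeling.non_island_centroid is None:
            return None
        d = labeling.island_centroid - labeling.non_island_centroid
        n = np.linalg.norm(d)
        return d / n if n > 0 else None
    axis = labeling.separation_axis
    if labeling.island_centroid is not None and labeling.non_island_centroid is not None:
        if (labeling.island_centroid - labeling.non_island_centroid) @ axis < 0:
            axis = -axis
    return axis


def soma_to_input_vector(
    neuron_id: str,
    circuit: Circuit,
    labeling: BoutonLabeling,
    class_filter: tuple[BoutonClass, ...] = _DEFAULT_FILTER,
    reference_axis=None,
) -> AsymmetryRecord:
    """Displacement from soma to mean retinal-input position for one cell.

    Inputs are weighted equally (one vote per annotated contact); ambiguous
    boutons are excluded by the default class filter.  ``reference_axis``
    defaults to the labeling's separation axis oriented toward the island.
    """
    rec = circuit.neurons[neuron_id]
    if rec.soma_position is None:
        raise UndefinedMetricError(f"neuron {neuron_id!r} has no soma position")
    inputs = [
        s.position
        for s in circuit.synapses_onto(neuron_id, pre_kind=PreKind.RGC)
        if labeling.label_of(s.synapse_id) in class_filter
    ]
    if not inputs:
        raise UndefinedMetricError(
            f"neuron {neuron_id!r} has no retinal input passing the class filter"
        )
    inputs = np.array(inputs)
    soma = rec.soma_position
    mean_pos = inputs.mean(axis=0)
    disp = mean_pos - soma
    mag = float(np.linalg.norm(disp))
    mean_dist = float(np.linalg.norm(inputs - soma, axis=1).mean())
    index = 0.0 if mean_dist == 0 else mag / mean_dist
    if reference_axis is None:
        reference_axis = _island_pointing_axis(labeling)
    if reference_axis is None or mag == 0:
        alignment = 0.0
    else:
        ref = np.asarray(reference_axis, dtype=float)
        alignment = float(disp @ ref / (mag * np.linalg.norm(ref)))
    return AsymmetryRecord(
        neuron_id=neuron_id,
        soma_position=soma,
        mean_input_position=mean_pos,
        displacement=disp,
        magnitude=mag,
        asymmetry_index=index,
        alignment=alignment,
    )


def cohort_asymmetry_summary(
    records: list[AsymmetryRecord], profiles: list[CaptureProfile]
) -> dict:
    """Per-capture-class asymmetry means plus an alignment sign test.

    The sign test asks whether island-captured cells align positively and
    non-island-captured cells negatively with the island-pointing axis
    (successes pooled across both classes, exact binomial against 0.5,
    one-sided).
    """
    if len(records) < 2:
        raise UndefinedMetricError("cohort summary needs at least two records")
    class_of = {p.neuron_id: p.capture_class for p in profiles}
    by_class: dict[str, list[AsymmetryRecord]] = {}
    for r in records:
        cls = class_of.get(r.neuron_id)
        if cls is not None:
            by_class.setdefault(cls.value, []).append(r)
    summary: dict = {"per_class": {}}
    for cls, recs in sorted(by_class.items()):
        summary["per_class"][cls] = {
            "n": len(recs),
            "mean_asymmetry_index": float(np.mean([r.asymmetry_index for r in recs])),
            "mean_alignment": float(np.mean([r.alignment for r in recs])),
        }
    successes = trials = 0
    for r in by_class.get(CaptureClass.ISLAND_ONLY.value, []):
        trials += 1
        successes += r.alignment > 0
    for r in by_class.get(CaptureClass.NON_ISLAND_ONLY.value, []):
        trials += 1
        successes += r.alignment < 0
    if trials > 0:
        test = binomtest(successes, trials, 0.5, alternative="greater")
        summary["alignment_sign_test"] = {
            "successes": int(successes),
            "n": int(trials),
            "p_value": float(test.pvalue),
        }
    return summary
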
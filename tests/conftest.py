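import numpy as np
import pytest

from islandseg.circuit import (
    Circuit,
    NeuronKind,
    NeuronRecord,
    PreKind,
    Skeleton,
    SkeletonNode,
    SynapseRecord,
)
from islandseg.segregation import BoutonClass, BoutonLabeling
from islandseg.synthetic import SyntheticParams, generate_circuit

#: Innervated-primary-dendrite counts of the nine-cell exclusion-zone cohort.
REFERENCE_COUNTS = (2, 2, 3, 4, 4, 4, 5, 5, 7)

#: region_mask options matching the default generator geometry
#: (island radius 15 um, gap 5 um).
MASK_OPTIONS = {"center": [0.0, 0.0, 0.0], "radius": 15.0, "outer_radius": 20.0}


@pytest.fixture(scope="session")
def reference_counts():
    return REFERENCE_COUNTS


@pytest.fixture(scope="session")
def mask_options():
    return dict(MASK_OPTIONS)


@pytest.fixture(scope="session")
def segregated_circuit():
    """Fully segregated circuit (s=1): every cell captured by construction."""
    return generate_circuit(SyntheticParams(seed=11, segregation=1.0))


@pytest.fixture(scope="session")
def null_circuit():
    """Independent-dendrite circuit (s=0): the capture null made flesh."""
    return generate_circuit(SyntheticParams(seed=12, segregation=0.0))


def manual_labeling(labels: dict[str, str], positions: dict[str, np.ndarray] | None = None):
    """Build a BoutonLabeling directly from synapse_id -> class strings."""
    lab = {sid: BoutonClass(v) for sid, v in labels.items()}
    island = non = None
    if positions:
        ip = [positions[s] for s, v in lab.items() if v is BoutonClass.ISLAND]
        np_ = [positions[s] for s, v in lab.items() if v is BoutonClass.NON_ISLAND]
        island = np.mean(ip, axis=0) if ip else None
        non = np.mean(np_, axis=0) if np_ else None
    return BoutonLabeling(
        labels=lab,
        separation_axis=None,
        projection_gap=float("nan"),
        island_centroid=island,
        non_island_centroid=non,
        method="manual",
    )


def star_skeleton(neuron_id="tc", n_branches=3, soma=(0.0, 0.0, 0.0), length=10.0):
    """Soma with ``n_branches`` straight two-node dendrites in the xy plane."""
    soma = np.asarray(soma, float)
    nodes = [SkeletonNode(1, None, soma, radius=4.0, tag=1)]
    nid = 2
    for i in range(n_branches):
        ang = 2 * np.pi * i / max(n_branches, 1)
        d = np.array([np.cos(ang), np.sin(ang), 0.0])
        nodes.append(SkeletonNode(nid, 1, soma + 0.4 * length * d, radius=0.6, tag=3))
        nodes.append(SkeletonNode(nid + 1, nid, soma + length * d, radius=0.4, tag=3))
        nid += 2
    return Skeleton(neuron_id, nodes)


def simple_circuit(synapse_specs, skeleton=None, soma=(0.0, 0.0, 0.0)):
    """One TC plus an RGC axon; synapse_specs = [(id, position, post_node), ...]."""
    neurons = [
        NeuronRecord("tc", NeuronKind.TC, soma_position=soma),
        NeuronRecord("rgc", NeuronKind.RGC_AXON),
    ]
    synapses = [
        SynapseRecord(sid, "rgc", "tc", PreKind.RGC, pos, post_node=node)
        for sid, pos, node in synapse_specs
    ]
    return Circuit(neurons, [skeleton] if skeleton else [], synapses)
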
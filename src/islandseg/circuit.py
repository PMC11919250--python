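"""Domain types for reconstructed retinogeniculate circuits.

A :class:`Circuit` bundles the three things the analysis needs in one
coordinate frame (micrometers): neuron records (thalamocortical relay cells,
local inhibitory neurons, retinal ganglion cell axons), soma-rooted skeleton
trees, and a synapse table.  A retinal bouton is represented by a
:class:`SynapseRecord` whose presynaptic kind is ``RGC``; multi-synaptic
boutons in raw annotations collapse to one record per annotated contact,
because the analysis counts bouton-level innervation rather than active
zones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import CircuitValidationError

__all__ = [
    "NeuronKind",
    "PreKind",
    "NeuronRecord",
    "SkeletonNode",
    "Skeleton",
    "SynapseRecord",
    "Circuit",
]


class NeuronKind(str, enum.Enum):
    """Cell classes present in the reconstruction."""

    TC = "TC"  # thalamocortical relay cell
    LIN = "LIN"  # local inhibitory neuron
    RGC_AXON = "RGC_AXON"  # retinal ganglion cell axon (axon-only object)
    OTHER = "OTHER"


class PreKind(str, enum.Enum):
    """Presynaptic bouton classes of a synapse."""

    RGC = "RGC"
    LIN = "LIN"
    CORTICAL = "CORTICAL"
    OTHER = "OTHER"


def _as_point(x) -> np.ndarray:
    p = np.asarray(x, dtype=float).reshape(3)
    return p


@dataclass(frozen=True)
class NeuronRecord:
    """One cell (or axon-only object) of the reconstruction.

    ``soma_position`` is in micrometers and is required for TC and LIN
    records; axon-only objects (RGC axons entering the volume) have none.
    """

    neuron_id: str
    kind: NeuronKind = NeuronKind.OTHER
    soma_position: np.ndarray | None = None

    def __post_init__(self):
        if self.soma_position is not None:
            object.__setattr__(self, "soma_position", _as_point(self.soma_position))


@dataclass
class SkeletonNode:
    """One node of an SWC-style skeleton tree (positions in micrometers)."""

    node_id: int
    parent_id: int | None
    position: np.ndarray
    radius: float = 1.0
    tag: int = 0  # SWC structure tag; only the root/soma flag is semantic

    def __post_init__(self):
        self.position = _as_point(self.position)


class Skeleton:
    """A soma-rooted tree of nodes for one neuron.

    Invariants (checked by :meth:`validate`): exactly one root, parent links
    form a tree with every node reachable from the root, and finite
    positions.
    """

    def __init__(self, neuron_id: str, nodes: list[SkeletonNode]):
        self.neuron_id = neuron_id
        self.nodes = list(nodes)
        self._by_id = {n.node_id: n for n in self.nodes}
        roots = [n.node_id for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise CircuitValidationError(
                f"skeleton {neuron_id!r}: expected exactly one root, found {len(roots)}"
            )
        self.root = roots[0]
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        by_id = self._by_id
        if len(by_id) != len(self.nodes):
            raise CircuitValidationError(
                f"skeleton {self.neuron_id!r}: duplicate node ids"
            )
        for n in self.nodes:
            if n.parent_id is not None and n.parent_id not in by_id:
                raise CircuitValidationError(
                    f"skeleton {self.neuron_id!r}: node {n.node_id} references "
                    f"missing parent {n.parent_id}"
                )
            if not np.all(np.isfinite(n.position)):
                raise CircuitValidationError(
                    f"skeleton {self.neuron_id!r}: node {n.node_id} has non-finite position"
                )
        # reachability from root == tree (each node has exactly one parent)
        children = self.children_map()
        seen = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise CircuitValidationError(
                    f"skeleton {self.neuron_id!r}: cycle detected at node {nid}"
                )
            seen.add(nid)
            stack.extend(children.get(nid, ()))
        if len(seen) != len(self.nodes):
            orphans = sorted(set(by_id) - seen)
            raise CircuitValidationError(
                f"skeleton {self.neuron_id!r}: nodes unreachable from root: {orphans}"
            )

    def node(self, node_id: int) -> SkeletonNode:
        return self._by_id[node_id]

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._by_id

    def __len__(self) -> int:
        return len(self.nodes)

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for n in self.nodes:
            if n.parent_id is not None:
                out.setdefault(n.parent_id, []).append(n.node_id)
        return out

    def root_children(self) -> list[int]:
        return self.children_map().get(self.root, [])

    def branch_of(self) -> dict[int, int]:
        """Map each non-root node to the root-child (primary-branch stem) above it."""
        children = self.children_map()
        branch: dict[int, int] = {}
        for stem in children.get(self.root, []):
            stack = [stem]
            while stack:
                nid = stack.pop()
                branch[nid] = stem
                stack.extend(children.get(nid, ()))
        return branch

    def subtree_nodes(self, node_id: int) -> set[int]:
        children = self.children_map()
        out: set[int] = set()
        stack = [node_id]
        while stack:
            nid = stack.pop()
            out.add(nid)
            stack.extend(children.get(nid, ()))
        return out

    def positions(self) -> np.ndarray:
        """(n, 3) array of node positions, in node order."""
        return np.array([n.position for n in self.nodes], dtype=float)

    def node_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes]


@dataclass
class SynapseRecord:
    """One annotated synaptic contact.

    An RGC bouton is a record with ``pre_kind == PreKind.RGC``; ``position``
    is the bouton location in micrometers.  ``post_node`` optionally links
    the contact to a node of the postsynaptic cell's skeleton.
    """

    synapse_id: str
    pre_id: str
    post_id: str
    pre_kind: PreKind
    position: np.ndarray
    post_node: int | None = None

    def __post_init__(self):
        self.position = _as_point(self.position)


class Circuit:
    """Neurons + skeletons + synapses in one micrometer coordinate frame."""

    units = "um"

    def __init__(
        self,
        neurons: list[NeuronRecord],
        skeletons: list[Skeleton] | None = None,
        synapses: list[SynapseRecord] | None = None,
    ):
        self.neurons: dict[str, NeuronRecord] = {}
        for rec in neurons:
            if rec.neuron_id in self.neurons:
                raise CircuitValidationError(f"duplicate neuron_id {rec.neuron_id!r}")
            self.neurons[rec.neuron_id] = rec
        self.skeletons: dict[str, Skeleton] = {}
        for sk in skeletons or []:
            self.skeletons[sk.neuron_id] = sk
        self.synapses: list[SynapseRecord] = list(synapses or [])

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid).

        Validation is read-only and therefore idempotent: revalidating a
        valid circuit reports zero new problems.
        """
        problems: list[str] = []
        for nid, rec in self.neurons.items():
            if rec.kind in (NeuronKind.TC, NeuronKind.LIN) and rec.soma_position is None:
                problems.append(f"neuron {nid!r} of kind {rec.kind.value} lacks soma_position")
            if rec.soma_position is not None and not np.all(np.isfinite(rec.soma_position)):
                problems.append(f"neuron {nid!r} has non-finite soma_position")
        for nid in self.skeletons:
            if nid not in self.neurons:
                problems.append(f"skeleton references unknown neuron {nid!r}")
        for syn in self.synapses:
            if syn.pre_id not in self.neurons:
                problems.append(f"synapse {syn.synapse_id!r} references unknown pre {syn.pre_id!r}")
            if syn.post_id not in self.neurons:
                problems.append(
                    f"synapse {syn.synapse_id!r} references unknown post {syn.post_id!r}"
                )
            if syn.pre_id == syn.post_id:
                problems.append(f"synapse {syn.synapse_id!r} is an autapse (pre == post)")
            if not np.all(np.isfinite(syn.position)):
                problems.append(f"synapse {syn.synapse_id!r} has non-finite position")
        return problems

    # -- queries -----------------------------------------------------------
    def rgc_synapses(self) -> list[SynapseRecord]:
        return [s for s in self.synapses if s.pre_kind is PreKind.RGC]

    def synapses_onto(self, neuron_id: str, pre_kind: PreKind | None = None) -> list[SynapseRecord]:
        if neuron_id not in self.neurons:
            raise KeyError(f"unknown neuron {neuron_id!r}")
        return [
            s
            for s in self.synapses
            if s.post_id == neuron_id and (pre_kind is None or s.pre_kind is pre_kind)
        ]

    def neurons_of_kind(self, kind: NeuronKind) -> list[NeuronRecord]:
        return [r for r in self.neurons.values() if r.kind is kind]
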
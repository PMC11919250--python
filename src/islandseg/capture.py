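"""Per-cell innervation profiles and capture classification.

A relay cell is *captured* when every retinal bouton innervating it belongs
to a single spatial class (island-only or non-island-only).  This module
computes per-cell class counts, applies the capture classification rule,
counts innervated primary dendrites (the k fed to the null model), measures
per-branch class purity, and aggregates the cohort capture fraction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .circuit import Circuit, NeuronKind, PreKind, Skeleton
from .errors import UndefinedMetricError, UnresolvedSynapseError
from .segregation import BoutonClass, BoutonLabeling

__all__ = [
    "CaptureClass",
    "CaptureProfile",
    "rgc_input_profile",
    "classify_capture",
    "count_primary_dendrites",
    "branch_purity",
    "capture_fraction",
    "build_profiles",
]


class CaptureClass(str, enum.Enum):
    ISLAND_ONLY = "island_only"
    NON_ISLAND_ONLY = "non_island_only"
    MIXED = "mixed"
    AMBIGUOUS = "ambiguous"
    NO_INPUT = "no_input"


@dataclass
class CaptureProfile:
    """Retinal-input profile of one relay cell.

    ``primary_dendrite_count`` is the number of soma-emanating dendrites
    whose subtree receives at least one retinal bouton (None when no
    skeleton is available).
    """

    neuron_id: str
    n_island: int
    n_non_island: int
    n_ambiguous: int
    capture_class: CaptureClass
    primary_dendrite_count: int | None = None

    @property
    def total_inputs(self) -> int:
        return self.n_island + self.n_non_island + self.n_ambiguous


def rgc_input_profile(
    neuron_id: str, circuit: Circuit, labeling: BoutonLabeling
) -> tuple[int, int, int]:
    """Counts of (island, non-island, ambiguous) retinal boutons onto a cell."""
    syns = circuit.synapses_onto(neuron_id, pre_kind=PreKind.RGC)
    n = {c: 0 for c in BoutonClass}
    for s in syns:
        n[labeling.label_of(s.synapse_id)] += 1
    return n[BoutonClass.ISLAND], n[BoutonClass.NON_ISLAND], n[BoutonClass.AMBIGUOUS]


def classify_capture(
    n_island: int, n_non_island: int, n_ambiguous: int, min_inputs: int = 1
) -> CaptureClass:
    """Capture classification rule.

    - no input (or fewer than ``min_inputs`` total) -> NO_INPUT
    - both decided classes present -> MIXED (ambiguous boutons do not
      rescue a cell that already mixes classes)
    - any ambiguous bouton otherwise -> AMBIGUOUS (a cell with
      exclusion-zone inputs is set aside rather than forced onto a side)
    - else the single decided class -> ISLAND_ONLY / NON_ISLAND_ONLY
    """
    total = n_island + n_non_island + n_ambiguous
    if total == 0 or total < min_inputs:
        return CaptureClass.NO_INPUT
    if n_island > 0 and n_non_island > 0:
        return CaptureClass.MIXED
    if n_ambiguous > 0:
        return CaptureClass.AMBIGUOUS
    return CaptureClass.ISLAND_ONLY if n_island > 0 else CaptureClass.NON_ISLAND_ONLY


def _resolve_synapse_nodes(
    synapses,
    skeleton: Skeleton,
    nearest_node_radius: float | None,
) -> dict[str, int]:
    """Map each synapse to a skeleton node via post_node or nearest-node search.

    Nearest-node assignment considers non-root nodes only (a bouton belongs
    to a dendrite, not the soma centroid) and requires the match to lie
    within ``nearest_node_radius`` micrometers.  Unresolvable synapses raise
    :class:`UnresolvedSynapseError` listing the offending ids.
    """
    resolved: dict[str, int] = {}
    pending = []
    for s in synapses:
        if s.post_node is not None and s.post_node in skeleton:
            resolved[s.synapse_id] = s.post_node
        else:
            pending.append(s)
    if pending:
        if nearest_node_radius is None:
            raise UnresolvedSynapseError([s.synapse_id for s in pending])
        cand = [n for n in skeleton.nodes if n.node_id != skeleton.root]
        unresolved = []
        if cand:
            tree = cKDTree(np.array([n.position for n in cand]))
            dists, idx = tree.query(np.array([s.position for s in pending]))
            for s, d, i in zip(pending, np.atleast_1d(dists), np.atleast_1d(idx)):
                if d <= nearest_node_radius:
                    resolved[s.synapse_id] = cand[int(i)].node_id
                else:
                    unresolved.append(s.synapse_id)
        else:
            unresolved = [s.synapse_id for s in pending]
        if unresolved:
            raise UnresolvedSynapseError(unresolved)
    return resolved


def count_primary_dendrites(
    skeleton: Skeleton,
    circuit: Circuit,
    neuron_id: str,
    nearest_node_radius: float | None = 2.0,
) -> int:
    """Number of root-children whose subtree receives >= 1 retinal bouton."""
    syns = circuit.synapses_onto(neuron_id, pre_kind=PreKind.RGC)
    if not syns:
        return 0
    node_of = _resolve_synapse_nodes(syns, skeleton, nearest_node_radius)
    branch = skeleton.branch_of()
    stems = {branch[nid] for nid in node_of.values() if nid in branch}
    return len(stems)


def branch_purity(
    subtree_root: int,
    skeleton: Skeleton,
    circuit: Circuit,
    labeling: BoutonLabeling,
    neuron_id: str | None = None,
    nearest_node_radius: float | None = 2.0,
) -> float:
    """Majority class fraction of labeled retinal inputs to one subtree.

    max(n_island, n_non_island) / (n_island + n_non_island); ambiguous
    boutons are excluded from the denominator.  1.0 means a pure branch,
    0.5 an even mix.
    """
    neuron_id = neuron_id or skeleton.neuron_id
    syns = circuit.synapses_onto(neuron_id, pre_kind=PreKind.RGC)
    node_of = _resolve_synapse_nodes(syns, skeleton, nearest_node_radius)
    members = skeleton.subtree_nodes(subtree_root)
    n_island = n_non = 0
    for s in syns:
        if node_of.get(s.synapse_id) in members:
            lab = labeling.label_of(s.synapse_id)
            if lab is BoutonClass.ISLAND:
                n_island += 1
            elif lab is BoutonClass.NON_ISLAND:
                n_non += 1
    if n_island + n_non == 0:
        raise UndefinedMetricError(
            f"branch purity undefined: subtree {subtree_root} of {neuron_id!r} "
            "receives no decided-class retinal input"
        )
    return max(n_island, n_non) / (n_island + n_non)


def capture_fraction(
    profiles, cohort_filter=None
) -> tuple[float, int, int]:
    """Fraction of cohort cells captured by a single bouton class.

    Default cohort excludes NO_INPUT and AMBIGUOUS cells, mirroring the
    treatment of cells with no retinal input or exclusion-zone input.
    Returns (fraction, captured, total).
    """
    if cohort_filter is None:
        cohort_filter = lambda p: p.capture_class not in (
            CaptureClass.NO_INPUT,
            CaptureClass.AMBIGUOUS,
        )
    cohort = [p for p in profiles if cohort_filter(p)]
    if not cohort:
        raise UndefinedMetricError("capture fraction undefined on an empty cohort")
    captured = sum(
        p.capture_class in (CaptureClass.ISLAND_ONLY, CaptureClass.NON_ISLAND_ONLY)
        for p in cohort
    )
    return captured / len(cohort), captured, len(cohort)


def build_profiles(
    circuit: Circuit,
    labeling: BoutonLabeling,
    kinds: tuple[NeuronKind, ...] = (NeuronKind.TC,),
    min_inputs: int = 1,
    count_dendrites: bool = True,
    nearest_node_radius: float | None = 2.0,
) -> list[CaptureProfile]:
    """Capture profiles for every neuron of the given kinds."""
    out = []
    for rec in circuit.neurons.values():
        if rec.kind not in kinds:
            continue
        ni, nn, na = rgc_input_profile(rec.neuron_id, circuit, labeling)
        k = None
        if count_dendrites and rec.neuron_id in circuit.skeletons:
            k = count_primary_dendrites(
                circuit.skeletons[rec.neuron_id], circuit, rec.neuron_id, nearest_node_radius
            )
        out.append(
            CaptureProfile(
                neuron_id=rec.neuron_id,
                n_island=ni,
                n_non_island=nn,
                n_ambiguous=na,
                capture_class=classify_capture(ni, nn, na, min_inputs=min_inputs),
                primary_dendrite_count=k,
            )
        )
    return out
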
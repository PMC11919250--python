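"""Synthetic circuits with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
dense ball of island boutons, a surrounding bouton field, a bouton-free gap
(exclusion zone) of width ``gap_width`` between them, and relay cells whose
primary dendrites connect to boutons of one class or the other with a
tunable segregation parameter ``s``:

- with probability ``s`` all of a cell's dendrites take the same class
  (island with probability ``class_prob``) — full segregation;
- with probability ``1 - s`` each dendrite independently takes the island
  class with probability ``class_prob`` — exactly the capture null.

So ``s = 0`` reproduces the null's generative assumption and ``s = 1`` the
fully captured observation.  The field is placed on one side of the island
(a shell sector beyond the gap along ``field_direction``), mirroring an
island sitting near the edge of the nucleus with the bouton field to one
side; this also gives the two classes a well-defined linear separation so
the projection-gap machinery has ground truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from .circuit import (
    Circuit,
    NeuronKind,
    NeuronRecord,
    PreKind,
    Skeleton,
    SkeletonNode,
    SynapseRecord,
)
from .errors import InvalidParameterError
from .io import write_swc, write_synapse_table

__all__ = ["SyntheticParams", "GroundTruth", "generate_circuit", "generate_arbor", "write_circuit"]

#: Default dendrite-count multiset: innervated-primary-dendrite counts of the
#: nine exclusion-zone relay cells in the reference reconstruction.
DEFAULT_DENDRITE_COUNTS = (2, 2, 3, 4, 4, 4, 5, 5, 7)

#: Default boutons-per-dendrite range (uniform); per-cell totals for a 2-7
#: dendrite cell then span roughly 6-100, matching the broad per-cell spread
#: seen in reconstructions.  A placeholder distribution — real bouton counts
#: per dendrite are not published.
DEFAULT_BOUTONS_PER_DENDRITE = tuple(range(3, 16))


def _make_sampler(spec, default):
    """Normalize a count-distribution spec: callable, constant, or multiset."""
    if spec is None:
        spec = default
    if callable(spec):
        return spec
    if isinstance(spec, (int, np.integer)):
        v = int(spec)
        if v < 1:
            raise InvalidParameterError(f"count must be >= 1, got {v}")
        return lambda rng, size: np.full(size, v, dtype=int)
    seq = np.asarray(spec, dtype=int)
    if seq.ndim != 1 or len(seq) == 0 or np.any(seq < 1):
        raise InvalidParameterError("count multiset must be a non-empty sequence of positive ints")
    return lambda rng, size: rng.choice(seq, size=size, replace=True)


@dataclass
class SyntheticParams:
    """Generator knobs; defaults are the reference study conditions."""

    n_tc: int = 9
    dendrite_count_sampler: object = None  # default: resample DEFAULT_DENDRITE_COUNTS
    island_center: tuple = (0.0, 0.0, 0.0)
    island_radius: float = 15.0  # um
    gap_width: float = 5.0  # um, exclusion-zone width g
    background_extent: float = 60.0  # um, outer radius of the bouton field
    boutons_per_dendrite: object = None  # default: uniform 3..15
    segregation: float = 0.0  # s in [0, 1]
    class_prob: float = 0.5  # p, island probability per assignment
    seed: int = 0
    field_direction: tuple = (1.0, 0.0, 0.0)
    soma_cone_deg: float = 30.0  # somata placed in the gap within this cone
    one_sided_field: bool = True  # field occupies a shell sector beyond the gap

    def __post_init__(self):
        if self.n_tc < 1:
            raise InvalidParameterError(f"n_tc must be >= 1, got {self.n_tc}")
        if self.island_radius <= 0:
            raise InvalidParameterError(f"island_radius must be > 0, got {self.island_radius}")
        if self.gap_width < 0:
            raise InvalidParameterError(f"gap_width must be >= 0, got {self.gap_width}")
        if self.background_extent <= self.island_radius + self.gap_width:
            raise InvalidParameterError(
                "infeasible geometry: background_extent must exceed "
                f"island_radius + gap_width = {self.island_radius + self.gap_width}"
            )
        if not (0.0 <= self.segregation <= 1.0):
            raise InvalidParameterError(f"segregation must be in [0, 1], got {self.segregation}")
        if not (0.0 < self.class_prob < 1.0):
            raise InvalidParameterError(f"class_prob must be in (0, 1), got {self.class_prob}")
        self.island_center = np.asarray(self.island_center, dtype=float).reshape(3)
        u = np.asarray(self.field_direction, dtype=float).reshape(3)
        n = np.linalg.norm(u)
        if n == 0:
            raise InvalidParameterError("field_direction must be non-zero")
        self.field_direction = u / n


@dataclass
class GroundTruth:
    """Generator-side truth for every bouton, dendrite and cell."""

    bouton_class: dict[str, str]  # synapse_id -> island / non_island / ambiguous
    dendrite_class: dict[str, list[str]]  # neuron_id -> class per primary dendrite
    captured: dict[str, bool]  # neuron_id -> all dendrites one class
    params: dict = dfield(default_factory=dict)

    def dendrite_counts(self) -> dict[str, int]:
        return {nid: len(v) for nid, v in self.dendrite_class.items()}

    def to_json(self) -> dict:
        return {
            "bouton_class": self.bouton_class,
            "dendrite_class": self.dendrite_class,
            "captured": self.captured,
            "params": self.params,
        }


def _unit_rows(rng, size) -> np.ndarray:
    v = rng.normal(size=(size, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _cone_directions(rng, size, axis, half_angle_deg) -> np.ndarray:
    """Uniform directions within a cone about ``axis``."""
    cos_min = np.cos(np.deg2rad(half_angle_deg))
    ct = cos_min + (1.0 - cos_min) * rng.random(size)
    st = np.sqrt(1.0 - ct**2)
    phi = 2 * np.pi * rng.random(size)
    # orthonormal basis about axis
    a = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return (
        ct[:, None] * axis[None, :]
        + (st * np.cos(phi))[:, None] * e1[None, :]
        + (st * np.sin(phi))[:, None] * e2[None, :]
    )


def _sample_island(rng, m, params: SyntheticParams) -> np.ndarray:
    r = params.island_radius * rng.random(m) ** (1.0 / 3.0)
    return params.island_center + _unit_rows(rng, m) * r[:, None]


def _sample_field(rng, m, params: SyntheticParams) -> np.ndarray:
    """Uniform points in the one-sided shell sector beyond the gap.

    Radius in (R + g, E], constrained to project at least R + g onto the
    field direction, so every field bouton clears the island by the gap
    width along that axis as well as radially.  With
    ``one_sided_field=False`` the sector constraint is dropped and the
    field fully surrounds the island.
    """
    R, g, E = params.island_radius, params.gap_width, params.background_extent
    inner = R + g
    out = np.empty((0, 3))
    for _ in range(1000):
        need = m - len(out)
        if need <= 0:
            break
        batch = max(4 * need, 16)
        r = (inner**3 + (E**3 - inner**3) * rng.random(batch)) ** (1.0 / 3.0)
        pts = _unit_rows(rng, batch) * r[:, None]
        if params.one_sided_field:
            ok = pts @ params.field_direction >= inner
        else:
            ok = np.ones(batch, dtype=bool)
        out = np.vstack([out, pts[ok][:need]])
    if len(out) < m:
        raise InvalidParameterError(
            "infeasible geometry: field sector beyond the gap is too thin to sample"
        )
    return params.island_center + out


def generate_arbor(
    neuron_id: str, soma_position, dendrite_boutons: list[np.ndarray], first_node_id: int = 1
) -> tuple[Skeleton, list[list[int]]]:
    """Build a soma-rooted skeleton with one primary branch per dendrite.

    Each branch runs root -> stem (midway to the nearest bouton) -> boutons
    chained in order of distance from the soma, so the root has exactly one
    child per dendrite and every bouton lies on its dendrite's subtree.
    Returns the skeleton and, per dendrite, the node ids of its boutons in
    the input order.
    """
    soma = np.asarray(soma_position, dtype=float).reshape(3)
    root_id = first_node_id
    nodes = [SkeletonNode(root_id, None, soma, radius=5.0, tag=1)]
    next_id = root_id + 1
    bouton_nodes: list[list[int]] = []
    for boutons in dendrite_boutons:
        boutons = np.atleast_2d(np.asarray(boutons, dtype=float))
        if len(boutons) < 1:
            raise InvalidParameterError("each dendrite needs at least one target bouton")
        order = np.argsort(np.linalg.norm(boutons - soma, axis=1), kind="stable")
        stem_pos = soma + 0.5 * (boutons[order[0]] - soma)
        nodes.append(SkeletonNode(next_id, root_id, stem_pos, radius=0.8, tag=3))
        prev = next_id
        next_id += 1
        ids = [0] * len(boutons)
        for j in order:
            nodes.append(SkeletonNode(next_id, prev, boutons[j], radius=0.5, tag=3))
            ids[int(j)] = next_id
            prev = next_id
            next_id += 1
        bouton_nodes.append(ids)
    return Skeleton(neuron_id, nodes), bouton_nodes


def generate_circuit(params: SyntheticParams) -> tuple[Circuit, GroundTruth]:
    """Generate a circuit and its ground truth, reproducibly from the seed.

    Independent PCG64 streams (spawned from the master seed) drive dendrite
    counts, dendrite class assignment, bouton counts, bouton placement and
    soma placement, so e.g. changing ``n_tc`` does not perturb the bouton
    placement of cells already generated.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_k, rng_cls, rng_nb, rng_pos, rng_soma = (np.random.default_rng(c) for c in ss.spawn(5))
    k_sampler = _make_sampler(params.dendrite_count_sampler, DEFAULT_DENDRITE_COUNTS)
    nb_sampler = _make_sampler(params.boutons_per_dendrite, DEFAULT_BOUTONS_PER_DENDRITE)

    ks = k_sampler(rng_k, params.n_tc)
    soma_r = params.island_radius + params.gap_width / 2.0
    cone = params.soma_cone_deg if params.one_sided_field else 180.0
    soma_dirs = _cone_directions(rng_soma, params.n_tc, params.field_direction, cone)
    somata = params.island_center + soma_r * soma_dirs

    neurons = [
        NeuronRecord("rgc_island", NeuronKind.RGC_AXON),
        NeuronRecord("rgc_field", NeuronKind.RGC_AXON),
    ]
    skeletons: list[Skeleton] = []
    synapses: list[SynapseRecord] = []
    bouton_class: dict[str, str] = {}
    dendrite_class: dict[str, list[str]] = {}
    captured: dict[str, bool] = {}
    syn_counter = 0

    for i in range(params.n_tc):
        nid = f"tc{i + 1:03d}"
        k = int(ks[i])
        if rng_cls.random() < params.segregation:
            is_island = bool(rng_cls.random() < params.class_prob)
            classes = np.full(k, is_island)
        else:
            classes = rng_cls.random(k) < params.class_prob
        nbs = nb_sampler(rng_nb, k)
        dendrite_boutons = [
            _sample_island(rng_pos, int(nb), params)
            if cls
            else _sample_field(rng_pos, int(nb), params)
            for cls, nb in zip(classes, nbs)
        ]
        skeleton, bouton_nodes = generate_arbor(nid, somata[i], dendrite_boutons)
        neurons.append(NeuronRecord(nid, NeuronKind.TC, soma_position=somata[i]))
        skeletons.append(skeleton)
        for d, (cls, boutons, node_ids) in enumerate(zip(classes, dendrite_boutons, bouton_nodes)):
            pre = "rgc_island" if cls else "rgc_field"
            label = "island" if cls else "non_island"
            for pos, node_id in zip(boutons, node_ids):
                syn_counter += 1
                sid = f"s{syn_counter:06d}"
                synapses.append(
                    SynapseRecord(sid, pre, nid, PreKind.RGC, pos, post_node=node_id)
                )
                bouton_class[sid] = label
        dendrite_class[nid] = ["island" if c else "non_island" for c in classes]
        captured[nid] = bool(classes.all() or (~classes).all())

    circuit = Circuit(neurons, skeletons, synapses)
    truth = GroundTruth(
        bouton_class=bouton_class,
        dendrite_class=dendrite_class,
        captured=captured,
        params={
            "n_tc": params.n_tc,
            "island_radius": params.island_radius,
            "gap_width": params.gap_width,
            "background_extent": params.background_extent,
            "segregation": params.segregation,
            "class_prob": params.class_prob,
            "seed": params.seed,
        },
    )
    return circuit, truth


def write_circuit(circuit: Circuit, truth: GroundTruth | None, out_dir) -> Path:
    """Write a circuit as inspectable plain text: SWC per cell, a synapse
    table, and (when given) the ground truth as JSON."""
    out = Path(out_dir)
    (out / "skeletons").mkdir(parents=True, exist_ok=True)
    for nid, sk in circuit.skeletons.items():
        write_swc(sk, out / "skeletons" / f"{nid}.swc")
    write_synapse_table(circuit.synapses, out / "synapses.tsv")
    if truth is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_json(), fh, indent=1)
    return out
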
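"""Bouton class labeling and exclusion-zone geometry.

Boutons are assigned to one of two spatial classes — the dense *island*
cluster or the surrounding *non-island* field — with a third *ambiguous*
label for boutons sitting inside the bouton-free gap (the exclusion zone)
between them.  The direction of clearest separation, found by visual
rotation in the original workflow, is made reproducible here as a
deterministic search over a unit-sphere grid maximizing the 1-D projection
gap between the two classes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .circuit import Circuit, PreKind
from .errors import (
    DegenerateLabelingWarning,
    InvalidParameterError,
    UndefinedMetricError,
)

__all__ = [
    "BoutonClass",
    "BoutonLabeling",
    "find_separation_axis",
    "label_boutons",
    "exclusion_zone_metrics",
]


class BoutonClass(str, enum.Enum):
    ISLAND = "island"
    NON_ISLAND = "non_island"
    AMBIGUOUS = "ambiguous"


@dataclass
class BoutonLabeling:
    """Per-bouton class labels plus the separation-axis geometry.

    ``separation_axis`` is a unit vector oriented so projections *increase
    toward the island class* (from the non-island centroid toward the island
    centroid); ``projection_gap`` is the clearance between the classes along
    that axis (<= 0 means the classes overlap along every tested direction).
    """

    labels: dict[str, BoutonClass]
    separation_axis: np.ndarray | None
    projection_gap: float
    island_centroid: np.ndarray | None
    non_island_centroid: np.ndarray | None
    method: str
    options: dict = field(default_factory=dict)

    def label_of(self, synapse_id: str) -> BoutonClass:
        return self.labels[synapse_id]

    def counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in BoutonClass}
        for lab in self.labels.values():
            out[lab.value] += 1
        return out


def _sphere_grid(step_deg: float) -> np.ndarray:
    """Deterministic unit-sphere grid: theta, phi multiples of ``step_deg``.

    Halving the step yields a superset of directions, so refining the grid
    can only increase the maximum projection gap found.
    """
    if step_deg <= 0:
        raise InvalidParameterError(f"grid step must be positive, got {step_deg}")
    thetas = np.deg2rad(np.arange(0.0, 180.0 + step_deg / 2, step_deg))
    phis = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    dirs = [np.array([0.0, 0.0, 1.0])]
    for th in thetas:
        if th < 1e-12 or abs(th - np.pi) < 1e-12:
            continue
        st, ct = np.sin(th), np.cos(th)
        for ph in phis:
            dirs.append(np.array([st * np.cos(ph), st * np.sin(ph), ct]))
    if thetas[-1] >= np.pi - 1e-9:
        dirs.append(np.array([0.0, 0.0, -1.0]))
    return np.array(dirs)


def find_separation_axis(
    points_a, points_b, grid_step_deg: float = 2.0
) -> tuple[np.ndarray, float]:
    """Direction maximizing the projection gap between two point clouds.

    Searches a deterministic unit-sphere grid with angular step
    ``grid_step_deg`` and returns ``(axis, gap)`` where the axis is oriented
    so cloud *a* precedes cloud *b* and ``gap = min(proj b) - max(proj a)``.
    ``gap <= 0`` means the clouds overlap along every tested direction.
    Ties are broken by the lexicographically smallest axis vector.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both point sets must be non-empty")
    dirs = _sphere_grid(grid_step_deg)
    proj_a = a @ dirs.T  # (na, m)
    proj_b = b @ dirs.T
    max_a, min_a = proj_a.max(axis=0), proj_a.min(axis=0)
    max_b, min_b = proj_b.max(axis=0), proj_b.min(axis=0)
    gap_fwd = min_b - max_a  # axis = +u, a precedes b
    gap_rev = min_a - max_b  # axis = -u
    best = max(gap_fwd.max(), gap_rev.max())
    tol = 1e-12 + 1e-9 * abs(best)
    candidates = [dirs[i] for i in np.flatnonzero(gap_fwd >= best - tol)]
    candidates += [-dirs[i] for i in np.flatnonzero(gap_rev >= best - tol)]
    axis = min(candidates, key=lambda u: tuple(np.round(u, 12)))
    return axis, float(best)


def _object_array(value, n: int) -> np.ndarray:
    # np.full would coerce a str-enum fill value to plain str
    arr = np.empty(n, dtype=object)
    arr[:] = value
    return arr


def _ball_mask_labels(positions: np.ndarray, center, radius: float, outer_radius: float):
    d = np.linalg.norm(positions - np.asarray(center, dtype=float), axis=1)
    labels = _object_array(BoutonClass.NON_ISLAND, len(positions))
    labels[d <= radius] = BoutonClass.ISLAND
    labels[(d > radius) & (d <= outer_radius)] = BoutonClass.AMBIGUOUS
    return labels


def _polygon_prism_labels(positions: np.ndarray, polygon, zmin: float, zmax: float):
    from matplotlib.path import Path as MplPath

    poly = MplPath(np.asarray(polygon, dtype=float))
    inside_xy = poly.contains_points(positions[:, :2])
    inside_z = (positions[:, 2] >= zmin) & (positions[:, 2] <= zmax)
    labels = _object_array(BoutonClass.NON_ISLAND, len(positions))
    labels[inside_xy & inside_z] = BoutonClass.ISLAND
    return labels


def _two_class_split_labels(positions: np.ndarray, seed: int, n_restarts: int):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(positions)
    # the island is the spatially compact cluster: smaller RMS radius wins,
    # ties resolved by lexicographically smaller centroid
    rms = []
    for c in (0, 1):
        pts = positions[assign == c]
        rms.append(float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum(axis=1).mean())))
    if abs(rms[0] - rms[1]) > 1e-12:
        island_cluster = int(np.argmin(rms))
    else:
        island_cluster = int(
            min((0, 1), key=lambda c: tuple(np.round(km.cluster_centers_[c], 12)))
        )
    labels = _object_array(BoutonClass.NON_ISLAND, len(positions))
    labels[assign == island_cluster] = BoutonClass.ISLAND
    return labels


def label_boutons(circuit: Circuit, method: str = "two_class_split", options: dict | None = None) -> BoutonLabeling:
    """Assign island / non-island / ambiguous labels to every RGC bouton.

    Methods
    -------
    ``region_mask``
        Geometric mask in micrometer space.  Ball: ``center``, ``radius``
        and optional ``outer_radius`` (boutons in the shell between the two
        radii — the exclusion-zone annulus — are labeled ambiguous).
        Polygon prism: ``polygon`` (xy vertices), ``zmin``, ``zmax``.
    ``two_class_split``
        2-cluster partition of bouton positions (fixed ``seed``, default 0,
        ``n_restarts`` = 10, best inertia wins); the spatially compact
        cluster is the island.
    ``manual``
        Per-bouton labels from ``labels`` (synapse_id -> class) or a
        delimited-text ``path`` with columns synapse_id, class.

    After the initial assignment the separation axis and projection gap are
    computed between the decided classes, and any bouton whose projection
    falls strictly inside the open gap interval is labeled ambiguous.
    """
    options = dict(options or {})
    boutons = circuit.rgc_synapses()
    if not boutons:
        raise UndefinedMetricError("circuit contains no RGC synapses to label")
    syn_ids = [s.synapse_id for s in boutons]
    positions = np.array([s.position for s in boutons])

    if method == "region_mask":
        if "polygon" in options:
            arr = _polygon_prism_labels(
                positions, options["polygon"], options["zmin"], options["zmax"]
            )
        else:
            radius = float(options["radius"])
            outer = float(options.get("outer_radius", radius))
            if outer < radius:
                raise InvalidParameterError("outer_radius must be >= radius")
            arr = _ball_mask_labels(positions, options["center"], radius, outer)
    elif method == "two_class_split":
        seed = int(options.get("seed", 0))
        options["seed"] = seed
        arr = _two_class_split_labels(positions, seed, int(options.get("n_restarts", 10)))
    elif method == "manual":
        if "labels" in options:
            mapping = {str(k): v for k, v in options["labels"].items()}
        else:
            import pandas as pd

            df = pd.read_csv(options["path"], sep=None, engine="python")
            mapping = dict(zip(df["synapse_id"].astype(str), df["class"]))
        try:
            arr = np.array([BoutonClass(str(mapping[sid]).strip().lower()) for sid in syn_ids],
                           dtype=object)
        except KeyError as exc:
            raise InvalidParameterError(f"manual labels missing synapse {exc}") from None
    else:
        raise InvalidParameterError(f"unknown labeling method {method!r}")

    # identity masks: numpy == would coerce the str-enum scalar to a plain str
    mask_island = np.array([lab is BoutonClass.ISLAND for lab in arr], dtype=bool)
    mask_non = np.array([lab is BoutonClass.NON_ISLAND for lab in arr], dtype=bool)
    island = positions[mask_island]
    non_island = positions[mask_non]
    axis = None
    gap = float("nan")
    island_centroid = island.mean(axis=0) if len(island) else None
    non_island_centroid = non_island.mean(axis=0) if len(non_island) else None
    if len(island) == 0 or len(non_island) == 0:
        warnings.warn(
            f"labeling method {method!r} produced a degenerate partition "
            f"({len(island)} island / {len(non_island)} non-island boutons)",
            DegenerateLabelingWarning,
            stacklevel=2,
        )
    else:
        # axis oriented non-island -> island so projections grow toward the island
        axis, gap = find_separation_axis(
            non_island, island, grid_step_deg=float(options.get("grid_step_deg", 2.0))
        )
        if gap > 0:
            proj = positions @ axis
            lo = (non_island @ axis).max()
            hi = (island @ axis).min()
            inside = (proj > lo + 1e-12) & (proj < hi - 1e-12)
            arr[inside] = BoutonClass.AMBIGUOUS

    return BoutonLabeling(
        labels=dict(zip(syn_ids, arr)),
        separation_axis=axis,
        projection_gap=gap,
        island_centroid=island_centroid,
        non_island_centroid=non_island_centroid,
        method=method,
        options=options,
    )


def exclusion_zone_metrics(labeling: BoutonLabeling, circuit: Circuit) -> dict:
    """Geometry of the bouton-free zone between the two classes.

    Returns the projection gap along the separation axis, the minimum and
    median nearest cross-class neighbor distance (pooled over both classes),
    and the ambiguous-bouton count.
    """
    pos = {s.synapse_id: s.position for s in circuit.rgc_synapses()}
    island = np.array(
        [pos[sid] for sid, lab in labeling.labels.items() if lab is BoutonClass.ISLAND]
    )
    non_island = np.array(
        [pos[sid] for sid, lab in labeling.labels.items() if lab is BoutonClass.NON_ISLAND]
    )
    n_ambiguous = sum(1 for lab in labeling.labels.values() if lab is BoutonClass.AMBIGUOUS)
    if len(island) == 0 or len(non_island) == 0:
        raise UndefinedMetricError(
            "exclusion-zone metrics undefined: one bouton class is empty"
        )
    d_i, _ = cKDTree(non_island).query(island)
    d_n, _ = cKDTree(island).query(non_island)
    cross = np.concatenate([np.atleast_1d(d_i), np.atleast_1d(d_n)])
    return {
        "projection_gap_um": float(labeling.projection_gap),
        "min_cross_class_distance_um": float(cross.min()),
        "median_cross_class_distance_um": float(np.median(cross)),
        "n_island": int(len(island)),
        "n_non_island": int(len(non_island)),
        "n_ambiguous": int(n_ambiguous),
    }
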
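"""Readers and writers for the plain-text formats the pipeline touches.

Skeletons travel as standard 7-column SWC; synapse tables as delimited text
with a header row and a configurable column map; everything is normalized to
micrometers on ingestion.  Raw EM annotations are often in voxel indices, so
:func:`voxel_to_micron` converts with the anisotropic voxel size of the
serial-section volume, (26, 20, 40) nm by default — x and y are the in-plane
fast/slow axes, z the section (rostro-caudal cutting) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import PreKind, Skeleton, SkeletonNode, SynapseRecord
from .errors import ColumnMappingError, InvalidParameterError, SwcFormatError

__all__ = [
    "DEFAULT_VOXEL_SIZE_NM",
    "voxel_to_micron",
    "read_swc",
    "write_swc",
    "read_synapse_table",
    "write_synapse_table",
    "TableReadResult",
]

#: Anisotropic voxel size (nm) of the serial-section EM volume, ordered
#: (x, y, z) = (in-plane fast, in-plane slow, section number).
DEFAULT_VOXEL_SIZE_NM = (26.0, 20.0, 40.0)


def voxel_to_micron(voxel_coords, voxel_size_nm=DEFAULT_VOXEL_SIZE_NM) -> np.ndarray:
    """Convert voxel indices to micrometers.

    Elementwise product with the voxel size (nm), scaled nm -> um.  Accepts a
    single 3-vector or an (n, 3) array.  The map is linear, so it commutes
    with integer-vector addition.
    """
    size = np.asarray(voxel_size_nm, dtype=float).reshape(3)
    if np.any(size <= 0) or not np.all(np.isfinite(size)):
        raise InvalidParameterError(f"voxel size must be positive and finite, got {voxel_size_nm}")
    coords = np.asarray(voxel_coords, dtype=float)
    if coords.shape[-1] != 3:
        raise InvalidParameterError(f"voxel coordinates must be 3-vectors, got shape {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise InvalidParameterError("voxel coordinates must be finite")
    return coords * size / 1000.0


# ---------------------------------------------------------------------------
# SWC


def read_swc(path, neuron_id: str | None = None, scale: float = 1.0) -> Skeleton:
    """Read a standard 7-column SWC file into a :class:`Skeleton`.

    Columns: node_id, structure tag, x, y, z, radius, parent_id (-1 for the
    root).  Positions are assumed micrometers unless ``scale`` converts them.
    Node order is preserved.  Multiple roots, orphan parents and cycles raise
    :class:`SwcFormatError` naming the offending line.
    """
    path = Path(path)
    if neuron_id is None:
        neuron_id = path.stem
    nodes: list[SkeletonNode] = []
    lines_of: dict[int, int] = {}
    root_line = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcFormatError(f"expected 7 columns, got {len(parts)}", line=lineno)
            try:
                nid = int(parts[0])
                tag = int(parts[1])
                pos = [float(parts[2]), float(parts[3]), float(parts[4])]
                radius = float(parts[5])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcFormatError(f"unparseable record ({exc})", line=lineno) from None
            if nid in lines_of:
                raise SwcFormatError(f"duplicate node id {nid}", line=lineno)
            lines_of[nid] = lineno
            if parent == -1:
                if root_line is not None:
                    raise SwcFormatError(
                        f"second root node {nid} (first root on line {root_line})", line=lineno
                    )
                root_line = lineno
            nodes.append(
                SkeletonNode(
                    node_id=nid,
                    parent_id=None if parent == -1 else parent,
                    position=np.asarray(pos) * scale,
                    radius=radius * scale,
                    tag=tag,
                )
            )
    if root_line is None:
        raise SwcFormatError(f"{path}: no root node (parent -1) found")
    known = set(lines_of)
    for n in nodes:
        if n.parent_id is not None and n.parent_id not in known:
            raise SwcFormatError(
                f"node {n.node_id} references missing parent {n.parent_id}",
                line=lines_of[n.node_id],
            )
    try:
        return Skeleton(neuron_id, nodes)
    except Exception as exc:  # cycles / unreachable nodes found by Skeleton
        raise SwcFormatError(f"{path}: {exc}") from exc


def write_swc(skeleton: Skeleton, path) -> None:
    """Write a :class:`Skeleton` as standard 7-column SWC (positions in um)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# SWC export of neuron {skeleton.neuron_id}\n")
        fh.write("# id tag x y z radius parent\n")
        for n in skeleton.nodes:
            parent = -1 if n.parent_id is None else n.parent_id
            x, y, z = n.position
            fh.write(f"{n.node_id} {n.tag} {x:.6f} {y:.6f} {z:.6f} {n.radius:.6f} {parent}\n")


# ---------------------------------------------------------------------------
# Synapse tables

_REQUIRED = ("pre_id", "post_id", "pre_kind", "x", "y", "z")
_OPTIONAL = ("synapse_id", "post_node")


@dataclass
class TableReadResult:
    """Validated synapse records plus per-row rejects (1-based data row, reason)."""

    records: list[SynapseRecord]
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "n_records": len(self.records),
            "n_rejected": len(self.rejects),
            "rejects": [{"row": r, "reason": why} for r, why in self.rejects],
        }


def _coerce_pre_kind(value) -> PreKind:
    try:
        return PreKind(str(value).strip().upper())
    except ValueError:
        return PreKind.OTHER


def read_synapse_table(
    path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    voxel_size_nm=None,
) -> TableReadResult:
    """Read a delimited synapse table into validated :class:`SynapseRecord` s.

    ``column_map`` maps canonical names (pre_id, post_id, pre_kind, x, y, z,
    and optionally synapse_id, post_node) to the file's column names; by
    default the canonical names themselves are expected.  When
    ``voxel_size_nm`` is given the x/y/z columns are treated as voxel indices
    and converted via :func:`voxel_to_micron`.  Rows failing validation are
    reported with their 1-based data-row number rather than aborting the read.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=sep, engine="python")
    resolved: dict[str, str] = {}
    for canon in _REQUIRED + _OPTIONAL:
        col = column_map.get(canon, canon)
        if col in df.columns:
            resolved[canon] = col
        elif canon in _REQUIRED:
            raise ColumnMappingError(
                f"required column {canon!r} (mapped to {col!r}) not found in {path}; "
                f"available: {list(df.columns)}"
            )
    records: list[SynapseRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            pos = np.array(
                [float(rowd[resolved["x"]]), float(rowd[resolved["y"]]), float(rowd[resolved["z"]])]
            )
        except (TypeError, ValueError):
            rejects.append((i, "non-numeric coordinate"))
            continue
        if not np.all(np.isfinite(pos)):
            rejects.append((i, "non-finite coordinate"))
            continue
        if voxel_size_nm is not None:
            pos = voxel_to_micron(pos, voxel_size_nm)
        pre_id = str(rowd[resolved["pre_id"]])
        post_id = str(rowd[resolved["post_id"]])
        if pre_id == post_id:
            rejects.append((i, "pre_id equals post_id"))
            continue
        syn_id = str(rowd[resolved["synapse_id"]]) if "synapse_id" in resolved else f"syn{i}"
        post_node = None
        if "post_node" in resolved and not pd.isna(rowd[resolved["post_node"]]):
            try:
                post_node = int(rowd[resolved["post_node"]])
            except (TypeError, ValueError):
                rejects.append((i, "non-integer post_node"))
                continue
        records.append(
            SynapseRecord(
                synapse_id=syn_id,
                pre_id=pre_id,
                post_id=post_id,
                pre_kind=_coerce_pre_kind(rowd[resolved["pre_kind"]]),
                position=pos,
                post_node=post_node,
            )
        )
    return TableReadResult(records=records, rejects=rejects)


def write_synapse_table(records: list[SynapseRecord], path, sep: str = "\t") -> None:
    """Write synapse records as delimited text with canonical column names."""
    rows = [
        {
            "synapse_id": r.synapse_id,
            "pre_id": r.pre_id,
            "post_id": r.post_id,
            "pre_kind": r.pre_kind.value,
            "x": r.position[0],
            "y": r.position[1],
            "z": r.position[2],
            "post_node": "" if r.post_node is None else r.post_node,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
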
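"""Morphometry of traced neurons: SWC I/O, branch-tip counts, Sholl analysis.

A reconstruction is a rooted tree of 3-D points (the SWC convention:
``id type x y z radius parent``). Dendritic complexity is summarised two
ways, matching common practice for adult-born granule cells: the number of
terminal dendritic tips, and the Sholl profile — the number of dendritic
segments crossing concentric spheres centred on the soma at fixed radial
steps (10 um by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Morphology", "ShollProfile", "read_swc", "write_swc",
           "count_branch_tips", "sholl"]

SOMA_TYPE = 1
AXON_TYPE = 2

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


class Morphology:
    """A single neuron reconstruction (SWC-style node table).

    Invariants enforced on construction: exactly one root (parent == -1),
    every parent id refers to an already-defined node (so the table is in
    topological order and acyclic), and the tree is connected.
    """

    def __init__(self, nodes: pd.DataFrame):
        missing = [c for c in SWC_COLUMNS if c not in nodes.columns]
        if missing:
            raise ValueError(f"morphology table missing columns: {missing}")
        nodes = nodes.reset_index(drop=True)
        roots = nodes.index[nodes["parent"] == -1]
        if len(roots) != 1:
            raise ValueError(f"morphology must have exactly one root, found {len(roots)}")
        seen: set = set()
        for row in nodes.itertuples(index=False):
            if row.parent != -1 and row.parent not in seen:
                raise ValueError(
                    f"node {row.id} references parent {row.parent} "
                    "before it is defined (orphan or cycle)"
                )
            if row.id in seen:
                raise ValueError(f"duplicate node id {row.id}")
            seen.add(row.id)
        self.nodes = nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> pd.Series:
        return self.nodes[self.nodes["parent"] == -1].iloc[0]

    @property
    def soma_xyz(self) -> np.ndarray:
        r = self.root
        return np.array([r["x"], r["y"], r["z"]], dtype=float)

    def children_count(self) -> pd.Series:
        """Number of children per node id."""
        counts = self.nodes["parent"].value_counts()
        return self.nodes["id"].map(counts).fillna(0).astype(int)


@dataclass
class ShollProfile:
    """Intersections per concentric radius (radii strictly increasing, um)."""

    radii_um: np.ndarray
    intersections: np.ndarray

    def __post_init__(self):
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if np.any(np.diff(self.radii_um) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.intersections < 0):
            raise ValueError("intersections must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"radius_um": self.radii_um, "intersections": self.intersections}
        )


def read_swc(path) -> Morphology:
    """Parse an SWC file (7 whitespace-separated fields, ``#`` comments).

    Malformed lines raise ``ValueError`` naming the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                rows.append(
                    (
                        int(fields[0]),
                        int(fields[1]),
                        float(fields[2]),
                        float(fields[3]),
                        float(fields[4]),
                        float(fields[5]),
                        int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no SWC nodes found")
    df = pd.DataFrame(rows, columns=SWC_COLUMNS)
    try:
        return Morphology(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_swc(morphology: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for row in morphology.nodes.itertuples(index=False):
            fh.write(
                f"{row.id} {row.type} {row.x:.6f} {row.y:.6f} {row.z:.6f} "
                f"{row.radius:.6f} {row.parent}\n"
            )


def count_branch_tips(morphology: Morphology) -> int:
    """Number of terminal points of the dendritic tree.

    A tip is a non-soma node with no children.
    """
    n_children = morphology.children_count()
    is_tip = (n_children == 0) & (morphology.nodes["type"] != SOMA_TYPE)
    return int(is_tip.sum())


def _radial_distances(morphology: Morphology, planar: bool) -> np.ndarray:
    xyz = morphology.nodes[["x", "y", "z"]].to_numpy(dtype=float)
    delta = xyz - morphology.soma_xyz
    if planar:
        delta = delta[:, :2]
    return np.linalg.norm(delta, axis=1)


def sholl(
    morphology: Morphology,
    step: float = 10.0,
    max_radius: float | None = None,
    planar: bool = False,
) -> ShollProfile:
    """Sholl profile: dendritic segment crossings per concentric shell.

    For each shell radius r (multiples of ``step``), a parent->child segment
    contributes one crossing when its endpoint distances from the soma
    straddle r, i.e. min(d_parent, d_child) < r <= max(d_parent, d_child).
    A segment spanning several shells counts once per shell. Soma- and
    axon-typed nodes are excluded; distances are 3-D Euclidean from the
    root node unless ``planar`` collapses z.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    nodes = morphology.nodes
    dist = _radial_distances(morphology, planar)
    id_to_idx = {nid: i for i, nid in enumerate(nodes["id"])}

    # dendritic segments: child node not soma/axon typed, has a parent
    child_mask = (nodes["parent"] != -1) & ~nodes["type"].isin((SOMA_TYPE, AXON_TYPE))
    d_child = dist[child_mask.to_numpy()]
    parent_idx = nodes.loc[child_mask, "parent"].map(id_to_idx).to_numpy()
    d_parent = dist[parent_idx]

    if d_child.size == 0:
        raise ValueError("morphology has no dendritic segments")

    farthest = float(dist.max())
    if max_radius is None:
        max_radius = step * max(1, int(np.ceil(farthest / step)))
    radii = np.arange(step, max_radius + step / 2, step)

    lo = np.minimum(d_parent, d_child)
    hi = np.maximum(d_parent, d_child)
    # crossings per shell: lo < r <= hi
    counts = np.array([(np.count_nonzero((lo < r) & (r <= hi))) for r in radii])
    return ShollProfile(radii, counts)
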
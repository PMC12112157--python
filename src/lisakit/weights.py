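"""Spatial weight matrices from areal contiguity.

A :class:`WeightMatrix` carries the original binary adjacency structure
(``base``) alongside the current working matrix, so that self-inclusion and
row-normalization can always be re-derived — in particular when the matrix
is subset to the areas observed at one time point.

Conventions: contiguity is symmetric before self-inclusion; row
normalization scales every nonzero row to sum to 1; islands (areas with no
neighbors) keep empty rows and are reported, never zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from shapely import STRtree

from .errors import WeightError
from .geodata import AreaGeometry

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class WeightMatrix:
    """Sparse spatial weights aligned to a fixed area order.

    ``base`` is the self-excluded binary adjacency from which ``matrix`` is
    derived by (optional) self-inclusion followed by (optional) row
    normalization.
    """

    base: sparse.csr_array
    matrix: sparse.csr_array
    index: tuple[str, ...]
    row_normalized: bool = False
    includes_self: bool = False

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def degrees(self) -> np.ndarray:
        """Neighbor count per area on the binary structure (self excluded)."""
        return np.diff(self.base.indptr)

    def islands(self) -> np.ndarray:
        """Indices of areas with no neighbors."""
        return np.flatnonzero(self.degrees() == 0)

    def neighbors(self, i: int) -> np.ndarray:
        return self.base.indices[self.base.indptr[i] : self.base.indptr[i + 1]]

    def entries(self) -> dict[tuple[int, int], float]:
        """Current weights as a sparse (i, j) -> w map (no explicit zeros)."""
        coo = self.matrix.tocoo()
        return {
            (int(i), int(j)): float(v)
            for i, j, v in zip(coo.row, coo.col, coo.data)
            if v != 0.0
        }

    def to_pairs(self):
        """Neighbor pairs of the binary structure, for audit export."""
        coo = self.base.tocoo()
        return [
            (self.index[i], self.index[j]) for i, j in zip(coo.row, coo.col) if i < j
        ]

    def to_pairs_csv(self, path) -> None:
        """Write the neighbor pairs as a two-column CSV for audit."""
        with open(path, "w") as fh:
            fh.write("area_id,neighbor_id\n")
            for a, b in sorted(self.to_pairs()):
                fh.write(f"{a},{b}\n")

    @classmethod
    def from_adjacency(
        cls, adjacency: np.ndarray, index: list[str] | None = None
    ) -> "WeightMatrix":
        """Build from a dense 0/1 adjacency matrix (mostly for tests/audit)."""
        adj = np.asarray(adjacency, dtype=float)
        if adj.shape[0] != adj.shape[1]:
            raise WeightError("adjacency must be square")
        if not np.allclose(adj, adj.T):
            raise WeightError("adjacency must be symmetric")
        np.fill_diagonal(adj, 0.0)
        mat = sparse.csr_array(adj)
        mat.eliminate_zeros()
        if index is None:
            index = [str(i) for i in range(adj.shape[0])]
        return cls(base=mat, matrix=mat.copy(), index=tuple(index))


def _adjacent(g1, g2, rule: str) -> bool:
    inter = g1.boundary.intersection(g2.boundary)
    if rule == "rook":
        return inter.length > 0.0
    return not inter.is_empty


def contiguity_weights(geoms: list[AreaGeometry], rule: str = "queen") -> WeightMatrix:
    """Binary contiguity weights: queen (any shared boundary point) or rook
    (shared boundary segment of positive length).

    Emits a warning listing island areas; they are permitted and keep empty
    rows.
    """
    if rule not in ("queen", "rook"):
        raise WeightError(f"contiguity rule must be 'queen' or 'rook', got {rule!r}")
    if len(geoms) < 2:
        raise WeightError("need at least 2 areas to build contiguity weights")
    shapes = [g.geometry for g in geoms]
    tree = STRtree(shapes)
    left, right = tree.query(shapes, predicate="intersects")
    rows: list[int] = []
    cols: list[int] = []
    for i, j in zip(left.tolist(), right.tolist()):
        if i >= j:
            continue
        if _adjacent(shapes[i], shapes[j], rule):
            rows.extend((i, j))
            cols.extend((j, i))
    n = len(geoms)
    mat = sparse.csr_array(
        (np.ones(len(rows)), (np.array(rows, dtype=int), np.array(cols, dtype=int))),
        shape=(n, n),
    )
    mat.sum_duplicates()
    mat.data[:] = 1.0
    wm = WeightMatrix(base=mat, matrix=mat.copy(), index=tuple(g.area_id for g in geoms))
    isl = wm.islands()
    if isl.size:
        logger.warning(
            "island areas (no %s neighbors): %s",
            rule,
            ", ".join(wm.index[i] for i in isl),
        )
    return wm


def add_self(W: WeightMatrix) -> WeightMatrix:
    """Return a copy with unit diagonal entries (the Gi* convention)."""
    if W.includes_self:
        raise WeightError("weight matrix already includes self")
    eye = sparse.eye_array(W.n, format="csr")
    mat = sparse.csr_array(W.base + eye)
    return replace(W, matrix=mat, includes_self=True, row_normalized=False)


def row_normalize(W: WeightMatrix) -> WeightMatrix:
    """Scale every nonzero row of the working matrix to sum to 1.

    Rows of isolated areas stay empty.
    """
    mat = W.matrix.tocsr(copy=True)
    rowsum = mat.sum(axis=1)
    scale = np.divide(1.0, rowsum, out=np.zeros_like(rowsum, dtype=float), where=rowsum > 0)
    mat = sparse.csr_array(sparse.diags_array(scale) @ mat)
    mat.eliminate_zeros()
    return replace(W, matrix=mat, row_normalized=True)


def subset_weights(W: WeightMatrix, keep) -> WeightMatrix:
    """Restrict W to ``keep x keep`` on the original binary structure, then
    re-apply W's self-inclusion and row-normalization flags.

    ``keep`` is a non-empty collection of area indices (original order is
    preserved).
    """
    keep = np.asarray(sorted(set(int(k) for k in keep)), dtype=int)
    if keep.size == 0:
        raise WeightError("keep set must be non-empty")
    if keep.min() < 0 or keep.max() >= W.n:
        raise WeightError("keep indices out of range")
    base = sparse.csr_array(W.base[keep][:, keep])
    base.eliminate_zeros()
    out = WeightMatrix(
        base=base,
        matrix=base.copy(),
        index=tuple(W.index[i] for i in keep),
    )
    if W.includes_self:
        out = add_self(out)
    if W.row_normalized:
        out = row_normalize(out)
    return out
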
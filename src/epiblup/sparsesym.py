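"""Lower-triangle triplet storage for symmetric inverse-covariance matrices.

The animal-breeding file dialects store A⁻¹, Λ⁻¹ and H⁻¹ as ``row col value``
triples of the lower triangle (1-based ids, diagonal included).  This module
holds that representation and converts it to scipy sparse matrices for
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass
class SparseSymTriplets:
    """Symmetric matrix stored as accumulated lower-triangle triplets.

    Entries with ``row >= col`` (1-based).  Duplicate (row, col) pairs are
    summed on :meth:`accumulate`, matching the way Henderson-rule
    contributions are written out animal by animal.
    """

    n: int
    rows: list[int] = field(default_factory=list)
    cols: list[int] = field(default_factory=list)
    vals: list[float] = field(default_factory=list)

    def add(self, row: int, col: int, value: float) -> None:
        if row < col:
            row, col = col, row
        self.rows.append(row)
        self.cols.append(col)
        self.vals.append(float(value))

    def accumulate(self) -> "SparseSymTriplets":
        """Sum duplicate coordinates; returns self with unique entries."""
        coo = self._lower_coo()
        coo.sum_duplicates()
        self.rows = list(coo.row + 1)
        self.cols = list(coo.col + 1)
        self.vals = list(coo.data)
        return self

    def _lower_coo(self) -> sp.coo_matrix:
        return sp.coo_matrix(
            (np.asarray(self.vals, dtype=float),
             (np.asarray(self.rows, dtype=int) - 1,
              np.asarray(self.cols, dtype=int) - 1)),
            shape=(self.n, self.n),
        )

    def to_csr(self) -> sp.csr_matrix:
        """Full symmetric CSR matrix (both triangles)."""
        low = self._lower_coo().tocsr()
        low.sum_duplicates()
        upper = sp.triu(low.T, k=1)
        return (low + upper).tocsr()

    def to_dense(self) -> np.ndarray:
        return self.to_csr().toarray()

    def write(self, path) -> None:
        """Write ``row col value`` lines, 1-based, lower triangle only."""
        coo = self._lower_coo().tocoo()
        coo.sum_duplicates()
        with open(path, "w") as fh:
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r + 1} {c + 1} {v:.12g}\n")

    @classmethod
    def from_csr(cls, mat: sp.spmatrix) -> "SparseSymTriplets":
        low = sp.tril(mat.tocsr()).tocoo()
        out = cls(n=mat.shape[0])
        out.rows = list(low.row + 1)
        out.cols = list(low.col + 1)
        out.vals = list(low.data)
        return out

    @classmethod
    def read(cls, path, n: int | None = None) -> "SparseSymTriplets":
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                rows.append(int(parts[0]))
                cols.append(int(parts[1]))
                vals.append(float(parts[2]))
        out = cls(n=n if n is not None else max(rows, default=0))
        out.rows, out.cols, out.vals = rows, cols, vals
        return out
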
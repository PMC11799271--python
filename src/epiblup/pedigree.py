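"""Pedigree handling: validation, pruning, completeness, inbreeding and A⁻¹.

The pedigree is the substrate for the numerator relationship matrix A and its
sparse inverse built by Henderson's rules with inbreeding, and for the
epigenetic relationship matrix Λ (see :mod:`epiblup.epirel`).  Animals are
renumbered 1..n in topological order (parents before offspring); 0 codes an
unknown parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sparsesym import SparseSymTriplets


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree with renumbered 1..n ids.

    ``sire[i-1]`` / ``dam[i-1]`` give the renumbered parent codes of animal
    ``i`` (0 = unknown).  ``original_id`` maps back to the input labels;
    ``generation``, ``sex`` and ``litter`` are optional metadata carried
    through from simulation or input files.
    """

    sire: np.ndarray
    dam: np.ndarray
    original_id: np.ndarray | None = None
    generation: np.ndarray | None = None
    sex: np.ndarray | None = None
    litter: np.ndarray | None = None
    _f: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.original_id is None:
            self.original_id = np.arange(1, self.n + 1, dtype=np.int64)
        self._validate()

    @property
    def n(self) -> int:
        return len(self.sire)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n + 1, dtype=np.int64)

    def _validate(self) -> None:
        if len(self.dam) != len(self.sire):
            raise PedigreeError("sire and dam arrays differ in length")
        ids = self.ids
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par < 0) or np.any(par > self.n):
                raise PedigreeError(f"{name} codes outside 0..n")
            bad = np.nonzero(par >= ids)[0]
            if bad.size:
                i = bad[0] + 1
                raise PedigreeError(
                    f"animal {i} does not precede its {name} {par[bad[0]]}: "
                    "pedigree is not in topological order"
                )

    def parents(self, i: int) -> tuple[int, int]:
        return int(self.sire[i - 1]), int(self.dam[i - 1])

    # ---- relationship machinery -------------------------------------------

    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients F (cached)."""
        if self._f is None:
            self._f = inbreeding_coefficients(self)
        return self._f

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"id": self.ids, "sire": self.sire, "dam": self.dam,
             "original_id": self.original_id}
        )
        for col in ("generation", "sex", "litter"):
            val = getattr(self, col)
            if val is not None:
                df[col] = val
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _toposort(ids, sires, dams):
    """Order ids parents-first; raise PedigreeError on cycles."""
    idx = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 on stack, 2 done
    order: list[int] = []
    for start in range(n):
        if state[start]:
            continue
        stack = [(start, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            if state[node] == 2:
                continue
            if state[node] == 1:
                raise PedigreeError(
                    f"pedigree cycle involving animal {ids[node]}"
                )
            state[node] = 1
            stack.append((node, True))
            for p in (sires[node], dams[node]):
                if p == 0:
                    continue
                k = idx[p]
                if state[k] == 1:
                    chain = ids[node], p
                    raise PedigreeError(f"pedigree cycle involving {chain}")
                if state[k] == 0:
                    stack.append((k, False))
    return order


def load_pedigree(path, **read_csv_kwargs) -> Pedigree:
    """Read a delimited animal/sire/dam file and renumber topologically.

    Parents referenced but never listed are appended as founders.  Cycles
    (including self-parenting) and duplicate ids raise :class:`PedigreeError`.
    Extra columns named ``generation``, ``sex`` or ``litter`` are carried
    through.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs at least 3 columns")
    return pedigree_from_frame(df)


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    cols = list(df.columns)
    anim = df[cols[0]].to_numpy(dtype=np.int64)
    sire = df[cols[1]].fillna(0).to_numpy(dtype=np.int64)
    dam = df[cols[2]].fillna(0).to_numpy(dtype=np.int64)

    if len(np.unique(anim)) != len(anim):
        dup = pd.Series(anim)
        dup = dup[dup.duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal id {dup}")
    if np.any(anim == sire) or np.any(anim == dam):
        bad = anim[(anim == sire) | (anim == dam)][0]
        raise PedigreeError(f"animal {bad} is its own parent")

    known = set(anim.tolist())
    phantom = sorted({p for p in np.concatenate([sire, dam]).tolist()
                      if p != 0 and p not in known})
    if phantom:
        anim = np.concatenate([anim, np.asarray(phantom, dtype=np.int64)])
        sire = np.concatenate([sire, np.zeros(len(phantom), dtype=np.int64)])
        dam = np.concatenate([dam, np.zeros(len(phantom), dtype=np.int64)])

    order = _toposort(anim.tolist(), sire, dam)
    renum = {int(anim[k]): j + 1 for j, k in enumerate(order)}
    new_sire = np.array([renum[int(sire[k])] if sire[k] else 0 for k in order])
    new_dam = np.array([renum[int(dam[k])] if dam[k] else 0 for k in order])
    orig = anim[order]

    extras = {}
    for col in ("generation", "sex", "litter"):
        if col in df.columns:
            vals = df[col].to_numpy()
            if len(phantom):
                fill = np.zeros(len(phantom), dtype=vals.dtype)
                vals = np.concatenate([vals, fill])
            extras[col] = vals[order]
    return Pedigree(sire=new_sire, dam=new_dam, original_id=orig, **extras)


def prune_to_depth(ped: Pedigree, anchors, max_gen: int = 4) -> Pedigree:
    """Keep anchors plus ancestors within ``max_gen`` generations.

    Mirrors the usual pre-analysis pedigree reduction: animals carrying
    phenotypes/genotypes anchor the traversal and only ``max_gen`` ancestral
    generations are retained; parents of retained animals that fall outside
    the window become unknown (0).
    """
    anchors = set(int(a) for a in anchors)
    if not anchors:
        raise PedigreeError("anchor set is empty")
    if not anchors.issubset(set(ped.ids.tolist())):
        raise PedigreeError("anchors contain ids not in the pedigree")

    depth = {a: 0 for a in anchors}
    frontier = set(anchors)
    for g in range(1, max_gen + 1):
        nxt = set()
        for a in frontier:
            for p in ped.parents(a):
                if p and (p not in depth or depth[p] > g):
                    depth[p] = g
                    nxt.add(p)
        frontier = nxt
    keep = sorted(depth)
    renum = {a: j + 1 for j, a in enumerate(keep)}

    def link(parent: int, animal: int) -> int:
        # a parent link survives only if the parent was retained and the
        # animal itself sits strictly above the depth limit
        if parent in renum and depth[animal] < max_gen:
            return renum[parent]
        return 0

    sire = np.array([link(int(ped.sire[a - 1]), a) for a in keep],
                    dtype=np.int64)
    dam = np.array([link(int(ped.dam[a - 1]), a) for a in keep],
                   dtype=np.int64)
    extras = {}
    for col in ("generation", "sex", "litter"):
        val = getattr(ped, col)
        if val is not None:
            extras[col] = val[[a - 1 for a in keep]]
    return Pedigree(sire=sire, dam=dam,
                    original_id=ped.original_id[[a - 1 for a in keep]],
                    **extras)


def completeness_index(ped: Pedigree, depth: int) -> np.ndarray:
    """MacCluer-style pedigree completeness index per animal.

    For each parental line, the proportion of known ancestors is averaged
    over generations 1..depth; the index is the mean of the sire-line and
    dam-line values.  Founders score 0; an animal with every ancestor known
    to ``depth`` scores 1.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = ped.n
    # known[g][i] = number of known ancestors of i at generation g (starting
    # at g=1 = parents); computed bottom-up since parents precede offspring.
    counts = np.zeros((n + 1, depth), dtype=float)  # 1-based rows, row 0 = unknown
    for i in range(1, n + 1):
        s, d = ped.parents(i)
        for g in range(depth):
            if g == 0:
                counts[i, 0] = (s != 0) + (d != 0)
            else:
                counts[i, g] = counts[s, g - 1] + counts[d, g - 1]
    idx = np.zeros(n)
    denom = np.array([2.0 ** (g + 1) for g in range(depth)])
    for i in range(1, n + 1):
        s, d = ped.parents(i)
        line = np.zeros(2)
        for k, p in enumerate((s, d)):
            if p == 0:
                continue
            # proportion of known ancestors of i through this parent at
            # generation g: the parent itself at g=1 then its ancestors.
            props = np.empty(depth)
            props[0] = 1.0
            for g in range(1, depth):
                props[g] = counts[p, g - 1] / (2.0 ** g)
            line[k] = props.mean()
        idx[i - 1] = line.mean()
    return idx


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo algorithm.

    Equivalent to the diagonal of the tabular relationship matrix minus one,
    without forming the dense matrix.  Uses the F(unknown) = −1 convention so
    the Mendelian variance d_i = 0.5 − 0.25(F_s + F_d) covers all parent
    configurations.
    """
    n = ped.n
    f = np.zeros(n + 1)
    f_base = lambda p: -1.0 if p == 0 else f[p]  # noqa: E731
    d = np.zeros(n + 1)
    sire = np.concatenate([[0], ped.sire]).astype(np.int64)
    dam = np.concatenate([[0], ped.dam]).astype(np.int64)
    point = np.zeros(n + 1, dtype=np.int64)  # descending-id linked list
    coeff = np.zeros(n + 1)                  # path coefficients L

    def insert(start: int, x: int, r: float) -> None:
        """Add r to L[x], splicing x into the list after node ``start``."""
        k = start
        while point[k] > x:
            k = point[k]
        coeff[x] += r
        if point[k] != x:
            point[x] = point[k]
            point[k] = x

    for i in range(1, n + 1):
        s, ds = sire[i], dam[i]
        d[i] = 0.5 - 0.25 * (f_base(s) + f_base(ds))
        if s == 0 or ds == 0:
            f[i] = 0.0
            continue
        fi = -1.0
        coeff[i] = 1.0
        t = i
        while t:
            r = 0.5 * coeff[t]
            ts, td = sire[t], dam[t]
            if ts:
                insert(t, ts, r)
            if td:
                insert(t, td, r)
            fi += coeff[t] ** 2 * d[t]
            coeff[t] = 0.0
            nxt = point[t]
            point[t] = 0
            t = nxt
        f[i] = fi
    return f[1:]


def mendelian_variances(ped: Pedigree) -> np.ndarray:
    """Within-family (Mendelian sampling) variance d_i for each animal."""
    f = np.concatenate([[0.0], ped.inbreeding()])
    s, d = ped.sire, ped.dam
    both = (s > 0) & (d > 0)
    one = (s > 0) ^ (d > 0)
    out = np.ones(ped.n)
    out[both] = 0.5 - 0.25 * (f[s[both]] + f[d[both]])
    p = np.maximum(s, d)
    out[one] = 0.75 - 0.25 * f[p[one]]
    return out


def build_a_inverse(ped: Pedigree) -> SparseSymTriplets:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    For each animal i with Mendelian sampling variance d_i: add 1/d_i to
    (i,i), −0.5/d_i to (i, parent) for each known parent, and 0.25/d_i to
    every known-parent pair (including the squares).
    """
    dvec = mendelian_variances(ped)
    out = SparseSymTriplets(n=ped.n)
    for i in range(1, ped.n + 1):
        s, d = ped.parents(i)
        w = 1.0 / dvec[i - 1]
        out.add(i, i, w)
        for p in (s, d):
            if p:
                out.add(i, p, -0.5 * w)
        known = [p for p in (s, d) if p]
        for a in known:
            for b in known:
                if a >= b:
                    out.add(a, b, 0.25 * w)
    return out.accumulate()


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method."""
    n = ped.n
    a = np.zeros((n + 1, n + 1))  # row/col 0 = unknown parent (all zero)
    for i in range(1, n + 1):
        s, d = ped.parents(i)
        a[i, 1:i] = 0.5 * (a[s, 1:i] + a[d, 1:i])
        a[1:i, i] = a[i, 1:i]
        a[i, i] = 1.0 + 0.5 * a[s, d] if (s and d) else 1.0
    return a[1:, 1:]


def extract_a22(ped: Pedigree, subset) -> np.ndarray:
    """Rows/columns of the tabular A for ``subset``, in subset order."""
    subset = [int(i) for i in subset]
    if any(i < 1 or i > ped.n for i in subset):
        raise PedigreeError("subset contains ids not in the pedigree")
    a = relationship_matrix(ped)
    idx = np.asarray(subset) - 1
    return a[np.ix_(idx, idx)]
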
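"""Sparse (CSR) population engine.

Haplotypes carry few mutations relative to the number of segregating
columns, so the production engine stores each haplotype as a sorted array
of column indices (CSR over 2N rows). Draws come from the same generator in
the same order as the dense reference path in :mod:`idsim.simcore`, so both
engines produce bit-identical trajectories for identical seeds; the dense
path remains the reference implementation used by the unit tests.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["SparseGroup", "sparse_fitness", "gamete_lengths", "gamete_fill"]


@numba.njit(cache=True)
def sparse_fitness(indptr, indices, lhet, lhom, N):
    """Multiplicative log-fitness from CSR haplotypes (two-pointer merge)."""
    w = np.empty(N, dtype=np.float64)
    for i in range(N):
        a, a1 = indptr[2 * i], indptr[2 * i + 1]
        b, b1 = indptr[2 * i + 1], indptr[2 * i + 2]
        acc = 0.0
        while a < a1 or b < b1:
            if b >= b1:
                acc += lhet[indices[a]]
                a += 1
            elif a >= a1:
                acc += lhet[indices[b]]
                b += 1
            elif indices[a] < indices[b]:
                acc += lhet[indices[a]]
                a += 1
            elif indices[b] < indices[a]:
                acc += lhet[indices[b]]
                b += 1
            else:
                acc += lhom[indices[a]]
                a += 1
                b += 1
        w[i] = np.exp(acc)
    return w


@numba.njit(cache=True)
def gamete_lengths(indptr, indices, pos, parents, starts, cross_bp, coffsets):
    """Number of inherited (pre-mutation) entries of each gamete."""
    G = len(parents)
    lens = np.zeros(G, dtype=np.int64)
    L = len(pos)
    for g in range(G):
        par = parents[g]
        rA = 2 * par + starts[g]
        rB = 2 * par + (1 - starts[g])
        lo, hi = coffsets[g], coffsets[g + 1]
        if lo == hi:
            lens[g] = indptr[rA + 1] - indptr[rA]
            continue
        total = 0
        use_A = True
        a_col = 0
        for j in range(lo, hi + 1):
            if j < hi:
                b_col = np.searchsorted(pos, cross_bp[j], side="right")
            else:
                b_col = L
            r = rA if use_A else rB
            s0, s1 = indptr[r], indptr[r + 1]
            total += np.searchsorted(
                indices[s0:s1], b_col
            ) - np.searchsorted(indices[s0:s1], a_col)
            a_col = b_col
            use_A = not use_A
        lens[g] = total
    return lens


@numba.njit(cache=True)
def gamete_fill(
    indptr, indices, pos, parents, starts, cross_bp, coffsets,
    nptr, nind, out_indptr, out_ind,
):
    """Fill gamete CSR: crossover segment copies merged with new mutations.

    Segment entries stream in ascending column order; per-gamete new-mutation
    columns (``nptr``/``nind``, sorted, always fresh slots) are merged in on
    the fly.
    """
    G = len(parents)
    L = len(pos)
    for g in range(G):
        par = parents[g]
        rA = 2 * par + starts[g]
        rB = 2 * par + (1 - starts[g])
        lo, hi = coffsets[g], coffsets[g + 1]
        w = out_indptr[g]
        np_ptr, np_end = nptr[g], nptr[g + 1]
        use_A = True
        a_col = 0
        for j in range(lo, hi + 1):
            if lo == hi:
                b_col = L
            elif j < hi:
                b_col = np.searchsorted(pos, cross_bp[j], side="right")
            else:
                b_col = L
            r = rA if use_A else rB
            s0, s1 = indptr[r], indptr[r + 1]
            e0 = s0 + np.searchsorted(indices[s0:s1], a_col)
            e1 = s0 + np.searchsorted(indices[s0:s1], b_col)
            for e in range(e0, e1):
                v = indices[e]
                while np_ptr < np_end and nind[np_ptr] < v:
                    out_ind[w] = nind[np_ptr]
                    np_ptr += 1
                    w += 1
                out_ind[w] = v
                w += 1
            a_col = b_col
            use_A = not use_A
            if lo == hi:
                break
        while np_ptr < np_end:
            out_ind[w] = nind[np_ptr]
            np_ptr += 1
            w += 1
    return out_ind


class SparseGroup:
    """One mutation group (selected or neutral) in CSR form."""

    def __init__(self, n_rows: int):
        self.indptr = np.zeros(n_rows + 1, dtype=np.int64)
        self.indices = np.empty(0, dtype=np.int64)
        self.pos = np.empty(0, dtype=np.int64)
        self.meta: dict[str, np.ndarray] = {}

    @property
    def n_cols(self) -> int:
        return len(self.pos)

    def counts(self) -> np.ndarray:
        return np.bincount(self.indices, minlength=self.n_cols)

    def reproduce(self, parents, starts, cross_bp, coffsets,
                  new_rows, new_pos, new_meta) -> None:
        """One generation: gametes from parents plus merge-inserted new columns.

        ``new_rows``/``new_pos``/``new_meta`` describe this generation's new
        mutations of this group, in draw order; merge slots follow the same
        tie rule as the dense engine (new columns after old ones at equal
        positions, new-among-new by position then draw order).
        """
        n_gam = len(parents)
        order = np.argsort(new_pos, kind="stable")
        npos = new_pos[order]
        m = len(npos)
        L = self.n_cols
        idx_old = np.arange(L) + np.searchsorted(npos, self.pos, side="left")
        idx_new = np.searchsorted(self.pos, npos, side="right") + np.arange(m)

        merged_pos = np.empty(L + m, dtype=np.int64)
        merged_pos[idx_old] = self.pos
        merged_pos[idx_new] = npos
        merged_meta = {}
        for key, old in self.meta.items():
            out = np.empty(L + m, dtype=old.dtype)
            out[idx_old] = old
            out[idx_new] = new_meta[key][order]
            merged_meta[key] = out

        indices = idx_old[self.indices] if L else self.indices
        posf = merged_pos.astype(np.float64)

        # per-gamete CSR of new-mutation columns
        rows = new_rows[order]
        pair_order = np.lexsort((idx_new, rows))
        nind = idx_new[pair_order]
        nptr = np.zeros(n_gam + 1, dtype=np.int64)
        np.cumsum(np.bincount(rows, minlength=n_gam), out=nptr[1:])

        lens = gamete_lengths(
            self.indptr, indices, posf, parents, starts, cross_bp, coffsets
        )
        out_indptr = np.zeros(n_gam + 1, dtype=np.int64)
        np.cumsum(lens + np.diff(nptr), out=out_indptr[1:])
        out_ind = np.empty(out_indptr[-1], dtype=np.int64)
        gamete_fill(
            self.indptr, indices, posf, parents, starts, cross_bp, coffsets,
            nptr, nind, out_indptr, out_ind,
        )
        self.indptr = out_indptr
        self.indices = out_ind
        self.pos = merged_pos
        self.meta = merged_meta

    def compact(self, n2: int) -> np.ndarray:
        """Drop lost and fixed columns; returns the ids of newly fixed ones."""
        c = self.counts()
        keep = (c > 0) & (c < n2)
        fixed_ids = self.meta["ids"][c == n2]
        if keep.all():
            return fixed_ids
        newidx = np.cumsum(keep) - 1
        entry_keep = keep[self.indices]
        row_of = np.repeat(np.arange(len(self.indptr) - 1), np.diff(self.indptr))
        self.indices = newidx[self.indices[entry_keep]]
        newptr = np.zeros_like(self.indptr)
        np.cumsum(
            np.bincount(row_of[entry_keep], minlength=len(self.indptr) - 1),
            out=newptr[1:],
        )
        self.indptr = newptr
        self.pos = self.pos[keep]
        self.meta = {k: v[keep] for k, v in self.meta.items()}
        return fixed_ids

    def to_dense(self, n_rows: int) -> np.ndarray:
        H = np.zeros((n_rows, self.n_cols), dtype=np.uint8)
        row_of = np.repeat(np.arange(n_rows), np.diff(self.indptr))
        H[row_of, self.indices] = 1
        return H
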
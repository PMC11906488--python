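"""Numba kernels for the per-generation inner loops of the simulator.

The population is stored as dense haplotype matrices (2N rows, one column per
segregating mutation). All randomness is drawn from a single numpy Generator
in the caller and passed in as arrays, so the kernels themselves are
deterministic.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["fitness_kernel", "gather_kernel"]


@numba.njit(cache=True, parallel=False)
def fitness_kernel(H, lhet, lhom):
    """Multiplicative log-fitness over selected loci.

    H : (2N, L) uint8 haplotype matrix (rows 2i, 2i+1 belong to individual i)
    lhet, lhom : (L,) log fitness factors log(1+sh), log(1+s); lhom may be
    -inf for s = -1, which propagates to fitness 0 through exp().
    """
    n2, L = H.shape
    n = n2 // 2
    w = np.empty(n, dtype=np.float64)
    for i in range(n):
        acc = 0.0
        a = 2 * i
        b = a + 1
        for l in range(L):
            c = H[a, l] + H[b, l]
            if c == 1:
                acc += lhet[l]
            elif c == 2:
                acc += lhom[l]
        w[i] = np.exp(acc)
    return w


@numba.njit(cache=True, parallel=False)
def gather_kernel(H, parents, starts, cross_bp, offsets, pos, colmap, out):
    """Form gametes by copying parental haplotypes with crossovers.

    For gamete g from parent p, the source haplotype at column l is the
    starting haplotype XOR the parity of the number of crossover breakpoints
    (physical positions, sorted per gamete in ``cross_bp``) lying at or below
    pos[l]. ``offsets`` is the CSR layout of crossovers per gamete.

    ``pos`` must be ascending, so each crossover becomes one binary-searched
    cut index and whole segments are copied. ``colmap`` maps source column l
    to its output column (merge-insertion slot for this generation's new
    mutations).
    """
    G = len(parents)
    L = len(pos)
    for g in range(G):
        par = parents[g]
        r0 = 2 * par + starts[g]
        r1 = 2 * par + (1 - starts[g])
        lo = offsets[g]
        hi = offsets[g + 1]
        if lo == hi:
            for l in range(L):
                out[g, colmap[l]] = H[r0, l]
        else:
            src = r0
            a = 0
            for j in range(lo, hi + 1):
                if j < hi:
                    b = np.searchsorted(pos, cross_bp[j], side="right")
                else:
                    b = L
                for l in range(a, b):
                    out[g, colmap[l]] = H[src, l]
                a = b
                src = r1 if src == r0 else r0
    return out
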
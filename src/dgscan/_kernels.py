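"""JIT-compiled dynamic-programming kernels for secondary-structure folding.

The kernels fill the DP tables only; tracebacks are done in Python from the
returned matrices (see :mod:`dgscan.folding`).  Segment matrices use
half-open indexing ``F[i, e]`` = best energy of residues ``i .. e-1`` so the
empty segment is ``F[i, i] = 0`` without sentinel rows; pair matrices
``C[i, j]`` / ``V[i, j]`` use inclusive endpoints of the closing pair.

Lone-pair exclusion is exact: a pair is admissible iff it is stacked on an
adjacent pair on at least one side (helices of length >= 2).  This is
encoded with two closing matrices: ``Cin``/``Vin`` require the immediately
inner pair (internal support), while ``Cany``/``Vany`` may rely on support
from an outer stack and are therefore only referenced where that outer
stack exists.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e9


@njit(cache=True)
def pairmax_tables(codes, wmat, minloop, lone_ok):
    """Weighted base-pair maximization (Nussinov-style).

    Returns (F, Cany, Cin): F half-open segment minima, Cany/Cin inclusive
    pair-closing minima (Cin = internally supported closing pair).
    """
    n = codes.shape[0]
    F = np.zeros((n + 1, n + 1))
    Cany = np.full((n, n), INF)
    Cin = np.full((n, n), INF)
    for s in range(1, n + 1):
        # closing-pair matrices at inclusive span s
        for i in range(0, n - s + 1):
            j = i + s - 1
            if j - i - 1 < minloop:
                continue
            w = wmat[codes[i], codes[j]]
            if w > INF / 2:
                continue
            interior = F[i + 1, j]  # segment i+1 .. j-1
            if lone_ok:
                Cany[i, j] = w + interior
                Cin[i, j] = Cany[i, j]
            else:
                best = interior
                if j - 1 - (i + 1) - 1 >= minloop and Cany[i + 1, j - 1] < best:
                    best = Cany[i + 1, j - 1]
                Cany[i, j] = w + best
                if (
                    j - 1 - (i + 1) - 1 >= minloop
                    and wmat[codes[i + 1], codes[j - 1]] < INF / 2
                ):
                    Cin[i, j] = w + Cany[i + 1, j - 1]
        # segment matrix at half-open span s
        for i in range(0, n - s + 1):
            e = i + s
            best = F[i + 1, e]
            for k in range(i + minloop + 1, e):
                c = Cany[i, k] if lone_ok else Cin[i, k]
                if c > INF / 2:
                    continue
                cand = c + F[k + 1, e]
                if cand < best:
                    best = cand
            F[i, e] = best
    return F, Cany, Cin


@njit(cache=True)
def nn_tables(codes, ptype, stack, hp, bl, il, ml_a, ml_b, ml_c, minloop, lone_ok, max_int):
    """Simplified nearest-neighbor (Zuker-style) DP.

    Returns (Vany, Vin, WM): Vany/Vin closing-pair minima (inclusive
    endpoints), WM half-open multiloop-segment minima (>= 1 branch).
    """
    n = codes.shape[0]
    Vany = np.full((n, n), INF)
    Vin = np.full((n, n), INF)
    WM = np.full((n + 1, n + 1), INF)
    for s in range(minloop + 2, n + 1):
        for i in range(0, n - s + 1):
            j = i + s - 1
            pt = ptype[codes[i], codes[j]]
            if pt >= 0:
                best = hp[j - i - 1]
                # helix extension (stack on the immediately inner pair)
                if j - 1 - (i + 1) - 1 >= minloop:
                    ptin = ptype[codes[i + 1], codes[j - 1]]
                    if ptin >= 0 and Vany[i + 1, j - 1] < INF / 2:
                        v = stack[pt, ptin] + Vany[i + 1, j - 1]
                        Vin[i, j] = v
                        if v < best:
                            best = v
                # bulge / internal loops (excluding the stack geometry)
                for p in range(i + 1, j - minloop - 1):
                    n1 = p - i - 1
                    if n1 > max_int:
                        break
                    for q in range(j - 1, p + minloop, -1):
                        n2 = j - q - 1
                        if n1 + n2 > max_int:
                            break
                        if n1 == 0 and n2 == 0:
                            continue
                        ptin = ptype[codes[p], codes[q]]
                        if ptin < 0:
                            continue
                        vb = Vany[p, q] if lone_ok else Vin[p, q]
                        if vb > INF / 2:
                            continue
                        if n1 == 0 or n2 == 0:
                            loop_e = bl[n1 + n2]
                        else:
                            loop_e = il[n1 + n2]
                        cand = loop_e + vb
                        if cand < best:
                            best = cand
                # multiloop closed by (i, j): interior split into two
                # segments each holding >= 1 branch
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k] < INF / 2 and WM[k, j] < INF / 2:
                        cand = ml_a + ml_b + WM[i + 1, k] + WM[k, j]
                        if cand < best:
                            best = cand
                if best < INF / 2:
                    Vany[i, j] = best
        # WM at half-open span s (same pass: Vany/Vin of span s are ready)
        for i in range(0, n - s + 1):
            e = i + s
            best = INF
            if WM[i, e - 1] < INF / 2:
                best = WM[i, e - 1] + ml_c
            vb = Vany[i, e - 1] if lone_ok else Vin[i, e - 1]
            if vb < INF / 2 and vb + ml_b < best:
                best = vb + ml_b
            for k in range(i + 1, e - 1):
                if WM[i, k] > INF / 2:
                    continue
                vb = Vany[k, e - 1] if lone_ok else Vin[k, e - 1]
                if vb < INF / 2 and WM[i, k] + vb + ml_b < best:
                    best = WM[i, k] + vb + ml_b
            WM[i, e] = best
    return Vany, Vin, WM
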
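"""Minimum-free-energy folding: scoring kernel, exhaustive oracle and DP.

The three entry points share one :class:`~dgscan.energy.EnergyModel`:

- :func:`structure_energy` scores an explicit dot-bracket structure; it is
  the single scoring kernel used everywhere.
- :func:`enumerate_all_structures` lists every admissible structure of a
  short sequence with its energy (the verification oracle).
- :func:`mfe_fold` computes the minimum over all admissible structures by
  dynamic programming, with a deterministic traceback.

Tie-breaking in the traceback is fixed and documented: candidates are
examined 5' to 3', pairing a position is preferred over leaving it single,
and the nearest admissible partner wins; within a closed pair the helix
extension is tried first, then the hairpin, then bulge/internal branches
(5' arm ascending, 3' arm descending), then multiloop splits ascending.
Two calls with identical input and model therefore return identical
structures, not merely equal energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import INF, PAIR_CLASSES, ConfigurationError, EnergyModel, encode
from .sequences import UtrSequence

_EPS = 1e-6


class StructureError(ValueError):
    """A dot-bracket string that is not admissible for the sequence/model."""


@dataclass(frozen=True)
class FoldResult:
    """A secondary structure and its Gibbs folding energy.

    ``delta_g`` is in kcal/mol relative to the fully unpaired chain (which
    is always admissible at 0.0), so ``delta_g <= 0`` for every input.
    """

    structure: str
    delta_g: float
    engine: str = "builtin"

    @property
    def pairs(self) -> tuple:
        return tuple(sorted(pairs_from_dotbracket(self.structure)))


# ----------------------------------------------------------------------
# dot-bracket utilities and admissibility
# ----------------------------------------------------------------------

def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    """Parse 0-based (i, j) pairs; raises StructureError if unbalanced."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {idx + 1}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {idx + 1}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1] + 1}")
    return sorted(pairs)


def dotbracket_from_pairs(n: int, pairs) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def check_structure(seq, structure: str, model: EnergyModel) -> list[tuple[int, int]]:
    """Validate a structure against the model's admissibility rules.

    Checks balance, length, allowed pair classes, the minimum hairpin loop
    and (when the model disallows them) lone pairs.  Returns the pair list.
    """
    residues = seq.residues if isinstance(seq, UtrSequence) else seq
    if len(structure) != len(residues):
        raise StructureError(
            f"structure length {len(structure)} != sequence length {len(residues)}"
        )
    pairs = pairs_from_dotbracket(structure)
    paired = dict(pairs)
    paired.update({j: i for i, j in pairs})
    for i, j in pairs:
        pc = residues[i] + residues[j]
        if pc not in model.allowed_pairs:
            raise StructureError(f"disallowed pair {pc} at ({i + 1},{j + 1})")
        if j - i - 1 < model.min_hairpin_loop:
            raise StructureError(
                f"hairpin loop of pair ({i + 1},{j + 1}) shorter than "
                f"{model.min_hairpin_loop}"
            )
    if not model.lone_pair_allowed:
        for i, j in pairs:
            inner = paired.get(i + 1) == j - 1
            outer = i >= 1 and j + 1 < len(residues) and paired.get(i - 1) == j + 1
            if not (inner or outer):
                raise StructureError(f"lone pair at ({i + 1},{j + 1})")
    return pairs


# ----------------------------------------------------------------------
# scoring kernel
# ----------------------------------------------------------------------

def structure_energy(seq, structure: str, model: EnergyModel) -> float:
    """Energy of an explicit structure: the shared kernel for DP and oracle.

    PAIRMAX: sum of pair-class weights.  NN: loop decomposition — stacks,
    hairpin/bulge/internal initiation and affine multiloop terms; external
    (unenclosed) residues are free.  The empty structure scores 0.0.
    """
    residues = seq.residues if isinstance(seq, UtrSequence) else seq
    pairs = check_structure(residues, structure, model)
    if model.mode == "PAIRMAX":
        return sum(model.pair_weight(residues[i], residues[j]) for i, j in pairs)
    return _nn_energy(residues, pairs, model)


def _children_of(pairs: list[tuple[int, int]]) -> dict:
    """Map each pair to its directly enclosed pairs (None = external level)."""
    children: dict = {None: []}
    stack: list[tuple[int, int]] = []
    for pair in pairs:  # pairs sorted by opening index
        while stack and pair[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(pair, [])
        children[parent].append(pair)
        stack.append(pair)
    return children


def _nn_energy(residues: str, pairs: list[tuple[int, int]], model: EnergyModel) -> float:
    children = _children_of(pairs)
    ml_a, ml_b, ml_c = model.multiloop_affine
    total = 0.0
    for pair, kids in children.items():
        if pair is None:
            continue  # external residues are free
        i, j = pair
        outer_pc = residues[i] + residues[j]
        if not kids:
            total += model.hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            p, q = kids[0]
            n1, n2 = p - i - 1, j - q - 1
            if n1 == 0 and n2 == 0:
                total += model.stack_energy(outer_pc, residues[p] + residues[q])
            elif n1 == 0 or n2 == 0:
                total += model.bulge_energy(n1 + n2)
            else:
                total += model.internal_energy(n1 + n2)
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in kids)
            total += ml_a + ml_b * (len(kids) + 1) + ml_c * unpaired
    return total


# ----------------------------------------------------------------------
# exhaustive enumeration oracle
# ----------------------------------------------------------------------

def enumerate_all_structures(seq, model: EnergyModel, max_len: int = 14):
    """Every admissible structure with its energy (ground truth for short inputs).

    Refuses sequences longer than ``max_len`` (combinatorial blow-up guard).
    The empty structure at 0.0 is always included.
    """
    residues = seq.residues if isinstance(seq, UtrSequence) else seq
    n = len(residues)
    if n > max_len:
        raise ValueError(f"enumeration refused: length {n} > max_len {max_len}")
    m = model.min_hairpin_loop

    def pairable(i: int, k: int) -> bool:
        return k - i - 1 >= m and residues[i] + residues[k] in model.allowed_pairs

    memo: dict = {}

    def enum(i: int, j: int):  # pair sets over [i, j] inclusive
        if j - i + 1 <= 0:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(enum(i + 1, j))
        for k in range(i + m + 1, j + 1):
            if not pairable(i, k):
                continue
            for left in enum(i + 1, k - 1):
                for right in enum(k + 1, j):
                    out.append(((i, k),) + left + right)
        memo[key] = out
        return out

    results = []
    for pairset in enum(0, n - 1):
        structure = dotbracket_from_pairs(n, pairset)
        try:
            energy = structure_energy(residues, structure, model)
        except StructureError:
            continue  # e.g. lone pair under a no-lone-pair model
        results.append((structure, energy))
    return results


# ----------------------------------------------------------------------
# dynamic program + traceback
# ----------------------------------------------------------------------

def mfe_fold(seq, model: EnergyModel) -> FoldResult:
    """Minimum-free-energy structure of ``seq`` under ``model``.

    Deterministic: ties are broken by the documented candidate order (see
    module docstring).  The returned energy always satisfies
    ``delta_g <= 0`` because the unpaired chain is admissible at 0.
    """
    residues = seq.residues if isinstance(seq, UtrSequence) else seq
    if len(residues) < 1:
        raise ValueError("cannot fold an empty sequence")
    n = len(residues)
    if n < model.min_hairpin_loop + 2:
        return FoldResult("." * n, 0.0, engine=_engine_tag(model))
    codes = encode(residues)
    if model.mode == "PAIRMAX":
        pairs, energy = _fold_pairmax(codes, model)
    else:
        pairs, energy = _fold_nn(codes, model)
    structure = dotbracket_from_pairs(n, pairs)
    recomputed = structure_energy(residues, structure, model)
    if abs(recomputed - energy) > 1e-4:  # internal consistency guard
        raise AssertionError(
            f"traceback energy {recomputed} != DP energy {energy} for {residues}"
        )
    return FoldResult(structure, float(energy), engine=_engine_tag(model))


def _engine_tag(model: EnergyModel) -> str:
    return "builtin-pairmax" if model.mode == "PAIRMAX" else "builtin-nn"


def _fold_pairmax(codes: np.ndarray, model: EnergyModel):
    n = len(codes)
    m = model.min_hairpin_loop
    lone_ok = model.lone_pair_allowed
    F, Cany, Cin = _kernels.pairmax_tables(codes, model.pair_weight_matrix(), m, lone_ok)
    if F[0, n] >= -_EPS:
        return [], 0.0
    Cb = Cany if lone_ok else Cin
    wmat = model.pair_weight_matrix()
    pairs: list[tuple[int, int]] = []
    todo: list[tuple] = [("F", 0, n)]
    while todo:
        kind, a, b = todo.pop()
        if kind == "F":
            i, e = a, b
            while e - i > 0:
                target = F[i, e]
                hit = False
                for k in range(i + m + 1, e):
                    if Cb[i, k] < INF / 2 and abs(Cb[i, k] + F[k + 1, e] - target) < _EPS:
                        todo.append(("Cin" if not lone_ok else "Cany", i, k))
                        i, e, hit = k + 1, e, True
                        break
                if not hit:
                    i += 1
        elif kind == "Cin":
            i, j = a, b
            pairs.append((i, j))
            todo.append(("Cany", i + 1, j - 1))
        else:  # Cany
            i, j = a, b
            pairs.append((i, j))
            w = wmat[codes[i], codes[j]]
            if lone_ok:
                todo.append(("F", i + 1, j))
            else:
                if (
                    j - 1 - (i + 1) - 1 >= m
                    and Cany[i + 1, j - 1] < INF / 2
                    and abs(w + Cany[i + 1, j - 1] - Cany[i, j]) < _EPS
                ):
                    todo.append(("Cany", i + 1, j - 1))
                else:
                    todo.append(("F", i + 1, j))
    return pairs, float(F[0, n])


def _fold_nn(codes: np.ndarray, model: EnergyModel):
    n = len(codes)
    m = model.min_hairpin_loop
    lone_ok = model.lone_pair_allowed
    ml_a, ml_b, ml_c = model.multiloop_affine
    hp, bl, il = model.loop_arrays(n)
    ptype = model.pair_type_matrix()
    stack = model.stack_matrix()
    Vany, Vin, WM = _kernels.nn_tables(
        codes, ptype, stack, hp, bl, il, ml_a, ml_b, ml_c, m, lone_ok, model.max_internal_loop
    )
    Vb = Vany if lone_ok else Vin

    # external level: suffix minima, traced 5' to 3'
    W = np.zeros(n + 1)
    for i in range(n - 1, -1, -1):
        best = W[i + 1]
        for k in range(i + m + 1, n):
            if Vb[i, k] < INF / 2 and Vb[i, k] + W[k + 1] < best:
                best = Vb[i, k] + W[k + 1]
        W[i] = best
    energy = float(W[0])
    if energy >= -_EPS:
        return [], 0.0

    pairs: list[tuple[int, int]] = []
    todo: list[tuple] = []
    i = 0
    while i < n:
        hit = False
        for k in range(i + m + 1, n):
            if Vb[i, k] < INF / 2 and abs(Vb[i, k] + W[k + 1] - W[i]) < _EPS:
                todo.append(("Vin" if not lone_ok else "Vany", i, k))
                i = k + 1
                hit = True
                break
        if not hit:
            i += 1

    while todo:
        kind, a, b = todo.pop()
        if kind == "Vin":
            i, j = a, b
            pairs.append((i, j))
            todo.append(("Vany", i + 1, j - 1))
            continue
        if kind == "WM":
            _trace_wm(a, b, WM, Vb, ml_b, ml_c, m, todo, lone_ok)
            continue
        # Vany
        i, j = a, b
        pairs.append((i, j))
        target = Vany[i, j]
        if Vin[i, j] < INF / 2 and abs(Vin[i, j] - target) < _EPS:
            todo.append(("Vany", i + 1, j - 1))
            continue
        if abs(hp[j - i - 1] - target) < _EPS:
            continue
        found = False
        for p in range(i + 1, j - m - 1):
            n1 = p - i - 1
            if n1 > model.max_internal_loop:
                break
            for q in range(j - 1, p + m, -1):
                n2 = j - q - 1
                if n1 + n2 > model.max_internal_loop:
                    break
                if n1 == 0 and n2 == 0:
                    continue
                if ptype[codes[p], codes[q]] < 0 or Vb[p, q] > INF / 2:
                    continue
                loop_e = bl[n1 + n2] if (n1 == 0 or n2 == 0) else il[n1 + n2]
                if abs(loop_e + Vb[p, q] - target) < _EPS:
                    todo.append(("Vin" if not lone_ok else "Vany", p, q))
                    found = True
                    break
            if found:
                break
        if found:
            continue
        for k in range(i + 2, j - 1):
            if (
                WM[i + 1, k] < INF / 2
                and WM[k, j] < INF / 2
                and abs(ml_a + ml_b + WM[i + 1, k] + WM[k, j] - target) < _EPS
            ):
                todo.append(("WM", i + 1, k))
                todo.append(("WM", k, j))
                found = True
                break
        if not found:  # pragma: no cover - would indicate a kernel bug
            raise AssertionError(f"traceback failed at pair ({i}, {j})")
    return pairs, energy


def _trace_wm(i, e, WM, Vb, ml_b, ml_c, m, todo, lone_ok):
    kind = "Vany" if lone_ok else "Vin"
    target = WM[i, e]
    if Vb[i, e - 1] < INF / 2 and abs(Vb[i, e - 1] + ml_b - target) < _EPS:
        todo.append((kind, i, e - 1))
        return
    for k in range(i + 1, e - 1):
        if (
            WM[i, k] < INF / 2
            and Vb[k, e - 1] < INF / 2
            and abs(WM[i, k] + Vb[k, e - 1] + ml_b - target) < _EPS
        ):
            todo.append(("WM", i, k))
            todo.append((kind, k, e - 1))
            return
    if WM[i, e - 1] < INF / 2 and abs(WM[i, e - 1] + ml_c - target) < _EPS:
        _trace_wm(i, e - 1, WM, Vb, ml_b, ml_c, m, todo, lone_ok)
        return
    raise AssertionError(f"WM traceback failed on segment [{i}, {e})")  # pragma: no cover
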
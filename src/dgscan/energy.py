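"""Energy models for RNA secondary-structure scoring.

Two modes are supported:

``PAIRMAX``
    A weighted base-pair-maximization model: every pair of class AU/UA,
    CG/GC, GU/UG contributes a fixed (negative) energy.  Fast, and simple
    enough that exhaustive enumeration can certify the dynamic program.

``NN``
    A simplified nearest-neighbor model: stacking energies for adjacent
    pairs, size-dependent hairpin/bulge/internal loop penalties with
    logarithmic extrapolation, and an affine multiloop cost.  Dangling
    ends, coaxial stacking and loop-asymmetry terms are deliberately
    excluded; temperature is fixed at 37 C.

Both the dynamic program and the enumeration oracle consume the same
:class:`EnergyModel` instance, so an equality between them certifies the
minimization, not the parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

PAIR_CLASSES = ("AU", "UA", "CG", "GC", "GU", "UG")
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
INF = 1e9

DEFAULT_PAIR_WEIGHTS = {"AU": -2.0, "UA": -2.0, "CG": -3.0, "GC": -3.0, "GU": -1.0, "UG": -1.0}


class ConfigurationError(ValueError):
    """Inconsistent or incomplete energy-model tables."""


def _mirror(key: str) -> str:
    # "XY>ZW" read from the other strand is "WZ>YX"
    outer, inner = key.split(">")
    return inner[::-1] + ">" + outer[::-1]


@dataclass(frozen=True)
class EnergyModel:
    """Parameters shared by the folding DP, the scoring kernel and the oracle.

    Attributes
    ----------
    mode : {"PAIRMAX", "NN"}
    allowed_pairs : frozenset of pair classes out of AU, UA, CG, GC, GU, UG.
    min_hairpin_loop : minimum unpaired residues enclosed by a pair (>= 3
        by default; the steric minimum for RNA).
    lone_pair_allowed : if False, every pair must be part of a helix of at
        least two consecutive stacked pairs.
    pair_weights : kcal/mol per pair class (PAIRMAX mode).
    stack_table : kcal/mol for each ordered outer>inner stack (NN mode).
    hairpin_penalties / bulge_penalties / internal_penalties : kcal/mol by
        loop size (NN mode); extrapolated logarithmically beyond the table.
    multiloop_affine : (offset, per_branch, per_unpaired) kcal/mol (NN mode).
    max_internal_loop : cap on total unpaired residues in an internal/bulge
        loop considered by the DP (standard practice; never binds at the
        oracle lengths used for verification).
    """

    mode: str = "PAIRMAX"
    allowed_pairs: frozenset = frozenset(PAIR_CLASSES)
    min_hairpin_loop: int = 3
    lone_pair_allowed: bool = True
    pair_weights: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS))
    stack_table: dict = field(default_factory=dict)
    hairpin_penalties: dict = field(default_factory=dict)
    bulge_penalties: dict = field(default_factory=dict)
    internal_penalties: dict = field(default_factory=dict)
    multiloop_affine: tuple = (3.4, 0.4, 0.1)
    loop_extrapolation_coeff: float = 1.0785
    max_internal_loop: int = 30

    def __post_init__(self) -> None:
        if self.mode not in ("PAIRMAX", "NN"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.min_hairpin_loop < 0:
            raise ConfigurationError("min_hairpin_loop must be >= 0")
        unknown = set(self.allowed_pairs) - set(PAIR_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown pair classes {sorted(unknown)}")
        if self.mode == "PAIRMAX":
            missing = set(self.allowed_pairs) - set(self.pair_weights)
            if missing:
                raise ConfigurationError(f"pair_weights missing {sorted(missing)}")
        else:
            self._validate_nn()

    def _validate_nn(self) -> None:
        for key, val in self.stack_table.items():
            outer, _, inner = key.partition(">")
            if outer not in PAIR_CLASSES or inner not in PAIR_CLASSES:
                raise ConfigurationError(f"bad stack key {key!r}")
            mkey = _mirror(key)
            mval = self.stack_table.get(mkey)
            if mval is not None and not math.isclose(mval, val, abs_tol=1e-9):
                raise ConfigurationError(
                    f"stack table asymmetric: {key}={val} but {mkey}={mval}"
                )
        for key in (f"{o}>{i}" for o in self.allowed_pairs for i in self.allowed_pairs):
            if key not in self.stack_table and _mirror(key) not in self.stack_table:
                raise ConfigurationError(f"stack table missing {key}")
        for name, table in (
            ("hairpin", self.hairpin_penalties),
            ("bulge", self.bulge_penalties),
            ("internal", self.internal_penalties),
        ):
            if not table:
                raise ConfigurationError(f"{name} penalties missing")
            if any(v < 0 for v in table.values()):
                raise ConfigurationError(f"{name} penalties must be non-negative")
        if len(self.multiloop_affine) != 3:
            raise ConfigurationError("multiloop_affine must be (offset, per_branch, per_unpaired)")

    # ------------------------------------------------------------------
    # lookup helpers
    # ------------------------------------------------------------------
    def pair_class(self, x: str, y: str) -> str | None:
        pc = x + y
        return pc if pc in self.allowed_pairs else None

    def pair_weight(self, x: str, y: str) -> float:
        pc = self.pair_class(x, y)
        if pc is None:
            raise ConfigurationError(f"{x}-{y} is not an allowed pair")
        return self.pair_weights[pc]

    def stack_energy(self, outer: str, inner: str) -> float:
        key = f"{outer}>{inner}"
        if key in self.stack_table:
            return self.stack_table[key]
        return self.stack_table[_mirror(key)]

    def _loop_penalty(self, table: dict, size: int) -> float:
        if size in table:
            return table[size]
        nmax = max(table)
        if size < nmax:
            raise ConfigurationError(f"no penalty for loop size {size}")
        return table[nmax] + self.loop_extrapolation_coeff * math.log(size / nmax)

    def hairpin_energy(self, size: int) -> float:
        if size < self.min_hairpin_loop:
            return INF
        return self._loop_penalty(self.hairpin_penalties, size)

    def bulge_energy(self, size: int) -> float:
        return self._loop_penalty(self.bulge_penalties, size)

    def internal_energy(self, size: int) -> float:
        return self._loop_penalty(self.internal_penalties, size)

    # ------------------------------------------------------------------
    # dense tables for the numba kernels
    # ------------------------------------------------------------------
    def pair_type_matrix(self) -> np.ndarray:
        """4x4 matrix of pair-class indices (order AU,UA,CG,GC,GU,UG), -1 if disallowed."""
        mat = np.full((4, 4), -1, dtype=np.int64)
        for idx, pc in enumerate(PAIR_CLASSES):
            if pc in self.allowed_pairs:
                mat[BASE_INDEX[pc[0]], BASE_INDEX[pc[1]]] = idx
        return mat

    def pair_weight_matrix(self) -> np.ndarray:
        """4x4 matrix of pair energies, +INF for disallowed pairs (PAIRMAX)."""
        mat = np.full((4, 4), INF, dtype=np.float64)
        for pc in self.allowed_pairs:
            mat[BASE_INDEX[pc[0]], BASE_INDEX[pc[1]]] = self.pair_weights[pc]
        return mat

    def stack_matrix(self) -> np.ndarray:
        """6x6 matrix of stack energies indexed by (outer, inner) pair class."""
        mat = np.full((6, 6), INF, dtype=np.float64)
        for i, outer in enumerate(PAIR_CLASSES):
            for j, inner in enumerate(PAIR_CLASSES):
                if outer in self.allowed_pairs and inner in self.allowed_pairs:
                    mat[i, j] = self.stack_energy(outer, inner)
        return mat

    def loop_arrays(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(hairpin, bulge, internal) penalties for every loop size 0..n."""
        hp = np.full(n + 1, INF)
        bl = np.full(n + 1, INF)
        il = np.full(n + 1, INF)
        for s in range(n + 1):
            if s >= self.min_hairpin_loop:
                hp[s] = self.hairpin_energy(s)
            if s >= 1:
                bl[s] = self.bulge_energy(s)
            if s >= 2:
                il[s] = self.internal_energy(s)
        return hp, bl, il


def encode(residues: str) -> np.ndarray:
    """Map an ACGU string to integer codes for the kernels."""
    try:
        return np.array([BASE_INDEX[b] for b in residues], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ConfigurationError(f"cannot encode residue {exc}") from exc


def default_parameter_path() -> Path:
    return Path(resources.files("dgscan").joinpath("params/turner_like_nn.yaml"))


def pairmax_model(
    pair_weights: dict | None = None,
    min_hairpin_loop: int = 3,
    lone_pair_allowed: bool = True,
    allowed_pairs=None,
) -> EnergyModel:
    """PAIRMAX model; lone pairs allowed by default."""
    weights = dict(pair_weights or DEFAULT_PAIR_WEIGHTS)
    pairs = frozenset(allowed_pairs) if allowed_pairs is not None else frozenset(weights)
    return EnergyModel(
        mode="PAIRMAX",
        allowed_pairs=pairs,
        min_hairpin_loop=min_hairpin_loop,
        lone_pair_allowed=lone_pair_allowed,
        pair_weights=weights,
    )


def nn_model(
    parameter_path: str | Path | None = None,
    min_hairpin_loop: int = 3,
    lone_pair_allowed: bool = False,
    max_internal_loop: int = 30,
) -> EnergyModel:
    """Nearest-neighbor model from a YAML parameter file (packaged default).

    Lone pairs are disallowed by default, the standard convention for
    thermodynamic folding.
    """
    path = Path(parameter_path) if parameter_path else default_parameter_path()
    raw = yaml.safe_load(path.read_text())
    multiloop = raw["multiloop"]
    return EnergyModel(
        mode="NN",
        allowed_pairs=frozenset(PAIR_CLASSES),
        min_hairpin_loop=min_hairpin_loop,
        lone_pair_allowed=lone_pair_allowed,
        stack_table={k: float(v) for k, v in raw["stacks"].items()},
        hairpin_penalties={int(k): float(v) for k, v in raw["hairpin"].items()},
        bulge_penalties={int(k): float(v) for k, v in raw["bulge"].items()},
        internal_penalties={int(k): float(v) for k, v in raw["internal"].items()},
        multiloop_affine=(
            float(multiloop["offset"]),
            float(multiloop["per_branch"]),
            float(multiloop["per_unpaired"]),
        ),
        loop_extrapolation_coeff=float(raw.get("loop_extrapolation_coeff", 1.0785)),
        max_internal_loop=max_internal_loop,
    )
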
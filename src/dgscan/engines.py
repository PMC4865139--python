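"""Folding engines: a common call contract over builtin DP and external tools.

An engine is anything with ``fold(residues: str) -> FoldResult``.  The scan
module folds thousands of near-identical mutants, so engines memoize by
sequence string.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess

from .energy import EnergyModel, nn_model, pairmax_model
from .folding import FoldResult, mfe_fold
from .sequences import UtrSequence


class BuiltinEngine:
    """DP-backed engine over an :class:`EnergyModel`, with per-instance cache."""

    def __init__(self, model: EnergyModel):
        self.model = model
        self._cache: dict[str, FoldResult] = {}

    def fold(self, residues) -> FoldResult:
        if isinstance(residues, UtrSequence):
            residues = residues.residues
        hit = self._cache.get(residues)
        if hit is None:
            hit = mfe_fold(residues, self.model)
            self._cache[residues] = hit
        return hit

    def delta_g(self, residues) -> float:
        return self.fold(residues).delta_g

    @property
    def tag(self) -> str:
        return "builtin-pairmax" if self.model.mode == "PAIRMAX" else "builtin-nn"

    def describe(self) -> str:
        return f"{self.tag} (min_loop={self.model.min_hairpin_loop}, lone_pairs={self.model.lone_pair_allowed})"


class ExternalEngine:
    """Adapter for an external folding program with RNAfold-style output.

    The program must accept the sequence on stdin and print a dot-bracket
    line with the energy in trailing parentheses, e.g.::

        GGGAAACCC
        (((...)))  ( -1.20)
    """

    def __init__(self, command: tuple[str, ...] = ("RNAfold", "--noPS")):
        self.command = tuple(command)
        self._cache: dict[str, FoldResult] = {}

    @classmethod
    def available(cls, executable: str = "RNAfold") -> bool:
        return shutil.which(executable) is not None

    def fold(self, residues) -> FoldResult:
        if isinstance(residues, UtrSequence):
            residues = residues.residues
        hit = self._cache.get(residues)
        if hit is None:
            hit = self._run(residues)
            self._cache[residues] = hit
        return hit

    def delta_g(self, residues) -> float:
        return self.fold(residues).delta_g

    def _run(self, residues: str) -> FoldResult:
        proc = subprocess.run(
            self.command,
            input=residues + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        structure, energy = _parse_fold_output(proc.stdout)
        if len(structure) != len(residues):
            raise RuntimeError(
                f"external engine returned structure of length {len(structure)} "
                f"for a {len(residues)}-nt input"
            )
        return FoldResult(structure, energy, engine="external")

    @property
    def tag(self) -> str:
        return "external"

    def describe(self) -> str:
        return "external: " + " ".join(self.command)


def _parse_fold_output(text: str) -> tuple[str, float]:
    for line in text.splitlines():
        line = line.strip()
        if not line or not set(line[:1]) <= set("(.)"):
            continue
        if "(" in line and line.rstrip().endswith(")"):
            open_idx = line.rfind("(")
            structure = line[:open_idx].strip()
            if set(structure) <= set("().") and structure:
                energy = float(line[open_idx + 1 : line.rfind(")")])
                return structure, energy
    raise RuntimeError(f"could not parse external engine output:\n{text}")


class StubEngine:
    """Fixed-value engine for plumbing tests: dG looked up per sequence."""

    def __init__(self, table: dict[str, float] | None = None, default: float = 0.0):
        self.table = dict(table or {})
        self.default = default
        self.calls = 0

    def fold(self, residues) -> FoldResult:
        if isinstance(residues, UtrSequence):
            residues = residues.residues
        self.calls += 1
        return FoldResult("." * len(residues), self.table.get(residues, self.default), engine="stub")

    def delta_g(self, residues) -> float:
        return self.fold(residues).delta_g

    tag = "stub"

    def describe(self) -> str:
        return "stub"


def make_engine(name: str, model: EnergyModel | None = None, parameter_path=None, command=None):
    """Factory for CLI use: ``pairmax``, ``nn`` or ``external``."""
    if name == "pairmax":
        return BuiltinEngine(model or pairmax_model())
    if name == "nn":
        return BuiltinEngine(model or nn_model(parameter_path))
    if name == "external":
        return ExternalEngine(tuple(command) if command else ("RNAfold", "--noPS"))
    raise ValueError(f"unknown engine {name!r}")


def parameter_checksum(path) -> str:
    """SHA-1 of an energy-parameter file, logged for provenance."""
    return hashlib.sha1(open(path, "rb").read()).hexdigest()[:12]
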
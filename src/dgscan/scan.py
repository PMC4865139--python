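"""Saturation single-nucleotide perturbation scan of a 5'UTR.

Every position of the UTR is substituted with each of the three non-wild-
type bases and the mutant's folding energy is compared with the wild type.
Positions where substitutions perturb the folding energy the most sit in
structured, potentially translation-regulating elements; the per-position
score is smoothed over a window of consecutive positions (default 6) and
local maxima of the smoothed signal are called as cis-acting elements,
ranked e1, e2, ... by peak signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel
from .engines import BuiltinEngine
from .sequences import RNA_BASES, UtrSequence, mutate

logger = logging.getLogger(__name__)

SCALINGS = ("none", "minmax", "zscore")


@dataclass(frozen=True)
class PerturbationProfile:
    """Per-position perturbation scores and the windowed element-calling signal.

    ``raw[i-1]`` is the mean absolute change in folding energy (kcal/mol)
    over the three substitutions at position ``i``; ``signal[j-1]`` is the
    arithmetic mean of ``raw`` over positions ``j .. j+window-1`` (valid
    windows only); ``signal_scaled`` is the display signal in [0, 100]
    (all zeros when the signal is constant).
    """

    seq_id: str
    wild_type_dg: float
    raw: np.ndarray
    window: int
    signal: np.ndarray
    signal_scaled: np.ndarray
    engine: str = "builtin"
    residues: str = ""

    def __post_init__(self) -> None:
        if len(self.signal) != len(self.raw) - self.window + 1:
            raise ValueError("signal length inconsistent with raw length and window")

    @property
    def length(self) -> int:
        return len(self.raw)


@dataclass(frozen=True)
class CisElement:
    """A contiguous 1-based inclusive UTR interval called from the signal."""

    seq_id: str
    start: int
    end: int
    peak_signal: float
    rank_label: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    def overlaps(self, other: "CisElement") -> bool:
        return self.start <= other.end and other.start <= self.end


def smooth_profile(raw, window: int) -> np.ndarray:
    """Sliding arithmetic mean over ``window`` consecutive scores (valid mode).

    Output index j (0-based) covers raw positions j .. j+window-1.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("empty raw profile")
    if not 1 <= window <= arr.size:
        raise ValueError(f"window {window} outside 1..{arr.size}")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(arr, kernel, mode="valid")


def scale_signal(signal: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Display scaling of the signal: none, min-max to [0, 100], or z-score.

    A constant signal min-max scales to all zeros by convention.
    """
    if mode not in SCALINGS:
        raise ValueError(f"unknown scaling {mode!r}")
    signal = np.asarray(signal, dtype=float)
    if mode == "none":
        return signal.copy()
    if mode == "minmax":
        span = signal.max() - signal.min()
        if span <= 0:
            return np.zeros_like(signal)
        return (signal - signal.min()) / span * 100.0
    sd = signal.std()
    if sd <= 0:
        return np.zeros_like(signal)
    return (signal - signal.mean()) / sd


def perturbation_profile(
    seq: UtrSequence,
    engine,
    window: int = 6,
    scaling: str = "minmax",
    signed: bool = False,
) -> PerturbationProfile:
    """Scan ``seq`` by saturation substitution under a folding engine.

    ``engine`` is an object with ``delta_g(residues) -> float`` (see
    :mod:`dgscan.engines`) or an :class:`EnergyModel`, which is wrapped in a
    caching :class:`BuiltinEngine`.  At most ``3 * L`` mutant folds are
    computed; identical mutant strings are served from the engine cache.

    With ``signed=True`` the per-position score is the mean signed change
    (exploratory mode); the default is the mean absolute change, since both
    stabilizing and destabilizing substitutions flag structural involvement.
    """
    if isinstance(engine, EnergyModel):
        engine = BuiltinEngine(engine)
    L = len(seq)
    if not 1 <= window <= L:
        raise ValueError(f"window {window} outside 1..{L}")
    wt_dg = engine.delta_g(seq.residues)
    raw = np.zeros(L)
    for pos in range(1, L + 1):
        wt_base = seq.base_at(pos)
        deltas = [
            engine.delta_g(mutate(seq, pos, base).residues) - wt_dg
            for base in RNA_BASES
            if base != wt_base
        ]
        raw[pos - 1] = np.mean(deltas) if signed else np.mean(np.abs(deltas))
    signal = smooth_profile(raw, window)
    return PerturbationProfile(
        seq_id=seq.id,
        wild_type_dg=float(wt_dg),
        raw=raw,
        window=window,
        signal=signal,
        signal_scaled=scale_signal(signal, scaling),
        engine=getattr(engine, "tag", "custom"),
        residues=seq.residues,
    )


def call_elements(
    profile: PerturbationProfile,
    threshold_percentile: float = 90.0,
    max_elements: int = 3,
    merge_gap: int | None = None,
) -> list[CisElement]:
    """Call cis-elements at maxima of the windowed signal.

    Windows with signal at or above the given percentile form runs; runs
    separated by at most ``merge_gap`` windows (default: the window length)
    are merged; each run's raw-coordinate footprint becomes an element.
    The top ``max_elements`` by peak signal are returned, labelled e1, e2,
    ... in descending peak order.  A constant signal yields no elements.
    """
    signal = profile.signal
    w = profile.window
    if merge_gap is None:
        merge_gap = w
    if signal.max() - signal.min() <= 0:
        logger.info("constant signal for %s: no elements called", profile.seq_id)
        return []
    threshold = np.percentile(signal, threshold_percentile)
    above = np.flatnonzero(signal >= threshold)
    if above.size == 0:
        return []
    runs: list[list[int]] = [[above[0], above[0]]]
    for idx in above[1:]:
        if idx - runs[-1][1] - 1 <= merge_gap:
            runs[-1][1] = idx
        else:
            runs.append([idx, idx])
    # footprint in raw coordinates (1-based inclusive); window j covers
    # raw positions j+1 .. j+w in 1-based terms
    intervals = [
        (int(j0) + 1, int(j1) + w, float(signal[j0 : j1 + 1].max())) for j0, j1 in runs
    ]
    intervals = _merge_overlapping(intervals)
    intervals.sort(key=lambda t: (-t[2], t[0]))
    elements = [
        CisElement(profile.seq_id, start, end, peak, f"e{rank}")
        for rank, (start, end, peak) in enumerate(intervals[:max_elements], start=1)
    ]
    return elements


def _merge_overlapping(intervals):
    merged: list[list] = []
    for start, end, peak in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] = max(merged[-1][2], peak)
        else:
            merged.append([start, end, peak])
    return [tuple(t) for t in merged]
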
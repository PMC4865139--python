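"""Synthetic planted-hairpin UTR generator.

Emulates the contrast between weakly and strongly folded 5'UTRs: an i.i.d.
background of tunable GC content with one or more perfect hairpins planted
at known coordinates (exact reverse-complement arms around a loop).  The
recorded ground truth drives the element-localization properties of the
scan: the planted stem is where substitutions perturb the folding energy.

What it does not emulate: real 5'UTR base composition structure (codon-free
but not i.i.d.), imperfect helices with bulges, pseudoknots, or any
sequence-level regulatory motif (uAUGs, IRES-like motifs).  Passing tests
therefore certify the scanning and calling machinery, not motif biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import UtrSequence, reverse_complement


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth of one generated fixture (all coordinates 1-based inclusive)."""

    seed: int
    length: int
    gc_bias: float
    stems: tuple  # of PlantedStem
    background_composition: tuple  # probabilities for A, C, G, U


@dataclass(frozen=True)
class PlantedStem:
    arm5: tuple  # (start, end) of the 5' arm
    loop: tuple  # (start, end) of the loop, or None when loop_len == 0
    arm3: tuple  # (start, end) of the 3' arm

    @property
    def footprint(self) -> tuple:
        """Whole-hairpin interval (5' arm start .. 3' arm end)."""
        return (self.arm5[0], self.arm3[1])


def generate_fixture_utr(
    length: int = 80,
    stem_len: int = 10,
    loop_len: int = 6,
    n_stems: int = 1,
    gc_bias: float = 0.5,
    seed: int = 0,
) -> tuple[UtrSequence, FixtureTruth]:
    """Generate a background UTR with ``n_stems`` planted perfect hairpins.

    The background is drawn i.i.d. with P(G) = P(C) = gc_bias/2 and
    P(A) = P(U) = (1 - gc_bias)/2.  Each hairpin occupies
    ``2 * stem_len + loop_len`` residues, centered in its equal share of
    the sequence; its 3' arm is the exact reverse complement of its 5' arm.
    Deterministic per seed (bit-identical regeneration).
    """
    if not 0.0 <= gc_bias <= 1.0:
        raise ValueError("gc_bias must be in [0, 1]")
    hairpin_span = 2 * stem_len + loop_len
    if n_stems < 0 or (n_stems > 0 and hairpin_span * n_stems > length):
        raise ValueError(
            f"{n_stems} hairpin(s) of span {hairpin_span} do not fit in length {length}"
        )
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    bases = np.array(list("ACGU"))
    residues = list(rng.choice(bases, size=length, p=probs))

    stems = []
    for s in range(n_stems):
        seg_lo = s * length // n_stems
        seg_hi = (s + 1) * length // n_stems
        start = seg_lo + (seg_hi - seg_lo - hairpin_span) // 2  # 0-based
        arm5 = "".join(rng.choice(bases, size=stem_len, p=probs))
        arm3 = reverse_complement(arm5)
        loop = "".join(rng.choice(bases, size=loop_len, p=probs))
        hp = arm5 + loop + arm3
        residues[start : start + hairpin_span] = list(hp)
        stems.append(
            PlantedStem(
                arm5=(start + 1, start + stem_len),
                loop=(start + stem_len + 1, start + stem_len + loop_len) if loop_len else None,
                arm3=(start + stem_len + loop_len + 1, start + hairpin_span),
            )
        )
    seq = UtrSequence(id=f"fixture_s{seed}", residues="".join(residues), source_alphabet="RNA")
    truth = FixtureTruth(
        seed=seed,
        length=length,
        gc_bias=gc_bias,
        stems=tuple(stems),
        background_composition=tuple(probs.tolist()),
    )
    return seq, truth


def shuffle_arms(seq: UtrSequence, truth: FixtureTruth, seed: int = 0) -> UtrSequence:
    """Return a copy with every planted arm's residues shuffled in place.

    Breaks the planted complementarity while keeping composition; used as
    the paired control when demonstrating that planting lowers the folding
    energy.
    """
    rng = np.random.default_rng(seed)
    residues = list(seq.residues)
    for stem in truth.stems:
        for lo, hi in (stem.arm5, stem.arm3):
            chunk = residues[lo - 1 : hi]
            rng.shuffle(chunk)
            residues[lo - 1 : hi] = chunk
    return UtrSequence(id=seq.id + "_armshuf", residues="".join(residues))
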
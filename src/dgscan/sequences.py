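"""Nucleotide sequence container and elementary sequence operations.

All user-facing coordinates are 1-based inclusive. Sequences are stored
internally as RNA (``T`` is normalized to ``U`` on input) with the original
alphabet remembered so the input letters can be reproduced losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

_COMPLEMENT_RNA = str.maketrans("ACGU", "UGCA")
_COMPLEMENT_DNA = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A residue outside the declared nucleotide alphabet."""


@dataclass(frozen=True)
class UtrSequence:
    """A named 5'UTR (or any nucleotide) sequence.

    Parameters
    ----------
    id : str
        Short label, typically the FASTA header up to the first whitespace.
    residues : str
        Residues over ``{A, C, G, U}``; ``T`` and lower case are normalized
        by :meth:`from_string`.
    source_alphabet : {"DNA", "RNA"}
        Alphabet of the original input, so :meth:`to_source` round-trips.
    """

    id: str
    residues: str
    source_alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(RNA_BASES)
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains non-RNA residues {sorted(bad)}"
            )
        if self.source_alphabet not in ("DNA", "RNA"):
            raise ValueError(f"unknown alphabet {self.source_alphabet!r}")

    @classmethod
    def from_string(cls, id: str, raw: str, alphabet: str | None = None) -> "UtrSequence":
        """Build from raw letters, case-folding and normalizing T->U.

        When ``alphabet`` is None it is inferred: a sequence containing ``T``
        is flagged DNA, one containing ``U`` is RNA, and an ambiguous
        (T- and U-free) sequence defaults to DNA, the common FASTA case.
        """
        up = raw.upper()
        if alphabet is None:
            if "T" in up and "U" in up:
                raise AlphabetError(f"sequence {id!r} mixes T and U")
            alphabet = "RNA" if "U" in up else "DNA"
        bad = set(up) - set(RNA_BASES + "T")
        if bad:
            raise AlphabetError(
                f"sequence {id!r} contains invalid residues {sorted(bad)}"
            )
        return cls(id=id, residues=up.replace("T", "U"), source_alphabet=alphabet)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def to_source(self) -> str:
        """Return the residues in the original alphabet (upper case)."""
        if self.source_alphabet == "DNA":
            return self.residues.replace("U", "T")
        return self.residues

    def base_at(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        self._check_pos(pos)
        return self.residues[pos - 1]

    def subsequence(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval [start, end]."""
        self._check_pos(start)
        self._check_pos(end)
        if start > end:
            raise IndexError(f"start {start} > end {end}")
        return self.residues[start - 1 : end]

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= len(self.residues):
            raise IndexError(
                f"position {pos} outside 1..{len(self.residues)} of {self.id!r}"
            )


def mutate(seq: UtrSequence, pos: int, base: str) -> UtrSequence:
    """Return a copy of ``seq`` with the residue at 1-based ``pos`` set to ``base``.

    The input is never modified; substituting the wild-type base returns an
    equal (but distinct) object.
    """
    base = base.upper().replace("T", "U")
    if base not in RNA_BASES:
        raise AlphabetError(f"invalid substitution base {base!r}")
    seq._check_pos(pos)
    residues = seq.residues[: pos - 1] + base + seq.residues[pos:]
    return replace(seq, residues=residues)


def complement(residues: str, alphabet: str = "RNA") -> str:
    """Element-wise Watson-Crick complement (no reversal)."""
    _validate(residues, alphabet)
    table = _COMPLEMENT_RNA if alphabet == "RNA" else _COMPLEMENT_DNA
    return residues.translate(table)


def reverse_complement(residues: str, alphabet: str = "RNA") -> str:
    """Reverse complement; an involution on valid sequences."""
    return complement(residues, alphabet)[::-1]


def to_alphabet(residues: str, alphabet: str) -> str:
    """Convert letters between DNA (T) and RNA (U) spelling."""
    if alphabet == "DNA":
        return residues.upper().replace("U", "T")
    if alphabet == "RNA":
        return residues.upper().replace("T", "U")
    raise ValueError(f"unknown alphabet {alphabet!r}")


def _validate(residues: str, alphabet: str) -> None:
    allowed = set(RNA_BASES if alphabet == "RNA" else DNA_BASES)
    bad = set(residues.upper()) - allowed
    if bad:
        raise AlphabetError(f"invalid {alphabet} residues {sorted(bad)}")
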
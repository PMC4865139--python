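"""Design of translation-modulating oligonucleotides (dGoligos).

Against a called cis-element the designer emits, per request:

- SENSE: the element subsequence itself (binds distant sequences that
  normally fold with the element, releasing it);
- ANTISENSE: the reverse complement (binds the element directly);
- MIR_LIKE_SENSE / MIR_LIKE_ANTISENSE: the same with a short central
  insertion (default 3 nt, range 2-3) that bulges out of the duplex,
  mimicking a metazoan microRNA:target loop;
- SCRAMBLED: a seeded composition-preserving shuffle with bounded
  complementarity to the target UTR, used as a specificity control.

Chemistry is annotated as plain DNA (T alphabet) or nuclease-resistant
2'-O-methyl RNA (U alphabet).  Tm (Wallace rule) and GC% are rough
annotations only.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .scan import CisElement
from .sequences import UtrSequence, reverse_complement, to_alphabet

CATEGORIES = ("SENSE", "ANTISENSE", "MIR_LIKE_SENSE", "MIR_LIKE_ANTISENSE", "SCRAMBLED")
CHEMISTRIES = ("DNA", "RNA_2OME")

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class Oligo:
    """A designed oligonucleotide with its target bookkeeping."""

    name: str
    category: str
    chemistry: str
    residues: str
    target_seq_id: str = ""
    target_interval: tuple | None = None  # 1-based inclusive on the UTR
    insertion: tuple | None = None  # (position after parent residue, inserted residues)
    seed: int | None = None  # RNG seed for SCRAMBLED

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")

    @property
    def rna(self) -> str:
        return to_alphabet(self.residues, "RNA")

    @property
    def gc_percent(self) -> float:
        s = self.rna
        return 100.0 * sum(b in "GC" for b in s) / len(s)

    @property
    def tm_wallace(self) -> float:
        """Wallace-rule melting temperature (rough annotation, deg C)."""
        s = self.rna
        gc = sum(b in "GC" for b in s)
        return 2.0 * (len(s) - gc) + 4.0 * gc


@dataclass(frozen=True)
class BindingReport:
    """In-silico gapless hybridization summary of an oligo against a target.

    ``longest_complementary_run`` is the longest contiguous Watson-Crick
    complementary stretch over all gapless antisense appositions;
    ``total_matched`` and ``wobble_positions`` describe the single best
    apposition (most Watson-Crick matches, ties to the 5'-most offset).
    """

    longest_complementary_run: int
    wobble_positions: int
    total_matched: int
    best_offset: int = 0


def _chem_convert(residues: str, chemistry: str) -> str:
    return to_alphabet(residues, "DNA" if chemistry == "DNA" else "RNA")


def design_oligos(
    utr: UtrSequence,
    element: CisElement,
    categories=("SENSE", "ANTISENSE"),
    chemistry: str = "DNA",
    insertion_len: int = 3,
    scramble_seed: int | None = None,
    max_run: int = 7,
) -> list[Oligo]:
    """Design oligos of the requested categories against one element.

    The microRNA-like insertion is placed after residue ``floor(n/2)`` of
    the parent and its residues are chosen to be non-complementary to the
    apposed target residues, guaranteeing a loop rather than accidental
    pairing.  SCRAMBLED is derived from the first non-scrambled oligo
    designed (or the element's antisense if only SCRAMBLED is requested)
    and requires ``scramble_seed``.
    """
    if not categories:
        raise ValueError("categories must be non-empty")
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    if insertion_len not in (2, 3):
        raise ValueError(f"insertion_len must be 2 or 3, got {insertion_len}")
    if not (1 <= element.start <= element.end <= len(utr)):
        raise IndexError(
            f"element [{element.start}, {element.end}] outside 1..{len(utr)}"
        )
    target_sub = utr.subsequence(element.start, element.end)
    interval = (element.start, element.end)
    label = element.rank_label
    out: list[Oligo] = []

    def add(name_suffix, category, residues, insertion=None, seed=None):
        out.append(
            Oligo(
                name=f"dG_{label}_{name_suffix}",
                category=category,
                chemistry=chemistry,
                residues=_chem_convert(residues, chemistry),
                target_seq_id=utr.id,
                target_interval=interval,
                insertion=insertion,
                seed=seed,
            )
        )

    for category in [c for c in CATEGORIES if c in categories and c != "SCRAMBLED"]:
        if category == "SENSE":
            add("s", category, target_sub)
        elif category == "ANTISENSE":
            add("as", category, reverse_complement(target_sub))
        else:
            parent = (
                target_sub
                if category == "MIR_LIKE_SENSE"
                else reverse_complement(target_sub)
            )
            residues, insertion = _insert_loop(parent, insertion_len)
            add("mir_s" if category == "MIR_LIKE_SENSE" else "mir_as",
                category, residues, insertion=insertion)

    if "SCRAMBLED" in categories:
        if scramble_seed is None:
            raise ValueError("SCRAMBLED requires scramble_seed")
        parent = out[0] if out else Oligo(
            name=f"dG_{label}_as",
            category="ANTISENSE",
            chemistry=chemistry,
            residues=_chem_convert(reverse_complement(target_sub), chemistry),
            target_seq_id=utr.id,
            target_interval=interval,
        )
        out.append(make_scrambled(parent, scramble_seed, target=utr, max_run=max_run))
    return out


def _insert_loop(parent: str, insertion_len: int) -> tuple[str, tuple]:
    """Insert a non-pairing run after residue floor(n/2) of ``parent``.

    The inserted base must not Watson-Crick-pair with the two binding-
    partner residues flanking the insertion point (so the duplex keeps a
    true loop: at most two bases are excluded, a valid choice always
    exists); among the remaining bases the one least able to pair
    (Watson-Crick scored 2, wobble 1) with the surrounding partner window
    wins, ties breaking alphabetically.
    """
    n = len(parent)
    h = n // 2
    partner = reverse_complement(parent)  # what the parent would bind, 5'->3'
    # partner residues apposing the junction: parent[h] pairs partner[n-h]
    # (1-based), so the loop sits against partner indices n-h-1 and n-h
    junction = partner[max(0, n - h - 1) : n - h + 1]
    lo, hi = max(0, n - h - insertion_len), min(n, n - h + insertion_len)
    window = partner[lo:hi]

    def pair_score(base: str, residues: str) -> int:
        return sum(
            2 if (base, t) in _WC else (1 if (base, t) in _WOBBLE else 0)
            for t in residues
        )

    candidates = [b for b in "ACGU" if all((b, t) not in _WC for t in junction)]
    base = min(sorted(candidates), key=lambda b: pair_score(b, window))
    inserted = base * insertion_len
    return parent[:h] + inserted + parent[h:], (h, inserted)


def make_scrambled(
    parent: Oligo,
    seed: int,
    target: UtrSequence | None = None,
    max_run: int = 7,
    max_tries: int = 1000,
) -> Oligo:
    """Seeded Fisher-Yates shuffle of ``parent`` with bounded target complementarity.

    Shuffles are redrawn until the longest perfectly complementary run
    against the full target UTR is < ``max_run``; composition and length
    are preserved and the result is reproducible from (parent, seed).
    """
    if target is None:
        raise ValueError("make_scrambled needs the target UTR to check runs against")
    rng = random.Random(seed)
    letters = list(parent.residues)
    degenerate = len(set(letters)) == 1
    for _ in range(max_tries):
        rng.shuffle(letters)
        candidate = "".join(letters)
        probe = Oligo(
            name=parent.name + "_sc",
            category="SCRAMBLED",
            chemistry=parent.chemistry,
            residues=candidate,
            seed=seed,
        )
        if hybridization_report(probe, target).longest_complementary_run < max_run:
            return probe
        if degenerate:
            break  # every shuffle is identical; re-drawing cannot help
    raise RuntimeError(
        f"no acceptable shuffle of {parent.name} within {max_tries} tries; "
        f"consider a larger max_run (current {max_run})"
    )


def hybridization_report(oligo: Oligo | str, target: UtrSequence | str) -> BindingReport:
    """Scan all gapless antisense appositions of ``oligo`` against ``target``.

    The oligo is reversed so that its 5' end apposes the target's 3' side,
    as in a duplex.  Watson-Crick appositions count as matches; G:U counts
    separately as wobble.  The best apposition maximizes Watson-Crick
    matches (ties to the smallest offset); the longest perfect run is
    global over all offsets.
    """
    o = to_alphabet(oligo.residues if isinstance(oligo, Oligo) else oligo, "RNA")
    t = target.residues if isinstance(target, UtrSequence) else to_alphabet(target, "RNA")
    if not o or not t:
        raise ValueError("oligo and target must be non-empty")
    rev = o[::-1]
    n, m = len(rev), len(t)
    best = (-1, -1, 0)  # (wc, wobble, offset); ties resolve to the 5'-most offset
    longest = 0
    for offset in range(-(n - 1), m):
        wc = wobble = run = 0
        for k in range(n):
            tpos = offset + k
            if not 0 <= tpos < m:
                run = 0
                continue
            pair = (rev[k], t[tpos])
            if pair in _WC:
                wc += 1
                run += 1
                longest = max(longest, run)
            else:
                run = 0
                if pair in _WOBBLE:
                    wobble += 1
        if (wc, wobble) > (best[0], best[1]):
            best = (wc, wobble, offset)
    return BindingReport(
        longest_complementary_run=longest,
        wobble_positions=best[1],
        total_matched=max(best[0], 0),
        best_offset=best[2],
    )
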
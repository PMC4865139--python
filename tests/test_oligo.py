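"""Oligo design: categories, insertions, scrambles, hybridization reports."""

from collections import Counter

import pytest

from dgscan.oligo import (
    Oligo,
    design_oligos,
    hybridization_report,
    make_scrambled,
)
from dgscan.scan import CisElement
from dgscan.sequences import UtrSequence, reverse_complement, to_alphabet


@pytest.fixture()
def utr():
    # 60-nt UTR with the element at 21..29 spelling AUGGCAUCC
    residues = "GCAUGCAUGCAUGCAUGCAU" + "AUGGCAUCC" + "GCUAGCUAGCUAGCUAGCUAGCUAGCUAGCU"
    return UtrSequence("utr1", residues)


@pytest.fixture()
def element():
    return CisElement("utr1", 21, 29, peak_signal=10.0, rank_label="e1")


class TestDesignOligos:
    def test_sense_is_target_in_dna_alphabet(self, utr, element):
        (oligo,) = design_oligos(utr, element, categories=("SENSE",), chemistry="DNA")
        assert oligo.residues == "ATGGCATCC"
        assert oligo.category == "SENSE"
        assert oligo.target_interval == (21, 29)

    def test_antisense_is_reverse_complement_dna(self, utr, element):
        (oligo,) = design_oligos(utr, element, categories=("ANTISENSE",), chemistry="DNA")
        assert oligo.residues == "GGATGCCAT"

    def test_sense_antisense_pair_are_reverse_complements(self, utr, element):
        pair = design_oligos(utr, element, categories=("SENSE", "ANTISENSE"),
                             chemistry="RNA_2OME")
        sense = next(o for o in pair if o.category == "SENSE")
        anti = next(o for o in pair if o.category == "ANTISENSE")
        assert reverse_complement(sense.rna) == anti.rna

    @pytest.mark.parametrize("insertion_len", [2, 3])
    def test_mir_like_insertion_preserves_flanks(self, utr, element, insertion_len):
        (mir,) = design_oligos(utr, element, categories=("MIR_LIKE_ANTISENSE",),
                               chemistry="RNA_2OME", insertion_len=insertion_len)
        parent = reverse_complement(utr.subsequence(21, 29))
        n = len(parent)
        h = n // 2
        assert len(mir.residues) == n + insertion_len
        assert mir.rna[:h] == parent[:h]
        assert mir.rna[h + insertion_len :] == parent[h:]
        pos, inserted = mir.insertion
        assert pos == h and len(inserted) == insertion_len

    def test_mir_like_20mer_flank_layout(self):
        # 20-nt parent with a 3-nt insertion: residues 1-10 and 14-23 equal
        # parent residues 1-10 and 11-20
        utr = UtrSequence("u", "G" * 5 + "AUGGCAUCCAUGGCAUCCAU" + "C" * 5)
        element = CisElement("u", 6, 25, 1.0, "e1")
        (mir,) = design_oligos(utr, element, categories=("MIR_LIKE_ANTISENSE",),
                               chemistry="RNA_2OME", insertion_len=3)
        parent = reverse_complement(utr.subsequence(6, 25))
        assert len(mir.rna) == 23
        assert mir.rna[:10] == parent[:10]
        assert mir.rna[13:] == parent[10:]

    def test_chemistry_round_trip(self, utr, element):
        (dna,) = design_oligos(utr, element, categories=("SENSE",), chemistry="DNA")
        (rna,) = design_oligos(utr, element, categories=("SENSE",), chemistry="RNA_2OME")
        assert to_alphabet(dna.residues, "RNA") == rna.residues
        assert to_alphabet(rna.residues, "DNA") == dna.residues

    def test_element_outside_sequence_rejected(self, utr):
        bad = CisElement("utr1", 55, 70, 1.0, "e1")
        with pytest.raises(IndexError):
            design_oligos(utr, bad)

    def test_bad_insertion_length_rejected(self, utr, element):
        with pytest.raises(ValueError, match="insertion_len"):
            design_oligos(utr, element, categories=("MIR_LIKE_SENSE",), insertion_len=4)

    def test_names_encode_element_and_category(self, utr, element):
        oligos = design_oligos(
            utr, element,
            categories=("SENSE", "ANTISENSE", "MIR_LIKE_ANTISENSE", "SCRAMBLED"),
            scramble_seed=17,
        )
        names = {o.name for o in oligos}
        assert {"dG_e1_s", "dG_e1_as", "dG_e1_mir_as", "dG_e1_s_sc"} == names


class TestScrambled:
    def test_seeded_reproducibility(self, utr, element):
        (parent,) = design_oligos(utr, element, categories=("ANTISENSE",))
        s1 = make_scrambled(parent, seed=17, target=utr)
        s2 = make_scrambled(parent, seed=17, target=utr)
        assert s1.residues == s2.residues
        assert s1.seed == 17

    def test_composition_and_length_preserved(self, utr, element):
        (parent,) = design_oligos(utr, element, categories=("ANTISENSE",))
        scrambled = make_scrambled(parent, seed=3, target=utr)
        assert Counter(scrambled.residues) == Counter(parent.residues)
        assert len(scrambled.residues) == len(parent.residues)

    def test_complementarity_bound_enforced(self):
        rng_target = UtrSequence("t", ("AUGGCAUCCGAUUACGGAUCCGUAGCAUGG" * 4)[:100])
        parent = Oligo("p", "ANTISENSE", "RNA_2OME",
                       reverse_complement(rng_target.subsequence(11, 30)),
                       target_seq_id="t", target_interval=(11, 30))
        scrambled = make_scrambled(parent, seed=17, target=rng_target)
        report = hybridization_report(scrambled, rng_target)
        assert report.longest_complementary_run < 7

    def test_degenerate_parent_flagged(self):
        target = UtrSequence("t", "GCGCGCGCGCGCGCGCGCGC")
        parent = Oligo("p", "ANTISENSE", "DNA", "AAAAAA")
        # every shuffle is identical; accepted only if it meets the bound
        scrambled = make_scrambled(parent, seed=1, target=target)
        assert scrambled.residues == "AAAAAA"


class TestHybridizationReport:
    def test_exact_antisense_10mer_full_run_no_wobble(self):
        target = UtrSequence("t", "GGAUCCAUGGCAUCCGAUUA")
        oligo = reverse_complement(target.subsequence(6, 15))
        report = hybridization_report(oligo, target)
        assert report.longest_complementary_run == 10
        assert report.total_matched == 10
        assert report.wobble_positions == 0

    def test_central_mismatch_splits_run(self):
        target = UtrSequence("t", "GGAUCCAUGGCAUCCGAUUA")
        perfect = reverse_complement(target.subsequence(6, 15))
        # corrupt the central position with a non-pairing base
        mid = len(perfect) // 2
        target_base = target.subsequence(6, 15)[len(perfect) - 1 - mid]
        for base in "ACGU":
            if base + target_base not in ("AU", "UA", "CG", "GC", "GU", "UG"):
                break
        mutated = perfect[:mid] + base + perfect[mid + 1 :]
        report = hybridization_report(mutated, target)
        assert report.longest_complementary_run == max(mid, len(perfect) - mid - 1)

    def test_all_G_vs_all_U_is_pure_wobble(self):
        report = hybridization_report("GGGGG", UtrSequence("t", "UUUUU"))
        assert report.total_matched == 0
        assert report.wobble_positions == 5

    def test_mir_like_oligo_shows_single_insertion_gap(self, utr, element):
        (mir,) = design_oligos(utr, element, categories=("MIR_LIKE_ANTISENSE",),
                               chemistry="RNA_2OME", insertion_len=3)
        parent = reverse_complement(utr.subsequence(21, 29))
        h, inserted = mir.insertion
        element_only = UtrSequence("el", utr.subsequence(21, 29))
        # flanks are fully complementary, so the longest run is the larger flank
        report = hybridization_report(mir, element_only)
        assert report.longest_complementary_run == max(h, len(parent) - h)
        # removing the insertion restores full-length complementarity
        restored = mir.rna[:h] + mir.rna[h + len(inserted):]
        assert (hybridization_report(restored, element_only).longest_complementary_run
                == len(parent))
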
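"""Motif-level analyses: loop-positioned integrin motifs, repeat blocks,
assembly-region profiling, heptad scoring and position-frequency matrices."""
import math

import numpy as np
import pytest

from tenascope import domain_scan as ds
from tenascope import motif_scan as ms
from tenascope.records import (
    AnnotationMethod,
    Architecture,
    DomainAnnotation,
    DomainKind,
    ProteinRecord,
)
from tenascope.synthetic_data import make_reference_tnc

from conftest import random_protein


def _fn3_arch(pid, domain_len, n_domains=1, offset=0):
    doms = []
    pos = offset
    for _ in range(n_domains):
        doms.append(DomainAnnotation(protein_id=pid, kind=DomainKind.FN3,
                                     start=pos + 1, end=pos + domain_len,
                                     method=AnnotationMethod.EXTERNAL))
        pos += domain_len
    arch = Architecture(protein_id=pid, seq_length=pos, domains=doms)
    arch.n_fn3 = n_domains
    return arch


def _plant(seq_len, motif, at):
    s = ["A"] * seq_len
    s[at - 1:at - 1 + len(motif)] = list(motif)
    return "".join(s)


class TestIntegrinMotifs:
    def test_rgd_in_fg_window_reported(self):
        seq = _plant(90, "RGD", 70)
        hits = ms.find_integrin_motifs(_fn3_arch("p", 90), seq)
        assert [(h.motif, h.loop, h.fn3_index, h.position) for h in hits] == \
            [("RGD", "FG", 1, 70)]

    def test_rgd_outside_window_not_reported(self):
        seq = _plant(90, "RGD", 5)
        assert ms.find_integrin_motifs(_fn3_arch("p", 90), seq) == []

    def test_idg_in_bc_window(self):
        seq = _plant(90, "IDG", 25)
        hits = ms.find_integrin_motifs(_fn3_arch("p", 90), seq)
        assert [(h.motif, h.loop) for h in hits] == [("IDG", "BC")]

    def test_elvis_in_strand_a(self):
        seq = _plant(90, "ELVIS", 3)
        hits = ms.find_integrin_motifs(_fn3_arch("p", 90), seq)
        assert [(h.motif, h.loop) for h in hits] == [("ELVIS", "STRAND_A")]

    def test_fn3_index_counts_n_to_c(self):
        seq = _plant(180, "KGD", 90 + 70)  # second domain's FG loop
        hits = ms.find_integrin_motifs(_fn3_arch("p", 90, n_domains=2), seq)
        assert [(h.fn3_index, h.motif) for h in hits] == [(2, "KGD")]

    def test_fuzz_matches_independent_window_rule(self, rng):
        """500 random plantings agree with a re-implementation of the rule."""
        all_motifs = {"FG": ["RGD", "RGE", "KGD"], "BC": ["IDG", "IEG"],
                      "STRAND_A": ["ELVIS"]}

        def oracle(L, motif, at):
            out = []
            for loop, motifs in all_motifs.items():
                lo_f, hi_f = ms.LOOP_WINDOWS[loop]
                lo = max(1, math.floor(lo_f * L))
                hi = min(L, math.ceil(hi_f * L))
                if motif in motifs and lo <= at <= hi and at + len(motif) - 1 <= L:
                    out.append((motif, loop))
            return out

        flat = [m for v in all_motifs.values() for m in v]
        for _ in range(500):
            L = int(rng.integers(40, 140))
            motif = flat[rng.integers(0, len(flat))]
            at = int(rng.integers(1, L - len(motif) + 2))
            hits = ms.find_integrin_motifs(_fn3_arch("p", L),
                                           _plant(L, motif, at))
            assert [(h.motif, h.loop) for h in hits] == oracle(L, motif, at)

    def test_requires_fn3(self):
        arch = Architecture(protein_id="p", seq_length=100)
        with pytest.raises(ValueError):
            ms.find_integrin_motifs(arch, "A" * 100)


class TestRepeatBlocks:
    def _repeat_protein(self, n_units, period=70, motif="KEQTQST"):
        unit = motif + "P" * (period - len(motif))
        return ProteinRecord(id="p", seq="M" * 25 + unit * n_units + "W" * 30)

    def test_fourteen_planted_units_one_block(self):
        rec = self._repeat_protein(14)
        blocks = ms.detect_repeats(rec)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.n_units == 14
        assert b.unit_length_mean == pytest.approx(70.0)

    def test_distant_singletons_suppressed(self):
        rec = ProteinRecord(
            id="p", seq="A" * 10 + "KEQTQST" + "A" * 300 + "KEQTQST" + "A" * 10)
        assert ms.detect_repeats(rec) == []

    def test_kd_variant_matched(self):
        rec = self._repeat_protein(3, motif="KDQTQST")
        assert ms.detect_repeats(rec)[0].n_units == 3

    def test_single_mismatch_tolerated(self):
        unit_good = "KEQTQST" + "P" * 63
        unit_bad = "KEQTQAT" + "P" * 63  # one substitution
        rec = ProteinRecord(id="p", seq=(unit_good + unit_bad) * 2)
        assert ms.detect_repeats(rec)[0].n_units == 4

    def test_invariant_to_flanking_padding(self):
        core = ("KEQTQST" + "P" * 63) * 5
        b1 = ms.detect_repeats(ProteinRecord(id="p", seq=core))[0]
        b2 = ms.detect_repeats(ProteinRecord(id="p", seq="W" * 200 + core + "W" * 137))[0]
        assert b1.n_units == b2.n_units == 5
        assert b2.start - b1.start == 200


class TestAssemblyRegion:
    def test_reference_against_itself_all_cysteines(self):
        ref = make_reference_tnc()
        anns = ds.annotate_builtin(ref)
        arch = ds.build_architecture(ref, anns)
        prof = ms.profile_assembly_region(ref, arch, ref)
        assert all(prof.cysteines.values())
        assert set(prof.cysteines) == {64, 111, 113, 140, 146, 147}
        assert prof.rhexle_present
        assert any(h["pattern"] == "vFnHvYnINvP" for h in prof.conserved_motif_hits)

    def test_mutated_c64_reported_absent(self):
        ref = make_reference_tnc()
        mutated = ProteinRecord(id="q", seq=ref.seq[:63] + "S" + ref.seq[64:])
        arch = ds.build_architecture(mutated, ds.annotate_builtin(mutated))
        prof = ms.profile_assembly_region(mutated, arch, ref)
        assert prof.cysteines[64] is False
        assert all(prof.cysteines[p] for p in (111, 113, 140, 146, 147))

    def test_missing_egf_errors(self):
        arch = Architecture(protein_id="p", seq_length=100)
        with pytest.raises(ValueError, match="EGF"):
            ms.assembly_region(arch)

    def test_conserved_motif_exact_instance_found(self):
        hits = ms.find_conserved_motifs("QQQVFNHVYNINVPQQQ")
        assert [(h["pattern"], h["position"]) for h in hits] == \
            [("vFnHvYnINvP", 4)]

    def test_conserved_motif_uppercase_positions_are_strict(self):
        # mutate an upper-case (highly conserved) position: no hit
        assert ms.find_conserved_motifs("QQQVANHVYNINVPQQQ") == []
        # two lower-case deviations are tolerated, three are not
        assert ms.find_conserved_motifs("QQQGFNHGYNINVPQQQ")
        assert ms.find_conserved_motifs("QQQGFNHGYNINGPQQQ") == []


class TestHeptads:
    def test_perfect_ad_register_scores_one(self):
        rec = ProteinRecord(id="p", seq="LAELKAE" * 4)
        ann = ms.detect_heptads(rec, (1, 28))
        assert ann is not None
        assert ann.score == pytest.approx(1.0)
        assert (ann.start, ann.register_offset) == (1, 0)

    def test_poly_serine_no_heptad(self):
        rec = ProteinRecord(id="p", seq="S" * 60)
        assert ms.detect_heptads(rec, (1, 60)) is None

    def test_rhexle_detected_inside_window(self):
        window = list("LAELKAE" * 4)
        window[4:10] = list("RLEALE")  # keeps the a/d register hydrophobic
        rec = ProteinRecord(id="p", seq="".join(window))
        ann = ms.detect_heptads(rec, (1, len(rec.seq)))
        assert ann is not None and ann.rhexle_present

    def test_planted_register_recovered(self, rng):
        """Ideal coiled-coil windows are always found with their register."""
        for offset_shift in range(3):
            pad = "S" * (10 + offset_shift)
            rec = ProteinRecord(id="p", seq=pad + "LAELKAE" * 4 + "S" * 9)
            ann = ms.detect_heptads(rec, (1, len(rec.seq)))
            assert ann is not None and ann.score == pytest.approx(1.0)
            # the reported window overlaps the planted repeat and every one
            # of its a/d slots sits on a hydrophobic residue
            assert ann.start <= len(pad) + 28 and ann.end > len(pad)
            window = rec.seq[ann.start - 1:ann.end]
            ad = [window[i] for i in range(len(window))
                  if (i + ann.register_offset) % 7 in (0, 3)]
            assert all(c in ms.HEPTAD_HYDROPHOBIC for c in ad)


class TestPositionFrequencies:
    def test_identical_sequences_unit_frequencies(self):
        pfm = ms.position_frequencies(["ACD", "ACD"])
        for col, res in zip(pfm.columns, "ACD"):
            assert col == {res: 1.0}
        assert pfm.information_content == pytest.approx([math.log2(20)] * 3)

    def test_mixed_column_arithmetic(self):
        pfm = ms.position_frequencies(["C", "C", "S", "C"])
        assert pfm.columns[0] == {"C": 0.75, "S": 0.25}
        expected = math.log2(20) - (-0.75 * math.log2(0.75) - 0.25 * math.log2(0.25))
        assert pfm.information_content[0] == pytest.approx(expected)

    def test_gap_fraction_excluded_from_entropy(self):
        pfm = ms.position_frequencies(["A-", "AA", "A-", "AA"])
        assert pfm.gap_fractions == [0.0, 0.5]
        assert pfm.information_content[1] == pytest.approx(math.log2(20))
        assert sum(pfm.columns[1].values()) == pytest.approx(1.0)

    def test_ragged_input_errors(self):
        with pytest.raises(ValueError, match="ragged"):
            ms.position_frequencies(["AC", "A"])

    def test_columns_sum_to_one_and_ic_in_range(self, rng):
        seqs = ["".join("ACDEF-"[i] for i in rng.integers(0, 6, 40))
                for _ in range(12)]
        pfm = ms.position_frequencies(seqs)
        for col, ic in zip(pfm.columns, pfm.information_content):
            assert sum(col.values()) == pytest.approx(1.0, abs=1e-9)
            assert -1e-9 <= ic <= math.log2(20) + 1e-9
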
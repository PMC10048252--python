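"""Isoform catalog: capture sets, deletions, ORF/PTC/NMD annotation and
amplicon-length prediction."""

import numpy as np
import pytest

from inpp5d_iso import (Exon, PrimerPair, PrimerSite, Transcript,
                        annotate_orf, apply_deletion, capture_set,
                        nmd_candidate, predict_amplicon_length)
from inpp5d_iso.isoform_model import (D26_NOVEL_TAIL, catalog_from_json,
                                      catalog_to_json, d26_variant,
                                      d47_variant)

EXPECTED_CAPTURE = {
    "ex2-ex3": {"201", "204", "205"},
    "ex10-ex12": {"201", "204"},
    "ex11-ex12": {"201", "202", "204"},
    "ex15-ex16": {"201", "202", "204", "213"},
    "in14-ex16": {"213"},
}


class TestCaptureSets:
    @pytest.mark.parametrize("pair, expected", sorted(EXPECTED_CAPTURE.items()))
    def test_published_primer_pairs(self, catalog, pair, expected):
        assert capture_set(catalog.capture_pairs[pair], catalog) == expected

    def test_tss_assignments(self, catalog):
        assert catalog.tss_isoforms() == {"A": {"201", "204", "205"},
                                          "B": {"202"}, "C": {"213"}}

    def test_unknown_anchor(self, catalog):
        with pytest.raises(ValueError, match="unknown anchor"):
            capture_set(("ex2", "ex99"), catalog)

    def test_missing_internal_exon_breaks_capture(self, catalog):
        # an isoform lacking exon 11 cannot be amplified from ex10 to ex12
        t = catalog["201"]
        skipped = apply_deletion(t, "ex11", 0, t.exon("ex11").length)
        cat2 = type(catalog)(transcripts={"v": skipped})
        assert capture_set(("ex10", "ex12"), cat2) == set()


class TestApplyDeletion:
    def test_length_bookkeeping(self, catalog):
        t = catalog["201"]
        v = apply_deletion(t, "ex12", 0, 47)
        assert t.spliced_length - v.spliced_length == 47
        assert v.deletions[-1].length_nt == 47
        assert v.parent_id == "201"

    def test_zero_length_identity(self, catalog):
        t = catalog["201"]
        v = apply_deletion(t, "ex12", 10, 0)
        assert v.spliced_length == t.spliced_length
        assert v.isoform_id == t.isoform_id

    def test_whole_exon_skip_removes_exon(self, catalog):
        v = d26_variant(catalog)
        assert "ex26" not in v.exon_labels

    def test_out_of_bounds_rejected(self, catalog):
        with pytest.raises(ValueError, match="exceeds the exon boundary"):
            apply_deletion(catalog["201"], "ex12", 120, 47)

    def test_frameshift_iff_length_not_multiple_of_three(self, catalog):
        t = catalog["201"]
        for length in (3, 6, 45, 47, 44, 1):
            v = apply_deletion(t, "ex12", 0, length)
            ann = annotate_orf(v, reference=t)
            assert ann.frameshift == (length % 3 != 0)


class TestAnnotateOrf:
    def test_direct_translation(self):
        t = Transcript("t", (Exon("ex1", 9, "ATGAAATAG"),), cds_start=1,
                       coding=True)
        ann = annotate_orf(t)
        assert ann.protein == "MK"
        assert not ann.frameshift and ann.novel_tail == ""

    def test_toy_frameshift_against_manual_translation(self):
        # reference ATG AAA CCC GGG TAA; delete 1 nt inside codon 2 ->
        # shifted frame reads ATG AAC CCG GGT AA.. (manual oracle)
        ref = Transcript("r", (Exon("ex1", 9, "ATGAAACCC"),
                               Exon("ex2", 6, "GGGTAA")), cds_start=1,
                         coding=True)
        var = apply_deletion(ref, "ex1", 4, 1)
        ann = annotate_orf(var, reference=ref)
        assert ann.frameshift
        assert ann.protein == "MNPG"
        assert ann.non_stop   # shifted frame loses the stop codon
        assert ann.novel_tail == "NPG"

    def test_d26_novel_tail_is_printed_peptide(self, catalog):
        ann = annotate_orf(d26_variant(catalog), reference=catalog["201"])
        assert ann.frameshift
        assert ann.novel_tail == D26_NOVEL_TAIL
        assert len(ann.novel_tail) == 17
        # tail sits in the final exon, so it escapes the junction rule
        assert not ann.nmd_candidate

    def test_d47_introduces_ptc_and_nmd(self, catalog):
        ann = annotate_orf(d47_variant(catalog), reference=catalog["201"])
        assert ann.frameshift
        assert ann.ptc_position is not None
        assert ann.nmd_candidate

    def test_agrees_with_independent_codon_oracle(self):
        """Translation path vs a hand-rolled codon dictionary on random CDSs."""
        codon_map = _codon_dictionary()
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3 * n))
            expected = ""
            for i in range(0, len(seq), 3):
                aa = codon_map[seq[i:i + 3]]
                if aa == "*":
                    break
                expected += aa
            t = Transcript("t", (Exon("ex1", len(seq), seq),), cds_start=1,
                           coding=True)
            assert annotate_orf(t).protein == expected

    def test_noncoding_transcript_rejected(self, catalog):
        with pytest.raises(ValueError, match="cds_start"):
            annotate_orf(catalog["213"])


def _codon_dictionary():
    """Standard genetic code written out independently of Biopython."""
    bases = "TCAG"
    aas = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
           "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
    return {a + b + c: aas[16 * i + 4 * j + k]
            for i, a in enumerate(bases)
            for j, b in enumerate(bases)
            for k, c in enumerate(bases)}


class TestNmdRule:
    def _two_exon(self, first_len=300):
        return Transcript("t", (Exon("ex1", first_len, "A" * first_len),
                                Exon("ex2", 200, "G" * 200)), cds_start=1,
                          coding=True)

    def test_far_upstream_ptc_triggers(self):
        # stop ends at nt 3*ptc; junction at 300 -> 210 nt of clearance
        assert nmd_candidate(self._two_exon(), ptc_position=30)

    def test_last_exon_ptc_escapes(self):
        # stop ends at nt 360, downstream of the junction at 300
        assert not nmd_candidate(self._two_exon(), ptc_position=120)

    def test_boundary_is_strict(self):
        # junction at 200: a stop ending exactly 50 nt upstream (codon 50)
        # is not a candidate; one codon earlier (53 nt clearance) is
        t = self._two_exon(first_len=200)
        assert not nmd_candidate(t, ptc_position=50)
        assert nmd_candidate(t, ptc_position=49)

    def test_single_exon_never_candidate(self):
        t = Transcript("t", (Exon("ex1", 300, "A" * 300),), cds_start=1)
        assert not nmd_candidate(t, ptc_position=10)


class TestAmpliconLengths:
    def test_published_fig_panel_lengths(self, catalog):
        ref = catalog["201"]
        d47 = d47_variant(catalog)
        p9_12 = catalog.primer_pairs["ex9-ex12"]
        assert predict_amplicon_length(p9_12, ref) == 458
        assert predict_amplicon_length(p9_12, d47, reference=ref) == 411
        p11_12 = catalog.primer_pairs["ex11-ex12"]
        assert predict_amplicon_length(p11_12, ref) == 224
        assert predict_amplicon_length(p11_12, d47, reference=ref) == 177

    def test_length_difference_equals_deleted_overlap(self, catalog):
        ref = catalog["201"]
        pair = catalog.primer_pairs["ex9-ex12"]
        for length in (1, 10, 47, 100):
            v = apply_deletion(ref, "ex12", 0, length)
            assert (predict_amplicon_length(pair, ref)
                    - predict_amplicon_length(pair, v, reference=ref)
                    == length)

    def test_single_exon_pair_is_primer_span(self, catalog):
        pair = PrimerPair("p", PrimerSite("ex9", 11, 20),
                          PrimerSite("ex9", 81, 20))
        assert predict_amplicon_length(pair, catalog["201"]) == 90

    def test_absent_anchor_no_product(self, catalog):
        pair = PrimerPair("p", PrimerSite("ex26", 5, 10),
                          PrimerSite("ex26", 30, 10))
        assert predict_amplicon_length(pair, d26_variant(catalog),
                                       reference=catalog["201"]) is None

    def test_disrupted_footprint_no_product(self, catalog):
        ref = catalog["201"]
        pair = PrimerPair("p", PrimerSite("ex12", 1, 20),
                          PrimerSite("ex12", 131, 20))
        d47 = d47_variant(catalog)      # removes the forward footprint
        assert predict_amplicon_length(pair, d47, reference=ref) is None

    def test_out_of_bounds_primer_rejected(self, catalog):
        pair = PrimerPair("p", PrimerSite("ex9", 115, 20),
                          PrimerSite("ex12", 131, 20))
        with pytest.raises(ValueError, match="out of exon bounds"):
            predict_amplicon_length(pair, catalog["201"])


class TestCatalogJson:
    def test_round_trip(self, catalog):
        text = catalog_to_json(catalog)
        loaded = catalog_from_json(text)
        assert set(loaded.transcripts) == set(catalog.transcripts)
        for iso in catalog.transcripts:
            a, b = catalog[iso], loaded[iso]
            assert a.exon_labels == b.exon_labels
            assert a.sequence == b.sequence
            assert a.cds_start == b.cds_start
        assert catalog_to_json(loaded) == text   # byte-stable

    def test_schema_version_mismatch(self, catalog):
        text = catalog_to_json(catalog).replace('"schema_version": 1',
                                                '"schema_version": 99')
        with pytest.raises(ValueError, match="schema version"):
            catalog_from_json(text)
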
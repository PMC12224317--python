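"""Signal-peptide heuristics, cytochrome motifs, operon categories, dedupe."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faoclassify.signpost_scan import (
    GeneRecord,
    dedupe_by_identity,
    detect_cytc,
    detect_fusion,
    detect_sec_signal,
    detect_tat_signal,
    pairwise_identity,
    scan_fao_context,
)

MATURE = "DEQNTYHDEQNTYHDEQNTYHDEQNTYHDEQNTYHDEQNTYH"
TAT_N = "MSTRRNFLK" + "AAVLLGALAG"
PELB = "MKYLLPTAAAGLLLLAAQPAMA"

protein_strategy = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=40,
                           max_size=120)


class TestTat:
    def test_planted_consensus_found_at_position_3(self):
        call = detect_tat_signal(TAT_N + MATURE)
        assert call.type == "TAT"
        assert call.motif_position == 3

    def test_no_arg_pair_is_none(self):
        assert detect_tat_signal("M" + "K" * 99).type == "none"

    def test_motif_outside_window_is_none(self):
        seq = "M" + "DEQNTYH" * 30 + "STRRNFLLLLLLLL" + MATURE
        assert detect_tat_signal(seq).type == "none"

    def test_motif_without_hydrophobic_region_is_none(self):
        assert detect_tat_signal("MSTRRNF" + "DEQNT" * 20).type == "none"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            detect_tat_signal("MSTRRNFLKB1" + MATURE)


class TestSec:
    def test_pelb_is_sec_with_cleavage_at_22(self):
        call = detect_sec_signal(PELB + MATURE)
        assert call.type == "Sec"
        assert call.cleavage_position == 22

    def test_polar_n_terminus_is_none(self):
        assert detect_sec_signal("S" * 60).type == "none"

    def test_tat_sequence_is_not_sec(self):
        assert detect_sec_signal(TAT_N + MATURE).type == "none"

    @given(protein_strategy)
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_mutual_exclusion(self, seq):
        """No sequence is ever called both TAT and Sec."""
        calls = {detect_tat_signal(seq).type, detect_sec_signal(seq).type}
        assert calls != {"TAT", "Sec"}
        if detect_tat_signal(seq).type == "TAT":
            assert detect_sec_signal(seq).type != "Sec"


class TestCytc:
    def test_no_cysteines(self):
        ev = detect_cytc("DEQNTY" * 20)
        assert ev.cytc_class == "not_cytc" and ev.motif_count == 0

    def test_monoheme_small_protein(self):
        seq = "M" + "DEQNTY" * 9 + "CAGCH" + "DEQNTY" * 7
        ev = detect_cytc(seq)
        assert ev.motif_count == 1
        assert ev.cytc_class == "class_I_monoheme"

    def test_diheme_c4_size(self):
        seq = ("M" + "DEQNTY" * 14 + "CAGCH" + "DEQNTY" * 14 + "CMTCH"
               + "DEQNT")
        ev = detect_cytc(seq)
        assert ev.motif_count == 2
        assert 150 <= ev.length <= 250
        assert ev.cytc_class == "c4_diheme"

    def test_mature_length_uses_sec_cleavage(self):
        # 22-aa PelB + 122-aa mature: full length 144 > 130 but mature <= 130
        mature = ("DEQNTY" * 13 + "CAGCH" + "DEQNTY" * 6 + "DEQ")
        assert len(mature) <= 130 < len(PELB + mature)
        ev = detect_cytc(PELB + mature)
        assert ev.cytc_class == "class_I_monoheme"


class TestFusion:
    FUSED = TAT_N + "DEQNTY" * 75 + "CAGCH" + "DEQNTY"

    def test_tat_long_protein_with_cterminal_heme_motif(self):
        assert len(self.FUSED) >= 450
        assert detect_fusion(self.FUSED) is True

    def test_without_heme_motif_false(self):
        assert detect_fusion(TAT_N + "DEQNTY" * 80) is False

    def test_short_cytc_alone_false(self):
        assert detect_fusion(PELB + "DEQNTY" * 15 + "CAGCH") is False


def _gene(locus, start, protein, contig="c1", product="protein"):
    return GeneRecord(locus, contig, start, start + 3 * len(protein) + 2, "+",
                      product, protein)


class TestOperonContext:
    FAO_TAT = TAT_N + "DEQNTY" * 80
    FAO_PLAIN = "M" + "DEQNTY" * 80
    CYTC = PELB + "DEQNTY" * 9 + "CAGCH" + "DEQNTY" * 7

    def test_exemplar_operon_both_faos_blue(self):
        """nicA2-like(TAT) - cytC - pnao-like(TAT): both FAOs categorize blue."""
        genes = [
            _gene("nicA2", 1000, self.FAO_TAT),
            _gene("cycN", 1000 + 3 * len(self.FAO_TAT) + 100, self.CYTC),
            _gene("pnao", 1000 + 3 * len(self.FAO_TAT)
                  + 3 * len(self.CYTC) + 200, self.FAO_TAT),
        ]
        assert scan_fao_context(genes, 0).category == "blue"
        assert scan_fao_context(genes, 2).category == "blue"

    def test_lone_unsignaled_fao_black(self):
        assert scan_fao_context([_gene("f", 100, self.FAO_PLAIN)], 0
                                ).category == "black"

    def test_cytc_outside_bp_window_red(self):
        genes = [
            _gene("fao", 1000, self.FAO_TAT),
            _gene("cytc", 1000 + 3 * len(self.FAO_TAT) + 10000, self.CYTC),
        ]
        assert scan_fao_context(genes, 0).category == "red"

    def test_cytc_beyond_gene_count_window_red(self):
        start = 1000
        genes = [_gene("fao", start, self.FAO_TAT)]
        pos = start + 3 * len(self.FAO_TAT) + 50
        for i in range(3):  # three intervening decoys within bp reach
            genes.append(_gene(f"d{i}", pos, "M" + "DEQNTY" * 10))
            pos += 250
        genes.append(_gene("cytc", pos, self.CYTC))
        assert scan_fao_context(genes, 0, window_bp=10**6).category == "red"

    def test_fused_gene_green(self):
        fused = TAT_N + "DEQNTY" * 75 + "CAGCH" + "DEQNTY"
        assert scan_fao_context([_gene("f", 100, fused)], 0).category == "green"

    def test_empty_contig_rejected(self):
        with pytest.raises(ValueError):
            scan_fao_context([], 0)


class TestIdentityAndDedupe:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEF" * 10, "ACDEF" * 10) == 1.0

    def test_disjoint_sequences(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_single_substitution_99_percent(self):
        a = ("ACDEFGHIKLMNPQRSTVWY" * 5)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        assert pairwise_identity(a, b) == pytest.approx(0.99)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")

    def _mutate(self, seq, n_sub, seed=0):
        rng = random.Random(seed)
        s = list(seq)
        for pos in rng.sample(range(len(s)), n_sub):
            s[pos] = "W" if s[pos] != "W" else "Y"
        return "".join(s)

    def test_dedupe_cutoff_straddle(self):
        """A 99%-identical pair collapses to one; a 97% pair keeps both."""
        base = ("ACDEFGHIKLMNPQRSTVY" * 10)[:100]  # no W
        near = self._mutate(base, 1)    # 99/100
        far = self._mutate(base, 3)     # 97/100
        assert pairwise_identity(base, near) == pytest.approx(0.99)
        assert pairwise_identity(base, far) == pytest.approx(0.97)
        kept, _ = dedupe_by_identity([base, near], cutoff=0.98)
        assert kept == [0]
        kept, _ = dedupe_by_identity([base, far], cutoff=0.98)
        assert kept == [0, 1]

    def test_dedupe_identical_and_unrelated(self):
        seq = "ACDEFGHIKL" * 8
        kept, cluster = dedupe_by_identity([seq, seq, "WYWYWYWYWY" * 8])
        assert kept == [0, 2]
        assert cluster == {0: 0, 1: 0, 2: 2}

    def test_dedupe_idempotent(self):
        base = ("ACDEFGHIKLMNPQRSTVY" * 10)[:100]
        seqs = [base, self._mutate(base, 1), self._mutate(base, 3),
                "WYWYWYWYWY" * 10]
        kept1, _ = dedupe_by_identity(seqs)
        once = [seqs[i] for i in kept1]
        kept2, _ = dedupe_by_identity(once)
        assert [once[i] for i in kept2] == once
        assert len(kept1) <= len(seqs)
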
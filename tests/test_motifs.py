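"""Hexamer scanning, repeat syntax and Fisher enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from auxphase import (
    HEXAMERS,
    RepeatConfig,
    enrichment_frame,
    fisher_exact_enrichment,
    hexamer_enrichment_table,
    repeat_configs_by_gene,
    repeat_enrichment_table,
    scan_hexamers,
    scan_repeat_configurations,
    reverse_complement,
)
from conftest import (
    brute_force_configs,
    brute_force_occurrences,
    hypergeom_upper_tail,
    random_dna,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=80)


class TestScanHexamers:
    def test_single_forward_match(self):
        (occ,) = scan_hexamers("TGTCGGAT")
        assert (occ.offset, occ.strand_rel, occ.hexamer) == (0, "+", "TGTCGG")

    def test_single_reverse_match_written_core_first(self):
        (occ,) = scan_hexamers("CCGACA")
        assert (occ.offset, occ.strand_rel, occ.hexamer) == (0, "-", "TGTCGG")

    def test_overlapping_matches_all_reported(self):
        occs = scan_hexamers("TGTCTGTCGG")
        assert [(o.offset, o.strand_rel, o.hexamer) for o in occs] == [
            (0, "+", "TGTCTG"),
            (4, "+", "TGTCGG"),
        ]

    def test_incomplete_footprint_not_reported(self):
        assert scan_hexamers("AATGTCG") == []  # core present, 6-mer runs off the end

    def test_n_bases_never_match(self):
        assert scan_hexamers("TGTCNN") == []
        assert scan_hexamers("NGTCGG") == []

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            scan_hexamers("TGTCQQ")

    @given(seq=dna)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_occurrence_conservation_matches_brute_force(self, seq):
        got = {(o.offset, o.strand_rel, o.hexamer) for o in scan_hexamers(seq)}
        assert got == set(brute_force_occurrences(seq))


class TestFisherEnrichment:
    def test_no_signal_gives_p_one(self):
        assert fisher_exact_enrichment(0, 10, 0, 100) == 1.0

    def test_matches_bigint_tail(self):
        p = fisher_exact_enrichment(8, 10, 20, 100)
        assert p == pytest.approx(hypergeom_upper_tail(8, 110, 28, 10), abs=1e-15)

    def test_extreme_table_closed_form(self):
        p = fisher_exact_enrichment(10, 10, 0, 100)
        assert p == pytest.approx(1 / math.comb(110, 10), rel=1e-12)

    def test_rejects_zero_totals(self):
        with pytest.raises(ValueError):
            fisher_exact_enrichment(0, 0, 5, 10)

    def test_monotone_in_foreground_hits(self):
        """Adding motif-bearing foreground genes never weakens enrichment."""
        ps = [fisher_exact_enrichment(k, 20, 10, 100) for k in range(21)]
        assert all(p2 <= p1 + 1e-15 for p1, p2 in zip(ps, ps[1:]))


class TestRepeatConfigurations:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("TGTCGGAAATGTCGG", {("DR", 3)}),
            ("TGTCGGAAACCGACA", {("IR", 3)}),
            ("CCGACAAAATGTCGG", {("ER", 3)}),
        ],
    )
    def test_worked_orientation_examples(self, seq, expected):
        configs = scan_repeat_configurations(scan_hexamers(seq))
        assert {(c.orientation, c.spacer) for c in configs} == expected

    def test_spacer_bounds_respected(self):
        seq = "TGTCGG" + "A" * 26 + "TGTCGG"  # spacer 26 > default max 25
        assert scan_repeat_configurations(scan_hexamers(seq)) == set()

    def test_brute_force_agreement_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(6, 301)))
            got = {
                (c.orientation, c.spacer)
                for c in scan_repeat_configurations(scan_hexamers(seq))
            }
            assert got == brute_force_configs(seq)

    @given(seq=dna)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reverse_complement_invariance(self, seq):
        fwd = scan_repeat_configurations(scan_hexamers(seq))
        rev = scan_repeat_configurations(scan_hexamers(reverse_complement(seq)))
        assert fwd == rev


class TestEnrichmentTables:
    def _promoters(self, seqs, prefix):
        return {f"{prefix}{i}": s for i, s in enumerate(seqs)}

    def test_sixteen_hexamer_records(self):
        fg = self._promoters(["TGTCGGAT", "ACGTACGT"], "f")
        bg = self._promoters(["ACGTACGT"] * 3, "b")
        records = hexamer_enrichment_table(fg, bg)
        assert len(records) == 16
        assert sorted(str(r.feature) for r in records) == list(HEXAMERS)

    def test_coreless_promoters_give_all_p_one(self):
        fg = self._promoters(["AAAAAAAA"] * 2, "f")
        bg = self._promoters(["CCCCCCCC"] * 3, "b")
        records = hexamer_enrichment_table(fg, bg)
        assert all(r.fg_with == r.bg_with == 0 and r.p_value == 1.0 for r in records)

    def test_overlapping_sets_rejected(self):
        fg = {"g1": "ACGT"}
        with pytest.raises(ValueError, match="g1"):
            hexamer_enrichment_table(fg, {"g1": "ACGT", "g2": "ACGT"})

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            hexamer_enrichment_table({}, {"g": "ACGT"})

    def test_consensus_table_has_78_records_and_fractions(self):
        fg = self._promoters(
            ["TGTCGGAAAAAAATGTCGG"] * 2 + ["ACGTACGTACGTACGTACG"] * 2, "f"
        )  # (DR, 7) in 2 of 4 foreground genes
        bg = self._promoters(["ACGTACGTACGTACGTACG"] * 5, "b")
        records = repeat_enrichment_table(
            repeat_configs_by_gene(fg), repeat_configs_by_gene(bg)
        )
        assert len(records) == 78
        by_feature = {(r.feature.orientation, r.feature.spacer): r for r in records}
        assert by_feature[("DR", 7)].fg_fraction == 0.5

    def test_enrichment_frame_has_bh_column(self):
        fg = self._promoters(["TGTCGGAT"], "f")
        bg = self._promoters(["ACGTACGT"] * 3, "b")
        df = enrichment_frame(hexamer_enrichment_table(fg, bg))
        assert {"feature", "p_value", "q_value", "neg_log10_p"} <= set(df.columns)
        assert (df["q_value"] >= df["p_value"] - 1e-15).all()


def test_repeat_config_requires_known_orientation():
    with pytest.raises(ValueError):
        RepeatConfig("XX", 3)
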
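"""Liability scanning, pI, hydropathy, charge and traffic lights."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from vhhmine import campaign
from vhhmine.developability import (
    ReferenceStats,
    assess,
    cdr_hydropathy,
    cdr_positive_charge,
    default_hydropathy_scale,
    default_pka_table,
    detect_liabilities,
    framework_identity,
    isoelectric_point,
    net_charge,
)
from vhhmine.repertoire import AA_ALPHABET, AnnotatedVHH

aa_text = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=15)


def oracle_scan(region: str, seq: str):
    """Independent regex-based liability scan (category, position, severity)."""
    found = set()
    for m in re.finditer("N", seq):
        i = m.start()
        nxt = seq[i + 1 : i + 2]
        sev = (
            "high"
            if nxt == "G"
            else "moderate" if nxt and nxt in "STNDH" else "low"
        )
        found.add(("deamidation", i + 1, sev))
        if re.match("N[^P][ST]", seq[i : i + 3]):
            found.add(("glycosylation_sequon", i + 1, "high"))
    for m in re.finditer("D", seq):
        i = m.start()
        nxt = seq[i + 1 : i + 2]
        sev = "high" if nxt == "G" else "moderate" if nxt and nxt in "STD" else "low"
        found.add(("isomerization", i + 1, sev))
    for m in re.finditer("M", seq):
        found.add(("oxidation", m.start() + 1, "high"))
    for m in re.finditer("C", seq):
        found.add(("unpaired_cysteine", m.start() + 1, "high"))
    return found


class TestDetectLiabilities:
    def test_published_asn_tyr_motif_flagged_low(self):
        # CDR1 of the candidate that deamidated 18.7% in forced degradation
        flags = detect_liabilities("GRTFSNYAIS", "RGGDNTAA", "VFTPTDTVVFINKEPYNY")
        nys = [
            f
            for f in flags
            if f.region == "cdr1" and f.category == "deamidation" and f.position == 6
        ]
        assert len(nys) == 1
        assert nys[0].motif == "NY"
        assert nys[0].severity == "low"

    def test_published_met_oxidation_flagged_high(self):
        flags = detect_liabilities("GGTFGSYAIS", "RSGGSTAA", "AGGMGSTTVVVSTIPYKY")
        mets = [f for f in flags if f.category == "oxidation"]
        assert [(f.region, f.position, f.severity) for f in mets] == [
            ("cdr3", 4, "high")
        ]

    def test_proline_blocks_sequon(self):
        flags = detect_liabilities("NPT", "G", "G")
        assert "glycosylation_sequon" not in {f.category for f in flags}

    def test_ngs_motif_composes_deamidation_and_sequon(self):
        flags = detect_liabilities("NGS", "G", "G")
        cats = {(f.category, f.severity) for f in flags if f.region == "cdr1"}
        assert ("deamidation", "high") in cats
        assert ("glycosylation_sequon", "high") in cats

    def test_motif_is_substring_at_stated_position(self):
        flags = detect_liabilities("ANGTD", "MDSC", "NYT")
        for f in flags:
            region = {"cdr1": "ANGTD", "cdr2": "MDSC", "cdr3": "NYT"}[f.region]
            assert region[f.position - 1 : f.position - 1 + len(f.motif)] == f.motif

    @settings(max_examples=100, deadline=None)
    @given(cdr1=aa_text, cdr2=aa_text, cdr3=aa_text)
    def test_matches_exhaustive_pattern_oracle(self, cdr1, cdr2, cdr3):
        flags = detect_liabilities(cdr1, cdr2, cdr3)
        for region, seq in (("cdr1", cdr1), ("cdr2", cdr2), ("cdr3", cdr3)):
            got = {
                (f.category, f.position, f.severity)
                for f in flags
                if f.region == region
            }
            assert got == oracle_scan(region, seq)


class TestIsoelectricPoint:
    def test_net_charge_vanishes_at_reported_pi(self):
        for seq in ("GFTFSSYAIS", "KKDDE", "ACDEFGHIKLMNPQRSTVWY"):
            pi = isoelectric_point(seq)
            assert abs(net_charge(seq, pi)) < 1e-3

    def test_basic_sequences_above_acidic(self):
        assert isoelectric_point("KKKKK") > isoelectric_point("DDDDD")

    def test_full_alphabet_matches_grid_scan_oracle(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        # oracle: fine pH grid, pick the sign change of the charge curve
        pka = default_pka_table()
        grid = [i * 1e-3 for i in range(14001)]
        crossing = min(grid, key=lambda ph: abs(net_charge(seq, ph, pka)))
        assert isoelectric_point(seq, pka) == pytest.approx(crossing, abs=1e-3)

    @settings(max_examples=30, deadline=None)
    @given(seq=aa_text)
    def test_adding_lysine_never_decreases_pi(self, seq):
        assert isoelectric_point(seq + "K") >= isoelectric_point(seq) - 1e-6


class TestHydropathyAndCharge:
    def test_hydrophobic_window_beats_charged_window(self):
        assert cdr_hydropathy("IIIII", "G", "G") > cdr_hydropathy("RRRRR", "G", "G")

    def test_window_equal_to_cdr_length_gives_plain_mean(self):
        kd = default_hydropathy_scale()
        assert cdr_hydropathy("ACDEF", "G", "G", window=5) == pytest.approx(
            max(
                sum(kd[a] for a in "ACDEF") / 5,
                kd["G"],
            )
        )

    def test_hand_summed_window_value(self):
        # VVVSTIPYKY, window 5: best window is VVSTI
        # (4.2 + 4.2 - 0.8 - 0.7 + 4.5) / 5 = 2.28 on the Kyte-Doolittle scale
        assert cdr_hydropathy("G", "G", "VVVSTIPYKY", window=5) == pytest.approx(2.28)

    def test_positive_charge_counts(self):
        assert cdr_positive_charge("GGGG", "GGGG", "GGGG") == 0.0
        assert cdr_positive_charge("RG", "KG", "GG") == 2.0
        assert cdr_positive_charge("H", "G", "G") == pytest.approx(0.1)

    def test_published_candidate_charge_is_hand_count(self):
        # candidate 29: CDR1 GRTLGNYAIS (1 R), CDR2 WGGSRTAT (1 R), CDR3 none
        df = campaign.candidate_sequences()
        row = df[df.candidate_id == 29].iloc[0]
        assert cdr_positive_charge(row.cdr1, row.cdr2, row.cdr3) == 2.0


class TestFrameworkIdentity:
    def test_identical_sequences_score_100(self):
        assert framework_identity("EVQLVESGG", "EVQLVESGG") == 100.0

    def test_single_substitution_in_87_positions(self):
        a = ("EVQLVESGG" * 10)[:87]
        b = a[:40] + "W" + a[41:]
        assert framework_identity(a, b) == pytest.approx(86 / 87 * 100, abs=0.01)

    def test_fully_different_same_length(self):
        assert framework_identity("EEEE", "GGGG") == 0.0


class TestAssessAndLights:
    def test_lights_follow_sd_bands(self):
        ref = ReferenceStats({"cdr_hydropathy": (1.0, 0.5), "cdr_positive_charge": (2.0, 1.0)})
        assert ref.light("cdr_hydropathy", 1.0) == "green"
        assert ref.light("cdr_hydropathy", 1.75) == "yellow"
        assert ref.light("cdr_hydropathy", 2.5 + 1e-9) == "red"

    def test_missing_reference_omits_lights_but_reports_values(self):
        seq = AnnotatedVHH(seq_id="x", cdr1="GRTFSNYAIS", cdr2="RGGDNTAA", cdr3="VFTP")
        profile = assess(seq)
        assert profile.lights == {}
        assert profile.pI > 0
        assert profile.flags

    def test_descriptors_are_pure_functions(self):
        seq = AnnotatedVHH(seq_id="x", cdr1="GRTFSNYAIS", cdr2="RGGDNTAA", cdr3="VFTP")
        p1, p2 = assess(seq), assess(seq)
        assert (p1.pI, p1.cdr_hydropathy, p1.cdr_positive_charge) == (
            p2.pI,
            p2.cdr_hydropathy,
            p2.cdr_positive_charge,
        )
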
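"""Probe masking: exact scores vs brute-force oracles, flag logic,
threshold monotonicity, idempotent probe-set redefinition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xenostroma.chip import ChipDefinition
from xenostroma.masking import (
    longest_offtarget_match,
    redefine_probesets,
    scan_cross_hybridization,
)

from _oracles import brute_best_identity, brute_longest_match, revcomp

DNA = st.text(alphabet="ACGT", min_size=25, max_size=25)


def test_verbatim_substring_scores_full_probe_length():
    probe = "ACGTACGTACGTACGTACGTACGTA"
    assert longest_offtarget_match(probe, {"t": "GG" + probe + "TT"}) == 25


def test_empty_transcript_set_scores_zero():
    assert longest_offtarget_match("ACGTACGTACGTACGTACGTACGTA", {}) == 0


def test_shared_window_of_known_length_is_recovered():
    rng = np.random.default_rng(0)
    bases = "ACGT"
    probe = "".join(bases[i] for i in rng.integers(0, 4, 25))
    window = probe[4:20]  # 16 nt
    transcript = "".join(bases[i] for i in rng.integers(0, 4, 40)) + window + \
        "".join(bases[i] for i in rng.integers(0, 4, 40))
    got = longest_offtarget_match(probe, {"t": transcript})
    assert got == brute_longest_match(probe, {"t": transcript})
    assert got >= 16


def test_reverse_complement_matches_are_found():
    probe = "ACGTACGTACGTACGTACGTACGTA"
    t = {"t": "TT" + revcomp(probe) + "GG"}
    assert longest_offtarget_match(probe, t) == 25
    assert longest_offtarget_match(probe, t, both_strands=False) < 25


def test_malformed_probe_rejected():
    with pytest.raises(ValueError):
        longest_offtarget_match("ACGTN" * 5, {"t": "ACGT" * 10})
    with pytest.raises(ValueError):
        longest_offtarget_match("", {"t": "ACGT"})


@settings(deadline=None, max_examples=30, derandomize=True)
@given(probe=DNA, text=st.text(alphabet="ACGT", min_size=25, max_size=200))
def test_longest_match_equals_brute_force(probe, text):
    assert longest_offtarget_match(probe, {"t": text}) == brute_longest_match(probe, {"t": text})


class TestScan:
    def test_scan_matches_oracles_and_planted_truth(self, small_reference):
        """Flag decisions, match lengths and identities agree with brute
        force, and the flag set equals the planted set exactly."""
        report = scan_cross_hybridization(
            small_reference.chipdef, small_reference.human_transcripts
        )
        assert report.flagged_probes() == set(small_reference.truth.crosshyb_probes)
        human = small_reference.human_transcripts
        rng = np.random.default_rng(1)
        tbl = report.table
        sample = rng.choice(len(tbl), size=40, replace=False)
        seq_of = {
            pid: seq
            for probes in small_reference.chipdef.probesets.values()
            for pid, seq in probes
        }
        for i in sample:
            pid = tbl.index[i]
            assert tbl.loc[pid, "match_len"] == brute_longest_match(seq_of[pid], human)
            assert tbl.loc[pid, "identity"] == pytest.approx(
                brute_best_identity(seq_of[pid], human), abs=1e-12
            )

    def test_partner_transcript_contains_the_match(self, small_reference):
        report = scan_cross_hybridization(
            small_reference.chipdef, small_reference.human_transcripts
        )
        flagged = report.table[report.table["flagged"]]
        for pid, row in flagged.iterrows():
            assert row["partner"] in small_reference.human_transcripts

    def test_flag_monotonicity_in_l_min(self, small_reference):
        r15 = scan_cross_hybridization(small_reference.chipdef,
                                       small_reference.human_transcripts, l_min=15)
        r20 = scan_cross_hybridization(small_reference.chipdef,
                                       small_reference.human_transcripts, l_min=20)
        assert r20.flagged_probes() <= r15.flagged_probes()

    def test_rejection_sampled_chip_has_no_flags_against_fresh_sequences(self):
        chip = ChipDefinition({"ps1": [("p1", "ACGTACGTACGTACGTACGTACGTA")]})
        with pytest.raises(ValueError):
            scan_cross_hybridization(ChipDefinition({}), {"t": "ACGT" * 10})
        report = scan_cross_hybridization(chip, {}, l_min=15)
        assert not report.flagged_probes()

    def test_n_containing_probe_is_flagged_conservatively(self):
        chip = ChipDefinition({
            "ps1": [("pN", "ACGTNCGTACGTACGTACGTACGTA"),
                    ("p2", "TTTTGGGGCCCCAAAATTTTGGGGC")],
        })
        report = scan_cross_hybridization(chip, {"t": "ACGAA" * 30})
        assert "pN" in report.flagged_probes()


class TestRedefine:
    def _toy(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        chip = {}
        for s in range(3):
            chip[f"set{s+1}"] = [
                (f"set{s+1}:p{j}", "".join(bases[i] for i in rng.integers(0, 4, 25)))
                for j in range(11)
            ]
        return ChipDefinition(chip)

    def _report(self, chipdef, flags):
        import pandas as pd

        rows = []
        for ps, probes in chipdef.probesets.items():
            for pid, _ in probes:
                rows.append((pid, ps, 0, 0.0, pid in flags, None))
        df = pd.DataFrame(rows, columns=["probe_id", "probeset_id", "match_len",
                                         "identity", "flagged", "partner"]).set_index("probe_id")
        from xenostroma.masking import CrossHybReport

        return CrossHybReport(df, params={"l_min": 15, "i_min": 0.8})

    def test_zero_flags_is_identity(self):
        chipdef = self._toy()
        masked = redefine_probesets(chipdef, self._report(chipdef, set()), min_probes=4)
        assert masked.dropped_probesets == []
        assert masked.probesets == {
            ps: [pid for pid, _ in probes] for ps, probes in chipdef.probesets.items()
        }

    def test_hand_checked_survivor_arithmetic(self):
        """9 of 11 flagged -> 2 < 4 survivors, dropped; 2 flagged -> 9 retained."""
        chipdef = self._toy()
        flags = {f"set1:p{j}" for j in range(9)} | {"set2:p0", "set2:p1"}
        masked = redefine_probesets(chipdef, self._report(chipdef, flags), min_probes=4)
        assert [ps for ps, _ in masked.dropped_probesets] == ["set1"]
        assert len(masked.probesets["set2"]) == 9
        assert len(masked.probesets["set3"]) == 11

    def test_fully_flagged_probeset_reports_reason(self):
        chipdef = self._toy()
        flags = {f"set1:p{j}" for j in range(11)}
        masked = redefine_probesets(chipdef, self._report(chipdef, flags), min_probes=4)
        assert ("set1", "all probes cross-hybridizing") in masked.dropped_probesets

    def test_remasking_is_idempotent(self, small_reference):
        report = scan_cross_hybridization(
            small_reference.chipdef, small_reference.human_transcripts
        )
        masked1 = redefine_probesets(small_reference.chipdef, report)
        chip2 = ChipDefinition({
            ps: [(pid, dict(small_reference.chipdef.probesets[ps])[pid]) for pid in pids]
            for ps, pids in masked1.probesets.items()
        })
        report2 = scan_cross_hybridization(chip2, small_reference.human_transcripts)
        masked2 = redefine_probesets(chip2, report2)
        assert masked2.probesets == masked1.probesets
        assert masked2.dropped_probesets == []

    def test_raising_min_probes_never_recovers_a_dropped_set(self, small_reference):
        report = scan_cross_hybridization(
            small_reference.chipdef, small_reference.human_transcripts
        )
        dropped4 = {ps for ps, _ in redefine_probesets(
            small_reference.chipdef, report, min_probes=4).dropped_probesets}
        dropped6 = {ps for ps, _ in redefine_probesets(
            small_reference.chipdef, report, min_probes=6).dropped_probesets}
        assert dropped4 <= dropped6


def test_chip_tsv_roundtrip(tmp_path, small_reference):
    path = tmp_path / "chip.tsv"
    small_reference.chipdef.to_tsv(path)
    back = ChipDefinition.from_tsv(path)
    assert back.probesets == small_reference.chipdef.probesets
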
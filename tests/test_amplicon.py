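"""Editing-window rule, alignment, tabulation, stop calls and report thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cbekit as ck
from cbekit.amplicon import PositionProfile, build_editing_report
from cbekit.errors import InvalidArgument, NotApplicable

from conftest import binom_3sd


class TestEditingWindow:
    def test_gap_widened_by_one_base_each_side(self):
        ref = ck.AmpliconReference("a", "A" * 32, left_arm=(0, 12), right_arm=(20, 32))
        assert ck.derive_editing_window(ref) == (11, 21)

    def test_abutting_arms_leave_two_flanking_bases(self):
        ref = ck.AmpliconReference("a", "A" * 24, left_arm=(0, 12), right_arm=(12, 24))
        assert ck.derive_editing_window(ref) == (11, 13)

    @given(st.integers(1, 20), st.integers(0, 15), st.integers(1, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_window_length_is_gap_plus_two(self, left_len, gap, right_len):
        le = 1 + left_len
        rs = le + gap
        total = rs + right_len
        ref = ck.AmpliconReference("a", "A" * total, left_arm=(1, le),
                                   right_arm=(rs, total))
        ws, we = ck.derive_editing_window(ref)
        assert we - ws == gap + 2

    def test_overlapping_arms_rejected(self):
        ref = ck.AmpliconReference("a", "A" * 30, left_arm=(0, 12), right_arm=(10, 20))
        with pytest.raises(InvalidArgument):
            ck.derive_editing_window(ref)


class TestAlignment:
    def test_identical_read_has_no_mismatches(self, amplicon_ref):
        read = ck.SimRead("r", amplicon_ref.sequence, "I" * 90)
        aln = ck.align_amplicon_read(read, amplicon_ref)
        assert all(b == amplicon_ref.sequence[p] for p, b in aln.pairs)
        assert aln.insertions == []

    def test_single_substitution_located(self, amplicon_ref):
        seq = list(amplicon_ref.sequence)
        seq[25] = "T"
        aln = ck.align_amplicon_read(ck.SimRead("r", "".join(seq), "I" * 90),
                                     amplicon_ref)
        mismatches = [(p, b) for p, b in aln.pairs if b != amplicon_ref.sequence[p]]
        assert mismatches == [(25, "T")]

    def test_three_bp_deletion_recovered(self, amplicon_ref):
        seq = amplicon_ref.sequence[:40] + amplicon_ref.sequence[43:]
        aln = ck.align_amplicon_read(ck.SimRead("r", seq, "I" * len(seq)),
                                     amplicon_ref)
        deleted = [p for p, b in aln.pairs if b is None]
        assert len(deleted) == 3
        assert aln.has_indel_in(*amplicon_ref.window)

    def test_reverse_complement_read_realigned(self, amplicon_ref):
        rc = ck.revcomp(amplicon_ref.sequence)
        aln = ck.align_amplicon_read(ck.SimRead("r", rc, "I" * 90), amplicon_ref)
        assert aln.orientation == "-"
        assert all(b == amplicon_ref.sequence[p] for p, b in aln.pairs)

    def test_empty_read_rejected(self, amplicon_ref):
        with pytest.raises(InvalidArgument):
            ck.align_amplicon_read(ck.SimRead("r", "", ""), amplicon_ref)

    def test_junk_read_discarded_and_counted(self, amplicon_ref):
        junk = ck.SimRead("j", "A" * 90, "I" * 90)
        good = ck.SimRead("g", amplicon_ref.sequence, "I" * 90)
        kept, discarded = ck.align_reads([junk, good], amplicon_ref)
        assert len(kept) + discarded == 2
        assert discarded >= 1


class TestTabulation:
    def test_unedited_reads_give_reference_frequency_one(self, amplicon_ref):
        reads = [ck.SimRead(f"r{i}", amplicon_ref.sequence, "I" * 90)
                 for i in range(100)]
        alns, _ = ck.align_reads(reads, amplicon_ref)
        prof = ck.tabulate_positions(alns, amplicon_ref)
        for pos, base in enumerate(amplicon_ref.sequence):
            assert prof.base_frequency(pos, base) == 1.0

    def test_simulated_edit_rate_recovered(self, amplicon_ref):
        n = 2_000
        reads, _ = ck.simulate_amplicon_reads(
            amplicon_ref.sequence,
            ck.AmpliconSimProfile(substitutions={(25, "T"): 0.30},
                                  n_reads=n, seed=8))
        alns, _ = ck.align_reads(reads, amplicon_ref)
        prof = ck.tabulate_positions(alns, amplicon_ref)
        assert abs(prof.base_frequency(25, "T") - 0.30) < binom_3sd(0.30, n)

    def test_frequency_invariants(self, amplicon_ref):
        reads, _ = ck.simulate_amplicon_reads(
            amplicon_ref.sequence,
            ck.AmpliconSimProfile(substitutions={(25, "T"): 0.4},
                                  indel_rate=0.1, indel_position=40,
                                  error_rate=0.005, n_reads=500, seed=9))
        alns, _ = ck.align_reads(reads, amplicon_ref)
        prof = ck.tabulate_positions(alns, amplicon_ref)
        freqs = prof.frequencies()
        assert np.all(freqs >= 0) and np.all(freqs <= 1)
        assert np.all(freqs.sum(axis=0) <= 1 + 1e-9)


class TestStopCall:
    def _reads_with_codon(self, ref, codon, n):
        seq = list(ref.sequence)
        seq[30:33] = list(codon)
        return [ck.SimRead(f"{codon}{i}", "".join(seq), "I" * 90) for i in range(n)]

    def test_gtoa_at_second_position_yields_tag(self, amplicon_ref):
        # TGG with G->A at its middle base reads TAG: a stop
        alns, _ = ck.align_reads(self._reads_with_codon(amplicon_ref, "TAG", 10),
                                 amplicon_ref)
        res = ck.call_stop_codon_fraction(alns, amplicon_ref)
        assert res.stop_fraction == 1.0
        assert res.per_stop_counts["TAG"] == 10

    def test_unedited_reads_give_zero(self, amplicon_ref):
        alns, _ = ck.align_reads(self._reads_with_codon(amplicon_ref, "TGG", 20),
                                 amplicon_ref)
        assert ck.call_stop_codon_fraction(alns, amplicon_ref).stop_fraction == 0.0

    def test_codon_event_split_recovered(self, amplicon_ref):
        n = 4_000
        reads, _ = ck.simulate_amplicon_reads(
            amplicon_ref.sequence,
            ck.AmpliconSimProfile(codon_events=[(30, "TGA", 0.40), (30, "TAA", 0.10)],
                                  n_reads=n, seed=10))
        alns, _ = ck.align_reads(reads, amplicon_ref)
        res = ck.call_stop_codon_fraction(alns, amplicon_ref)
        assert abs(res.stop_fraction - 0.50) < binom_3sd(0.50, n)
        assert abs(res.per_stop_counts["TGA"] / res.n_informative - 0.40) \
            < binom_3sd(0.40, n)
        assert abs(res.per_stop_counts["TAA"] / res.n_informative - 0.10) \
            < binom_3sd(0.10, n)

    def test_antisense_codon_read_on_bottom_strand(self):
        # bottom-strand codon: top strand shows revcomp(TGG) = CCA
        rng = np.random.default_rng(3)
        seq = list(rng.choice(list("ACGT"), size=60))
        seq[25:28] = list("CCA")
        ref = ck.AmpliconReference("anti", "".join(seq), left_arm=(0, 10),
                                   right_arm=(45, 55), target_codon_start=25,
                                   codon_strand="antisense")
        reads = [ck.SimRead("r", "".join(seq), "I" * 60)]
        alns, _ = ck.align_reads(reads, ref)
        res = ck.call_stop_codon_fraction(alns, ref)
        assert res.stop_fraction == 0.0  # TGG is not a stop
        # edit the top-strand C opposite the codon's last G: CCA -> CTA = revcomp TAG
        seq[26] = "T"
        alns, _ = ck.align_reads([ck.SimRead("r", "".join(seq), "I" * 60)], ref)
        res = ck.call_stop_codon_fraction(alns, ref)
        assert res.per_stop_counts["TAG"] == 1

    def test_missing_codon_annotation_signalled(self):
        ref = ck.AmpliconReference("a", "A" * 30, left_arm=(0, 10), right_arm=(20, 30))
        with pytest.raises(NotApplicable):
            ck.call_stop_codon_fraction([], ref)


def _profile_with_alt(ref, pos, alt, n_alt, n_total):
    """Counts with n_alt alternate calls at pos over n_total reads, reference
    elsewhere; built directly so boundary frequencies are exact."""
    L = len(ref.sequence)
    counts = np.zeros((5, L), dtype=np.int64)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for p, b in enumerate(ref.sequence):
        counts[idx[b], p] = n_total
    counts[idx[ref.sequence[pos]], pos] = n_total - n_alt
    counts[idx[alt], pos] = n_alt
    return PositionProfile(ref.sequence, counts, np.zeros(L, dtype=np.int64), n_total)


class TestEditingReport:
    def test_outside_window_three_percent_boundary(self, amplicon_ref):
        # position 2 lies outside window [19, 61)
        below = build_editing_report(
            _profile_with_alt(amplicon_ref, 2, "T", 29, 1000), amplicon_ref,
            None, 0.0)
        at = build_editing_report(
            _profile_with_alt(amplicon_ref, 2, "T", 30, 1000), amplicon_ref,
            None, 0.0)
        assert below.flagged_outside_window == []
        assert [(e.position, e.base) for e in at.flagged_outside_window] == [(2, "T")]

    def test_unintended_base_two_percent_boundary(self, amplicon_ref):
        # C->G at a window cytosine is not the deamination product
        rep = build_editing_report(
            _profile_with_alt(amplicon_ref, 25, "G", 20, 1000), amplicon_ref,
            None, 0.0)
        assert [(e.position, e.base) for e in rep.flagged_unintended_bases] == [(25, "G")]
        rep_below = build_editing_report(
            _profile_with_alt(amplicon_ref, 25, "G", 19, 1000), amplicon_ref,
            None, 0.0)
        assert rep_below.flagged_unintended_bases == []

    def test_intended_product_in_window_not_flagged_as_unintended(self, amplicon_ref):
        rep = build_editing_report(
            _profile_with_alt(amplicon_ref, 25, "T", 300, 1000), amplicon_ref,
            None, 0.0)
        assert all(e.position != 25 or e.base != "T"
                   for e in rep.flagged_unintended_bases)

    def test_zero_edit_fixture_clean_report(self, amplicon_ref):
        reads = [ck.SimRead(f"r{i}", amplicon_ref.sequence, "I" * 90)
                 for i in range(200)]
        rep = ck.quantify_amplicon(reads, amplicon_ref)
        assert rep.flagged_outside_window == []
        assert rep.flagged_unintended_bases == []
        assert rep.indel_fraction == 0.0

    def test_raising_thresholds_never_adds_flags(self, amplicon_ref):
        prof = _profile_with_alt(amplicon_ref, 2, "T", 50, 1000)
        low = build_editing_report(prof, amplicon_ref, None, 0.0,
                                   outside_threshold=0.03, unintended_threshold=0.02)
        high = build_editing_report(prof, amplicon_ref, None, 0.0,
                                    outside_threshold=0.06, unintended_threshold=0.06)
        assert len(high.flagged_outside_window) <= len(low.flagged_outside_window)
        assert len(high.flagged_unintended_bases) <= len(low.flagged_unintended_bases)

    def test_orientation_invariance(self, amplicon_ref):
        reads, _ = ck.simulate_amplicon_reads(
            amplicon_ref.sequence,
            ck.AmpliconSimProfile(substitutions={(25, "T"): 0.2},
                                  codon_events=[(30, "TGA", 0.3)],
                                  n_reads=300, seed=12))
        fwd = ck.quantify_amplicon(reads, amplicon_ref)
        flipped = [ck.SimRead(r.name, ck.revcomp(r.sequence), r.quality[::-1])
                   for r in reads]
        rev = ck.quantify_amplicon(flipped, amplicon_ref)
        assert fwd.stop_fraction == rev.stop_fraction
        assert fwd.indel_fraction == rev.indel_fraction
        assert fwd.substitution_frequencies == rev.substitution_frequencies
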
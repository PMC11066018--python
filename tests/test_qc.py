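import numpy as np
import pytest

from synidp import qc
from synidp.codons import revcomp
from synidp.qc import (
    FilterThresholds,
    align_read_circular,
    align_read_to_library,
    classify_read,
    count_perfect_repeats,
    simulate_reads,
    summarize_library,
)

from conftest import random_dna


def dp_infix_edit_distance(query: str, target: str) -> int:
    """Full dynamic-programming oracle: edit distance with free gaps at both
    target ends (infix alignment)."""
    m, n = len(query), len(target)
    prev = np.zeros(n + 1, dtype=int)
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=int)
        cur[0] = i
        for j in range(1, n + 1):
            cost = 0 if query[i - 1] == target[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev.min())


def oracle_circular_distance(read: str, unit: str) -> int:
    target = unit * ((len(read) + 2 * len(unit)) // len(unit) + 1)
    return min(dp_infix_edit_distance(read, target),
               dp_infix_edit_distance(revcomp(read), target))


class TestAlignment:
    def test_exact_triple_copy(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        aln = align_read_circular(unit * 3, unit)
        assert aln.edit_distance == 0
        assert aln.n_perfect_repeats == 3
        assert aln.orientation == "forward"
        assert aln.phase_offset == 0

    def test_reverse_complement_flips_orientation(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        read = (unit * 3)[10:220]
        fwd = align_read_circular(read, unit)
        rev = align_read_circular(revcomp(read), unit)
        assert rev.orientation == "reverse_complement"
        assert rev.edit_distance == fwd.edit_distance == 0
        assert rev.phase_offset == fwd.phase_offset

    def test_single_substitution_in_middle_copy(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        read = list(unit * 3)
        pos = 100
        read[pos] = "A" if read[pos] != "A" else "C"
        read = "".join(read)
        aln = align_read_circular(read, unit)
        assert aln.edit_distance == 1
        assert aln.n_subs == 1
        assert aln.n_perfect_repeats == 2

    def test_phase_recovery(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        for phase in (0, 17, 44, 71):
            read = (unit * 4)[phase: phase + 200]
            aln = align_read_circular(read, unit)
            assert aln.phase_offset == phase
            assert aln.edit_distance == 0

    def test_short_read_rejected(self, gqsgl_design):
        with pytest.raises(ValueError):
            align_read_circular("ACGT", gqsgl_design.nt_seq)

    @pytest.mark.parametrize("seed", range(5))
    def test_edit_distance_matches_full_dp_oracle(self, seed,
                                                  small_reference_library):
        """Randomized reads up to 300 nt: banded aligner equals the
        exhaustive DP, including arbitrary corruption."""
        rng = np.random.default_rng(seed)
        unit = list(small_reference_library.values())[seed % 3]
        tiled = unit * 6
        start = int(rng.integers(0, 72))
        length = int(rng.integers(50, 301))
        read = list(tiled[start:start + length])
        # corrupt with a few random edits
        for _ in range(int(rng.integers(0, 8))):
            op = rng.integers(3)
            i = int(rng.integers(len(read)))
            if op == 0:
                read[i] = "ACGT"[rng.integers(4)]
            elif op == 1 and len(read) > 30:
                del read[i]
            else:
                read.insert(i, "ACGT"[rng.integers(4)])
        read = "".join(read)
        aln = align_read_circular(read, unit)
        assert aln.edit_distance == oracle_circular_distance(read, unit)

    def test_library_assignment_picks_generating_design(
            self, small_reference_library):
        for ref_id, unit in small_reference_library.items():
            read = (unit * 4)[13:213]
            aln = align_read_to_library(read, small_reference_library)
            assert aln.best_reference == ref_id

    def test_adding_errors_never_decreases_distance(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        rng = np.random.default_rng(0)
        read = list((unit * 4)[:250])
        positions = rng.choice(len(read), size=6, replace=False)
        prev_dist, prev_perfect = 0, 3
        for i in positions:
            alt = "ACGT"[rng.integers(4)]
            while alt == read[i]:
                alt = "ACGT"[rng.integers(4)]
            read[i] = alt
            aln = align_read_circular("".join(read), unit)
            assert aln.edit_distance >= prev_dist
            assert aln.n_perfect_repeats <= prev_perfect
            prev_dist = aln.edit_distance
            prev_perfect = aln.n_perfect_repeats


class TestPerfectRepeats:
    def test_counts_rotated_copies(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        rotated = unit[30:] + unit[:30]
        assert count_perfect_repeats(rotated * 3, unit) == 3

    def test_bounded_by_read_length(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        read = (unit * 5)[:300]
        assert count_perfect_repeats(read, unit) <= 300 // 72


class TestFilters:
    def test_clean_read_passes(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        read = unit * 3
        verdict = classify_read(align_read_circular(read, unit), read)
        assert verdict.passed

    def test_few_perfect_repeats(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        read = list(unit * 3)
        read[40] = "A" if read[40] != "A" else "C"
        read[150] = "A" if read[150] != "A" else "C"
        read = "".join(read)
        verdict = classify_read(align_read_circular(read, unit), read)
        assert "few_perfect_repeats" in verdict.reasons

    def test_too_short(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        read = unit[:80]
        verdict = classify_read(align_read_circular(read, unit), read)
        assert "too_short" in verdict.reasons

    def test_nonsense_stop_codon(self, gqsgl_design):
        # plant TAA in the design reading frame of a clean read
        unit = gqsgl_design.nt_seq
        read = list(unit * 3)
        read[72 + 6: 72 + 9] = list("TAA")  # third codon of the middle copy
        read = "".join(read)
        aln = align_read_circular(read, unit)
        verdict = classify_read(aln, read)
        assert "nonsense" in verdict.reasons

    def test_large_frameshift(self, gqsgl_design):
        # single deletion never compensated: frame broken to the read end
        unit = gqsgl_design.nt_seq
        read = (unit * 3)[:100] + (unit * 3)[101:216]
        aln = align_read_circular(read, unit)
        verdict = classify_read(aln, read)
        assert "large_frameshift" in verdict.reasons

    def test_compensated_frameshift_within_window_passes(self, gqsgl_design):
        # deletion followed 12 nt later by an insertion restores the frame
        unit = gqsgl_design.nt_seq
        base = unit * 3
        read = base[:100] + base[101:113] + "A" + base[113:216]
        aln = align_read_circular(read, unit)
        assert not qc._has_large_frameshift(aln, len(read), window=24)

    def test_poor_alignment(self, gqsgl_design):
        unit = gqsgl_design.nt_seq
        rng = np.random.default_rng(1)
        read = random_dna(rng, 150)
        verdict = classify_read(align_read_circular(read, unit), read)
        assert "poor_alignment" in verdict.reasons


class TestReadSimulator:
    def test_zero_error_reads_are_exact_substrings(self, small_reference_library):
        records = simulate_reads(small_reference_library, n_reads=20,
                                 read_len=200, seed=5)
        concats = {k: v * 10 for k, v in small_reference_library.items()}
        for rec in records:
            truth = dict(f.split("=") for f in rec.id.split("|")[1:])
            seq = str(rec.seq)
            if truth["orient"] == "rc":
                seq = revcomp(seq)
            assert seq in concats[truth["ref"]]

    def test_deterministic_fastq(self, small_reference_library, tmp_path):
        a, b = tmp_path / "a.fq", tmp_path / "b.fq"
        for path in (a, b):
            qc.write_fastq(simulate_reads(small_reference_library, 10,
                                          sub_rate=0.01, seed=3), path)
        assert a.read_bytes() == b.read_bytes()

    def test_mean_edit_distance_tracks_sub_rate(self, small_reference_library):
        sub_rate = 0.01
        records = simulate_reads(small_reference_library, n_reads=40,
                                 read_len=300, sub_rate=sub_rate, seed=8)
        nerr = [int(dict(f.split("=") for f in rec.id.split("|")[1:])["nerr"])
                for rec in records]
        assert np.mean(nerr) == pytest.approx(sub_rate * 300, rel=0.5)

    def test_rate_validation(self, small_reference_library):
        with pytest.raises(ValueError):
            simulate_reads(small_reference_library, 1, sub_rate=1.5)


class TestSummary:
    def test_forward_and_revcomp_buckets(self, small_reference_library):
        refs = small_reference_library
        results = []
        ids = list(refs)
        for ref_id in ids:
            read = (refs[ref_id] * 4)[:220]
            aln = align_read_to_library(read, refs)
            results.append((read, aln, classify_read(aln, read)))
        rc_read = revcomp((refs[ids[0]] * 4)[:220])
        aln = align_read_to_library(rc_read, refs)
        results.append((rc_read, aln, classify_read(aln, rc_read)))
        summary = summarize_library(results)
        assert summary["n_forward_refs"] == 3
        assert summary["n_revcomp_refs"] == 1
        assert summary["n_pass"] == 4

    def test_pass_count_matches_planted_clean_reads(self, small_reference_library):
        records = simulate_reads(small_reference_library, n_reads=25,
                                 read_len=250, seed=2)
        results = []
        for rec in records:
            seq = str(rec.seq)
            aln = align_read_to_library(seq, small_reference_library, rec.id)
            results.append((seq, aln, classify_read(aln, seq)))
        assert summarize_library(results)["n_pass"] == len(records)
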
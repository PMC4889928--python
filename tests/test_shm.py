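"""Tests of the SHM spectrum pipeline."""

import numpy as np
import pytest
from scipy import stats

from apomut.shm import (
    CloneObservation,
    MutationCall,
    Reference,
    SubstitutionSpectrum,
    build_spectrum,
    call_mutations,
    compare_spectra,
    filter_and_dedupe,
    mutation_frequency,
    positional_distribution,
    strand_bias_test,
)
from apomut.simulator import SUBSTITUTION_CLASSES
from tests.conftest import clones_from_sequences, make_reference


def _spectrum(counts: dict, n_bases: dict, n_sequences=1, n_tandems=0):
    full = {c: counts.get(c, 0) for c in SUBSTITUTION_CLASSES}
    return SubstitutionSpectrum(
        counts=full,
        total_sequenced_bases=n_bases,
        n_sequences=n_sequences,
        n_tandems=n_tandems,
    )


class TestCallMutations:
    def test_identity_clone_has_no_calls(self):
        ref = Reference("r", "ACGT")
        calls, indel = call_mutations(ref, CloneObservation("c", "s", "ACGT"))
        assert calls == [] and indel is False

    def test_single_substitution(self):
        ref = Reference("r", "ACGT")
        calls, indel = call_mutations(ref, CloneObservation("c", "s", "ACTT"))
        assert indel is False
        assert [(c.position, c.substitution) for c in calls] == [(2, "G>T")]

    def test_planted_substitutions_and_gap_recovered(self, rng):
        """Brute-force positional diff on a 300-nt clone with 7 planted
        substitutions and one gap."""
        ref = make_reference(rng, 300)
        seq = list(ref.sequence)
        planted = sorted(rng.choice(280, size=8, replace=False))
        gap_pos = planted[-1]
        expected = []
        for pos in planted[:-1]:
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            expected.append((pos, seq[pos], alt))
            seq[pos] = alt
        seq[gap_pos] = "-"
        calls, indel = call_mutations(ref, CloneObservation("c", "s", "".join(seq)))
        assert indel is True
        assert [(c.position, c.ref_base, c.alt_base) for c in calls] == expected

    def test_ambiguity_codes_are_no_calls(self):
        ref = Reference("r", "ACGT")
        calls, indel = call_mutations(ref, CloneObservation("c", "s", "ANRT"))
        assert calls == [] and indel is False

    def test_length_mismatch_rejected(self):
        ref = Reference("r", "ACGT")
        with pytest.raises(ValueError, match="length"):
            call_mutations(ref, CloneObservation("c", "s", "ACG"))

    def test_non_iupac_symbol_rejected(self):
        ref = Reference("r", "ACGT")
        with pytest.raises(ValueError, match="non-IUPAC"):
            call_mutations(ref, CloneObservation("c", "s", "AC@T"))

    def test_calls_restricted_to_analysis_window(self):
        ref = Reference("r", "ACGTACGT", analysis_window=(2, 6))
        calls, _ = call_mutations(ref, CloneObservation("c", "s", "TCGAACGA"))
        assert [(c.position) for c in calls] == [3]


class TestFilterAndDedupe:
    def test_clonal_duplicates_collapse_within_sample(self):
        ref = Reference("r", "ACGTACGTAC", cdr3_window=(8, 10))
        seqs = ["AGGTACGTAC", "AGGTACGTAC"]
        retained, _, log = filter_and_dedupe(ref, clones_from_sequences(seqs))
        assert len(retained) == 1
        assert retained[0].clone_id == "c000"  # lexicographically smallest
        assert log[0]["rule"] == "duplicate_sequence"

    def test_identical_mutations_different_cdr3_both_retained(self):
        ref = Reference("r", "ACGTACGTAC", cdr3_window=(8, 10))
        seqs = ["AGGTACGTAC", "AGGTACGTCA"]  # same call at pos 1, CDR3 differs
        retained, calls, _ = filter_and_dedupe(ref, clones_from_sequences(seqs))
        # the CDR3 positions differ from the reference too; restrict the
        # analysis window so only the shared substitution is a call
        ref2 = Reference("r", "ACGTACGTAC", analysis_window=(0, 8), cdr3_window=(8, 10))
        retained2, _, _ = filter_and_dedupe(ref2, clones_from_sequences(seqs))
        assert len(retained2) == 2

    def test_same_mutations_different_sample_both_retained(self):
        ref = Reference("r", "ACGTACGTAC", cdr3_window=(8, 10))
        clones = [
            CloneObservation("a", "mouse1", "AGGTACGTAC"),
            CloneObservation("b", "mouse2", "AGGTACGTAC"),
        ]
        retained, _, _ = filter_and_dedupe(ref, clones)
        assert len(retained) == 2

    def test_enumerated_exclusions(self):
        """10 clones: 3 planted duplicate pairs and 2 unmutated -> 5 kept."""
        ref = Reference("r", "ACGTACGTAC", cdr3_window=(8, 10))
        base = ref.sequence
        mutate = lambda s, pos, alt: s[:pos] + alt + s[pos + 1:]
        seqs = [
            mutate(base, 0, "G"), mutate(base, 0, "G"),   # pair 1
            mutate(base, 1, "T"), mutate(base, 1, "T"),   # pair 2
            mutate(base, 2, "A"), mutate(base, 2, "A"),   # pair 3
            base, base,                                    # unmutated
            mutate(base, 4, "G"), mutate(base, 5, "G"),   # unique
        ]
        retained, _, log = filter_and_dedupe(ref, clones_from_sequences(seqs))
        assert len(retained) == 5
        rules = sorted(e["rule"] for e in log)
        assert rules == ["duplicate_sequence"] * 3 + ["unmutated"] * 2

    def test_indel_clones_fully_excluded(self):
        ref = Reference("r", "ACGTACGTAC")
        seqs = ["AGGTACGTAC", "AGG-ACGTAC"]
        retained, _, log = filter_and_dedupe(ref, clones_from_sequences(seqs))
        assert [c.clone_id for c in retained] == ["c000"]
        assert log == [{"clone_id": "c001", "rule": "indel", "representative": ""}]

    def test_idempotent(self, rng):
        ref = make_reference(rng, 60)
        seqs = []
        for _ in range(12):
            s = list(ref.sequence)
            for pos in rng.choice(60, size=2, replace=False):
                s[pos] = str(rng.choice([b for b in "ACGT" if b != s[pos]]))
            seqs.append("".join(s))
        seqs += seqs[:3]  # plant duplicates
        retained, _, _ = filter_and_dedupe(ref, clones_from_sequences(seqs))
        again, _, _ = filter_and_dedupe(ref, retained)
        assert [c.clone_id for c in again] == [c.clone_id for c in retained]


class TestBuildSpectrum:
    def test_composition_corrected_percentages(self):
        """2 C>G with N_C=100 and 1 A>T with N_A=200: rates 0.02 vs 0.005
        give corrected percentages 80% and 20%."""
        sp = _spectrum(
            {"C>G": 2, "A>T": 1},
            {"A": 200, "C": 100, "G": 150, "T": 150},
        )
        assert sp.corrected_percent["C>G"] == pytest.approx(80.0, abs=1e-9)
        assert sp.corrected_percent["A>T"] == pytest.approx(20.0, abs=1e-9)

    def test_correction_is_identity_under_uniform_composition(self, rng):
        counts = {c: int(rng.integers(0, 20)) for c in SUBSTITUTION_CLASSES}
        counts["C>T"] += 1
        sp = _spectrum(counts, {b: 500 for b in "ACGT"})
        for cls in SUBSTITUTION_CLASSES:
            assert sp.corrected_percent[cls] == pytest.approx(
                sp.raw_percent[cls], abs=1e-9
            )

    def test_percentages_sum_to_100(self, rng):
        counts = {c: int(rng.integers(0, 30)) for c in SUBSTITUTION_CLASSES}
        counts["G>A"] += 1
        sp = _spectrum(counts, {"A": 100, "C": 80, "G": 120, "T": 90})
        assert sum(sp.raw_percent.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(sp.corrected_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_count_conservation_and_tandems(self):
        ref = Reference("r", "A" * 50)
        clone = CloneObservation("c", "s", "A" * 10 + "CC" + "A" * 28 + "G" + "A" * 9)
        retained, calls, _ = filter_and_dedupe(ref, [clone])
        sp = build_spectrum(ref, retained, calls)
        assert sp.n_mutations == sum(sp.counts.values()) == 3
        assert sp.n_tandems == 1  # positions 10,11 adjacent; 40 isolated

    def test_denominators_drop_no_call_positions(self):
        ref = Reference("r", "ACGT")
        clone = CloneObservation("c", "s", "NCTT")
        retained, calls, _ = filter_and_dedupe(ref, [clone])
        sp = build_spectrum(ref, retained, calls)
        assert sp.total_sequenced_bases == {"A": 0, "C": 1, "G": 1, "T": 1}

    def test_empty_input_rejected(self):
        ref = Reference("r", "ACGT")
        with pytest.raises(ValueError):
            build_spectrum(ref, [], {})


class TestMutationFrequency:
    @pytest.mark.parametrize(
        "n_mut, n_bp, expected",
        [(773, 68770, 1.12), (757, 61254, 1.24), (0, 1000, 0.0)],
    )
    def test_reported_frequencies(self, n_mut, n_bp, expected):
        assert mutation_frequency(n_mut, n_bp) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            mutation_frequency(10, 0)


class TestPositionalDistribution:
    def test_single_mutated_position(self):
        ref = Reference("r", "ACGTACGT")
        seqs = ["ACGTACGG", "ACGTACGC", "ACGTACGT"]
        clones = clones_from_sequences(seqs)
        retained, calls, _ = filter_and_dedupe(ref, clones)
        dist = positional_distribution(ref, retained, calls)
        assert dist[7] == pytest.approx(100.0)
        assert dist[:7].sum() == 0.0

    def test_matches_columnwise_tally(self, rng):
        ref = make_reference(rng, 80)
        seqs = []
        for _ in range(50):
            s = list(ref.sequence)
            for pos in rng.choice(80, size=int(rng.integers(1, 5)), replace=False):
                s[pos] = str(rng.choice([b for b in "ACGT" if b != s[pos]]))
            seqs.append("".join(s))
        retained, calls, _ = filter_and_dedupe(ref, clones_from_sequences(seqs))
        dist = positional_distribution(ref, retained, calls)
        matrix = np.array(
            [[a != b for a, b in zip(ref.sequence, c.sequence)] for c in retained]
        )
        np.testing.assert_allclose(dist, 100.0 * matrix.mean(axis=0))


class TestStrandBias:
    def test_equal_counts_give_null_result(self):
        sp = _spectrum({"G>C": 5, "C>G": 5}, {b: 100 for b in "ACGT"})
        r = strand_bias_test(sp, "pair_only")
        assert (r.chi2_statistic, r.p_value, r.ratio) == (0.0, 1.0, 1.0)

    def test_pair_only_goodness_of_fit(self):
        """(30, 10): chi2 = 20^2/40 = 10, p = chi2(1) tail ~ 0.001565."""
        sp = _spectrum({"G>C": 30, "C>G": 10}, {b: 1000 for b in "ACGT"})
        r = strand_bias_test(sp, "pair_only")
        assert r.chi2_statistic == pytest.approx(10.0, abs=1e-12)
        assert r.p_value == pytest.approx(0.001565, abs=2e-6)

    def test_printed_bias_ratio(self):
        sp = _spectrum({"G>C": 17, "C>G": 5}, {b: 1000 for b in "ACGT"})
        r = strand_bias_test(sp, "vs_sequenced")
        assert r.ratio == pytest.approx(3.4)

    def test_vs_sequenced_matches_hand_computed_table(self):
        sp = _spectrum({"G>C": 30, "C>G": 10}, {"A": 0, "C": 100, "G": 100, "T": 0})
        r = strand_bias_test(sp, "vs_sequenced")
        chi2, p, _, _ = stats.chi2_contingency(
            [[30, 70], [10, 90]], correction=False
        )
        assert r.chi2_statistic == pytest.approx(chi2)
        assert r.p_value == pytest.approx(p)

    def test_zero_counts_rejected(self):
        sp = _spectrum({"C>T": 4}, {b: 100 for b in "ACGT"})
        with pytest.raises(ValueError, match="undefined"):
            strand_bias_test(sp, "pair_only")


class TestCompareSpectra:
    def test_identical_spectra_are_null(self):
        sp = _spectrum({"C>G": 10}, {b: 100 for b in "ACGT"})
        chi2, p = compare_spectra(sp, sp, "C>G")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        """[[10,90],[30,70]] -> Pearson chi2 = 12.5 (expected cells
        20/80/20/80), p ~ 0.000407."""
        a = _spectrum({"C>G": 10}, {"A": 0, "C": 100, "G": 0, "T": 0})
        b = _spectrum({"C>G": 30}, {"A": 0, "C": 100, "G": 0, "T": 0})
        chi2, p = compare_spectra(a, b, "C>G")
        assert chi2 == pytest.approx(12.5, abs=1e-12)
        assert p == pytest.approx(0.000407, abs=2e-6)

    def test_zero_denominator_rejected(self):
        a = _spectrum({"C>G": 10}, {"A": 0, "C": 100, "G": 0, "T": 0})
        with pytest.raises(ValueError, match="zero sequenced"):
            compare_spectra(a, a, "A>T")
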
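"""Epiallele pattern tables, grouping, per-CpG means and read classes."""

import numpy as np
import pytest

from methamp import (
    MethRead,
    MixtureConfig,
    Strand,
    classify_reads,
    group_patterns,
    pattern_table,
    per_cpg_methylation,
)
from methamp.align import AlignedRead
from methamp.patterns import call_pattern
from methamp.simulate import simulate_amplicon_reads


def reads_from(patterns):
    return [MethRead(f"r{i}", p, Strand.OT) for i, p in enumerate(patterns)]


class TestCallPattern:
    def test_sequencing_error_at_cpg_gives_n(self, toy_amplicon):
        # base A at an OT CpG cytosine is neither C nor T -> uncallable
        ref_bases = {p: "T" for p in range(len(toy_amplicon.sequence))}
        ref_bases[toy_amplicon.cpg_positions[1]] = "A"
        ref_bases[toy_amplicon.cpg_positions[0]] = "C"
        aln = AlignedRead("r", Strand.OT, 0, 0.0, 0.0, ref_bases, True)
        assert call_pattern(aln, toy_amplicon).states == "MNUUU"

    def test_uncovered_cpgs_are_n(self, toy_amplicon):
        ref_bases = {toy_amplicon.cpg_positions[0]: "C"}
        aln = AlignedRead("r", Strand.OT, 0, 0.0, 0.0, ref_bases, True)
        assert call_pattern(aln, toy_amplicon).states == "MNNNN"


class TestPatternTable:
    def test_direct_counts(self):
        table = pattern_table(reads_from(["MM", "MM", "UU", "MU"]))
        assert table.total_reads == 4
        assert table.frequencies == {"MM": 0.5, "UU": 0.25, "MU": 0.25}

    def test_singleton(self):
        table = pattern_table(reads_from(["MUM"]))
        assert table.frequencies == {"MUM": 1.0}

    def test_incomplete_reads_dropped_and_tallied(self):
        table = pattern_table(reads_from(["MM", "MN", "UU"]))
        assert table.total_reads == 2 and table.n_discarded == 1

    def test_zero_retained_reads_rejected(self):
        with pytest.raises(ValueError):
            pattern_table(reads_from(["MN", "NU"]))

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(9)
        patterns = [
            "".join(rng.choice(["M", "U"], 6)) for _ in range(500)
        ]
        table = pattern_table(reads_from(patterns))
        assert sum(table.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(table.counts.values()) == table.total_reads

    def test_mixture_all_u_frequency_matches_closed_form(self, toy_amplicon):
        w_u, w_s, w_m, theta, n = 0.6, 0.3, 0.1, 0.5, 2000
        _, truth = simulate_amplicon_reads(
            toy_amplicon,
            MixtureConfig(seed=4, weights=(w_u, w_s, w_m), theta=theta, n_reads=n),
        )
        table = pattern_table(
            reads_from(truth["pattern"].tolist())
        )
        l = toy_amplicon.n_cpgs
        expected = w_u + w_s * (1 - theta) ** l  # stochastic all-U leakage
        se = np.sqrt(expected * (1 - expected) / n)
        observed = table.frequencies.get("U" * l, 0.0)
        assert abs(observed - expected) < 3 * se


class TestGroupPatterns:
    def test_hand_run_of_greedy_rule(self):
        table = pattern_table(reads_from(["MM"] * 6 + ["MU"] * 3 + ["UU"]))
        grouped = group_patterns(table, max_hamming=1)
        assert grouped.frequencies == {"MM": 0.9, "UU": 0.1}

    def test_hamming_zero_is_identity(self):
        table = pattern_table(reads_from(["MM", "MU", "UU", "MM"]))
        grouped = group_patterns(table, max_hamming=0)
        assert grouped.counts == table.counts

    def test_singleton_group(self):
        table = pattern_table(reads_from(["MUM"]))
        grouped = group_patterns(table)
        assert grouped.frequencies == {"MUM": 1.0}

    def test_top_k_pools_into_other(self):
        patterns = ["MMMM", "UUUU", "MUMU", "UMUM", "MMUU", "UUMM"]
        table = pattern_table(reads_from(patterns))
        grouped = group_patterns(table, max_hamming=0, top_k=2)
        assert set(grouped.counts) == {"MMMM", "MMUU", "other"}
        assert sum(grouped.counts.values()) == table.total_reads

    def test_conserves_frequency_and_top_group_never_shrinks(self):
        rng = np.random.default_rng(23)
        patterns = ["".join(rng.choice(["M", "U"], 5)) for _ in range(400)]
        table = pattern_table(reads_from(patterns))
        grouped = group_patterns(table, max_hamming=1)
        assert sum(grouped.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        assert max(grouped.frequencies.values()) >= max(table.frequencies.values())


class TestPerCpgMethylation:
    def test_balanced(self):
        np.testing.assert_allclose(
            per_cpg_methylation(reads_from(["MM", "UU"])), [0.5, 0.5]
        )

    def test_n_excluded_per_cpg(self):
        np.testing.assert_allclose(
            per_cpg_methylation(reads_from(["MN", "NU"])), [1.0, 0.0]
        )

    def test_uncalled_cpg_reported_missing(self):
        out = per_cpg_methylation(reads_from(["MN", "UN"]))
        assert out[0] == 0.5 and np.isnan(out[1])

    def test_mixture_closed_form(self, toy_amplicon):
        w_u, w_s, w_m, theta, n = 0.5, 0.4, 0.1, 0.5, 2000
        _, truth = simulate_amplicon_reads(
            toy_amplicon,
            MixtureConfig(seed=6, weights=(w_u, w_s, w_m), theta=theta, n_reads=n),
        )
        means = per_cpg_methylation(reads_from(truth["pattern"].tolist()))
        expected = w_m + w_s * theta
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(means - expected) < 3 * se)


class TestClassifyReads:
    def test_direct_count(self):
        s = classify_reads(reads_from(["UU", "UU", "MM", "MU"]))
        assert (s.frac_fully_unmethylated, s.frac_fully_methylated, s.frac_stochastic) == (
            0.5,
            0.25,
            0.25,
        )

    def test_degenerate_all_unmethylated(self):
        s = classify_reads(reads_from(["UU"] * 5))
        assert s.frac_fully_unmethylated == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(31)
        patterns = ["".join(rng.choice(["M", "U"], 4)) for _ in range(300)]
        s = classify_reads(reads_from(patterns))
        total = s.frac_fully_unmethylated + s.frac_fully_methylated + s.frac_stochastic
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_no_complete_reads_rejected(self):
        with pytest.raises(ValueError):
            classify_reads(reads_from(["MN"]))

    def test_mixture_weights_recovered_across_seeds(self, toy_amplicon):
        """Leakage-corrected class fractions recover the generator weights
        within +/-3 SE at n=2000 reads, across 20 seeds."""
        w_u, w_s, w_m, theta, n = 0.55, 0.40, 0.05, 0.3, 2000
        l = toy_amplicon.n_cpgs
        leak_u, leak_m = (1 - theta) ** l, theta**l
        exp_u = w_u + w_s * leak_u
        exp_m = w_m + w_s * leak_m
        exp_s = w_s * (1 - leak_u - leak_m)
        for seed in range(20):
            _, truth = simulate_amplicon_reads(
                toy_amplicon,
                MixtureConfig(seed=seed, weights=(w_u, w_s, w_m), theta=theta, n_reads=n),
            )
            s = classify_reads(reads_from(truth["pattern"].tolist()))
            for observed, expected in [
                (s.frac_fully_unmethylated, exp_u),
                (s.frac_fully_methylated, exp_m),
                (s.frac_stochastic, exp_s),
            ]:
                se = np.sqrt(expected * (1 - expected) / n)
                assert abs(observed - expected) < 3 * se
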
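"""Two-strand k-mer counting, binomial significance and pattern assembly."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from budnet.core_io import PromoterRecord
from budnet.motifs import (
    OligoStat,
    assemble_patterns,
    base_frequencies,
    canonical_oligo,
    count_oligos,
    discover_motifs,
    forward_window_count,
    n_canonical_oligos,
    oligo_significance,
    revcomp,
)

_COMP = str.maketrans("ACGT", "TGCA")


def naive_two_strand_counts(sequences: list[str], k: int) -> Counter:
    """Independent oracle: scan each strand separately, collapse canonically."""
    counts: Counter = Counter()
    for seq in sequences:
        for strand_seq in (seq, seq.translate(_COMP)[::-1]):
            for i in range(len(strand_seq) - k + 1):
                w = strand_seq[i : i + k]
                if "N" in w:
                    continue
                counts[canonical_oligo(w)] += 1
    # palindromes are seen identically on both strands: collapse to one
    for oligo in list(counts):
        if oligo == revcomp(oligo):
            counts[oligo] //= 2
    return counts


def _records(seqs: list[str]) -> list[PromoterRecord]:
    return [PromoterRecord(f"p{i}", s) for i, s in enumerate(seqs)]


class TestCounting:
    def test_homopolymer_worked_example(self):
        counts = count_oligos(_records(["AAAAAAA"]), 6)
        assert counts["AAAAAA"] == 4

    def test_palindrome_counted_once_per_window(self):
        counts = count_oligos(_records(["ACGCGT"]), 6)
        assert counts["ACGCGT"] == 1

    def test_empty_input(self):
        assert count_oligos([], 6) == Counter()

    @pytest.mark.parametrize("k", [6, 7, 8])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_oracle(self, k, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=300))
                for _ in range(5)]
        assert count_oligos(_records(seqs), k) == naive_two_strand_counts(seqs, k)

    def test_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(4)]
        flipped = [seqs[0].translate(_COMP)[::-1], *seqs[1:]]
        assert count_oligos(_records(seqs), 6) == count_oligos(_records(flipped), 6)

    def test_k_outside_range_needs_override(self):
        with pytest.raises(ValueError, match="6-8"):
            count_oligos(_records(["ACGTACGTAC"]), 4)
        assert count_oligos(_records(["ACGTA"]), 4, allow_any_k=True)


class TestSignificance:
    def test_uniform_background_worked_example(self):
        # 1000 windows/strand at word probability 4^-6: expected count
        # 2000/4096 ≈ 0.488; P(X ≥ 5) by direct binomial summation
        counts = Counter({"AAATCG": 10})  # observed two-strand sum = 10 -> 5 events
        stats = oligo_significance(
            counts, 6, n_forward_windows=1000, background=np.full(4, 0.25)
        )
        s = stats[0]
        assert s.expected == pytest.approx(2000 / 4096, rel=1e-12)
        oracle = 1.0 - sum(
            math.comb(2000, j) * (4.0**-6) ** j * (1 - 4.0**-6) ** (2000 - j)
            for j in range(5)
        )
        assert s.pval == pytest.approx(oracle, rel=1e-9)
        assert s.pval == pytest.approx(1.5e-4, rel=0.05)

    def test_zero_observed_has_pval_one(self):
        stats = oligo_significance(Counter({"AAATCG": 0}), 6, 1000,
                                   background=np.full(4, 0.25))
        assert stats[0].pval == 1.0
        assert stats[0].sig <= 0

    def test_evalue_is_pval_times_tested_count(self):
        stats = oligo_significance(Counter({"AAATCG": 12}), 6, 1000,
                                   background=np.full(4, 0.25))
        s = stats[0]
        assert s.evalue == pytest.approx(s.pval * n_canonical_oligos(6))

    def test_pval_monotone_in_observed(self):
        pvals = [
            oligo_significance(Counter({"AAATCG": 2 * n}), 6, 1000,
                               background=np.full(4, 0.25))[0].pval
            for n in range(1, 8)
        ]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_log_tail_survives_extreme_counts(self):
        stats = oligo_significance(Counter({"AAATCG": 800}), 6, 100000,
                                   background=np.full(4, 0.25))
        s = stats[0]
        assert s.log10_pval < -200
        assert math.isfinite(s.log10_pval)

    def test_canonical_count_formula(self):
        assert n_canonical_oligos(6) == (4**6 + 4**3) // 2
        assert n_canonical_oligos(7) == 4**7 // 2

    def test_background_estimated_from_input_is_symmetric(self):
        freqs = base_frequencies(_records(["AAAACC"]))
        assert freqs[0] == freqs[3] and freqs[1] == freqs[2]
        assert freqs.sum() == pytest.approx(1.0)

    def test_calibration_on_motif_free_promoters(self):
        """Without a planted motif the minimum E-value at each word length
        drops below 0.05 in at most 5% of seeded replicates (the E-value's
        family is the oligo set at one k)."""
        rng = np.random.default_rng(99)
        below = {6: 0, 7: 0, 8: 0}
        for _ in range(100):
            seqs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(20)]
            records = _records(seqs)
            for k in (6, 7, 8):
                counts = count_oligos(records, k)
                stats = oligo_significance(counts, k, forward_window_count(records, k),
                                           promoters=records)
                if stats[0].evalue < 0.05:
                    below[k] += 1
        assert all(v <= 5 for v in below.values()), below


def _stat(oligo: str, observed: int, log10_e: float) -> OligoStat:
    return OligoStat(oligo=oligo, k=len(oligo), observed=observed, expected=1.0,
                     pval=10.0 ** (log10_e - 3), evalue=10.0 ** log10_e,
                     log10_pval=log10_e - 3, palindrome=False)


class TestAssembly:
    def test_overlapping_oligos_assemble(self):
        mats = assemble_patterns([_stat("TTATCC", 10, -5), _stat("TATCCA", 8, -4)])
        assert mats[0].consensus == "TTATCCA"

    def test_single_oligo_gives_unit_matrix(self):
        mats = assemble_patterns([_stat("ACGTAA", 3, -2)])
        assert mats[0].consensus == "ACGTAA"
        np.testing.assert_allclose(mats[0].frequencies.max(axis=1), 1.0)

    def test_reverse_complement_orientation_merges(self):
        mats = assemble_patterns([_stat("TTATCC", 10, -5), _stat("TGGATA", 8, -4)])
        # TGGATA revcomp = TATCCA, overlaps TTATCC at offset 1
        assert len(mats) == 1
        assert mats[0].consensus == "TTATCCA"

    def test_unrelated_oligos_stay_separate(self):
        mats = assemble_patterns([_stat("AAAAAA", 5, -5), _stat("CCGGTC", 5, -4)])
        assert len(mats) == 2

    def test_empty_input_empty_output(self):
        assert assemble_patterns([]) == []


class TestPlantedRecovery:
    def test_planted_motif_tops_ranking_and_assembles(self, bundle):
        promoters = bundle["promoters"]
        stats, matrices = discover_motifs(promoters)
        planted = canonical_oligo("TTATCCAC")
        assert stats[0].oligo == planted
        top = matrices[0].consensus.upper()
        assert "TATCCA" in top or "TATCCA" in revcomp(top)
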
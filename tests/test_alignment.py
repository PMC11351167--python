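"""Alignment wrapper tests, including an independent exhaustive-search oracle.

The oracle scores alignments by top-down recursion over (position, position,
previous column type), exploring every monotone alignment path with affine
gap costs — written independently of the production alignment engine.
"""

from functools import lru_cache

import numpy as np
import pytest

from matsplice.alignment import (
    AlignmentParams,
    format_pairwise,
    format_tabular,
    pairwise_align,
    percent_identity,
)

NEG_INF = float("-inf")


def _scorer(params):
    if params.protein_matrix:
        from Bio.Align import substitution_matrices

        matrix = substitution_matrices.load(params.protein_matrix)
        return lambda x, y: float(matrix[x, y])
    return lambda x, y: params.match if x == y else params.mismatch


def oracle_global(a, b, params):
    sub = _scorer(params)
    open_cost = params.gap_open + params.gap_extend
    ext_cost = params.gap_extend

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        score = NEG_INF
        if i < len(a) and j < len(b):
            score = max(score, sub(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            step = ext_cost if state == "D" else open_cost
            score = max(score, step + best(i + 1, j, "D"))
        if j < len(b):
            step = ext_cost if state == "I" else open_cost
            score = max(score, step + best(i, j + 1, "I"))
        return score

    return best(0, 0, "M")


def oracle_semiglobal(a, b, params):
    """Free end gaps: at each end exactly one sequence may overhang at zero
    cost, so the best score is the best global score over substring pairs
    where at least one substring starts at its sequence start and at least
    one ends at its sequence end."""
    best = NEG_INF
    for i0 in range(len(a) + 1):
        for i1 in range(i0, len(a) + 1):
            for j0 in range(len(b) + 1):
                for j1 in range(j0, len(b) + 1):
                    if not (i0 == 0 or j0 == 0):
                        continue
                    if not (i1 == len(a) or j1 == len(b)):
                        continue
                    best = max(
                        best, oracle_global(a[i0:i1], b[j0:j1], params)
                    )
    return best


def random_seq(rng, alphabet, max_len=8):
    n = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(list(alphabet), n))


class TestExamples:
    def test_identical(self):
        res = pairwise_align("ACGT", "ACGT", AlignmentParams.nucleotide("global"))
        assert res.identities == 4 and res.aligned_columns == 4
        assert res.score == 8.0

    def test_single_gap(self):
        res = pairwise_align("ACGT", "AGT", AlignmentParams.nucleotide("global"))
        assert res.identities == 3
        assert res.aligned_query.count("-") + res.aligned_subject.count("-") == 1

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("ACGT", "MKVL")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACGT")

    def test_semiglobal_free_end_gaps(self):
        res = pairwise_align(
            "CCCCACGTCCCC", "ACGT", AlignmentParams.nucleotide("semiglobal")
        )
        assert res.score == 8.0
        assert res.aligned_columns == 4
        assert (res.query_span.start, res.query_span.end) == (5, 8)

    def test_determinism(self):
        params = AlignmentParams.nucleotide("global")
        first = pairwise_align("ACGTACGT", "AGTAGT", params)
        for _ in range(5):
            again = pairwise_align("ACGTACGT", "AGTAGT", params)
            assert again.aligned_query == first.aligned_query
            assert again.aligned_subject == first.aligned_subject


class TestOracle:
    def test_global_matches_exhaustive_search(self, rng):
        nt = AlignmentParams.nucleotide("global")
        prot = AlignmentParams.protein("global")
        for trial in range(300):
            if trial % 2:
                a = random_seq(rng, "ACGT")
                b = random_seq(rng, "ACGT")
                params = nt
            else:
                a = random_seq(rng, "ACDEFGHIKLMNPQRSTVWY")
                b = random_seq(rng, "ACDEFGHIKLMNPQRSTVWY")
                params = prot
            res = pairwise_align(a, b, params)
            assert res.score == pytest.approx(oracle_global(a, b, params)), (
                a, b, params.mode
            )

    def test_semiglobal_matches_exhaustive_search(self, rng):
        params = AlignmentParams.nucleotide("semiglobal")
        for _ in range(200):
            a = random_seq(rng, "ACGT", max_len=6)
            b = random_seq(rng, "ACGT", max_len=6)
            res = pairwise_align(a, b, params)
            assert res.score == pytest.approx(oracle_semiglobal(a, b, params))


class TestInvariants:
    def test_symmetry(self, rng):
        params = AlignmentParams.nucleotide("global")
        for _ in range(50):
            a = random_seq(rng, "ACGT", 12)
            b = random_seq(rng, "ACGT", 12)
            assert pairwise_align(a, b, params).score == pytest.approx(
                pairwise_align(b, a, params).score
            )

    def test_local_score_nonnegative(self, rng):
        params = AlignmentParams.nucleotide("local")
        for _ in range(30):
            a = random_seq(rng, "ACGT", 15)
            b = random_seq(rng, "ACGT", 15)
            assert pairwise_align(a, b, params).score >= 0

    def test_global_identical_score(self, rng):
        params = AlignmentParams.nucleotide("global")
        for _ in range(20):
            a = random_seq(rng, "ACGT", 30)
            assert pairwise_align(a, a, params).score == params.match * len(a)

    def test_gap_stripped_query_equals_span(self):
        res = pairwise_align(
            "GGACGTACGTGG", "ACGTACG", AlignmentParams.nucleotide("semiglobal")
        )
        stripped = res.aligned_query.replace("-", "")
        span = stripped[
            res.query_span.start - 1: res.query_span.end
        ]
        assert span in "GGACGTACGTGG"


class TestPercentIdentity:
    def test_identical_100(self):
        res = pairwise_align("A" * 100, "A" * 100,
                             AlignmentParams.nucleotide("global"))
        assert percent_identity(res) == 100.0

    def test_three_quarters(self):
        res = pairwise_align("ACGT", "ACGA", AlignmentParams.nucleotide("global"))
        assert percent_identity(res) == 75.0

    def test_substitution_oracle(self, rng):
        # mutate k of n positions without indels: identity is 100(n-k)/n
        from matsplice.seqcore import round_half_up

        for _ in range(20):
            n = int(rng.integers(50, 200))
            seq = list("".join(rng.choice(list("ACGT"), n)))
            k = int(rng.integers(0, n // 4))
            sites = rng.choice(n, size=k, replace=False)
            mutant = seq.copy()
            for s in sites:
                mutant[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[s]]
            res = pairwise_align("".join(seq), "".join(mutant),
                                 AlignmentParams.nucleotide("global"))
            if "-" in res.aligned_query + res.aligned_subject:
                continue  # rare co-optimal gapped alignment; oracle needs gap-free
            assert percent_identity(res) == round_half_up(100.0 * (n - k) / n, 1)

    def test_zero_denominator(self):
        res = pairwise_align("ACGT", "ACGT", AlignmentParams.nucleotide("global"))
        object.__setattr__(res, "aligned_columns", 0)
        with pytest.raises(ValueError):
            percent_identity(res)


class TestFormats:
    def test_pairwise_layout_round_numbers(self):
        res = pairwise_align("ACGT", "ACGT", AlignmentParams.nucleotide("global"))
        text = format_pairwise(res)
        assert "Query  ACGT" in text and "||||" in text

    def test_tabular_fields(self):
        res = pairwise_align("ACGT", "ACGT", AlignmentParams.nucleotide("global"))
        line = format_tabular("q", "s", res)
        fields = line.split("\t")
        assert fields[:3] == ["q", "s", "100.0"]
        assert len(fields) == 9
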
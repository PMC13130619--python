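import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fusiontriage.errors import ConfigError, InputFormatError
from fusiontriage.imbalance import (
    GROUP1_HIGHER,
    GROUP2_HIGHER,
    ExonCountVector,
    assess_fusion,
    assess_gene,
    rank_sum_test,
    read_exon_counts,
    split_exons,
)
from fusiontriage.fusion_calls import FIVE_PRIME, THREE_PRIME

from conftest import make_model


def rank_sum_oracle(a, b, alternative="two_sided"):
    """Independent brute force: enumerate all label assignments of the
    pooled mid-ranks and count those at least as extreme as observed."""
    data = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)
    ranks = stats.rankdata(data)
    t_obs = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        t = ranks[list(idx)].sum()
        total += 1
        if alternative == "greater":
            hits += t >= t_obs - 1e-9
        elif alternative == "less":
            hits += t <= t_obs + 1e-9
        else:
            hits += abs(t - mean) >= abs(t_obs - mean) - 1e-9
    return hits / total


def count_vector(counts, bp, side, gene="GX"):
    return ExonCountVector(
        gene_name=gene,
        transcript_id=f"{gene}.t1",
        exon_ranks=tuple(range(1, len(counts) + 1)),
        counts=tuple(counts),
        breakpoint_exon_rank=bp,
        retained_side=side,
    )


class TestReadExonCounts:
    HEADER = "gene\ttranscript\tcontig\tstart\tend\tstrand\tcount\n"

    def test_minus_strand_genomic_order_reversed(self, write_text):
        # minus-strand gene: rank 1 = rightmost; table rows in genomic order
        model = make_model(
            gene="GM", transcript="GM.t1", strand="-", exons=((20, 30), (0, 10))
        )
        rows = (
            "GM\tGM.t1\tchrT\t1\t10\t-\t7\n"  # genomic-left exon = rank 2
            "GM\tGM.t1\tchrT\t21\t30\t-\t9\n"  # genomic-right exon = rank 1
        )
        (vec,) = read_exon_counts(write_text(self.HEADER + rows, "c.tsv"), [model])
        assert vec.counts == (9, 7)

    def test_missing_exon_flagged_not_zero(self, write_text):
        model = make_model(gene="GX", transcript="GX.t1")
        rows = "GX\tGX.t1\tchrT\t1\t10\t+\t5\n"
        (vec,) = read_exon_counts(write_text(self.HEADER + rows, "c.tsv"), [model])
        assert vec.counts == (5, None)

    def test_empty_table(self, write_text):
        assert read_exon_counts(write_text(self.HEADER, "c.tsv"), []) == []

    def test_duplicate_exon_error(self, write_text):
        model = make_model(gene="GX", transcript="GX.t1")
        rows = "GX\tGX.t1\tchrT\t1\t10\t+\t5\nGX\tGX.t1\tchrT\t1\t10\t+\t6\n"
        with pytest.raises(InputFormatError):
            read_exon_counts(write_text(self.HEADER + rows, "c.tsv"), [model])

    def test_unannotated_exon_dropped(self, write_text, caplog):
        model = make_model(gene="GX", transcript="GX.t1")
        rows = "GX\tGX.t1\tchrT\t1\t10\t+\t5\nGX\tGX.t1\tchrT\t90\t99\t+\t6\n"
        (vec,) = read_exon_counts(write_text(self.HEADER + rows, "c.tsv"), [model])
        assert vec.counts == (5, None)


class TestSplitExons:
    def test_three_prime_29_exons_breakpoint_18(self):
        vec = count_vector([10] * 29, bp=18, side=THREE_PRIME)
        split = split_exons(vec)
        assert split.group1 == tuple(range(1, 18))
        assert split.group2 == tuple(range(18, 30))

    def test_five_prime_breakpoint_2_of_7(self):
        vec = count_vector([10] * 7, bp=2, side=FIVE_PRIME)
        split = split_exons(vec)
        assert split.group1 == (1, 2)
        assert split.group2 == (3, 4, 5, 6, 7)

    def test_all_zero_counts_both_groups_empty(self):
        vec = count_vector([0] * 5, bp=3, side=FIVE_PRIME)
        split = split_exons(vec)
        assert split.group1 == split.group2 == ()
        assert split.zero_excluded == (1, 2, 3, 4, 5)

    def test_opposite_assignment_flag(self):
        vec = count_vector([10] * 7, bp=2, side=FIVE_PRIME)
        split = split_exons(vec, breakpoint_opposite=True)
        assert split.group1 == (1,)
        assert split.group2 == (2, 3, 4, 5, 6, 7)

    def test_partition_properties(self):
        vec = count_vector([5, 0, 7, None, 9, 3], bp=3, side=THREE_PRIME)
        split = split_exons(vec)
        covered = set(split.group1) | set(split.group2) | set(
            split.zero_excluded
        ) | set(split.missing_excluded)
        assert covered == set(vec.exon_ranks)
        assert not set(split.group1) & set(split.group2)
        if split.group1 and split.group2:
            assert max(split.group1) < min(split.group2)

    def test_missing_breakpoint_error(self):
        vec = ExonCountVector(
            gene_name="G", transcript_id="t", exon_ranks=(1, 2), counts=(1, 2)
        )
        with pytest.raises(ConfigError):
            split_exons(vec)


class TestRankSumTest:
    def test_identical_groups(self):
        _, p = rank_sum_test([5, 5, 5], [5, 5, 5], mode="exact")
        assert p == 1.0

    def test_worked_example_most_extreme_split(self):
        # 2 of C(6,3)=20 assignments are as extreme -> p = 0.1
        _, p = rank_sum_test([1, 2, 3], [10, 12, 14], mode="exact")
        assert p == pytest.approx(0.1)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2], mode="exact")

    def test_bad_mode_and_alternative(self):
        with pytest.raises(ConfigError):
            rank_sum_test([1], [2], mode="bogus")
        with pytest.raises(ConfigError):
            rank_sum_test([1], [2], alternative="sideways")

    @given(
        n1=st.integers(1, 5),
        n2=st.integers(1, 5),
        seed=st.integers(0, 10_000),
        alternative=st.sampled_from(["two_sided", "greater", "less"]),
    )
    @settings(max_examples=150, deadline=None)
    def test_exact_matches_enumeration_oracle(self, n1, n2, seed, alternative):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 4, size=n1 + n2)  # heavy tie patterns
        a, b = vals[:n1], vals[n1:]
        _, p = rank_sum_test(a, b, mode="exact", alternative=alternative)
        assert p == pytest.approx(rank_sum_oracle(a, b, alternative), abs=1e-12)

    @given(n1=st.integers(2, 6), n2=st.integers(2, 6), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_two_sided_symmetric_under_swap(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 20, size=n1)
        b = rng.integers(0, 20, size=n2)
        _, p_ab = rank_sum_test(a, b, mode="exact", alternative="two_sided")
        _, p_ba = rank_sum_test(b, a, mode="exact", alternative="two_sided")
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_exact_close_to_normal_approx_tie_free(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            _, pe = rank_sum_test(a, b, mode="exact")
            _, pn = rank_sum_test(a, b, mode="normal_approx")
            assert abs(pe - pn) < 0.02

    def test_auto_mode_switches(self):
        a = list(range(11))
        b = list(range(11, 22))
        u_auto, p_auto = rank_sum_test(a, b, mode="auto")  # n=22 -> normal
        u_norm, p_norm = rank_sum_test(a, b, mode="normal_approx")
        assert (u_auto, p_auto) == (u_norm, p_norm)

    def test_u_statistic_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 50, 6)
        b = rng.integers(0, 50, 8)
        u, _ = rank_sum_test(a, b, mode="exact")
        assert u == stats.mannwhitneyu(a, b, alternative="two-sided").statistic


class TestAssessGene:
    def test_drastic_step_is_significant(self):
        counts = [10] * 17 + [1000] * 12
        vec = count_vector(counts, bp=18, side=THREE_PRIME)
        result = assess_gene(vec)
        assert result.significant
        assert result.direction == GROUP2_HIGHER
        # exact enumeration value for complete rank separation, n=29 -> auto
        # mode uses the normal approximation; p is far below alpha
        assert result.p_value < 1e-4

    def test_flat_counts_not_significant(self):
        vec = count_vector([10] * 12, bp=6, side=FIVE_PRIME)
        result = assess_gene(vec)
        assert not result.significant
        assert not result.indeterminate

    def test_small_group_indeterminate(self):
        vec = count_vector([5, 7, 8, 9, 10], bp=1, side=FIVE_PRIME)
        result = assess_gene(vec)  # group1 has a single exon
        assert result.indeterminate
        assert not result.significant
        assert "nonzero exons" in result.reason

    def test_require_direction_blocks_wrong_way(self):
        counts = [1000] * 17 + [10] * 12  # higher on the LOST side of a 3' gene
        vec = count_vector(counts, bp=18, side=THREE_PRIME)
        free = assess_gene(vec, require_direction=False)
        directed = assess_gene(vec, require_direction=True)
        assert free.significant
        assert not directed.significant
        assert directed.direction == GROUP1_HIGHER

    def test_alpha_validation(self):
        vec = count_vector([10] * 6, bp=3, side=FIVE_PRIME)
        with pytest.raises(ConfigError):
            assess_gene(vec, alpha=1.5)


class TestAssessFusion:
    @staticmethod
    def step_vec(side, bp, n, fold):
        counts = []
        for rank in range(1, n + 1):
            retained = rank <= bp if side == FIVE_PRIME else rank >= bp
            counts.append(1000 if (retained and fold) else 10)
        return count_vector(counts, bp=bp, side=side, gene=f"G{side}")

    def test_both_significant_fires(self):
        r = assess_fusion(
            self.step_vec(FIVE_PRIME, 6, 12, True),
            self.step_vec(THREE_PRIME, 18, 29, True),
        )
        assert r.overall_verdict

    def test_flat_both_sides(self):
        r = assess_fusion(
            self.step_vec(FIVE_PRIME, 6, 12, False),
            self.step_vec(THREE_PRIME, 18, 29, False),
        )
        assert not r.overall_verdict

    def test_one_significant_is_not_enough(self):
        r = assess_fusion(
            self.step_vec(FIVE_PRIME, 6, 12, True),
            self.step_vec(THREE_PRIME, 18, 29, False),
        )
        assert r.five_prime.significant and not r.three_prime.significant
        assert not r.overall_verdict

    def test_indeterminate_partner_propagates(self):
        vec5 = count_vector([5, 7, 8, 9, 10], bp=1, side=FIVE_PRIME)
        r = assess_fusion(vec5, self.step_vec(THREE_PRIME, 18, 29, True))
        assert not r.overall_verdict
        assert "indeterminate" in r.reason
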
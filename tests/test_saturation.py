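"""OV site rates, rate partitioning, and the saturation index."""

import numpy as np
import pytest

from seedcoal.saturation import (MAX_OTU, _shape_topology, iss, iss_critical,
                                 ov_scores, partition_by_rate,
                                 saturation_test)
from seedcoal.simulate import SeqSimConfig, simulate_sequences


class TestOVScores:
    @pytest.mark.parametrize("column,score", [
        ("AAC", 2),
        ("A-C", 1),
        ("AAAAA", 0),
        ("ACGT", 6),
        ("A?CN", 1),
    ])
    def test_single_column(self, column, score):
        assert ov_scores([c for c in column]) == [score]

    def test_row_permutation_invariant(self):
        rows = ["ACGT", "AGGT", "TCGA"]
        assert ov_scores(rows) == ov_scores(rows[::-1])

    def test_bounded_by_pair_count(self):
        rows = ["ACGT", "AGGT", "TCGA", "CCGT"]
        n = len(rows)
        assert all(s <= n * (n - 1) / 2 for s in ov_scores(rows))

    def test_site_subset(self):
        rows = ["AAC", "AAC", "CCC"]
        assert ov_scores(rows, sites=[2]) == [0]


class TestPartitionByRate:
    def test_even_split_by_score(self):
        slow, fast = partition_by_rate([10, 11, 12, 13], [0, 5, 2, 7])
        assert set(slow.ov_scores) == {0, 2}
        assert set(fast.ov_scores) == {5, 7}

    def test_odd_count_spills_to_slow(self):
        slow, fast = partition_by_rate(list(range(5)), [3, 1, 4, 1, 5])
        assert len(slow.site_indices) == 3
        assert len(fast.site_indices) == 2

    def test_all_tied_scores_split_by_site_index(self):
        slow, fast = partition_by_rate([4, 1, 3, 2], [9, 9, 9, 9])
        assert slow.site_indices == [1, 2]
        assert fast.site_indices == [3, 4]

    def test_slow_never_exceeds_fast(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 50, size=101).tolist()
        slow, fast = partition_by_rate(list(range(101)), scores)
        assert max(slow.ov_scores) <= min(fast.ov_scores)


class TestIss:
    def test_invariant_alignment_is_zero(self):
        value, reps = iss(["ACGT" * 25] * 8, n_mc=20, seed=0)
        assert value == pytest.approx(0.0)
        assert all(r == 0.0 for r in reps)

    def test_iid_uniform_data_is_one(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACGT"), 2000)) for _ in range(64)]
        value, _ = iss(rows, n_mc=100, seed=2)
        assert value == pytest.approx(1.0, abs=0.02)

    def test_duplicating_taxa_leaves_iss_unchanged(self):
        """Entropy depends only on the column distribution, so doubling the
        rows moves Iss only through the finite-cell bias of the saturated
        expectation, which is negligible at 64 rows."""
        t = _shape_topology(32, "symmetrical")
        aln = simulate_sequences(t, SeqSimConfig(length=1500, seed=4,
                                                 rate_multiplier=0.3))
        rows = list(aln.values()) * 2  # 64 rows
        v1, _ = iss(rows, n_mc=100, seed=5)
        v2, _ = iss(rows + rows, n_mc=100, seed=6)
        assert v2 == pytest.approx(v1, abs=0.03)

    def test_strictly_increasing_with_substitution_load(self):
        t = _shape_topology(8, "symmetrical")
        values = []
        for k, mult in enumerate([0.02, 0.1, 0.4, 1.2, 3.0]):
            aln = simulate_sequences(t, SeqSimConfig(length=3000, seed=7,
                                                     rate_multiplier=mult))
            values.append(iss(list(aln.values()), n_mc=50, seed=8 + k)[0])
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="four"):
            iss(["ACGT", "ACGT"])


class TestIssCritical:
    def test_deterministic_given_seed(self):
        a = iss_critical(8, 400, "asymmetrical", seed=3, n_sim=8)
        b = iss_critical(8, 400, "asymmetrical", seed=3, n_sim=8)
        assert a == b

    def test_symmetrical_at_least_asymmetrical(self):
        asym = iss_critical(8, 500, "asymmetrical", seed=5, n_sim=16)
        sym = iss_critical(8, 500, "symmetrical", seed=5, n_sim=16)
        assert sym >= asym

    def test_asymmetrical_non_increasing_in_taxa(self):
        values = [iss_critical(n, 500, "asymmetrical", seed=5, n_sim=20)
                  for n in (8, 16, 32)]
        assert values[0] >= values[1] >= values[2]

    def test_taxon_cap_and_minimum(self):
        with pytest.raises(ValueError, match="at least 4"):
            iss_critical(3, 100, "asymmetrical")
        assert MAX_OTU == 32


class TestSaturationTest:
    kwargs = dict(critical_kwargs={"n_sim": 6}, n_mc=40)

    def test_unsaturated_slice_verdict(self):
        t = _shape_topology(8, "symmetrical")
        aln = simulate_sequences(t, SeqSimConfig(length=1200, seed=9,
                                                 rate_multiplier=0.05))
        rep = saturation_test(list(aln.values()), seed=1, **self.kwargs)
        assert rep.verdict == "no evidence of saturation"
        assert rep.p_value_c1 < 1e-6

    def test_saturated_slice_verdict(self):
        t = _shape_topology(8, "symmetrical")
        aln = simulate_sequences(t, SeqSimConfig(length=1200, seed=10,
                                                 rate_multiplier=20.0))
        rep = saturation_test(list(aln.values()), seed=1, **self.kwargs)
        assert rep.verdict == "substantial saturation"

    def test_iss_equal_to_critical_counts_as_saturated(self):
        """'Not smaller than the critical value' is the saturation rule, so
        equality must flag saturation; exercised via the >= comparison."""
        t = _shape_topology(8, "symmetrical")
        aln = simulate_sequences(t, SeqSimConfig(length=800, seed=11,
                                                 rate_multiplier=20.0))
        rep = saturation_test(list(aln.values()), seed=2, **self.kwargs)
        assert rep.iss >= rep.iss_c1
        assert rep.verdict == "substantial saturation"

    def test_zero_variance_replicates_reported(self):
        rows = ["ACGT" * 50] * 8
        rep = saturation_test(rows, seed=3, **self.kwargs)
        assert rep.zero_variance
        assert rep.verdict == "no evidence of saturation"
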
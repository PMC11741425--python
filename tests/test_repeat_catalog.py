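import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repeatflux.repeat_catalog import (LengthDistribution, bootstrap_envelope,
                                       count_repeats, filter_contigs,
                                       median_distribution, motif_class,
                                       normalize, shuffled_baseline,
                                       truncate_low_occupancy)
from .oracle import brute_force_counts


class TestMotifClass:
    @pytest.mark.parametrize("unit,members", [
        ("A", {"A", "T"}),
        ("AC", {"AC", "CA", "GT", "TG"}),
        ("AT", {"AT", "TA"}),
        ("C", {"C", "G"}),
    ])
    def test_equivalence_classes(self, unit, members):
        cls = motif_class(unit)
        assert cls.members == frozenset(members)
        assert cls.unit == min(members)

    def test_closed_under_rotation_and_revcomp(self):
        cls = motif_class("ACG")
        for m in cls.members:
            assert m[1:] + m[0] in cls.members

    @pytest.mark.parametrize("bad", ["", "AXC", "acn"])
    def test_invalid_alphabet(self, bad):
        with pytest.raises(ValueError):
            motif_class(bad)


class TestCountRepeats:
    def test_mononucleotide_example(self, mono_class):
        dist_a, dist_b = count_repeats("AAACAA", mono_class)
        assert dist_a.counts == {3: 1, 2: 1}
        assert dist_b.counts == {1: 1}

    def test_empty_sequence(self, mono_class):
        dist_a, dist_b = count_repeats("", mono_class)
        assert dist_a.counts == {} and dist_b.counts == {}

    def test_dinucleotide_partial_copy_ignored(self):
        dist_a, _ = count_repeats("ACACAG", motif_class("AC"))
        assert dist_a.counts.get(2) == 1          # ACAC; trailing AG partial

    def test_n_breaks_runs(self, mono_class):
        dist_a, dist_b = count_repeats("AANAA", mono_class)
        assert dist_a.counts == {2: 2}
        assert dist_b.counts == {}                # N is in neither side

    def test_adjacent_member_runs_counted_separately(self, mono_class):
        dist_a, _ = count_repeats("AAATTT", mono_class)
        assert dist_a.counts == {3: 2}

    @pytest.mark.parametrize("unit", ["A", "AC", "ACG", "AAAC"])
    def test_matches_brute_force_oracle(self, unit):
        rng = np.random.default_rng(sum(map(ord, unit)))
        cls = motif_class(unit)
        for _ in range(40):
            seq = "".join(rng.choice(list("AACGT"), size=300))
            dist_a, dist_b = count_repeats(seq, cls)
            oa, ob = brute_force_counts(seq, cls.members)
            assert dist_a.counts == oa
            assert dist_b.counts == ob

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_mononucleotide_length_conservation(self, seq):
        """A-run length plus B-string length accounts for every non-N base."""
        dist_a, dist_b = count_repeats(seq, motif_class("A"))
        covered = sum(L * c for L, c in dist_a.counts.items())
        covered += sum(L * c for L, c in dist_b.counts.items())
        assert covered == sum(1 for b in seq.upper() if b != "N")

    @given(st.text(alphabet="AC", min_size=0, max_size=120))
    @settings(max_examples=150, deadline=None)
    def test_dinucleotide_no_double_counting(self, seq):
        """Dedup over frames/members never covers more bases than exist."""
        cls = motif_class("AC")
        dist_a, dist_b = count_repeats(seq, cls)
        covered = 2 * sum(L * c for L, c in dist_a.counts.items())
        covered += sum(L * c for L, c in dist_b.counts.items())
        assert covered == len(seq)


class TestPostProcessing:
    def test_normalize(self):
        dist = normalize(LengthDistribution({1: 3, 2: 1}))
        assert dist.freqs == {1: 0.75, 2: 0.25}
        assert dist.counts == {1: 3, 2: 1}        # raw counts retained

    def test_normalize_idempotent_values(self):
        dist = normalize(normalize(LengthDistribution({5: 10})))
        assert dist.freqs == {5: 1.0}

    def test_normalize_rejects_empty(self):
        with pytest.raises(ValueError):
            normalize(LengthDistribution({}))

    def test_truncation_at_first_failing_length(self):
        dist = truncate_low_occupancy(
            LengthDistribution({1: 100, 2: 40, 3: 10, 4: 50}), 30)
        assert set(dist.counts) == {1, 2}         # bin 4 dropped too
        assert dist.truncation_length == 3

    def test_truncation_no_cutoff(self):
        dist = truncate_low_occupancy(LengthDistribution({1: 100, 2: 40}), 30)
        assert set(dist.counts) == {1, 2}
        assert dist.truncation_length is None

    def test_truncation_everything(self):
        dist = truncate_low_occupancy(LengthDistribution({1: 5}), 30)
        assert dist.counts == {} and dist.truncation_length == 1

    def test_truncation_monotone_in_min_count(self):
        base = LengthDistribution({1: 90, 2: 50, 3: 20, 4: 7})
        kept = [set(truncate_low_occupancy(base, m).counts)
                for m in (5, 30, 60, 100)]
        for tighter, looser in zip(kept[1:], kept):
            assert tighter <= looser

    def test_median_identity(self):
        dists = [normalize(LengthDistribution({1: 3, 2: 1}))] * 3
        med = median_distribution(dists)
        assert med.freqs == pytest.approx({1: 0.75, 2: 0.25})

    def test_median_of_three(self):
        dists = [normalize(LengthDistribution({1: w, 2: 10 - w}))
                 for w in (1, 2, 9)]
        med = median_distribution(dists)
        assert med.freqs[1] == pytest.approx(0.2)

    def test_median_absent_bins_count_as_zero(self):
        dists = [normalize(LengthDistribution(c))
                 for c in ({1: 1, 9: 1}, {1: 1}, {1: 1})]
        med = median_distribution(dists)
        assert 9 not in med.freqs                 # median of {0.5, 0, 0} = 0

    def test_filter_contigs(self):
        contigs = {"a": "A" * 12_000, "b": "A" * 9_000}
        assert set(filter_contigs(contigs)) == {"a"}
        assert filter_contigs({"b": "A" * 9000}) == {}


class TestResampling:
    def test_bootstrap_zero_variance(self, mono_class):
        block = "AAC" * 400
        env = bootstrap_envelope({"c": block * 5}, mono_class, n=50,
                                 segment_length=len(block), seed=0)
        assert env.lower == env.point == env.upper

    def test_bootstrap_deterministic(self, mono_class):
        genome = {"c": "AACGATAAA" * 500}
        kw = dict(n=100, segment_length=900, seed=42)
        e1 = bootstrap_envelope(genome, mono_class, **kw)
        e2 = bootstrap_envelope(genome, mono_class, **kw)
        assert e1.lower == e2.lower and e1.upper == e2.upper

    def test_bootstrap_bounds_order_and_coverage(self, mono_class):
        rng = np.random.default_rng(3)
        genome = {"c": "".join(rng.choice(list("AACG"), size=60_000))}
        env = bootstrap_envelope(genome, mono_class, n=200,
                                 segment_length=5_000, seed=1)
        hits = sum(env.lower[L] <= env.point[L] <= env.upper[L]
                   for L in env.point)
        assert hits >= 0.95 * len(env.point)

    def test_bootstrap_requires_one_segment(self, mono_class):
        with pytest.raises(ValueError):
            bootstrap_envelope({"c": "ACGT" * 10}, mono_class,
                               segment_length=1_000_000)

    def test_shuffle_preserves_composition(self, mono_class):
        genome = {"c": "AAAACCGGTT" * 300}
        dist = shuffled_baseline(genome, mono_class, seed=0)
        total_units = sum(L * c for L, c in dist.counts.items())
        assert total_units == 300 * 6             # every A and T lands in a run

    def test_shuffled_geometric_ratio(self, mono_class):
        """I.i.d. A-runs decay geometrically with the A base fraction."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACG"), size=400_000,
                                 p=[0.4, 0.3, 0.3]))
        dist = shuffled_baseline({"c": seq}, mono_class, seed=9)
        ratios = [dist.counts[L + 1] / dist.counts[L] for L in (1, 2, 3)]
        assert np.allclose(ratios, 0.4, rtol=0.1)
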
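import numpy as np
import pandas as pd
import pytest

from repeatflux.rate_estimation import (LengthRateTable, MutationRecord,
                                        classify_indel, classify_substitution,
                                        context_target_counts,
                                        estimate_context_rates,
                                        estimate_indel_rates, fit_powerlaw,
                                        mask_low_coverage, poisson_ci,
                                        popstr_assign_parent,
                                        popstr_longest_run, popstr_rates,
                                        unmasked_bases)
from repeatflux.repeat_catalog import count_assembly, motif_class


def rec(pos, ref, alt, chrom="chr1"):
    return MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt)


class TestMasking:
    def test_window_without_substitutions_is_masked(self):
        contigs = {"chr1": "ACGT" * 60_000}        # 240 kb -> 3 windows
        records = [rec(50, "A", "G"), rec(150_000, "C", "T")]
        mask = mask_low_coverage(records, contigs)
        assert ("chr1", 2) in mask
        assert ("chr1", 0) not in mask and ("chr1", 1) not in mask
        assert unmasked_bases(contigs, mask) == 200_000

    def test_all_windows_hit(self):
        contigs = {"chr1": "ACGT" * 30_000}
        records = [rec(10, "A", "G"), rec(110_000, "C", "A")]
        assert mask_low_coverage(records, contigs) == set()


class TestClassifySubstitution:
    #      0123456789
    SEQ = "CCAACCACACCCGAC"

    @pytest.mark.parametrize("pos,ref,alt,expected", [
        (5, "C", "A", "lengthen"),      # A A C -> site C with one A neighbor
        (4, "A", "C", "shorten"),       # A A C, boundary A mutates away
        (8, "C", "A", "fusion"),        # A C A
        (11, "C", "A", "create_a1"),    # C C C -> new A1
        (8, "C", "G", "other"),         # B -> B never touches the motif
    ])
    def test_categories(self, pos, ref, alt, expected, mono_class):
        contigs = {"chr1": self.SEQ}
        assert classify_substitution(rec(pos, ref, alt), contigs,
                                     mono_class) == expected

    def test_fission_and_destroy(self, mono_class):
        contigs = {"chr1": "CAAAC" + "GACAG"}
        assert classify_substitution(rec(3, "A", "C"), contigs,
                                     mono_class) == "fission"
        assert classify_substitution(rec(9, "A", "G"), contigs,
                                     mono_class) == "destroy_a1"

    def test_contig_edge_is_other(self, mono_class):
        contigs = {"chr1": "AACC"}
        assert classify_substitution(rec(1, "A", "C"), contigs,
                                     mono_class) == "other"

    def test_target_counts_are_length_independent(self, mono_class):
        """The six categories depend only on the three-unit context, never
        on the length of the repeat the site belongs to."""
        # one A5 and one A2 run: both contribute exactly 2 shorten targets
        contigs = {"chr1": "CCAAAAACCAACC"}
        counts = context_target_counts(contigs, mono_class)
        assert counts["shorten"] == 4
        assert counts["fission"] == 3              # only interior of the A5


class TestClassifyIndel:
    GENOME = {"chr1": "GCC" + "A" * 8 + "CCGGC" + "A" * 3 + "GGCAG"}

    def test_expansion(self, mono_class):
        call = classify_indel(rec(4, "A", "AA"), self.GENOME, mono_class)
        assert (call.type, call.units, call.parental_length) == \
            ("expansion", 1, 8)

    def test_non_motif_insertion(self, mono_class):
        call = classify_indel(rec(6, "A", "AG"), self.GENOME, mono_class)
        assert (call.type, call.parental_length) == ("non_motif_insertion", 8)

    def test_contraction_two_units(self, mono_class):
        call = classify_indel(rec(4, "AAA", "A"), self.GENOME, mono_class)
        assert (call.type, call.units, call.parental_length) == \
            ("contraction", -2, 8)

    def test_left_alignment_attributes_to_run(self, mono_class):
        # deletion written at the right edge of the A8 run
        call = classify_indel(rec(10, "AA", "A"), self.GENOME, mono_class)
        assert (call.type, call.parental_length) == ("contraction", 8)

    def test_b_deletion(self, mono_class):
        call = classify_indel(rec(12, "GG", "G"), self.GENOME, mono_class)
        assert call.type == "b_deletion"


class TestPopstr:
    def test_longest_run_in_interval(self, mono_class):
        contigs = {"c": "C" + "A" * 7 + "G" + "A" * 12 + "C"}
        assert popstr_longest_run(contigs, "c", 0, 22, mono_class) == 12

    def test_no_motif_copy(self, mono_class):
        assert popstr_longest_run({"c": "CGCGCG"}, "c", 0, 6,
                                  mono_class) == 0

    def test_assign_parent_minimizes_difference(self):
        assert popstr_assign_parent(11, [10, 14, 9, 15]) == 10

    def test_assign_parent_tie_prefers_smaller(self):
        assert popstr_assign_parent(11, [12, 10, 25, 30]) == 10

    def test_assign_parent_respects_phase(self):
        assert popstr_assign_parent(11, [20, 25, 11, 12],
                                    phase="maternal") == 20

    def test_rate_arithmetic(self):
        loci = pd.DataFrame([{"locus_id": 0, "chrom": "c", "start": 0,
                              "end": 12, "motif": "A", "ref_length": 12,
                              "passing_trios": 100}])
        events = pd.DataFrame([
            {"locus_id": 0, "proband_length": 13, "parental_length": 12,
             "phase": None},
            {"locus_id": 0, "proband_length": 13, "parental_length": 12,
             "phase": None}])
        table = popstr_rates(events, loci, max_length=12)
        assert table.targets[11] == 200.0          # 2 alleles x 100 trios
        assert table.per_repeat("insertion")[11] == pytest.approx(0.01)
        assert table.per_target("insertion")[11] == pytest.approx(0.01 / 12)

    def test_zero_trios_missing(self):
        loci = pd.DataFrame([{"locus_id": 0, "chrom": "c", "start": 0,
                              "end": 12, "motif": "A", "ref_length": 12,
                              "passing_trios": 0}])
        table = popstr_rates(pd.DataFrame(columns=["locus_id",
                                                   "proband_length",
                                                   "parental_length",
                                                   "phase"]),
                             loci, max_length=12)
        assert np.isnan(table.per_repeat("insertion")[11])


class TestPoissonCI:
    def test_zero_count_degenerate(self):
        lo, hi = poisson_ci(np.array([0.0]), np.array([100.0]), seed=0)
        assert lo[0] == hi[0] == 0.0

    def test_large_count_normal_scale(self):
        lo, hi = poisson_ci(np.array([100.0]), np.array([1.0]), seed=0)
        assert 100 - 3 * 10 < lo[0] < 100 - 10
        assert 100 + 10 < hi[0] < 100 + 3 * 10

    def test_seed_reproducible(self):
        args = (np.array([7.0, 30.0]), np.array([10.0, 10.0]))
        assert np.array_equal(poisson_ci(*args, seed=5),
                              poisson_ci(*args, seed=5))


class TestPowerLaw:
    @staticmethod
    def table_from_rates(lengths, rates, targets=1e9):
        ev = {"insertion": np.asarray(rates) * lengths * targets}
        return LengthRateTable(lengths=np.asarray(lengths, dtype=float),
                               events=ev,
                               targets=np.full(len(lengths), targets))

    def test_exact_powerlaw_recovered(self):
        lengths = np.arange(10, 25)
        rates = 1e-7 * (lengths / 9.0) ** 2.5
        table = self.table_from_rates(lengths, rates)
        fit = fit_powerlaw(table, "insertion", (12, 19))
        assert fit.slope == pytest.approx(2.5, abs=1e-9)

    def test_constant_rate_zero_slope(self):
        lengths = np.arange(10, 25)
        table = self.table_from_rates(lengths, np.full(15, 3e-7))
        fit = fit_powerlaw(table, "insertion", (12, 19))
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_multiplier_over_reference(self):
        lengths = np.arange(10, 25)
        rates = 1e-7 * (lengths / 9.0) ** 2.0
        table = self.table_from_rates(lengths, rates)
        fit = fit_powerlaw(table, "insertion", (12, 19), rate8=5e-8)
        assert fit.m == pytest.approx(2.0, rel=1e-6)
        assert fit.m_range[0] <= fit.m <= fit.m_range[1]

    def test_insufficient_points(self):
        table = self.table_from_rates(np.array([12, 13]), [1e-7, 1e-7])
        with pytest.raises(ValueError):
            fit_powerlaw(table, "insertion", (12, 19))

    def test_noisy_slope_within_wide_ci(self):
        rng = np.random.default_rng(1)
        lengths = np.arange(12, 20)
        true = 2e-7 * (lengths / 9.0) ** 2.2
        targets = 5e8
        covered = 0
        for _ in range(30):
            ev = rng.poisson(true * lengths * targets).astype(float)
            table = LengthRateTable(lengths=lengths.astype(float),
                                    events={"insertion": ev},
                                    targets=np.full(8, targets))
            fit = fit_powerlaw(table, "insertion", (12, 19))
            covered += fit.slope_ci[0] <= 2.2 <= fit.slope_ci[1]
        assert covered >= 29        # 99.9% CI rarely misses


class TestRecoverySmoke:
    def test_context_and_indel_rates_recover_truth(self, small_genome,
                                                   boosted_truth,
                                                   mono_class):
        from repeatflux.synthetic_data import generate_trio_table
        records = generate_trio_table(small_genome, boosted_truth,
                                      n_offspring=150, seed=5)
        mask = mask_low_coverage(records, small_genome)
        est = estimate_context_rates(records, small_genome, mono_class,
                                     150, mask)
        for cat in ("lengthen", "shorten", "fission", "create_a1"):
            truth = getattr(boosted_truth.context, cat)
            assert getattr(est.rates, cat) == pytest.approx(truth, rel=0.6)
        dist, _ = count_assembly(small_genome, mono_class)
        table = estimate_indel_rates(records, small_genome, mono_class, 150,
                                     dist, mask, max_length=8)
        ratio = table.per_target("expansion") / boosted_truth.denovo_eps
        assert np.nanmedian(ratio) == pytest.approx(1.0, abs=0.35)
        assert table.plus_minus_one_fraction("expansion") == 1.0

    def test_doubling_offspring_halves_rates(self, small_genome, mono_class,
                                             boosted_truth):
        from repeatflux.synthetic_data import generate_trio_table
        records = generate_trio_table(small_genome, boosted_truth,
                                      n_offspring=100, seed=9)
        est1 = estimate_context_rates(records, small_genome, mono_class, 100)
        est2 = estimate_context_rates(records, small_genome, mono_class, 200)
        assert est2.rates.shorten == pytest.approx(est1.rates.shorten / 2)

    def test_zero_records_zero_rates(self, small_genome, mono_class):
        est = estimate_context_rates([], small_genome, mono_class, 10)
        assert est.rates.lengthen == 0 and est.rates.fission == 0
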
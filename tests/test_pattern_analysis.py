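"""Size classes, pooled group rates, regressions and age analysis."""

import numpy as np
import pytest

from ystr.haplotype_stats import FrequencyTable
from ystr.io_qc import Allele
from ystr.mutation_stats import MutationEvent, summaries_from_counts
from ystr.pattern_analysis import (
    LocusPatternRecord,
    age_analysis,
    average_repeat_number,
    classify_allele_sizes,
    direction_by_size,
    rates_by_group,
    regress_rate_on_repeats,
)
from ystr.refdata import load_mutation_counts


def A(x):
    return Allele.parse(str(x))


class TestSizeClasses:
    def test_four_equifrequent_alleles(self):
        ft = FrequencyTable("X", {A(a): 1 for a in (10, 11, 12, 13)}, 4)
        assert classify_allele_sizes(ft) == {
            A(10): "short", A(11): "moderate", A(12): "moderate", A(13): "long",
        }

    def test_single_allele_is_moderate(self):
        ft = FrequencyTable("X", {A(12): 5}, 5)
        assert classify_allele_sizes(ft) == {A(12): "moderate"}

    def test_invariant_to_monotone_shift(self):
        counts = {A(a): c for a, c in [(10, 3), (11, 5), (12, 8), (13, 2)]}
        shifted = {A(a + 7): c for a, c in [(10, 3), (11, 5), (12, 8), (13, 2)]}
        c1 = classify_allele_sizes(FrequencyTable("X", counts, 18))
        c2 = classify_allele_sizes(FrequencyTable("X", shifted, 18))
        assert [c1[A(a)] for a in (10, 11, 12, 13)] == [
            c2[A(a + 7)] for a in (10, 11, 12, 13)
        ]

    def test_boundary_allele_goes_to_majority_class(self):
        # allele 11 spans [0.2, 0.8): most of its mass is moderate
        ft = FrequencyTable("X", {A(10): 2, A(11): 6, A(12): 2}, 10)
        assert classify_allele_sizes(ft)[A(11)] == "moderate"

    def test_class_masses_near_targets(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            alleles = {A(a): int(c) for a, c in
                       enumerate(rng.integers(1, 50, size=8), start=10)}
            total = sum(alleles.values())
            ft = FrequencyTable("X", alleles, total)
            classes = classify_allele_sizes(ft)
            freqs = {a: c / total for a, c in alleles.items()}
            mass = {"short": 0.0, "moderate": 0.0, "long": 0.0}
            for a, cls in classes.items():
                mass[cls] += freqs[a]
            biggest = max(freqs.values())
            assert abs(mass["short"] - 0.25) <= biggest + 1e-12
            assert abs(mass["moderate"] - 0.50) <= 2 * biggest + 1e-12
            assert abs(mass["long"] - 0.25) <= biggest + 1e-12


class TestPooledGroupRates:
    def test_unit_length_groups_from_reference_counts(self, registry):
        summaries = summaries_from_counts(load_mutation_counts())
        df = rates_by_group(summaries, registry, by="unit_length").set_index("group")
        assert df.loc[3, "rate_x1000"] == 1.8
        assert df.loc[4, "rate_x1000"] == 4.1
        assert df.loc[5, "rate_x1000"] == 1.5
        assert df.loc[6, "rate_x1000"] == 0.4

    def test_trinucleotide_group_accounting(self, registry):
        summaries = summaries_from_counts(load_mutation_counts())
        df = rates_by_group(summaries, registry, by="unit_length").set_index("group")
        assert df.loc[3, "mutations"] == 14
        assert df.loc[3, "transfers"] == 7644

    def test_pooled_rate_bounded_by_member_rates(self, registry):
        summaries = summaries_from_counts(load_mutation_counts())
        df = rates_by_group(summaries, registry, by="motif_class")
        for row in df.itertuples(index=False):
            members = [
                s.rate for s in summaries
                if registry.get_locus(s.locus).motif_class == row.group
            ]
            assert min(members) - 1e-15 <= row.rate <= max(members) + 1e-15

    def test_single_group_equals_overall_rate(self, registry):
        summaries = summaries_from_counts(load_mutation_counts())
        df = rates_by_group(summaries, registry, by="rm_flag")
        pooled = df["mutations"].sum() / df["transfers"].sum()
        assert pooled == pytest.approx(356 / 104_468)

    def test_unknown_grouping_rejected(self, registry):
        with pytest.raises(ValueError):
            rates_by_group([], registry, by="zodiac")


class TestRegression:
    def _records(self, slope, intercept, noise, rng, n=20):
        xs = rng.uniform(10, 40, size=n)
        ys = slope * xs + intercept + rng.normal(0, noise, size=n)
        return [
            LocusPatternRecord(f"L{i}", x, max(y, 0) / 1000, "simple", 4, False)
            for i, (x, y) in enumerate(zip(xs, ys))
        ]

    def test_collinear_records_r2_one(self):
        rng = np.random.default_rng(0)
        recs = self._records(0.3, -2, 0.0, rng)
        out = regress_rate_on_repeats(recs)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert out["slope"] == pytest.approx(0.3, abs=1e-6)

    def test_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(200):
            recs = self._records(0.25, 1.0, 0.5, rng)
            out = regress_rate_on_repeats(recs)
            xs = np.array([r.avg_repeat_number for r in recs])
            ys = np.array([r.rate * 1000 for r in recs])
            from scipy.stats import linregress

            se = linregress(xs, ys).stderr
            if abs(out["slope"] - 0.25) <= 2 * se:
                hits += 1
        assert hits >= 180  # ~95% coverage expected

    def test_exclude_rm_drops_flagged_loci(self):
        rng = np.random.default_rng(2)
        recs = self._records(0.3, 0.0, 0.0, rng, n=10)
        recs += [LocusPatternRecord("RM1", 30.0, 0.02, "complex", 4, True)]
        full = regress_rate_on_repeats(recs)
        no_rm = regress_rate_on_repeats(recs, exclude_rm=True)
        assert no_rm["n_loci"] == 10
        assert no_rm["r_squared"] > full["r_squared"]

    def test_degenerate_predictor_rejected(self):
        recs = [LocusPatternRecord(f"L{i}", 15.0, 0.003, "simple", 4, False)
                for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            regress_rate_on_repeats(recs)

    def test_average_repeat_number_bounds(self):
        ft = FrequencyTable("X", {A(10): 1, A(14): 3}, 4)
        avg = average_repeat_number(ft)
        assert 10 <= avg <= 14 and avg == pytest.approx(13.0)


def _event(locus, f, s, ped="P1"):
    return MutationEvent.from_alleles(ped, locus, A(f), A(s))


class TestDirectionBySize:
    CLS = {"DYS19": {A(12): "short", A(14): "moderate", A(16): "long"}}

    def test_polarized_fixture_detects_association(self):
        events = [_event("DYS19", 12, 13, f"P{i}") for i in range(12)] + [
            _event("DYS19", 16, 15, f"Q{i}") for i in range(12)
        ]
        out = direction_by_size(events, self.CLS, seed=0)
        table = out["table"].set_index("size_class")
        assert table.loc["short", "gains"] == 12
        assert table.loc["long", "losses"] == 12
        assert out["p_exact"] < 0.01

    def test_margins_conserve_totals(self):
        events = [_event("DYS19", 12, 13), _event("DYS19", 14, 13),
                  _event("DYS19", 16, 17), _event("DYS19", 16, 15)]
        out = direction_by_size(events, self.CLS, seed=0)
        assert out["table"]["gains"].sum() == 2
        assert out["table"]["losses"].sum() == 2

    def test_null_fixture_large_p(self):
        # perfectly symmetric gains/losses in every class
        events = []
        for i in range(10):
            for f, s in [(12, 13), (12, 11), (16, 17), (16, 15)]:
                events.append(_event("DYS19", f, s, f"P{i}{f}{s}"))
        out = direction_by_size(events, self.CLS, seed=1)
        assert out["p_chi2"] > 0.9

    def test_deterministic_given_seed(self):
        events = [_event("DYS19", 12, 13, f"P{i}") for i in range(6)] + [
            _event("DYS19", 14, 13, f"Q{i}") for i in range(4)
        ] + [_event("DYS19", 16, 15, f"R{i}") for i in range(5)]
        a = direction_by_size(events, self.CLS, seed=7)
        b = direction_by_size(events, self.CLS, seed=7)
        assert a["p_exact"] == b["p_exact"]


class TestAgeAnalysis:
    def _pairs(self, make_pair, ages):
        return [
            make_pair({"DYS19": "14"}, {"DYS19": "14"}, pedigree_id=f"P{i}", age=a)
            for i, a in enumerate(ages)
        ]

    def test_age_moments(self, make_pair):
        pairs = self._pairs(make_pair, [20, 25, 30, 35])
        out = age_analysis(pairs, [], transfers_per_pair=41)
        assert out.mean_age == pytest.approx(27.5)
        assert out.median_age == pytest.approx(27.5)
        assert out.n_pairs_with_age == 4

    def test_same_age_everywhere_welch_na(self, make_pair):
        pairs = self._pairs(make_pair, [25] * 6)
        events = [_event("DYS19", 14, 15, "P0"), _event("DYS19", 14, 15, "P1")]
        out = age_analysis(pairs, events, transfers_per_pair=41)
        assert out.welch_p is None

    def test_interval_rates_and_missing_age_exclusion(self, make_pair):
        pairs = self._pairs(make_pair, [18, 25, 35, 45])
        pairs.append(
            make_pair({"DYS19": "14"}, {"DYS19": "15"}, pedigree_id="X", age=None)
        )
        events = [_event("DYS19", 14, 15, "P3")]
        out = age_analysis(pairs, events, transfers_per_pair=41)
        assert out.n_pairs_excluded == 1
        table = out.interval_table.set_index("age_interval")
        assert table.loc[">40", "mutations"] == 1
        assert table.loc["<20", "mutations"] == 0

    def test_null_simulation_slope_near_zero(self, make_pair):
        # age-independent mutations: slope should not be distinguishable
        # from zero in the bulk of replicates
        rng = np.random.default_rng(3)
        from scipy.stats import linregress

        hits = 0
        reps = 60
        for rep in range(reps):
            ages = rng.integers(20, 41, size=300)
            pairs = self._pairs(make_pair, list(map(float, ages)))
            events = [
                _event("DYS19", 14, 15, f"P{i}")
                for i in np.nonzero(rng.random(300) < 0.15)[0]
            ]
            out = age_analysis(pairs, events, transfers_per_pair=41)
            by_age = {}
            for p in pairs:
                by_age.setdefault(p.father_age, []).append(p.pedigree_id)
            ids = {e.pedigree_id for e in events}
            xs = sorted(by_age)
            ys = [sum(pid in ids for pid in by_age[a]) / (len(by_age[a]) * 41) * 1000
                  for a in xs]
            se = linregress(xs, ys).stderr
            if abs(out.slope) < 2 * se:
                hits += 1
        assert hits >= 0.85 * reps
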
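import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from casbind.stats import (
    apply_preprocessing_filters,
    average_replicates,
    context_effect_summary,
    efficiency_split,
    guideseq_filter,
    indel_frequency,
    logo_frequencies,
    pam_pattern_group_stats,
    scaffold_structure_filter,
    select_min_read_threshold,
    similarity_aware_split,
    sliding_condition_summary,
    structure_distances,
    sweet_spot_interval,
)


class TestIndelFrequency:
    @pytest.mark.parametrize("indel,total,expected",
                             [(0, 50, 0.0), (10, 40, 25.0), (40, 40, 100.0)])
    def test_values(self, indel, total, expected):
        assert indel_frequency(indel, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            indel_frequency(0, 0)


class TestMinReadThreshold:
    @staticmethod
    def day_frame(freqs, totals):
        n = len(freqs)
        return pd.DataFrame({
            "gRNA_id": ["g"] * n, "pam_context": [f"c{i}" for i in range(n)],
            "barcode": ["b"] * n, "indel_frequency": freqs, "total_reads": totals,
        })

    def test_noise_below_50_reads(self, rng):
        n = 120
        totals = rng.integers(5, 200, size=n)
        base = np.linspace(1, 90, n)
        f6 = np.where(totals >= 50, base, rng.uniform(0, 90, size=n))
        f10 = np.where(totals >= 50, base, rng.uniform(0, 90, size=n))
        d6 = self.day_frame(f6, totals)
        d10 = self.day_frame(f10, totals)
        chosen = select_min_read_threshold(d6, d10)
        # grid-search oracle
        best_p, best_n = math.inf, None
        for t in range(0, 201, 5):
            keep = totals >= t
            if keep.sum() < 3:
                continue
            p = sps.spearmanr(f6[keep], f10[keep]).pvalue
            if not math.isnan(p) and p < best_p:
                best_p, best_n = p, t
        assert chosen == best_n
        assert chosen >= 50

    def test_perfect_correlation_ties_to_zero(self):
        f = np.linspace(1, 50, 30)
        d = self.day_frame(f, np.full(30, 150))
        assert select_min_read_threshold(d, d) == 0

    def test_all_skipped_raises(self):
        d = self.day_frame([1.0, 2.0], [10, 10])
        with pytest.raises(ValueError):
            select_min_read_threshold(d, d)


class TestAverageReplicates:
    @staticmethod
    def records(rows):
        return pd.DataFrame(rows, columns=["gRNA_id", "pam_context", "treatment",
                                           "barcode", "day", "indel_frequency"])

    def test_identical_replicates(self):
        df = self.records([("g", "AGGT", "Dox-", "b1", d, 42.0) for d in (6, 10)])
        out = average_replicates(df)
        assert out.loc[0, "indel_frequency"] == 42.0
        assert out.loc[0, "normalised_sd"] == 0.0

    def test_two_barcodes_arithmetic_oracle(self):
        df = self.records(
            [("g", "AGGT", "Dox-", "b1", 6, 40.0), ("g", "AGGT", "Dox-", "b2", 6, 60.0)]
        )
        out = average_replicates(df)
        assert out.loc[0, "indel_frequency"] == pytest.approx(50.0)
        assert out.loc[0, "normalised_sd"] == pytest.approx(np.std([40.0, 60.0]) / 50.0)

    def test_days_averaged_before_barcodes(self):
        df = self.records(
            [("g", "AGGT", "Dox-", "b1", 6, 10.0), ("g", "AGGT", "Dox-", "b1", 10, 30.0),
             ("g", "AGGT", "Dox-", "b2", 6, 40.0)]
        )
        out = average_replicates(df)
        # b1 day-mean 20, b2 40 -> barcode mean 30
        assert out.loc[0, "indel_frequency"] == pytest.approx(30.0)


class TestPreprocessingFilters:
    @staticmethod
    def table():
        recs = pd.DataFrame({
            "gRNA_id": [f"g{i}" for i in range(10)],
            "pam_context": ["AGGT"] * 10,
            "indel_frequency": [0.5, 2.0, 1.99, 50, 80, 3, 90, 1.2, 2.01, 10],
        })
        spec = pd.DataFrame({"gRNA_id": [f"g{i}" for i in range(10)],
                             "crisprspec": [9, 9, 9, 4.9, 5.0, 9, 2, 9, 9, 9]})
        return recs, spec

    def test_low_spec_removed_with_reason(self):
        recs, spec = self.table()
        kept, removed = apply_preprocessing_filters(recs, spec)
        assert set(removed[removed.reason == "low_specificity"]["gRNA_id"]) == {"g3", "g6"}

    def test_boundary_exact_2pct_retained(self):
        recs, spec = self.table()
        kept, _ = apply_preprocessing_filters(recs, spec)
        assert "g1" in set(kept["gRNA_id"])  # 2.0 retained (strict <)
        assert "g8" in set(kept["gRNA_id"])  # 2.01 retained

    def test_survivors_equal_comprehension_oracle(self):
        recs, spec = self.table()
        kept, removed = apply_preprocessing_filters(recs, spec)
        spec_of = dict(zip(spec.gRNA_id, spec.crisprspec))
        expected = {
            r.gRNA_id
            for r in recs.itertuples()
            if spec_of[r.gRNA_id] >= 5 and r.indel_frequency >= 2.0
        }
        assert set(kept["gRNA_id"]) == expected
        assert len(kept) + len(removed) == len(recs)


class TestScaffoldFilter:
    def test_perfect_structure_distance_zero(self):
        n = 6
        probs = np.zeros((n, n))
        optimal = {(0, 5), (1, 4)}
        for i, j in optimal:
            probs[i, j] = probs[j, i] = 1.0
        paired, unpaired = structure_distances(probs, optimal)
        assert paired == 0.0 and unpaired == 0.0

    def test_hand_built_euclidean(self):
        n = 4
        probs = np.zeros((n, n))
        probs[0, 3] = probs[3, 0] = 0.7
        probs[1, 2] = probs[2, 1] = 0.2  # positions 1,2 unpaired in optimal
        paired, unpaired = structure_distances(probs, {(0, 3)})
        assert paired == pytest.approx(0.3)
        assert unpaired == pytest.approx(math.sqrt(2 * 0.2**2))

    def test_threshold_mode_341(self):
        dist = pd.Series({"a": 3.40, "b": 3.42, "c": 0.1})
        kept, removed = scaffold_structure_filter(dist, mode="threshold", cutoff=3.41)
        assert list(removed) == ["b"]
        assert set(kept) == {"a", "c"}

    def test_quantile_mode_top5pct(self, rng):
        dist = pd.Series(rng.uniform(0, 1, size=200))
        kept, removed = scaffold_structure_filter(dist, mode="quantile", quantile=0.95)
        assert 0 < len(removed) <= 10


class TestSimilaritySplit:
    def test_identical_items_co_assigned(self):
        items = ["A" * 30, "A" * 30, "C" * 30]
        train, test = similarity_aware_split(items, 0.4)
        side = {i: ("test" if i in test else "train") for i in range(3)}
        assert side[0] == side[1]

    def test_all_distant_fraction_respected(self, rng):
        items = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(40)]
        # random 30-mers are essentially always >3 apart
        train, test = similarity_aware_split(items, 0.25)
        assert abs(len(test) - 10) <= 1

    def test_components_equal_allpairs_oracle_and_no_leakage(self, rng):
        base = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(10)]
        items = []
        for b in base:
            items.append(b)
            for _ in range(int(rng.integers(0, 4))):
                mutated = list(b)
                for p in rng.choice(30, size=int(rng.integers(1, 4)), replace=False):
                    mutated[p] = rng.choice(list("ACGT"))
                items.append("".join(mutated))
        train, test = similarity_aware_split(items, 0.3)

        def ham(a, b):
            return sum(x != y for x, y in zip(a, b))

        for i in train:
            for j in test:
                assert ham(items[i], items[j]) >= 4
        # brute-force components via networkx-free transitive closure
        n = len(items)
        adj = {i: {j for j in range(n) if j != i and ham(items[i], items[j]) <= 3}
               for i in range(n)}
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            comps.append(comp)
        for comp in comps:
            sides = {("test" if i in set(test) else "train") for i in comp}
            assert len(sides) == 1


class TestEfficiencySplit:
    def test_n10_gives_groups_of_2(self):
        df = pd.DataFrame({"indel_frequency": range(10)})
        high, low = efficiency_split(df)
        assert len(high) == len(low) == 2
        assert set(high["indel_frequency"]) == {9, 8}
        assert set(low["indel_frequency"]) == {0, 1}

    def test_all_equal_deterministic(self):
        df = pd.DataFrame({"indel_frequency": [5.0] * 10, "tag": range(10)})
        h1, l1 = efficiency_split(df)
        h2, l2 = efficiency_split(df)
        assert list(h1["tag"]) == list(h2["tag"])
        assert list(l1["tag"]) == list(l2["tag"])

    def test_sizes_match_sort_slice_oracle(self, rng):
        n = 11602
        df = pd.DataFrame({"indel_frequency": rng.uniform(0, 100, size=n)})
        high, low = efficiency_split(df)
        assert len(high) == len(low) == 2320
        assert high["indel_frequency"].min() >= np.sort(df["indel_frequency"])[-2320]


class TestSweetSpot:
    def test_1_to_100_percentile_oracle(self):
        lo, hi = sweet_spot_interval(np.arange(1.0, 101.0))
        assert (lo, hi) == (pytest.approx(10.9), pytest.approx(90.1))

    def test_degenerate_identical(self):
        lo, hi = sweet_spot_interval([7.0] * 12)
        assert lo == hi == 7.0

    def test_coverage_property(self, rng):
        values = rng.normal(size=500)
        lo, hi = sweet_spot_interval(values, coverage=0.8)
        inside = np.mean((values >= lo) & (values <= hi))
        assert inside >= 0.8


class TestLogo:
    def test_single_sequence_one_hot(self):
        fg, _ = logo_frequencies(["ACGT"], ["ACGT"])
        assert fg.loc[1, "A"] == 1.0 and fg.loc[4, "T"] == 1.0
        assert fg.to_numpy().sum() == pytest.approx(4.0)

    def test_identical_sets_identical_matrices(self):
        seqs = ["ACGT", "AAGT", "ACGG"]
        fg, bg = logo_frequencies(seqs, seqs)
        pd.testing.assert_frame_equal(fg, bg)

    def test_counting_oracle(self):
        seqs = ["AA", "AC", "AG", "AT", "CA", "CC", "GA", "TA"]
        fg, _ = logo_frequencies(seqs, seqs)
        assert fg.loc[1, "A"] == pytest.approx(4 / 8)
        assert fg.loc[2, "A"] == pytest.approx(4 / 8)
        assert fg.loc[1, "C"] == pytest.approx(2 / 8)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            logo_frequencies(["ACG", "AC"], ["ACG"])


class TestGuideseqFilter:
    ON = pd.Series({"protospacer": "GACGCATAAAGATGAGACGC", "pam": "TGG", "reads": 5000})

    @staticmethod
    def site(proto, pam="TGG", reads=400):
        return {"protospacer": proto, "pam": pam, "reads": reads}

    def table(self):
        on = self.ON["protospacer"]
        rows = [
            self.site(on, reads=5000),                      # the on-target: kept
            self.site(on[:5] + "T" + on[6:]),               # 1 mm, kept
            self.site("TTTT" + on[4:]),                     # 4 mm, removed
            self.site(on[:17] + "A" + on[18:]),             # PAM-proximal mm (pos 18)
            self.site(on, pam="TAG"),                       # PAM variation
            self.site(on[:2] + "C" + on[3:], reads=299),    # kept, low reads
            self.site(on[:1] + "G" + on[2:], reads=6000),   # kept, above on-target
        ]
        return pd.DataFrame(rows)

    def test_on_target_retained(self):
        retained, _ = guideseq_filter(self.ON, self.table())
        assert (retained["mismatches"] == 0).any()

    def test_pam_proximal_mismatch_removed(self):
        _, removed = guideseq_filter(self.ON, self.table())
        assert "seed_mismatch" in set(removed["reason"])

    def test_rule_by_rule_oracle(self):
        retained, removed = guideseq_filter(self.ON, self.table())
        assert len(retained) == 4 and len(removed) == 3
        assert set(removed["reason"]) == {"too_many_mismatches", "seed_mismatch",
                                          "pam_variation"}
        low = retained[retained["reads"] == 299]
        assert (low["activity"] == "low").all()
        assert (retained[retained["reads"] == 6000]["vs_on_target"] == "above").all()

    def test_order_invariance(self, rng):
        df = self.table()
        shuffled = df.sample(frac=1.0, random_state=3)
        a, _ = guideseq_filter(self.ON, df)
        b, _ = guideseq_filter(self.ON, shuffled)
        pd.testing.assert_frame_equal(
            a.sort_values(["protospacer", "reads"]).reset_index(drop=True),
            b.sort_values(["protospacer", "reads"]).reset_index(drop=True),
            check_like=True,
        )


class TestSlidingConditionSummary:
    @staticmethod
    def frame(values_by_context):
        rows = []
        for ctx, values in values_by_context.items():
            rows += [{"pam_context": ctx, "indel_frequency": v} for v in values]
        return pd.DataFrame(rows)

    def test_equal_group_means_explained_zero(self):
        df = self.frame({"GGGA": [10, 20], "TGGG": [15, 15], "AGGT": [12, 18],
                         "GGGG": [14, 16]})
        s = sliding_condition_summary(df)
        assert s.explained == pytest.approx(0.0)

    def test_zero_within_group_variance_explained_one(self):
        df = self.frame({"GGGA": [30, 30], "TGGG": [10, 10], "AGGT": [20, 20],
                         "GGGG": [25, 25]})
        s = sliding_condition_summary(df)
        assert s.explained == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        df = self.frame({"GGGA": [10, 20], "TGGG": [30, 40], "AGGT": [50, 60],
                         "GGGG": [70, 80]})
        s = sliding_condition_summary(df)
        x = np.array([10, 20, 30, 40, 50, 60, 70, 80], float)
        gm = x.mean()
        ssq_sliding = 2 * ((15 - gm) ** 2 + (35 - gm) ** 2 + (55 - gm) ** 2
                           + (75 - gm) ** 2)
        ssq_tot = ((x - gm) ** 2).sum()
        assert s.grand_mean == pytest.approx(gm)
        assert s.explained == pytest.approx(ssq_sliding / ssq_tot)

    def test_grand_mean_identity(self, rng):
        contexts = rng.choice([f"{a}GG{b}" for a in "ACGT" for b in "ACGT"], size=60)
        df = pd.DataFrame({"pam_context": contexts,
                           "indel_frequency": rng.uniform(0, 100, size=60)})
        s = sliding_condition_summary(df)
        assert s.grand_mean == pytest.approx(df["indel_frequency"].mean())
        assert 0.0 <= s.explained <= 1.0

    def test_zero_total_ssq_is_nan(self):
        df = self.frame({"GGGA": [10.0], "AGGT": [10.0], "TGGG": [10.0]})
        assert math.isnan(sliding_condition_summary(df).explained)


class TestContextEffect:
    @staticmethod
    def frame():
        return pd.DataFrame({
            "pam_context": ["GGGA", "GGGT", "AGGT", "CGGA", "TGGG", "CGGG"],
            "indel_frequency": [55.0, 55.0, 50.0, 50.0, 44.0, 44.0],
        })

    def test_equal_means_zero(self):
        assert context_effect_summary(self.frame(), "HGGH", "HGGH") == 0.0

    def test_plus_10_percent(self):
        assert context_effect_summary(self.frame(), "GGGH", "HGGH") == pytest.approx(10.0)

    def test_absolute_mode(self):
        assert context_effect_summary(self.frame(), "GGGH", "HGGH",
                                      mode="absolute") == pytest.approx(5.0)

    def test_empty_group_rejected(self):
        df = self.frame()
        with pytest.raises(ValueError):
            context_effect_summary(df[df.pam_context == "AGGT"], "GGGH", "HGGH")


class TestPamPatternGroups:
    def test_wildcard_semantics(self):
        df = pd.DataFrame({"pam_context": ["GATC", "GGTC"],
                           "indel_frequency": [1.0, 2.0]})
        summary, _ = pam_pattern_group_stats(df, ["GHHH"])
        assert summary.loc[0, "n"] == 1

    def test_identical_groups_t0_p_half(self):
        df = pd.DataFrame({"pam_context": ["GATC"] * 4 + ["AATC"] * 4,
                           "indel_frequency": [1, 2, 3, 4] * 2})
        _, tests = pam_pattern_group_stats(df, ["GHHH", "HHHH"])
        assert tests.loc[0, "t"] == pytest.approx(0.0)
        assert tests.loc[0, "p"] == pytest.approx(0.5)

    def test_small_group_skipped(self):
        df = pd.DataFrame({"pam_context": ["GATC", "AATC", "ACTC"],
                           "indel_frequency": [1.0, 2.0, 3.0]})
        _, tests = pam_pattern_group_stats(df, ["GHHH", "HHHH"])
        assert tests.loc[0, "skipped"]

    def test_power_simulation_matches_closed_form(self, rng):
        n, delta, sigma, alpha = 30, 10.0, 5.0, 0.05
        reps = 200
        rejections = 0
        for _ in range(reps):
            a = rng.normal(delta, sigma, size=n)
            b = rng.normal(0.0, sigma, size=n)
            df = pd.DataFrame({
                "pam_context": ["GATC"] * n + ["AATC"] * n,
                "indel_frequency": np.concatenate([a, b]),
            })
            _, tests = pam_pattern_group_stats(df, ["GHHH", "HHHH"])
            rejections += tests.loc[0, "p"] < alpha
        dof = 2 * n - 2
        ncp = delta / (sigma * math.sqrt(2 / n))
        crit = sps.t.ppf(1 - alpha, dof)
        power = 1 - sps.nct.cdf(crit, dof, ncp)
        se = math.sqrt(power * (1 - power) / reps) + 1e-6
        assert abs(rejections / reps - power) < 4 * se + 0.02
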
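import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siliquant import (
    PhenotypePopulationSpec,
    ValidationError,
    aggregate_sample,
    aggregate_table,
    exclude_flagged,
    generate_phenotype_population,
    heritability_estimate,
    paired_treatment_test,
    rsd,
)

positive_floats = st.floats(0.1, 1e4, allow_nan=False, allow_infinity=False)


class TestRSD:
    def test_constant_values(self):
        assert rsd([1, 1, 1]) == 0.0

    def test_two_point_example(self):
        # sd([1,3]) = sqrt(2), mean 2
        assert rsd([1, 3]) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_mean_undefined(self):
        with pytest.raises(ValidationError):
            rsd([-1, 1])

    @given(st.lists(positive_floats, min_size=2, max_size=20), st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, values, c):
        base = rsd(values)
        scaled = rsd([c * v for v in values])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestAggregateSample:
    def test_mean_and_rsd(self):
        agg = aggregate_sample([1, 2, 3], sample_id="s", trait="SL_mm")
        assert agg.mean == 2.0
        assert agg.rsd == 0.5  # sd(n-1) = 1

    def test_all_equal_percentiles(self):
        agg = aggregate_sample([4.2] * 7)
        assert all(v == 4.2 for v in agg.percentiles.values())
        assert agg.rsd == 0.0

    def test_linear_interpolation_p95(self):
        # rank 0.95*(n-1)+1 = 95.05 for 1..100
        agg = aggregate_sample(np.arange(1, 101))
        assert agg.percentiles[95] == pytest.approx(95.05)

    def test_percentile_monotonicity_random(self, rng):
        for _ in range(20):
            vals = rng.lognormal(1, 0.6, size=rng.integers(2, 40))
            agg = aggregate_sample(vals)
            qs = [agg.percentiles[p] for p in (5, 25, 50, 75, 95)]
            assert qs == sorted(qs)

    def test_empty_sample_is_missing_not_zero(self):
        with pytest.raises(ValidationError):
            aggregate_sample([])

    def test_rejection_bookkeeping(self):
        agg = aggregate_sample([1.0, 2.0], n_rejected=2)
        assert agg.rejection_rate == 0.5

    def test_table_omits_fully_rejected_samples(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "a", "b"],
                "qc_status": ["accepted", "rejected", "rejected"],
                "SA_mm2": [1.0, np.nan, np.nan],
                "SL_mm": [2.0, np.nan, np.nan],
                "SD_mm": [0.5, np.nan, np.nan],
                "SV_mm3": [0.8, np.nan, np.nan],
            }
        )
        table = aggregate_table(df)
        assert set(table["sample_id"]) == {"a"}
        assert (table["n_rejected"] == 1).all()


class TestExcludeFlagged:
    def _samples(self, n_geno=10, reps=6):
        rows = []
        for g in range(n_geno):
            for r in range(reps):
                rows.append({"sample_id": f"g{g}r{r}", "genotype": f"g{g}"})
        return pd.DataFrame(rows)

    def test_flag_removes_all_replicates(self):
        samples = self._samples()
        kept, removed = exclude_flagged(samples, ["g3"])
        assert removed == 6
        assert "g3" not in set(kept["genotype"])

    def test_no_flags_keeps_all(self):
        samples = self._samples()
        kept, removed = exclude_flagged(samples, [])
        assert removed == 0 and len(kept) == len(samples)

    def test_conservation(self):
        samples = self._samples()
        kept, removed = exclude_flagged(samples, ["g1", "g7"])
        assert len(kept) + removed == len(samples)

    def test_unknown_genotype_warns(self):
        with pytest.warns(UserWarning, match="unknown"):
            exclude_flagged(self._samples(), ["nonexistent"])

    def test_study_scale_arithmetic(self):
        # 2,801 samples; flags chosen to remove 702 leave 2,099
        rows = []
        flags = []
        for g in range(100):  # 100 flagged genotypes x 7 samples = 700
            flags.append(f"flag{g}")
            rows += [{"sample_id": f"flag{g}r{r}", "genotype": f"flag{g}"} for r in range(7)]
        flags.append("flag100")  # + 1 flagged genotype x 2 samples = 702
        rows += [{"sample_id": f"flag100r{r}", "genotype": "flag100"} for r in range(2)]
        g = 0
        while len(rows) < 2801:  # unflagged filler up to the study total
            n = min(7, 2801 - len(rows))
            rows += [{"sample_id": f"keep{g}r{r}", "genotype": f"keep{g}"} for r in range(n)]
            g += 1
        samples = pd.DataFrame(rows)
        assert len(samples) == 2801
        kept, removed = exclude_flagged(samples, flags)
        assert removed == 702
        assert len(kept) == 2099


class TestPairedTreatmentTest:
    def _paired_df(self, diffs):
        rows = []
        for i, d in enumerate(diffs):
            rows.append({"line": f"l{i}", "treatment": "isolation", "value": 10.0})
            rows.append({"line": f"l{i}", "treatment": "group", "value": 10.0 + d})
        return pd.DataFrame(rows)

    def test_textbook_t_statistic(self):
        # diffs [1,2,3]: t = mean/ (sd/sqrt(n)) = 2 / (1/sqrt(3))
        res = paired_treatment_test(self._paired_df([1, 2, 3]))
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        assert res.n_pairs == 3

    def test_label_swap_antisymmetry(self):
        df = self._paired_df([0.5, 1.5, -0.3, 0.9])
        res = paired_treatment_test(df)
        swapped = df.copy()
        swapped["treatment"] = swapped["treatment"].map(
            {"isolation": "group", "group": "isolation"}
        )
        res2 = paired_treatment_test(swapped)
        assert res2.t == pytest.approx(-res.t)
        assert res2.p == pytest.approx(res.p)

    def test_unpaired_lines_dropped_and_counted(self):
        df = self._paired_df([1, 2, 3])
        df = pd.concat(
            [df, pd.DataFrame([{"line": "only", "treatment": "group", "value": 5.0}])],
            ignore_index=True,
        )
        res = paired_treatment_test(df)
        assert res.n_pairs == 3 and res.n_dropped == 1

    def test_degenerate_zero_differences(self):
        res = paired_treatment_test(self._paired_df([0, 0, 0]))
        assert res.degenerate and res.p == 1.0

    def test_replicates_averaged_per_genotype(self):
        rows = []
        for i in range(4):
            for rep, v in enumerate([9.0, 11.0]):  # mean 10 in isolation
                rows.append({"line": f"l{i}", "treatment": "isolation", "value": v})
            rows.append({"line": f"l{i}", "treatment": "group", "value": 10.0 + i})
        res = paired_treatment_test(pd.DataFrame(rows))
        assert res.n_pairs == 4
        # differences are exactly [0,1,2,3]
        assert res.t == pytest.approx(np.mean([0, 1, 2, 3]) / (np.std([0, 1, 2, 3], ddof=1) / 2))


class TestHeritability:
    def _population(self, line_sd, resid_sd, n_lines=300, reps=3, seed=0):
        spec = PhenotypePopulationSpec(
            n_lines=n_lines, reps_per_line=reps, line_sd=line_sd,
            resid_sd=resid_sd, seed=seed,
        )
        df = generate_phenotype_population(spec)
        return df[df["treatment"] == "isolation"]

    def test_equal_components_near_half(self):
        h2 = heritability_estimate(self._population(1.0, 1.0))
        assert h2 == pytest.approx(0.5, abs=0.1)

    def test_no_residual_gives_one(self):
        assert heritability_estimate(self._population(1.0, 0.0, n_lines=20)) == 1.0

    def test_no_line_variance_near_zero(self):
        h2 = heritability_estimate(self._population(0.0, 1.0))
        assert h2 <= 0.05

    def test_unbalanced_design_handled(self):
        df = self._population(1.0, 1.0, n_lines=200, reps=4, seed=3)
        # drop replicates unevenly, keep >= 1 per line
        df = df[~((df["replicate"] == 3) & (df["line"] < "L0100"))]
        df = df[~((df["replicate"] >= 1) & (df["line"] < "L0020"))]
        h2 = heritability_estimate(df)
        assert 0.3 <= h2 <= 0.7

    def test_requires_replication(self):
        df = self._population(1.0, 1.0, n_lines=10, reps=1)
        with pytest.raises(ValidationError):
            heritability_estimate(df)
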
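"""Diagnostic statistics: exact CIs, ROC/AUC, RR, age bands, strata."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from urivar.classify import SampleCall, as_fraction, classify, per_gene_calls
from urivar.diagnostics import (
    age_band_fpr,
    compare_groups,
    exact_binomial_ci,
    percent,
    relative_risk,
    roc_auc,
    round_half_away,
    sens_spec,
    sens_spec_from_counts,
    stratified_table,
)
from urivar.panel import SampleMeta
from urivar.quantify import max_vaf, vaf_table_from_counts


class TestExactCI:
    def test_matches_independent_exact_implementation(self, rng):
        """Cross-check against statsmodels' beta (Clopper-Pearson) CI."""
        from statsmodels.stats.proportion import proportion_confint

        for _ in range(200):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            ci = exact_binomial_ci(k, n)
            lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert ci.lower == pytest.approx(0.0 if k == 0 else lo, abs=1e-12)
            assert ci.upper == pytest.approx(1.0 if k == n else hi, abs=1e-12)

    def test_boundaries(self):
        assert exact_binomial_ci(0, 10).lower == 0.0
        assert exact_binomial_ci(10, 10).upper == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 0)
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)

    def test_coverage_is_conservative(self, rng):
        """Simulated coverage at n=50, p=0.7 stays at/above the nominal
        level (within 3 SE), the defining conservatism of the exact CI."""
        n, p, reps = 50, 0.7, 10_000
        ks = rng.binomial(n, p, size=reps)
        covered = 0
        for k, cnt in zip(*np.unique(ks, return_counts=True)):
            ci = exact_binomial_ci(int(k), n)
            covered += cnt * (ci.lower <= p <= ci.upper)
        se = math.sqrt(0.95 * 0.05 / reps)
        assert covered / reps >= 0.95 - 3 * se


class TestSensSpec:
    def test_printed_haematuria_counts(self):
        table, sens, spec = sens_spec_from_counts(tp=109, fn=56, fp=23, tn=261)
        assert percent(sens.point) == 66 and percent(spec.point) == 92
        assert (percent(sens.lower), percent(sens.upper)) == (58, 73)
        assert (percent(spec.lower), percent(spec.upper)) == (88, 95)

    def test_perfect_sensitivity_upper_ci(self):
        _, sens, _ = sens_spec_from_counts(tp=30, fn=0, fp=0, tn=10)
        assert sens.point == 1.0 and sens.upper == 1.0

    def test_zero_denominator_flagged(self):
        table, sens, spec = sens_spec_from_counts(tp=0, fn=0, fp=2, tn=8)
        assert sens is None and spec is not None

    def test_pairing_calls_with_labels(self):
        labels = [
            SampleMeta("P1", "haematuria_test", True, 70),
            SampleMeta("P2", "haematuria_test", True, 71),
            SampleMeta("N1", "haematuria_test", False, 60),
        ]
        t = as_fraction("0.02")
        calls = [
            SampleCall("P1", True, t),
            SampleCall("P2", False, t),
            SampleCall("N1", False, t),
        ]
        table, sens, spec = sens_spec(calls, labels)
        assert (table.tp, table.fn, table.fp, table.tn) == (1, 1, 0, 1)
        with pytest.raises(ValueError, match="unlabelled"):
            sens_spec([SampleCall("ghost", True, t)], labels)


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc([0.1, 0.2, 0.9, 0.8], [False, False, True, True])
        assert r.auc == pytest.approx(1.0)

    def test_null_auc_near_half(self, rng):
        scores = rng.random(2000)
        labels = np.r_[np.ones(1000, bool), np.zeros(1000, bool)]
        r = roc_auc(scores, labels)
        se = math.sqrt((2000 + 1) / (12 * 1000 * 1000))  # U-statistic null SE
        assert abs(r.auc - 0.5) < 3 * se

    def test_equals_pairwise_rank_oracle(self, rng):
        """AUC == mean over all (diseased, healthy) pairs of
        1[s_d > s_h] + 0.5*1[s_d == s_h], on 10^4 small instances."""
        for _ in range(10_000):
            n1 = int(rng.integers(1, 6))
            n0 = int(rng.integers(1, 6))
            # coarse grid to force ties often
            s1 = rng.integers(0, 4, n1)
            s0 = rng.integers(0, 4, n0)
            r = roc_auc(
                np.r_[s1, s0].astype(float),
                np.r_[np.ones(n1, bool), np.zeros(n0, bool)],
            )
            pairs = [
                1.0 if a > b else 0.5 if a == b else 0.0 for a in s1 for b in s0
            ]
            assert r.auc == pytest.approx(sum(pairs) / len(pairs))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = np.round(rng.random(400), 2)  # rounding induces ties
        labels = rng.random(400) < 0.4
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(300)
        labels = rng.random(300) < 0.5
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(np.log(scores + 1e-9), labels).auc
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    def test_curve_monotone(self, rng):
        r = roc_auc(rng.random(200), rng.random(200) < 0.3)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


class TestRelativeRisk:
    def test_reconstructed_surveillance_counts(self):
        # test-positive: 8 future recurrences, 31 without; test-negative:
        # 10 future recurrences, 215 without
        rr = relative_risk(8, 31, 10, 215)
        assert round(rr.rr, 2) == 4.62
        assert rr.risk_exposed == pytest.approx(8 / 39)
        assert rr.risk_unexposed == pytest.approx(10 / 225)
        assert rr.method == "katz-log" and not rr.continuity_corrected
        assert rr.lower < rr.rr < rr.upper

    def test_equal_risks_give_unity(self, rng):
        for _ in range(100):
            a = int(rng.integers(1, 50))
            b = int(rng.integers(1, 50))
            m = int(rng.integers(1, 5))
            rr = relative_risk(a, b, a * m, b * m)
            assert rr.rr == pytest.approx(1.0)

    def test_direct_ratio_oracle(self, rng):
        for _ in range(10_000):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, 4))
            rr = relative_risk(a, b, c, d)
            assert rr.rr == pytest.approx((a / (a + b)) / (c / (c + d)))

    def test_zero_unexposed_events_corrected(self):
        rr = relative_risk(5, 5, 0, 10)
        assert rr.continuity_corrected and math.isfinite(rr.rr)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(0, 0, 1, 1)


def nm(sid, age, bc=False):
    return SampleMeta(sid, "haematuria_test", bc, age)


class TestAgeBands:
    def test_all_negative(self):
        t = as_fraction("0.02")
        metas = [nm(f"S{i}", a) for i, a in enumerate([30, 55, 70])]
        calls = [SampleCall(m.sample_id, False, t) for m in metas]
        out = age_band_fpr(calls, metas)
        assert list(out["fpr"]) == [0.0, 0.0, 0.0]

    def test_band_rate_granularity(self):
        # 2 positives of 22 in the middle band -> 9% printed
        t = as_fraction("0.02")
        metas = [nm(f"M{i}", 55) for i in range(22)]
        calls = [SampleCall(m.sample_id, i < 2, t) for i, m in enumerate(metas)]
        out = age_band_fpr(calls, metas)
        mid = out[out["band"] == "[50,65)"].iloc[0]
        assert percent(mid.fpr) == 9

    def test_empty_band_undefined(self):
        t = as_fraction("0.02")
        metas = [nm("S1", 70)]
        calls = [SampleCall("S1", True, t)]
        out = age_band_fpr(calls, metas)
        assert np.isnan(out.iloc[0]["fpr"])
        assert out.iloc[2]["fpr"] == 1.0

    def test_diseased_samples_rejected(self):
        t = as_fraction("0.02")
        with pytest.raises(ValueError, match="disease-free"):
            age_band_fpr([SampleCall("S1", False, t)], [nm("S1", 70, bc=True)])

    def test_band_boundaries_half_open(self):
        t = as_fraction("0.02")
        metas = [nm("A", 50.0), nm("B", 65.0), nm("C", 49.999)]
        calls = [SampleCall(m.sample_id, False, t) for m in metas]
        out = age_band_fpr(calls, metas)
        assert list(out["n"]) == [1, 1, 1]


class TestCompareGroups:
    def test_identical_samples(self):
        g = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert g.median_a == g.median_b
        assert g.p_value == pytest.approx(1.0, abs=0.05)

    def test_exact_enumeration_case(self):
        # fully separated 3v3: one-sided exact p = 1/C(6,3) = 0.05
        g = compare_groups(
            [10, 11, 12], [1, 2, 3], method="exact", alternative="greater"
        )
        assert g.p_value == pytest.approx(0.05)

    def test_shifted_lognormals_significant(self, rng):
        a = np.exp(rng.normal(math.log(0.06), 0.8, 200))
        b = np.exp(rng.normal(math.log(0.007), 0.8, 200))
        g = compare_groups(a, b)
        assert g.p_value < 0.001
        assert g.median_a > g.median_b

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestStratifiedTable:
    def _cohort(self, panel):
        metas = [
            SampleMeta("B1", "haematuria_test", True, 70, "M", "Ta", "G3"),
            SampleMeta("B2", "haematuria_test", True, 71, "M", "Ta", "G3"),
            SampleMeta("B3", "haematuria_test", True, 72, "F", "T2plus", "G3"),
            SampleMeta("N1", "haematuria_test", False, 60),
        ]
        rows = []
        for m in metas:
            for h in panel:
                hot = m.sample_id in ("B1", "B2") and h.gene == "TBC1D12" and h.pos == 96162368
                a = 100 if hot else 0
                rows.append(
                    {"sample_id": m.sample_id, "gene": h.gene, "chrom": h.chrom,
                     "pos": h.pos, "alt": h.alt_base, "depth": 2000,
                     "alt_count": a, "vaf": a / 2000}
                )
        return metas, pd.DataFrame(rows)

    def test_fully_detected_stratum(self, panel):
        metas, table = self._cohort(panel)
        out = stratified_table(table, metas, panel, "0.02")
        assert out.loc["Any", "G3pTa"] == 2
        assert out.loc["Sensitivity", "G3pTa"] == 100
        assert out.loc["Any", "MIBC"] == 0
        assert out.loc["n", "All BCs"] == 3
        assert out.loc["Specificity", "Non-BCs"] == 100

    def test_empty_stratum_zero_row_undefined_sensitivity(self, panel):
        metas, table = self._cohort(panel)
        out = stratified_table(table, metas, panel, "0.02")
        assert out.loc["Any", "G1pTa"] == 0
        assert np.isnan(out.loc["Sensitivity", "G1pTa"])

    def test_gene_rows_bound_any_row(self, panel, small_cohort):
        """OR logic: per-stratum gene-row sums are >= the Any count, and
        Any equals the sample-level classifier calls (single source of
        truth)."""
        _, metas, counts, _ = small_cohort
        inc = [m for m in metas if m.cohort.startswith("haematuria")]
        table = vaf_table_from_counts(counts, panel)
        table = table[table.sample_id.isin([m.sample_id for m in inc])]
        out = stratified_table(table, inc, panel, "0.02")
        genes = [g for g in panel.genes]
        for col in out.columns:
            assert out.loc[genes, col].sum() >= out.loc["Any", col]
        # cross-module consistency with classify()
        n_pos = 0
        for sid, sub in table.groupby("sample_id"):
            m = next(x for x in inc if x.sample_id == sid)
            if m.bc_status and classify(max_vaf(sub, panel), "0.02").positive:
                n_pos += 1
        assert out.loc["Any", "All BCs"] == n_pos


@pytest.mark.parametrize(
    "x,decimals,expected",
    [(0.5, 0, 1.0), (1.5, 0, 2.0), (2.5, 0, 3.0), (-0.5, 0, -1.0), (0.125, 2, 0.13)],
)
def test_round_half_away(x, decimals, expected):
    assert round_half_away(x, decimals) == expected
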
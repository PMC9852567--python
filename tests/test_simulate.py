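"""Synthetic cohort and read generator: determinism, noise model, and
recovery of the generating parameters through the full pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from urivar.classify import classify
from urivar.consensus import collapse_reads
from urivar.panel import SampleMeta, default_panel
from urivar.quantify import max_vaf, max_vaf_table, pileup_vaf, vaf_table_from_counts
from urivar.simulate import (
    SimParams,
    analytic_detection_prob,
    simulate_cohort,
    simulate_counts,
    simulate_reads,
)


def meta(sid="S1"):
    return SampleMeta(sid, "haematuria_test", False, 60)


class TestSimulateCounts:
    def test_no_signal_no_error_all_zero(self, panel):
        params = SimParams(seed=3, per_base_error=0.0)
        counts = simulate_counts(panel, meta(), {}, params)
        assert (counts["alt_count"] == 0).all()
        assert (counts["depth"] > 0).all()

    def test_deterministic_given_seed(self, panel):
        params = SimParams(seed=5)
        truth = {panel.hotspots[0].key: 0.05}
        a = simulate_counts(panel, meta(), truth, params)
        b = simulate_counts(panel, meta(), truth, params)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, panel):
        truth = {panel.hotspots[0].key: 0.05}
        a = simulate_counts(panel, meta(), truth, SimParams(seed=5))
        b = simulate_counts(panel, meta(), truth, SimParams(seed=6))
        assert not a.equals(b)

    def test_observed_vaf_within_exact_binomial_band(self, panel):
        """At true VAF 5%, the observed count stays inside the central
        99.9% binomial band in >=999/1000 seeds (exact-quantile oracle)."""
        params = SimParams(per_base_error=0.0)
        key = panel.hotspots[0].key
        inside = 0
        for seed in range(1000):
            counts = simulate_counts(panel, meta(), {key: 0.05}, params, seed=seed)
            row = counts.iloc[0]
            lo = sps.binom.ppf(0.0005, row.depth, 0.05)
            hi = sps.binom.ppf(0.9995, row.depth, 0.05)
            inside += lo <= row.alt_count <= hi
        assert inside >= 999

    def test_invalid_truth_rejected(self, panel):
        with pytest.raises(ValueError):
            simulate_counts(panel, meta(), {panel.hotspots[0].key: 1.5}, SimParams())

    def test_conservation_alt_le_depth(self, panel, rng):
        params = SimParams(seed=9)
        truth = {h.key: float(v) for h, v in zip(panel, rng.random(len(panel)))}
        counts = simulate_counts(panel, meta(), truth, params)
        assert (counts["alt_count"] <= counts["depth"]).all()


class TestSimulateReads:
    def test_small_families_yield_zero_depth(self, panel):
        # force every family below the >=3-read rule
        params = SimParams(seed=2, raw_per_consensus_mean=1.0, raw_error=0.0)
        reads = simulate_reads(panel, {}, params, n_molecules_mean=30)
        calls = collapse_reads(reads, min_family_size=3)
        kept = [c for c in calls if c.family_size >= 3]
        # family size is 1 + Poisson(0) = 1 exactly, so nothing survives
        assert kept == [] and calls == []

    def test_no_error_no_signal_all_ref(self, panel):
        params = SimParams(seed=4, raw_error=0.0, qual_below30_frac=0.0)
        reads = simulate_reads(panel, {}, params, n_molecules_mean=20)
        calls = collapse_reads(reads)
        ref = {(h.chrom, h.pos): h.ref_base for h in panel}
        assert calls and all(c.base == ref[(c.chrom, c.pos)] for c in calls)

    def test_end_to_end_vaf_recovery(self):
        """Simulate reads at 5% true VAF, collapse, quantify: recovered VAF
        within 3 binomial SEs of truth."""
        panel = default_panel()
        one_site = panel.hotspots[:1]
        from urivar.panel import Panel

        small = Panel(one_site)
        params = SimParams(seed=8, raw_error=0.005)
        truth = {one_site[0].key: 0.05}
        reads = simulate_reads(small, truth, params, n_molecules_mean=2400)
        calls = collapse_reads(reads, min_family_size=3)
        table = pileup_vaf(calls, small, "S1", min_baseq=30)
        row = table.iloc[0]
        assert row.depth > 2000  # nearly every molecule yields a consensus
        se = math.sqrt(0.05 * 0.95 / row.depth)
        assert abs(row.vaf - 0.05) < 3 * se


class TestSimulateCohort:
    def test_no_bc_arm(self, panel):
        params = SimParams(seed=1, n_non_bc=10, n_bc=0)
        metas, counts, truth = simulate_cohort(panel, params)
        assert len(metas) == 10
        assert not any(m.bc_status for m in metas)

    def test_haematuria_design_shape(self, panel):
        params = SimParams(seed=1, n_non_bc=426, n_bc=165)
        metas, _, _ = simulate_cohort(panel, params)
        training = [m for m in metas if m.cohort == "haematuria_training"]
        test_non_bc = [
            m for m in metas if m.cohort == "haematuria_test" and not m.bc_status
        ]
        bc = [m for m in metas if m.bc_status]
        assert (len(training), len(test_non_bc), len(bc)) == (142, 284, 165)

    def test_determinism_bitwise(self, panel):
        params = SimParams(seed=42, n_non_bc=20, n_bc=10, n_surveillance_no_recur=8,
                           n_surveillance_recur=4, n_surveillance_pre_recur=2)
        m1, c1, t1 = simulate_cohort(panel, params)
        m2, c2, t2 = simulate_cohort(panel, params)
        assert m1 == m2
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_extending_cohort_preserves_prefix(self, panel):
        """Named per-sample substreams: adding samples never perturbs the
        ones already generated."""
        small = SimParams(seed=7, n_non_bc=15, n_bc=0, training_fraction=0.0)
        big = SimParams(seed=7, n_non_bc=30, n_bc=0, training_fraction=0.0)
        m_small, c_small, _ = simulate_cohort(panel, small)
        m_big, c_big, _ = simulate_cohort(panel, big)
        assert m_big[:15] == m_small
        pd.testing.assert_frame_equal(c_big.iloc[: len(c_small)], c_small)

    def test_truth_vafs_in_unit_interval(self, small_cohort):
        _, _, _, truth = small_cohort
        assert ((truth["true_vaf"] >= 0) & (truth["true_vaf"] <= 1)).all()

    def test_conservation_everywhere(self, small_cohort):
        _, _, counts, _ = small_cohort
        assert (counts["alt_count"] <= counts["depth"]).all()

    def test_pre_recurrence_flags(self, panel):
        params = SimParams(seed=3, n_non_bc=0, n_bc=0, n_surveillance_no_recur=10,
                           n_surveillance_recur=5, n_surveillance_pre_recur=4)
        metas, _, _ = simulate_cohort(panel, params)
        flags = [m.future_recurrence for m in metas if not m.bc_status]
        assert flags.count(True) == 4 and flags.count(False) == 6
        assert all(m.future_recurrence is None for m in metas if m.bc_status)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            SimParams(n_surveillance_no_recur=2, n_surveillance_pre_recur=3)


class TestDetectionProbabilityRecovery:
    def test_sensitivity_matches_analytic_oracle(self, panel):
        """Classifier sensitivity on a simulated incident BC arm lands
        within 3 binomial SEs of the analytic detection probability."""
        n = 1500
        params = SimParams(seed=13, n_non_bc=0, n_bc=n)
        metas, counts, _ = simulate_cohort(panel, params)
        table = vaf_table_from_counts(counts, panel)
        stats = max_vaf_table(table, panel)
        pos = sum(classify(s, "0.02").positive for s in stats)
        from urivar.simulate import analytic_sensitivity

        expect = analytic_sensitivity(params.tumour_vaf_median_incident, params)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(pos / n - expect) < 3 * se
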
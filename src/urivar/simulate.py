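"""Synthetic cohorts of UMI-tagged deep-sequencing hotspot data.

The generator reproduces the statistical structure the analysis assumes,
at two levels:

* **count level** (the workhorse): per-site quality-passing consensus depth
  is Poisson around ~2400x and alt counts are binomial at an effective alt
  rate ``true_vaf + e/3*(1 - true_vaf)``, where ``e`` is the per-consensus-
  base substitution error (default 1e-3, split evenly over the three
  non-reference bases).  Background error is modelled *per consensus base*
  — i.e. after error suppression — because every quantity the analysis
  reports is consensus-level; this keeps cohort simulation fast and the
  noise model identifiable.

* **read level** (to exercise the consensus module): UMI families of size
  1 + Poisson(raw_per_consensus_mean - 1) (default mean 15, giving a raw
  depth ~35,400x for a consensus depth ~2400x), within-family raw base
  errors, and Phred qualities with a configurable fraction below Q30.

Cohort structure: disease-free samples carry, with an age-band probability
(<50y: 1%, 50-65y: 9%, >=65y: 14%), a single clonally-expanded hotspot at a
log-normal VAF (median 3%) — emulating age-dependent clonal expansions of
APOBEC-mutated urothelium in the absence of cancer.  Cancer-positive
samples carry a tumour-derived hotspot with probability 74% (the fraction
of tumours bearing >=1 panel mutation) at a log-normal max VAF whose median
depends on context: 6% for incident disease, 3.3% for recurrence at
collection, 1.7% for samples collected before a future recurrence.

All randomness flows from one root seed through named sub-streams, keyed by
(seed, stream, sample index), so enlarging a cohort never perturbs the
samples already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

from .consensus import ReadRecord
from .panel import COUNT_COLUMNS, Panel, SampleMeta, SiteKey

__all__ = [
    "SimParams",
    "simulate_counts",
    "simulate_reads",
    "simulate_cohort",
    "analytic_detection_prob",
    "analytic_band_positive_rate",
    "analytic_sensitivity",
]

_WDR74_SITE: SiteKey = ("chr11", 62609254, "A")

# stream codes for derived RNGs
_STREAM_COHORT = 1
_STREAM_COUNTS = 2
_STREAM_READS = 3


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


@dataclass(frozen=True)
class SimParams:
    """All knobs of the cohort/read generator.

    Defaults are the study conditions: consensus depth ~2400x from ~15 raw
    reads per family, 1e-3 consensus-level substitution error, age-banded
    background clonal probabilities (0.01 / 0.09 / 0.14), 3% median
    background clonal VAF, 74% tumour mutation prevalence, and context-
    dependent tumour max-VAF medians (6% incident, 3.3% recurrent, 1.7%
    pre-recurrence).
    """

    seed: int = 0
    n_non_bc: int = 284
    n_bc: int = 165
    n_surveillance_no_recur: int = 0
    n_surveillance_recur: int = 0
    n_surveillance_pre_recur: int = 0  # subset of no_recur with later recurrence

    consensus_depth_mean: float = 2400.0
    raw_per_consensus_mean: float = 15.0
    per_base_error: float = 1e-3  # consensus-level, split over 3 alt bases
    raw_error: float = 5e-3  # per raw read base, used by simulate_reads
    qual_below30_frac: float = 0.05
    qual_pass: int = 37
    qual_fail: int = 22

    # (age upper bound, probability) pairs; last bound may be inf
    background_clonal_prob_by_age: tuple[tuple[float, float], ...] = (
        (50.0, 0.01),
        (65.0, 0.09),
        (math.inf, 0.14),
    )
    background_clonal_vaf_median: float = 0.03
    background_clonal_vaf_log_sd: float = 0.25
    multi_site_background: bool = False  # at most one clonal site by default

    tumour_mutation_prevalence: float = 0.74
    tumour_vaf_median_incident: float = 0.06
    tumour_vaf_median_recurrence: float = 0.033
    tumour_vaf_median_pre_recurrence: float = 0.017
    tumour_vaf_log_sd: float = 0.8
    multi_site_tumour: bool = False  # single mutated hotspot by default

    wdr74_extra_error: Optional[float] = None  # e.g. 3e-3 to emulate germline noise

    age_mean_non_bc: float = 59.5
    age_mean_bc: float = 72.5
    age_mean_surveillance: float = 74.0
    age_sd: float = 12.0
    male_fraction: float = 0.62
    training_fraction: float = 1.0 / 3.0  # of non-BC haematuria samples

    def __post_init__(self) -> None:
        for name in (
            "per_base_error",
            "raw_error",
            "qual_below30_frac",
            "tumour_mutation_prevalence",
            "male_fraction",
            "training_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.consensus_depth_mean <= 0 or self.raw_per_consensus_mean <= 0:
            raise ValueError("depths must be positive")
        for _, p in self.background_clonal_prob_by_age:
            if not 0.0 <= p <= 1.0:
                raise ValueError("age-band probabilities must be in [0, 1]")
        for name in (
            "background_clonal_vaf_median",
            "tumour_vaf_median_incident",
            "tumour_vaf_median_recurrence",
            "tumour_vaf_median_pre_recurrence",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(
            self.n_non_bc,
            self.n_bc,
            self.n_surveillance_no_recur,
            self.n_surveillance_recur,
            self.n_surveillance_pre_recur,
        ) < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_surveillance_pre_recur > self.n_surveillance_no_recur:
            raise ValueError("pre-recurrence samples are a subset of no-recurrence")

    def band_prob(self, age: float) -> float:
        for bound, p in self.background_clonal_prob_by_age:
            if age < bound:
                return p
        return self.background_clonal_prob_by_age[-1][1]


def _effective_alt_rate(true_vaf: float, params: SimParams, key: SiteKey) -> float:
    e = params.per_base_error / 3.0
    if params.wdr74_extra_error is not None and key == _WDR74_SITE:
        e += params.wdr74_extra_error
    return min(1.0, true_vaf + e * (1.0 - true_vaf))


def simulate_counts(
    panel: Panel,
    meta: SampleMeta,
    truth_vafs: dict[SiteKey, float],
    params: SimParams,
    seed: Optional[int] = None,
    sample_index: int = 0,
) -> pd.DataFrame:
    """Draw quality-filtered site counts for one sample.

    depth ~ Poisson(consensus_depth_mean); alt_count ~ Binomial(depth,
    true_vaf + e/3*(1-true_vaf)).  Deterministic given (seed, sample_index).
    """
    for key, v in truth_vafs.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"true VAF {v} at {key} outside [0, 1]")
    rng = _rng(params.seed if seed is None else seed, _STREAM_COUNTS, sample_index)
    rows = []
    for h in panel:
        depth = int(rng.poisson(params.consensus_depth_mean))
        rate = _effective_alt_rate(truth_vafs.get(h.key, 0.0), params, h.key)
        alt = int(rng.binomial(depth, rate)) if depth > 0 else 0
        rows.append(
            {
                "sample_id": meta.sample_id,
                "chrom": h.chrom,
                "pos": h.pos,
                "alt": h.alt_base,
                "depth": depth,
                "alt_count": alt,
            }
        )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def simulate_reads(
    panel: Panel,
    truth_vafs: dict[SiteKey, float],
    params: SimParams,
    seed: Optional[int] = None,
    sample_id: str = "S1",
    n_molecules_mean: Optional[float] = None,
) -> list[ReadRecord]:
    """Emit raw UMI-tagged reads whose consensus recovers the truth VAFs.

    Each site gets Poisson(n_molecules_mean) molecules (default: the
    consensus depth mean); each molecule yields a UMI family of size
    1 + Poisson(raw_per_consensus_mean - 1) with independent raw base
    errors and qualities straddling the Q30 filter.
    """
    rng = _rng(params.seed if seed is None else seed, _STREAM_READS)
    mean_mols = (
        params.consensus_depth_mean if n_molecules_mean is None else n_molecules_mean
    )
    bases = "ACGT"
    reads: list[ReadRecord] = []
    for h in panel:
        v = truth_vafs.get(h.key, 0.0)
        n_mols = int(rng.poisson(mean_mols))
        for m in range(n_mols):
            umi = "".join(bases[i] for i in rng.integers(0, 4, size=8))
            frag_start = max(1, h.pos - int(rng.integers(10, 140)))
            mol_base = h.alt_base if rng.random() < v else h.ref_base
            size = 1 + int(rng.poisson(max(0.0, params.raw_per_consensus_mean - 1)))
            for r in range(size):
                base = mol_base
                if rng.random() < params.raw_error:
                    base = bases[(bases.index(mol_base) + int(rng.integers(1, 4))) % 4]
                qual = (
                    params.qual_fail
                    if rng.random() < params.qual_below30_frac
                    else params.qual_pass
                )
                reads.append(
                    ReadRecord(
                        read_id=f"{sample_id}:{h.chrom}:{h.pos}:{m}:{r}",
                        umi=umi,
                        frag_start=frag_start,
                        chrom=h.chrom,
                        pos=h.pos,
                        base=base,
                        qual=qual,
                    )
                )
    return reads


def _draw_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 18.0, 100.0))


def _lognormal_vaf(rng: np.random.Generator, median: float, log_sd: float) -> float:
    return float(min(1.0, math.exp(math.log(median) + log_sd * rng.standard_normal())))


def _background_truth(
    rng: np.random.Generator, panel: Panel, params: SimParams, age: float
) -> dict[SiteKey, float]:
    """Clonal background: with age-band probability, one mutated hotspot."""
    truth: dict[SiteKey, float] = {}
    active = panel.active_hotspots()
    n_events = 0
    if rng.random() < params.band_prob(age):
        n_events = 1
        if params.multi_site_background:
            n_events += int(rng.poisson(0.5))
    if n_events:
        idx = rng.choice(len(active), size=min(n_events, len(active)), replace=False)
        for i in np.atleast_1d(idx):
            truth[active[int(i)].key] = _lognormal_vaf(
                rng, params.background_clonal_vaf_median, params.background_clonal_vaf_log_sd
            )
    return truth


def _tumour_truth(
    rng: np.random.Generator, panel: Panel, params: SimParams, median: float
) -> dict[SiteKey, float]:
    """Tumour signal: with prevalence, a mutated hotspot at log-normal VAF."""
    truth: dict[SiteKey, float] = {}
    active = panel.active_hotspots()
    if rng.random() < params.tumour_mutation_prevalence:
        vmax = _lognormal_vaf(rng, median, params.tumour_vaf_log_sd)
        n_sites = 1
        if params.multi_site_tumour:
            n_sites += int(rng.poisson(1.0))
        idx = rng.choice(len(active), size=min(n_sites, len(active)), replace=False)
        chosen = [active[int(i)] for i in np.atleast_1d(idx)]
        truth[chosen[0].key] = vmax
        for h in chosen[1:]:
            truth[h.key] = vmax * float(rng.uniform(0.2, 1.0))
    return truth


def simulate_cohort(
    panel: Panel, params: SimParams, seed: Optional[int] = None
) -> tuple[list[SampleMeta], pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: sample sheet, site counts, and ground truth.

    Returns ``(metas, counts, truth)`` where ``truth`` has one row per
    sample x mutated site (sample_id, chrom, pos, alt, true_vaf); samples
    with pure-background signal have no truth rows.

    Sample order: non-BC haematuria (the first ``training_fraction`` of
    them labelled ``haematuria_training``), incident BC, surveillance
    cystoscopy-negative (the first ``n_surveillance_pre_recur`` of them
    flagged for future recurrence), surveillance recurrence.
    """
    root_seed = params.seed if seed is None else seed
    metas: list[SampleMeta] = []
    plans: list[tuple[str, dict[SiteKey, float]]] = []  # (sample_id, truth)

    n_train = int(round(params.training_fraction * params.n_non_bc))
    spec_list: list[tuple[str, str, bool, Optional[bool], float, Optional[float]]] = []
    # (id_prefix+index handled below): cohort, kind, bc_status, future_rec, age_mean, tumour_median
    for i in range(params.n_non_bc):
        cohort = "haematuria_training" if i < n_train else "haematuria_test"
        spec_list.append((cohort, "background", False, None, params.age_mean_non_bc, None))
    for i in range(params.n_bc):
        spec_list.append(
            ("haematuria_test", "tumour", True, None, params.age_mean_bc,
             params.tumour_vaf_median_incident)
        )
    for i in range(params.n_surveillance_no_recur):
        if i < params.n_surveillance_pre_recur:
            spec_list.append(
                ("surveillance", "tumour", False, True, params.age_mean_surveillance,
                 params.tumour_vaf_median_pre_recurrence)
            )
        else:
            spec_list.append(
                ("surveillance", "background", False, False,
                 params.age_mean_surveillance, None)
            )
    for i in range(params.n_surveillance_recur):
        spec_list.append(
            ("surveillance", "tumour", True, None, params.age_mean_surveillance,
             params.tumour_vaf_median_recurrence)
        )

    strat_weights = {  # incident-disease stage/grade mixture for BC labels
        ("G1", "Ta"): 23, ("G2", "Ta"): 42, ("G3", "Ta"): 15,
        ("G2", "T1"): 8, ("G3", "T1"): 24, ("G3", "T2plus"): 36, ("nr", "nr"): 17,
    }
    strat_items = list(strat_weights.items())
    strat_p = np.array([w for _, w in strat_items], dtype=float)
    strat_p /= strat_p.sum()

    truth_rows = []
    count_frames = []
    for idx, (cohort, kind, bc, future_rec, age_mean, tmedian) in enumerate(spec_list):
        rng = _rng(root_seed, _STREAM_COHORT, idx)
        sid = f"S{idx:05d}"
        age = _draw_age(rng, age_mean, params.age_sd)
        sex = "M" if rng.random() < params.male_fraction else "F"
        stage = grade = "nr"
        if bc and cohort != "surveillance":
            (grade, stage) = strat_items[int(rng.choice(len(strat_items), p=strat_p))][0]
        meta = SampleMeta(
            sample_id=sid,
            cohort=cohort,
            bc_status=bc,
            age=round(age, 1),
            sex=sex,
            stage=stage,
            grade=grade,
            future_recurrence=future_rec,
        )
        metas.append(meta)
        if kind == "tumour":
            truth = _tumour_truth(rng, panel, params, float(tmedian))
        else:
            truth = _background_truth(rng, panel, params, age)
        for key, v in truth.items():
            truth_rows.append(
                {"sample_id": sid, "chrom": key[0], "pos": key[1], "alt": key[2],
                 "true_vaf": v}
            )
        count_frames.append(
            simulate_counts(panel, meta, truth, params, seed=root_seed, sample_index=idx)
        )

    counts = (
        pd.concat(count_frames, ignore_index=True)
        if count_frames
        else pd.DataFrame(columns=COUNT_COLUMNS)
    )
    truth_df = pd.DataFrame(
        truth_rows, columns=["sample_id", "chrom", "pos", "alt", "true_vaf"]
    )
    return metas, counts, truth_df


# ---------------------------------------------------------------------------
# analytic oracles for the generating model


def _depth_grid(mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depths within +-6 sd of the mean, with renormalised weights."""
    sd = math.sqrt(mean)
    lo = max(1, int(mean - 6 * sd))
    hi = int(mean + 6 * sd) + 1
    depths = np.arange(lo, hi)
    w = sps.poisson.pmf(depths, mean)
    return depths, w / w.sum()


def _tail_over_depth(rate: float, threshold, depths: np.ndarray, w: np.ndarray) -> float:
    """P(alt/depth > threshold) averaged over the depth distribution.

    The strict comparison alt > threshold*depth needs alt >= floor(t*d)+1,
    with t*d evaluated in exact rational arithmetic so thresholds such as
    0.015 never round the wrong way at depths where t*d is an integer.
    """
    from fractions import Fraction

    t = Fraction(repr(threshold)) if not isinstance(threshold, Fraction) else threshold
    kmax = np.array([int(t * int(d)) for d in depths])  # floor for positive t*d
    return float(np.sum(w * sps.binom.sf(kmax, depths, rate)))


def analytic_detection_prob(
    vaf_median: float,
    vaf_log_sd: float,
    params: SimParams,
    threshold: float = 0.02,
) -> float:
    """P(observed VAF > threshold) for a log-normal true-VAF signal.

    Integrates the binomial tail at the effective alt rate over both the
    log-normal VAF law and the Poisson depth distribution — an independent
    closed-form account of the generative process, to ~1e-4 accuracy.
    """
    depths, w = _depth_grid(params.consensus_depth_mean)

    def f(z: float) -> float:
        v = min(1.0, math.exp(math.log(vaf_median) + vaf_log_sd * z))
        rate = min(1.0, v + params.per_base_error / 3.0 * (1.0 - v))
        return sps.norm.pdf(z) * _tail_over_depth(rate, threshold, depths, w)

    val, _ = integrate.quad(f, -8.0, 8.0, limit=200)
    return float(val)


def _noise_only_positive_prob(params: SimParams, threshold: float, n_sites: int) -> float:
    depths, w = _depth_grid(params.consensus_depth_mean)
    p_site = _tail_over_depth(params.per_base_error / 3.0, threshold, depths, w)
    return 1.0 - (1.0 - p_site) ** n_sites


def analytic_band_positive_rate(
    band_prob: float, params: SimParams, threshold: float = 0.02, n_sites: int = 19
) -> float:
    """Expected positive-call rate for disease-free samples in one age band."""
    p_det = analytic_detection_prob(
        params.background_clonal_vaf_median,
        params.background_clonal_vaf_log_sd,
        params,
        threshold,
    )
    p_noise = _noise_only_positive_prob(params, threshold, n_sites)
    return band_prob * (p_det + (1 - p_det) * p_noise) + (1 - band_prob) * p_noise


def analytic_sensitivity(
    vaf_median: float, params: SimParams, threshold: float = 0.02, n_sites: int = 19
) -> float:
    """Expected positive-call rate for tumour-bearing-class samples."""
    p_det = analytic_detection_prob(
        vaf_median, params.tumour_vaf_log_sd, params, threshold
    )
    p_noise = _noise_only_positive_prob(params, threshold, n_sites)
    prev = params.tumour_mutation_prevalence
    return prev * (p_det + (1 - p_det) * p_noise) + (1 - prev) * p_noise
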
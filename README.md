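# urivar

Non-coding mutation hotspots as urinary biomarkers for bladder cancer.

Bladder tumours very frequently carry single-nucleotide mutations at a
small set of recurrent non-coding hotspots (19 sites in *ADGRG6*,
*PLEKHS1*, *WDR74*, *TBC1D12* and *LEPROTL1*, e.g. chr10:96162368 C>T in
*TBC1D12*). These mutations shed into urine, so the DNA of the urine cell
pellet (cpDNA) can be assayed for them non-invasively. The catch is that
the same mutations also occur at low levels in the urothelium of people
*without* cancer — clonal patches of APOBEC-mutated cells that become more
common with age — so detection is a signal-to-background problem, not a
presence/absence one.

`urivar` implements that analysis end to end for ultra-deep UMI-tagged
sequencing of a hotspot panel:

* **UMI consensus calling** — raw reads are grouped by (UMI, fragment
  start) into molecule families and collapsed to consensus bases, requiring
  ≥ 3 reads per family and a strict base majority; this error suppression
  is what makes VAFs of a few tenths of a percent measurable.
* **Hotspot quantification** — the variant allele frequency at each panel
  site is VAF = alt / depth over consensus calls with base quality ≥ 30;
  the per-sample score is **max VAF** over (non-excluded) panel sites.
* **Classification** — a sample is called positive when max VAF exceeds a
  threshold *t* (strictly). *t* is calibrated on a training set of
  cancer-free patients as the smallest candidate reaching a target
  specificity (2% at 90% specificity in the reference design).
* **Diagnostics** — sensitivity/specificity with exact Clopper–Pearson
  95% CIs, ROC curves and AUC from a threshold sweep, gene-by-stage/grade
  detection tables, age-band false-positive rates, Mann–Whitney group
  comparisons, and the relative risk (with Katz CI) of *future* recurrence
  for test-positive vs test-negative surveillance patients.
* **Synthetic cohorts** — a generator that emulates the assay (consensus
  depth ~2400×, raw depth ~35,400×, per-base background error 10⁻³,
  age-dependent clonal background, tumour-derived VAF distributions), so
  every stage is testable without sequencing data.

The shipped default panel contains the two published hotspot coordinates
plus 17 clearly-labelled synthetic placeholder sites; substitute the full
panel TSV for real analyses.

## Worked example

`examples/incident_cohort.py` simulates the haematuria-clinic design
(426 cancer-free patients, one third used for calibration; 165 cancers),
calibrates the threshold and evaluates the held-out samples:

```
threshold 0.010: training specificity 93.0%
threshold 0.015: training specificity 93.0%
threshold 0.020: training specificity 94.4%
selected threshold: 0.010

2x2 (test set): tp=118 fn=47 fp=31 tn=253
sensitivity: 72% (95% CI 64-78%)
specificity: 89% (95% CI 85-92%)
ROC AUC: 0.820
median max VAF: cancer 3.88% vs cancer-free 0.12% (Mann-Whitney p=1e-29)
```

Sensitivity lands near two-thirds at ~90% specificity because ~74% of
tumours carry a panel mutation and most shed enough DNA to clear the
threshold, while clonal background rarely does; the max-VAF medians differ
by more than an order of magnitude between groups. The other examples
cover consensus collapsing (`consensus_demo.py`), the age dependence of
false positives (`age_bands.py`), surveillance/recurrence analysis with
relative risk (`surveillance_recurrence.py`) and QC replicate
reproducibility (`qc_replicates.py`).

A thin CLI mirrors the stages (`urivar fixtures|simulate|consensus|
quantify|calibrate|call|report|run`); `urivar run --seed 1 --threshold
0.02 --out-dir out/` executes the whole chain and writes TSV/JSON
artefacts plus a manifest.

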
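"""Hotspot panel, sample sheet and per-site count tables.

The assay targets a small panel of recurrently mutated non-coding
single-nucleotide positions ("hotspots") in five genes (ADGRG6, PLEKHS1,
WDR74, TBC1D12, LEPROTL1).  Coordinates are 1-based, inclusive and
chromosome-scoped (hg19-style notation such as ``chr10:96162368 C>T``);
the panel file is self-describing and no reference FASTA is needed.

All tabular interchange formats are plain TSV:

* panel:        gene, chrom, pos, ref, alt   (``#`` comment lines allowed)
* sample sheet: sample_id, cohort, bc_status, age, sex, stage, grade,
                future_recurrence
* site counts:  sample_id, chrom, pos, alt, depth, alt_count
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "Hotspot",
    "Panel",
    "SampleMeta",
    "PanelError",
    "SampleSheetError",
    "COHORTS",
    "STAGES",
    "GRADES",
    "STRATA",
    "load_panel",
    "write_panel",
    "panel_to_bed",
    "default_panel",
    "load_sample_sheet",
    "write_sample_sheet",
    "load_site_counts",
    "write_site_counts",
    "stratum_of",
]

BASES = frozenset("ACGT")
COHORTS = ("haematuria_training", "haematuria_test", "surveillance", "germline", "qc")
STAGES = ("Tis", "Ta", "T1", "T2plus", "nr")
GRADES = ("G1", "G2", "G3", "nr")

#: Reporting strata for incident disease, in presentation order.
STRATA = ("G1pTa", "G2pTa", "G3pTa", "G2pT1", "G3pT1", "MIBC", "Other BC")

SiteKey = tuple[str, int, str]  # (chrom, pos, alt)


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


class SampleSheetError(ValueError):
    """Raised for malformed sample sheets."""


@dataclass(frozen=True)
class Hotspot:
    """One panel site: a single-nucleotide substitution at a fixed position."""

    gene: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"{self.gene}: position must be >= 1, got {self.pos}")
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise PanelError(
                f"{self.gene} {self.chrom}:{self.pos}: bases must be A/C/G/T, "
                f"got ref={self.ref_base!r} alt={self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise PanelError(
                f"{self.gene} {self.chrom}:{self.pos}: ref and alt are both "
                f"{self.ref_base!r}"
            )

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.alt_base)


@dataclass
class Panel:
    """An ordered collection of hotspots plus an optional exclusion set.

    ``excluded`` sites stay in the panel (they are still quantified) but are
    dropped from the per-sample max-VAF statistic.  This mirrors the
    treatment of germline-noise-prone sites such as WDR74 chr11:62609254G>A,
    which inflates apparent background signal even in blood DNA.
    """

    hotspots: list[Hotspot]
    excluded: set[SiteKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.hotspots:
            raise PanelError("panel is empty")
        seen: set[SiteKey] = set()
        for h in self.hotspots:
            if h.key in seen:
                raise PanelError(
                    f"duplicate panel site {h.chrom}:{h.pos} alt={h.alt_base}"
                )
            seen.add(h.key)
        unknown = set(self.excluded) - seen
        if unknown:
            raise PanelError(f"excluded sites not in panel: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.hotspots)

    def __iter__(self):
        return iter(self.hotspots)

    @property
    def keys(self) -> list[SiteKey]:
        return [h.key for h in self.hotspots]

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for h in self.hotspots:
            if h.gene not in out:
                out.append(h.gene)
        return out

    def active_hotspots(self) -> list[Hotspot]:
        """Hotspots contributing to the max-VAF statistic (not excluded)."""
        return [h for h in self.hotspots if h.key not in self.excluded]

    def with_excluded(self, excluded: Iterable[SiteKey]) -> "Panel":
        return Panel(list(self.hotspots), set(excluded))

    def by_key(self) -> dict[SiteKey, Hotspot]:
        return {h.key: h for h in self.hotspots}


def load_panel(path: Union[str, Path], excluded: Iterable[SiteKey] = ()) -> Panel:
    """Read a panel TSV (columns gene, chrom, pos, ref, alt; '#' comments).

    File order is preserved; duplicates and ref==alt rows raise
    :class:`PanelError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["gene", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing panel columns {missing}")
    if df.empty:
        raise PanelError(f"{path}: panel file has no sites")
    hotspots = [
        Hotspot(
            gene=str(r.gene),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_base=str(r.ref),
            alt_base=str(r.alt),
        )
        for r in df.itertuples()
    ]
    return Panel(hotspots, set(excluded))


def write_panel(panel: Panel, path: Union[str, Path]) -> None:
    rows = [
        {"gene": h.gene, "chrom": h.chrom, "pos": h.pos, "ref": h.ref_base, "alt": h.alt_base}
        for h in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def panel_to_bed(panel: Panel, path: Union[str, Path]) -> None:
    """Export sites as BED (0-based half-open; start = pos-1, end = pos)."""
    with open(path, "w") as fh:
        for h in panel:
            fh.write(f"{h.chrom}\t{h.pos - 1}\t{h.pos}\t{h.gene}:{h.ref_base}>{h.alt_base}\n")


# The two sites with published coordinates.  The remaining 17 panel
# coordinates live in the assay's primary reference and are shipped here as
# synthetic placeholders (positions are invented, clearly offset per gene)
# so the full 19-site / 5-gene panel shape is exercisable out of the box;
# substitute the true coordinates for real analyses.
_REAL_SITES = [
    ("TBC1D12", "chr10", 96162368, "C", "T"),
    ("WDR74", "chr11", 62609254, "G", "A"),
]

_PLACEHOLDER_PLAN = [
    # gene, chrom, base position for synthetic offsets, n placeholder sites
    ("ADGRG6", "chr6", 142_700_000, 5),
    ("PLEKHS1", "chr10", 115_500_000, 4),
    ("TBC1D12", "chr10", 96_162_000, 2),  # 3 total with the real site
    ("WDR74", "chr11", 62_609_000, 2),    # 3 total with the real site
    ("LEPROTL1", "chr8", 29_950_000, 4),
]


def default_panel() -> Panel:
    """The shipped 19-site, 5-gene demo panel.

    Contains the two published hotspot coordinates plus 17 synthetic
    placeholder sites (see module comment); suitable for simulation and
    testing, not for calling against a real genome.
    """
    hotspots = [Hotspot(*row) for row in _REAL_SITES]
    refs = "ACGT"
    for gene, chrom, base, n in _PLACEHOLDER_PLAN:
        for i in range(n):
            ref = refs[i % 4]
            alt = "T" if ref != "T" else "C"
            hotspots.append(Hotspot(gene, chrom, base + 100 * (i + 1) + 7, ref, alt))
    return Panel(hotspots)


# ---------------------------------------------------------------------------
# sample sheets


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample labels: cohort, disease status and clinical covariates.

    ``bc_status`` is disease presence on the day of urine collection.
    ``future_recurrence`` only applies to surveillance samples negative at
    collection (None elsewhere).  Stage and grade are meaningful only when
    ``bc_status`` is True; unknown values are coded ``nr``.
    """

    sample_id: str
    cohort: str
    bc_status: bool
    age: float
    sex: str = "unknown"
    stage: str = "nr"
    grade: str = "nr"
    future_recurrence: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise SampleSheetError("empty sample_id")
        if self.cohort not in COHORTS:
            raise SampleSheetError(
                f"{self.sample_id}: unknown cohort {self.cohort!r} (expected one of {COHORTS})"
            )
        if self.age < 0:
            raise SampleSheetError(f"{self.sample_id}: negative age {self.age}")
        if self.sex not in ("M", "F", "unknown"):
            raise SampleSheetError(f"{self.sample_id}: sex must be M/F/unknown")
        if self.stage not in STAGES:
            raise SampleSheetError(f"{self.sample_id}: unknown stage {self.stage!r}")
        if self.grade not in GRADES:
            raise SampleSheetError(f"{self.sample_id}: unknown grade {self.grade!r}")


def stratum_of(meta: SampleMeta) -> str:
    """Reporting stratum for an incident-disease sample.

    Muscle-invasive disease (stage T2+) maps to MIBC; the five named
    grade-stage combinations map to themselves; everything else (CIS,
    unrecorded stage or grade, G1pT1) is pooled as "Other BC".
    """
    if meta.stage == "T2plus":
        return "MIBC"
    combo = f"{meta.grade}p{meta.stage}"
    if combo in ("G1pTa", "G2pTa", "G3pTa", "G2pT1", "G3pT1"):
        return combo
    return "Other BC"


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}
_NA = {"n/a", "na", "", "none", "nan"}


def _parse_bool(value: str, *, allow_na: bool = False) -> Optional[bool]:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    if allow_na and v in _NA:
        return None
    raise SampleSheetError(f"cannot parse boolean field {value!r}")


def load_sample_sheet(path: Union[str, Path]) -> list[SampleMeta]:
    """Read a sample sheet TSV into validated :class:`SampleMeta` records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "cohort", "bc_status", "age"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SampleSheetError(f"{path}: missing columns {missing}")
    out: list[SampleMeta] = []
    for r in df.itertuples():
        if not str(r.sample_id).strip():
            raise SampleSheetError(f"{path}: row with missing sample_id")
        age = float(r.age)
        out.append(
            SampleMeta(
                sample_id=str(r.sample_id),
                cohort=str(r.cohort),
                bc_status=bool(_parse_bool(r.bc_status)),
                age=age,
                sex=getattr(r, "sex", "unknown") or "unknown",
                stage=getattr(r, "stage", "nr") or "nr",
                grade=getattr(r, "grade", "nr") or "nr",
                future_recurrence=_parse_bool(
                    getattr(r, "future_recurrence", "n/a"), allow_na=True
                ),
            )
        )
    return out


def write_sample_sheet(metas: Sequence[SampleMeta], path: Union[str, Path]) -> None:
    rows = []
    for m in metas:
        fr = "n/a" if m.future_recurrence is None else str(m.future_recurrence).lower()
        rows.append(
            {
                "sample_id": m.sample_id,
                "cohort": m.cohort,
                "bc_status": str(m.bc_status).lower(),
                "age": m.age,
                "sex": m.sex,
                "stage": m.stage,
                "grade": m.grade,
                "future_recurrence": fr,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-site quality-filtered count tables

COUNT_COLUMNS = ["sample_id", "chrom", "pos", "alt", "depth", "alt_count"]


def _validate_counts(df: pd.DataFrame, where: str = "site counts") -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{where}: missing columns {missing}")
    df = df.copy()
    df["pos"] = df["pos"].astype(int)
    df["depth"] = df["depth"].astype(int)
    df["alt_count"] = df["alt_count"].astype(int)
    bad = df[(df["alt_count"] < 0) | (df["alt_count"] > df["depth"])]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{where}: alt_count outside [0, depth] for sample "
            f"{row['sample_id']} at {row['chrom']}:{row['pos']}"
        )
    return df


def load_site_counts(path: Union[str, Path]) -> pd.DataFrame:
    """Read a site-count TSV (sample_id, chrom, pos, alt, depth, alt_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str, "sample_id": str})
    return _validate_counts(df, str(path))


def write_site_counts(df: pd.DataFrame, path: Union[str, Path]) -> None:
    _validate_counts(df)[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)
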
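"""Quality-filtered VAF quantification at panel hotspots.

The variant allele frequency (VAF) at a site is the fraction of
quality-passing consensus base calls equal to the panel alt base; the
denominator is *all* quality-passing, non-N calls at the coordinate
(reference, alt, and other substitutions alike), matching bam-readcount
semantics.  A site with zero passing depth is *undefined*, never zero —
missing coverage must not masquerade as a negative result.

The per-sample classifier score is the maximum VAF over the non-excluded
panel sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .consensus import ConsensusCall
from .panel import Panel, SiteKey

__all__ = [
    "MaxVafStat",
    "UnevaluableSampleError",
    "DEFAULT_MIN_BASEQ",
    "pileup_vaf",
    "vaf_table_from_counts",
    "max_vaf",
    "max_vaf_table",
    "write_vaf_table",
    "load_vaf_table",
]

DEFAULT_MIN_BASEQ = 30

VAF_COLUMNS = ["sample_id", "gene", "chrom", "pos", "alt", "depth", "alt_count", "vaf"]


class UnevaluableSampleError(ValueError):
    """No panel site has defined (non-zero-depth) VAF for this sample."""


@dataclass(frozen=True)
class MaxVafStat:
    """The per-sample max-VAF score and which site produced it.

    ``alt_count``/``depth`` of the argmax site are kept so threshold
    comparisons can be done in exact rational arithmetic.
    """

    sample_id: str
    max_vaf: float
    argmax: SiteKey
    n_sites_evaluated: int
    alt_count: int
    depth: int

    @property
    def exact_vaf(self) -> Fraction:
        return Fraction(self.alt_count, self.depth)


def pileup_vaf(
    calls: Iterable[ConsensusCall],
    panel: Panel,
    sample_id: str,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> pd.DataFrame:
    """Tabulate quality-filtered depth and alt count per panel site.

    Depth counts consensus calls with ``qual >= min_baseq`` and base != N;
    alt_count counts the subset matching the panel alt base.  Sites with no
    passing calls get depth 0 and NaN vaf (undefined).
    """
    depth: dict[tuple[str, int], int] = {}
    alt: dict[SiteKey, int] = {}
    panel_pos = {(h.chrom, h.pos) for h in panel}
    for c in calls:
        if c.qual < min_baseq or c.base == "N":
            continue
        loc = (c.chrom, c.pos)
        if loc not in panel_pos:
            continue
        depth[loc] = depth.get(loc, 0) + 1
        key = (c.chrom, c.pos, c.base)
        alt[key] = alt.get(key, 0) + 1

    rows = []
    for h in panel:
        d = depth.get((h.chrom, h.pos), 0)
        a = alt.get(h.key, 0)
        rows.append(
            {
                "sample_id": sample_id,
                "gene": h.gene,
                "chrom": h.chrom,
                "pos": h.pos,
                "alt": h.alt_base,
                "depth": d,
                "alt_count": a,
                "vaf": a / d if d > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=VAF_COLUMNS)


def vaf_table_from_counts(counts: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Build a VAF table from pre-computed quality-filtered site counts.

    ``counts`` has columns sample_id, chrom, pos, alt, depth, alt_count.
    Every panel site is emitted for every sample; sites absent from the
    counts are undefined (depth 0, NaN vaf), not zero.
    """
    by_key = {h.key: h for h in panel}
    lookup: dict[tuple[str, SiteKey], tuple[int, int]] = {}
    sample_ids: list[str] = []
    seen: set[str] = set()
    for r in counts.itertuples():
        key = (str(r.chrom), int(r.pos), str(r.alt))
        if key not in by_key:
            continue
        sid = str(r.sample_id)
        if sid not in seen:
            seen.add(sid)
            sample_ids.append(sid)
        lookup[(sid, key)] = (int(r.depth), int(r.alt_count))

    rows = []
    for sid in sample_ids:
        for h in panel:
            d, a = lookup.get((sid, h.key), (0, 0))
            rows.append(
                {
                    "sample_id": sid,
                    "gene": h.gene,
                    "chrom": h.chrom,
                    "pos": h.pos,
                    "alt": h.alt_base,
                    "depth": d,
                    "alt_count": a,
                    "vaf": a / d if d > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=VAF_COLUMNS)


def max_vaf(table: pd.DataFrame, panel: Panel) -> MaxVafStat:
    """Maximum defined VAF over non-excluded sites for a one-sample table.

    Ties break toward the earlier panel site.  Raises
    :class:`UnevaluableSampleError` when every eligible site is undefined.
    """
    sids = table["sample_id"].unique()
    if len(sids) != 1:
        raise ValueError(f"expected a single-sample table, got {len(sids)} samples")
    sid = str(sids[0])

    indexed = {
        (str(r.chrom), int(r.pos), str(r.alt)): (int(r.depth), int(r.alt_count))
        for r in table.itertuples()
    }
    best: Optional[tuple[Fraction, SiteKey, int, int]] = None
    n_eval = 0
    for h in panel.active_hotspots():
        entry = indexed.get(h.key)
        if entry is None:
            continue
        d, a = entry
        if d == 0:
            continue
        n_eval += 1
        v = Fraction(a, d)
        if best is None or v > best[0]:
            best = (v, h.key, a, d)
    if best is None:
        raise UnevaluableSampleError(
            f"sample {sid}: no panel site with defined VAF"
        )
    v, key, a, d = best
    return MaxVafStat(
        sample_id=sid,
        max_vaf=a / d,
        argmax=key,
        n_sites_evaluated=n_eval,
        alt_count=a,
        depth=d,
    )


def max_vaf_table(table: pd.DataFrame, panel: Panel) -> list[MaxVafStat]:
    """Per-sample max-VAF statistics for a multi-sample VAF table."""
    return [
        max_vaf(sub, panel)
        for _, sub in table.groupby("sample_id", sort=False)
    ]


def write_vaf_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table[VAF_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_vaf_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str, "sample_id": str})
    missing = [c for c in VAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
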
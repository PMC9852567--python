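"""Collapse UMI-tagged raw reads into consensus base calls.

Reads sharing a unique molecular identifier (UMI) and fragment start derive
from a single input DNA molecule; collapsing them suppresses PCR and
sequencing errors, which is what makes sub-percent variant allele
frequencies measurable at all.  A consensus requires at least
``min_family_size`` raw reads (default 3); smaller families are discarded
outright rather than emitted at low quality.

The consensus rule is deliberately simple: the most frequent base wins if
it is supported by a strict majority of the family, otherwise the call is
``N`` (never a guess).  Consensus quality is the mean quality of the
supporting reads, capped at Q40 — a simplification of full Bayesian
consensus models; the downstream Q30 filter is what matters.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "ReadRecord",
    "UmiFamily",
    "ConsensusCall",
    "group_families",
    "call_consensus",
    "collapse_reads",
    "load_read_records",
    "write_read_records",
    "sam_to_read_records",
]

DEFAULT_MIN_FAMILY_SIZE = 3
MAX_CONSENSUS_QUAL = 40


@dataclass(frozen=True)
class ReadRecord:
    """One raw base observation at one genomic position."""

    read_id: str
    umi: str
    frag_start: int  # 1-based fragment start; part of the molecule key
    chrom: str
    pos: int  # 1-based position of the observed base
    base: str  # A/C/G/T/N
    qual: int  # Phred

    def __post_init__(self) -> None:
        if self.pos < 1 or self.frag_start < 1:
            raise ValueError(f"read {self.read_id}: positions must be >= 1")
        if self.qual < 0:
            raise ValueError(f"read {self.read_id}: negative quality")
        if self.base not in "ACGTN":
            raise ValueError(f"read {self.read_id}: base must be A/C/G/T/N")


@dataclass
class UmiFamily:
    """All raw observations of one molecule at one position."""

    umi: str
    frag_start: int
    chrom: str
    pos: int
    members: list[ReadRecord]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusCall:
    chrom: str
    pos: int
    base: str
    qual: int
    family_size: int


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a, b)) <= 1


def group_families(
    reads: Iterable[ReadRecord], umi_merge_distance: int = 0
) -> list[UmiFamily]:
    """Partition reads into UMI families keyed by (umi, frag_start, chrom, pos).

    With ``umi_merge_distance=1``, UMIs within Hamming distance 1 of a more
    abundant UMI at the same fragment start are merged into it (a simple
    greedy correction for sequencing errors in the UMI itself); distance 0
    (default) requires exact UMI identity.
    """
    if umi_merge_distance not in (0, 1):
        raise ValueError("umi_merge_distance must be 0 or 1")

    buckets: dict[tuple[str, int, str, int], list[ReadRecord]] = defaultdict(list)
    for r in reads:
        buckets[(r.umi, r.frag_start, r.chrom, r.pos)].append(r)

    if umi_merge_distance == 1:
        # Merge within each (frag_start, chrom, pos) locus, largest-first.
        by_locus: dict[tuple[int, str, int], list[tuple[str, list[ReadRecord]]]] = defaultdict(list)
        for (umi, fs, chrom, pos), members in buckets.items():
            by_locus[(fs, chrom, pos)].append((umi, members))
        merged: dict[tuple[str, int, str, int], list[ReadRecord]] = {}
        for (fs, chrom, pos), groups in by_locus.items():
            groups.sort(key=lambda g: (-len(g[1]), g[0]))
            accepted: list[tuple[str, list[ReadRecord]]] = []
            for umi, members in groups:
                target = next((a for a in accepted if _hamming1(a[0], umi)), None)
                if target is None:
                    accepted.append((umi, list(members)))
                else:
                    target[1].extend(members)
            for umi, members in accepted:
                merged[(umi, fs, chrom, pos)] = members
        buckets = merged

    return [
        UmiFamily(umi=k[0], frag_start=k[1], chrom=k[2], pos=k[3], members=v)
        for k, v in buckets.items()
    ]


def call_consensus(
    family: UmiFamily, min_family_size: int = DEFAULT_MIN_FAMILY_SIZE
) -> Optional[ConsensusCall]:
    """Collapse one family to a consensus call, or None if too small.

    The winning base must be supported by strictly more than half the
    family; exact ties (or no majority) yield base ``N``.  ``N`` raw bases
    count toward family size but can also win only by the same rule.
    """
    n = len(family.members)
    if n == 0:
        raise ValueError("empty family")
    if n < min_family_size:
        return None
    counts = Counter(r.base for r in family.members)
    base, top = counts.most_common(1)[0]
    if top * 2 <= n:  # no strict majority
        return ConsensusCall(family.chrom, family.pos, "N", 0, n)
    supporters = [r.qual for r in family.members if r.base == base]
    qual = min(MAX_CONSENSUS_QUAL, round(sum(supporters) / len(supporters)))
    return ConsensusCall(family.chrom, family.pos, base, qual, n)


def collapse_reads(
    reads: Iterable[ReadRecord],
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
    umi_merge_distance: int = 0,
) -> list[ConsensusCall]:
    """group_families + call_consensus, dropping undersized families."""
    calls = []
    for fam in group_families(reads, umi_merge_distance):
        c = call_consensus(fam, min_family_size)
        if c is not None:
            calls.append(c)
    return calls


# ---------------------------------------------------------------------------
# IO

READ_COLUMNS = ["read_id", "umi", "frag_start", "chrom", "pos", "base", "qual"]


def load_read_records(path: Union[str, Path]) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "umi": str, "read_id": str})
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        ReadRecord(
            read_id=str(r.read_id),
            umi=str(r.umi),
            frag_start=int(r.frag_start),
            chrom=str(r.chrom),
            pos=int(r.pos),
            base=str(r.base),
            qual=int(r.qual),
        )
        for r in df.itertuples()
    ]


def write_read_records(reads: Sequence[ReadRecord], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "umi": r.umi,
                "frag_start": r.frag_start,
                "chrom": r.chrom,
                "pos": r.pos,
                "base": r.base,
                "qual": r.qual,
            }
            for r in reads
        ],
        columns=READ_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def sam_to_read_records(
    path: Union[str, Path], positions: Iterable[tuple[str, int]]
) -> list[ReadRecord]:
    """Extract per-base observations at panel positions from an aligned SAM.

    The UMI is taken from the RX tag when present, else from the final
    colon- or underscore-delimited field of the read name.  Only mapped,
    soft-clip-free single-end records are supported; positions are 1-based.
    """
    import pysam

    wanted = set((str(c), int(p)) for c, p in positions)
    out: list[ReadRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            if aln.cigartuples and any(op in (4, 5) for op, _ in aln.cigartuples):
                continue  # soft/hard clips shift the fragment start
            if aln.has_tag("RX"):
                umi = str(aln.get_tag("RX"))
            else:
                name = aln.query_name
                umi = name.split(":")[-1].split("_")[-1]
            frag_start = aln.reference_start + 1
            quals = aln.query_qualities
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                key = (aln.reference_name, rpos + 1)
                if key in wanted:
                    out.append(
                        ReadRecord(
                            read_id=aln.query_name,
                            umi=umi,
                            frag_start=frag_start,
                            chrom=aln.reference_name,
                            pos=rpos + 1,
                            base=aln.query_sequence[qpos].upper(),
                            qual=int(quals[qpos]) if quals is not None else 0,
                        )
                    )
    return out
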
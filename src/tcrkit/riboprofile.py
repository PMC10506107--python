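"""Ribosome-footprint region-density analysis for readthrough detection.

The analysis mirrors how readthrough is read out of ribosome profiling
data for a single transcript of interest: footprint reads are adapter
trimmed, length filtered (>= 24 nt), mapped to the transcript by exact
(100%) substring match, and assigned by their 5'-end position to one of
four regions —

* ``5UTR``: ``[0, cds_start)``
* ``CDS``:  ``[cds_start, stop1_start - upstream_offset)``
* ``ISR``:  ``[stop1_start - upstream_offset, stop2_start - downstream_offset)``
* ``3UTR``: ``[stop2_start - downstream_offset, transcript_length)``

The ISR window starts 12 nt upstream of the canonical stop and ends 22 nt
upstream of the downstream in-frame stop (defaults; both configurable).
The upstream shift makes the window a P-site proxy: a footprint whose
5' end sits ~12 nt upstream of a codon has that codon in its ribosomal
P-site, so reads from ribosomes decoding the stop and the ISR fall inside
the window, while elongating ribosomes that would only reach the distal
3'UTR by runoff are pushed out of it by the downstream margin.

Per-region density is read count divided by region length (reads/nt); the
readthrough signal is ISR density exceeding the distal-3'UTR background
across independent libraries (two-sided Welch t-test).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .reporter import TTestResult, welch_ttest
from .transcripts import IsrAnnotation, TranscriptModel

FIVE_UTR = "5UTR"
CDS_BODY = "CDS"
ISR_WINDOW = "ISR"
THREE_UTR_REST = "3UTR"
REGIONS = (FIVE_UTR, CDS_BODY, ISR_WINDOW, THREE_UTR_REST)

UNMAPPED = "unmapped"
AMBIGUOUS = "ambiguous"


class RegionSchemeError(ValueError):
    """The region partition is degenerate for the given offsets."""


@dataclass(frozen=True)
class FootprintRead:
    """A ribosome-protected fragment (24-34 nt in typical libraries)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Placement:
    """Result of exact-match mapping: a unique position, or a status."""

    status: str  # "mapped" | "unmapped" | "ambiguous"
    position: Optional[int] = None

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"


@dataclass(frozen=True)
class RegionScheme:
    """Partition of a transcript into the four density regions."""

    transcript_length: int
    cds_start: int
    stop1_start: int
    stop2_start: int
    upstream_offset: int = 12
    downstream_offset: int = 22

    def intervals(self) -> dict[str, tuple[int, int]]:
        return {
            FIVE_UTR: (0, self.cds_start),
            CDS_BODY: (self.cds_start, self.stop1_start - self.upstream_offset),
            ISR_WINDOW: (
                self.stop1_start - self.upstream_offset,
                self.stop2_start - self.downstream_offset,
            ),
            THREE_UTR_REST: (self.stop2_start - self.downstream_offset, self.transcript_length),
        }

    def region_length(self, region: str) -> int:
        lo, hi = self.intervals()[region]
        return hi - lo

    @property
    def boundaries(self) -> np.ndarray:
        """Interior breakpoints, sorted; used for vectorized assignment."""
        return np.array(
            [
                self.cds_start,
                self.stop1_start - self.upstream_offset,
                self.stop2_start - self.downstream_offset,
            ]
        )


def build_region_scheme(
    t: TranscriptModel,
    a: IsrAnnotation,
    upstream_offset: int = 12,
    downstream_offset: int = 22,
) -> RegionScheme:
    """Build the four-region partition with the ISR window offsets.

    Raises
    ------
    RegionSchemeError
        If the annotation has no ISR, the CDS body would be empty, or the
        ISR is too short for the offsets (the window needs
        ``isr_len_nt > downstream_offset - upstream_offset - 3``).
    """
    if upstream_offset < 0 or downstream_offset < 0:
        raise RegionSchemeError("offsets must be non-negative")
    if not a.has_isr:
        raise RegionSchemeError(f"{t.id}: no ISR annotated; cannot build region scheme")
    window_start = t.stop1_start - upstream_offset
    window_end = a.stop2_start - downstream_offset
    if window_start <= t.cds_start:
        raise RegionSchemeError(
            f"{t.id}: upstream offset {upstream_offset} reaches past the CDS start"
        )
    if window_end <= window_start:
        min_isr = downstream_offset - upstream_offset - 3
        raise RegionSchemeError(
            f"{t.id}: degenerate ISR window for offsets "
            f"({upstream_offset}, {downstream_offset}): ISR of {a.isr_len_nt} nt "
            f"requires length > {min_isr} nt"
        )
    scheme = RegionScheme(
        transcript_length=len(t.seq),
        cds_start=t.cds_start,
        stop1_start=t.stop1_start,
        stop2_start=a.stop2_start,
        upstream_offset=upstream_offset,
        downstream_offset=downstream_offset,
    )
    lengths = [scheme.region_length(r) for r in REGIONS]
    assert sum(lengths) == len(t.seq), "region intervals must partition the transcript"
    return scheme


def trim_adapter(read: FootprintRead, adapter: str, min_overlap: int = 3) -> FootprintRead:
    """Remove a 3' adapter by exact match.

    The cut point is the leftmost position where either the full adapter
    occurs, or a prefix of the adapter (at least ``min_overlap`` nt) runs
    to the read's 3' end. Reads without a detectable adapter are returned
    unchanged. This is a deliberately minimal exact-match trimmer; input
    pre-trimmed by a dedicated read processor is equally valid.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.seq
    cut = None
    full = seq.find(adapter)
    if full != -1:
        cut = full
    max_k = min(len(adapter), len(seq))
    for k in range(max_k, min_overlap - 1, -1):  # longest suffix match = leftmost cut
        if seq.endswith(adapter[:k]):
            pos = len(seq) - k
            cut = pos if cut is None else min(cut, pos)
            break
    if cut is None:
        return read
    return FootprintRead(id=read.id, seq=seq[:cut])


@dataclass
class FilterStats:
    n_input: int = 0
    n_too_short: int = 0
    n_with_n: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_too_short + self.n_with_n


def filter_reads(
    reads: Iterable[FootprintRead], min_len: int = 24
) -> tuple[list[FootprintRead], FilterStats]:
    """Retain reads with length >= ``min_len`` and no N calls.

    N-containing reads cannot satisfy the 100%-match mapping rule and are
    dropped up front; removal counts are reported per cause.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    stats = FilterStats()
    kept = []
    for read in reads:
        stats.n_input += 1
        if read.length < min_len:
            stats.n_too_short += 1
        elif "N" in read.seq:
            stats.n_with_n += 1
        else:
            kept.append(read)
    return kept, stats


def map_exact(
    read: FootprintRead, t: TranscriptModel, search_revcomp: bool = False
) -> Placement:
    """Map a read to the transcript by exact (100% match) substring search.

    Exactly one occurrence maps the read at its 0-based start; zero is
    unmapped; two or more is ambiguous (excluded from densities, counted).
    Footprints derive from the mRNA sense strand, so only the sense strand
    is searched unless ``search_revcomp`` is set, in which case occurrences
    of the reverse complement count toward ambiguity as well.
    """
    ref = t.seq
    queries = [read.seq]
    if search_revcomp:
        queries.append(reverse_complement(read.seq))
    hits: list[int] = []
    for q in queries:
        start = ref.find(q)
        while start != -1 and len(hits) < 2:
            hits.append(start)
            start = ref.find(q, start + 1)
        if len(hits) >= 2:
            break
    if not hits:
        return Placement(UNMAPPED)
    if len(hits) > 1:
        return Placement(AMBIGUOUS)
    return Placement("mapped", hits[0])


def assign_region(
    position: int,
    scheme: RegionScheme,
    read_length: Optional[int] = None,
    rule: str = "five_prime",
) -> str:
    """Label the region containing a mapped read.

    The default rule uses the read's 5'-end position (half-open interval
    membership), matching the P-site-proxy reading of the ISR window. The
    alternative ``rule="majority"`` assigns the region with the largest
    overlap with ``[position, position + read_length)`` (ties go to the
    5'-most region).
    """
    if not 0 <= position < scheme.transcript_length:
        raise ValueError(
            f"position {position} outside transcript [0, {scheme.transcript_length})"
        )
    if rule == "five_prime":
        for region, (lo, hi) in scheme.intervals().items():
            if lo <= position < hi:
                return region
        raise AssertionError("intervals do not partition the transcript")
    if rule == "majority":
        if read_length is None:
            raise ValueError("majority rule requires read_length")
        read_end = min(position + read_length, scheme.transcript_length)
        best_region, best_overlap = None, -1
        for region, (lo, hi) in scheme.intervals().items():
            overlap = max(0, min(hi, read_end) - max(lo, position))
            if overlap > best_overlap:
                best_region, best_overlap = region, overlap
        return best_region
    raise ValueError(f"unknown assignment rule {rule!r}")


def assign_regions(positions: np.ndarray, scheme: RegionScheme) -> np.ndarray:
    """Vectorized 5'-end region assignment; returns an array of labels."""
    positions = np.asarray(positions)
    if positions.size and (positions.min() < 0 or positions.max() >= scheme.transcript_length):
        raise ValueError("positions outside transcript bounds")
    idx = np.searchsorted(scheme.boundaries, positions, side="right")
    return np.array(REGIONS, dtype=object)[idx]


@dataclass
class RegionDensityTable:
    """Per-region counts, lengths and reads-per-nucleotide densities."""

    dataset_id: str
    counts: dict[str, int]
    lengths: dict[str, int]
    n_unmapped: int = 0
    n_ambiguous: int = 0
    n_filtered: int = 0
    densities: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.densities = {
            r: self.counts[r] / self.lengths[r] if self.lengths[r] else 0.0
            for r in REGIONS
        }

    @property
    def total_reads(self) -> int:
        """Accounting total: assigned + unmapped + ambiguous + filtered."""
        return sum(self.counts.values()) + self.n_unmapped + self.n_ambiguous + self.n_filtered

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset_id": self.dataset_id,
                "region": list(REGIONS),
                "read_count": [self.counts[r] for r in REGIONS],
                "region_len": [self.lengths[r] for r in REGIONS],
                "density": [self.densities[r] for r in REGIONS],
            }
        )


def compute_densities(
    assignments: Iterable[str],
    scheme: RegionScheme,
    dataset_id: str,
    n_unmapped: int = 0,
    n_ambiguous: int = 0,
    n_filtered: int = 0,
) -> RegionDensityTable:
    """Count region labels and divide by region lengths (reads/nt).

    Empty input is valid and yields zero densities.
    """
    counts = {r: 0 for r in REGIONS}
    for label in assignments:
        counts[label] += 1
    lengths = {r: scheme.region_length(r) for r in REGIONS}
    return RegionDensityTable(
        dataset_id=dataset_id,
        counts=counts,
        lengths=lengths,
        n_unmapped=n_unmapped,
        n_ambiguous=n_ambiguous,
        n_filtered=n_filtered,
    )


@dataclass
class DensityComparison:
    """ISR vs distal-3'UTR density comparison across footprint libraries."""

    dataset_ids: list[str]
    isr_densities: np.ndarray
    utr_densities: np.ndarray
    ratios: np.ndarray
    t_statistic: float
    df: float
    p_value: float
    n_datasets: int
    paired: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset_id": self.dataset_ids,
                "isr_density": self.isr_densities,
                "utr_density": self.utr_densities,
                "ratio": self.ratios,
            }
        )

    def summary_line(self) -> str:
        kind = "paired" if self.paired else "Welch"
        return (
            f"ISR vs 3'UTR density, N={self.n_datasets} datasets: "
            f"t={self.t_statistic:.3f}, df={self.df:.2f}, p={self.p_value:.3g} "
            f"(two-tailed {kind} t-test)"
        )


def compare_isr_vs_utr(
    tables: Sequence[RegionDensityTable], paired: bool = False
) -> DensityComparison:
    """Two-sided Welch t-test of ISR vs 3'UTR densities across datasets.

    Datasets are treated as independent samples by default (unpaired Welch
    with Welch–Satterthwaite degrees of freedom); a paired variant is
    available. Per-dataset ISR/3'UTR ratios are reported alongside.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 datasets to compare densities")
    isr = np.array([tab.densities[ISR_WINDOW] for tab in tables], dtype=float)
    utr = np.array([tab.densities[THREE_UTR_REST] for tab in tables], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(utr > 0, isr / np.where(utr > 0, utr, 1.0), np.inf)
    result: TTestResult = welch_ttest(isr, utr, paired=paired)
    return DensityComparison(
        dataset_ids=[tab.dataset_id for tab in tables],
        isr_densities=isr,
        utr_densities=utr,
        ratios=ratios,
        t_statistic=result.statistic,
        df=result.df,
        p_value=result.p_value,
        n_datasets=len(tables),
        paired=paired,
    )


def read_fastq(path: Union[Path, str]) -> list[FootprintRead]:
    """Read a FASTQ file (gzip allowed by suffix) into footprint reads."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return [FootprintRead(id=rec.id, seq=str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fastq")]


def process_library(
    reads: Sequence[FootprintRead],
    t: TranscriptModel,
    a: IsrAnnotation,
    dataset_id: str,
    min_len: int = 24,
    adapter: Optional[str] = None,
    min_overlap: int = 3,
    upstream_offset: int = 12,
    downstream_offset: int = 22,
    search_revcomp: bool = False,
    assignment_rule: str = "five_prime",
) -> RegionDensityTable:
    """Run one library through trim -> filter -> map -> assign -> densities.

    The accounting invariant holds by construction: region counts plus
    unmapped, ambiguous and filtered reads sum to the input read count.
    """
    scheme = build_region_scheme(t, a, upstream_offset, downstream_offset)
    if adapter:
        reads = [trim_adapter(r, adapter, min_overlap) for r in reads]
    kept, stats = filter_reads(reads, min_len=min_len)
    labels: list[str] = []
    n_unmapped = n_ambiguous = 0
    for read in kept:
        placement = map_exact(read, t, search_revcomp=search_revcomp)
        if placement.status == UNMAPPED:
            n_unmapped += 1
        elif placement.status == AMBIGUOUS:
            n_ambiguous += 1
        else:
            labels.append(
                assign_region(placement.position, scheme, read_length=read.length, rule=assignment_rule)
            )
    return compute_densities(
        labels,
        scheme,
        dataset_id=dataset_id,
        n_unmapped=n_unmapped,
        n_ambiguous=n_ambiguous,
        n_filtered=stats.n_removed,
    )
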
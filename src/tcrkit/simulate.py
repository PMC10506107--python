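"""Synthetic fixtures with the statistical structure the analysis assumes.

Every generator is deterministic given (seed, spec) and ships a truth
record, so each pipeline stage can be tested end-to-end with no external
downloads.

Three data types are emulated:

* a transcript with 5'UTR / CDS / ISR / distal-3'UTR architecture and
  exactly one in-frame stop codon downstream of the canonical one (the
  planted "stop 2");
* ribosome-footprint libraries whose read 5'-end positions follow a
  piecewise-constant per-nucleotide intensity — ``d`` on the CDS body,
  ``b + r*d`` on the ISR window, ``b`` elsewhere — where ``r`` is the
  readthrough fraction and ``b`` the untranslated background;
* dual-luciferase replicate tables with multiplicative log-normal noise
  around the true construct ratios, and ortholog peptide panels with
  i.i.d. per-column substitutions.

Default geometry follows the short neuronatin isoform on its mouse
transcript: an 81-codon CDS (246 nt with the stop), a 276-nt ISR, and a
UGA canonical stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .riboprofile import (
    REGIONS,
    FootprintRead,
    RegionScheme,
    build_region_scheme,
)
from .transcripts import (
    STOP_CODONS,
    IsrAnnotation,
    TranscriptModel,
    find_downstream_inframe_stop,
)

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """All generator parameters; the single source of fixture conditions.

    Transcript geometry defaults to the mouse neuronatin-like layout
    (246-nt CDS including the stop = 81 codons + stop; 276-nt ISR).
    Footprint densities are reads per nucleotide of generative intensity;
    they are rescaled so the expected library size equals ``n_reads``
    (region *ratios*, which every downstream estimator uses, are
    preserved). The luciferase model is parameterized by the true percent
    readthrough (default 11.1) with log-normal replicate noise.
    """

    seed: int = 0
    # transcript geometry (nt)
    utr5_len: int = 120
    cds_len: int = 246          # includes the canonical stop codon
    isr_len: int = 276
    utr3_rest_len: int = 399    # distal 3'UTR after the downstream stop
    # footprint model
    cds_density: float = 0.05           # reads/nt on the CDS body
    readthrough_fraction: float = 0.1
    background_density: float = 5e-4    # reads/nt off the translated regions
    read_len_range: tuple[int, int] = (24, 34)
    n_reads: int = 50_000
    upstream_offset: int = 12
    downstream_offset: int = 22
    # luciferase model
    true_percent: float = 11.1
    base_ratio: float = 0.63    # no-stop construct FLuc/RLuc ratio
    noise_sigma: float = 0.2    # log-scale SD of replicate noise
    n_replicates: int = 6
    # ortholog model
    n_species: int = 8
    substitution_prob: float = 0.1

    def __post_init__(self) -> None:
        for name in ("utr5_len", "cds_len", "isr_len", "utr3_rest_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cds_len % 3 or self.isr_len % 3:
            raise ValueError("cds_len and isr_len must be divisible by 3")
        if not 0 <= self.readthrough_fraction <= 1:
            raise ValueError("readthrough_fraction must be in [0, 1]")
        if self.cds_density < 0 or self.background_density < 0:
            raise ValueError("densities must be non-negative")
        lo, hi = self.read_len_range
        if lo < 1 or hi < lo:
            raise ValueError("read_len_range must satisfy 1 <= min <= max")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0 <= self.substitution_prob < 1:
            raise ValueError("substitution_prob must be in [0, 1)")
        if self.true_percent < 0:
            raise ValueError("true_percent must be non-negative")

    @property
    def transcript_length(self) -> int:
        return self.utr5_len + self.cds_len + self.isr_len + 3 + self.utr3_rest_len

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_transcript(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    stop1_codon: str = "TGA",
    stop2_codon: str = "TAA",
) -> tuple[TranscriptModel, IsrAnnotation]:
    """Random transcript with exactly one planted downstream in-frame stop.

    The CDS starts with ATG, its interior codons and all ISR codons are
    drawn uniformly from the 61 non-stop codons (so the first in-frame
    stop 3' of the canonical one is the planted stop 2, by construction),
    and the UTRs are unconstrained random sequence.
    """
    if stop1_codon not in STOP_CODONS or stop2_codon not in STOP_CODONS:
        raise ValueError("stop codons must be canonical (TAA/TAG/TGA)")
    if spec.cds_len < 9:
        raise ValueError("cds_len must fit start codon, one codon, and stop")
    if rng is None:
        rng = spec.rng(stream=1)
    n_interior = spec.cds_len // 3 - 2
    cds = "ATG" + "".join(rng.choice(_NON_STOP_CODONS, size=n_interior)) + stop1_codon
    isr = "".join(rng.choice(_NON_STOP_CODONS, size=spec.isr_len // 3))
    seq = (
        _random_nt(rng, spec.utr5_len)
        + cds
        + isr
        + stop2_codon
        + _random_nt(rng, spec.utr3_rest_len)
    )
    t = TranscriptModel(
        id=f"synthetic_tx_seed{spec.seed}",
        seq=seq,
        cds_start=spec.utr5_len,
        cds_end=spec.utr5_len + spec.cds_len,
    )
    ann = find_downstream_inframe_stop(t)
    assert ann.stop2_start == spec.utr5_len + spec.cds_len + spec.isr_len
    return t, ann


def _position_intensity(spec: SyntheticSpec, scheme: RegionScheme) -> np.ndarray:
    """Per-nucleotide generative intensity for read 5'-end positions."""
    rate = {
        "5UTR": spec.background_density,
        "CDS": spec.cds_density,
        "ISR": spec.background_density + spec.readthrough_fraction * spec.cds_density,
        "3UTR": spec.background_density,
    }
    lam = np.empty(scheme.transcript_length)
    for region, (lo, hi) in scheme.intervals().items():
        lam[lo:hi] = rate[region]
    return lam


@dataclass
class FootprintTruth:
    """Machine-readable ground truth for one simulated library."""

    spec: dict
    scheme_intervals: dict[str, tuple[int, int]]
    expected_counts: dict[str, float]
    expected_densities: dict[str, float]
    positions: np.ndarray = field(repr=False)
    n_reads: int = 0

    def to_dict(self) -> dict:
        """YAML-serializable view (positions summarized, not listed)."""
        return {
            "spec": self.spec,
            "scheme_intervals": {k: list(v) for k, v in self.scheme_intervals.items()},
            "expected_counts": self.expected_counts,
            "expected_densities": self.expected_densities,
            "n_reads": self.n_reads,
        }


def simulate_footprint_positions(
    spec: SyntheticSpec, scheme: RegionScheme, rng: np.random.Generator
) -> tuple[np.ndarray, FootprintTruth]:
    """Draw read 5'-end positions from the piecewise-constant intensity.

    Counts are Poisson per nucleotide, with the intensity scaled so the
    expected total equals ``spec.n_reads``. Positions cover the whole
    transcript; sequence extraction (and any 3'-end truncation) is the
    caller's concern.
    """
    lam = _position_intensity(spec, scheme)
    total = lam.sum()
    if total <= 0 or spec.n_reads == 0:
        scaled = np.zeros_like(lam)
    else:
        scaled = lam * (spec.n_reads / total)
    counts = rng.poisson(scaled)
    positions = np.repeat(np.arange(scheme.transcript_length), counts)
    rng.shuffle(positions)
    expected_counts = {
        region: float(scaled[lo:hi].sum())
        for region, (lo, hi) in scheme.intervals().items()
    }
    truth = FootprintTruth(
        spec=asdict(spec),
        scheme_intervals=scheme.intervals(),
        expected_counts=expected_counts,
        expected_densities={
            region: expected_counts[region] / scheme.region_length(region)
            for region in REGIONS
        },
        positions=positions,
        n_reads=int(positions.size),
    )
    return positions, truth


def simulate_footprints(
    t: TranscriptModel,
    a: IsrAnnotation,
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    mismatch_rate: float = 0.0,
    adapter: Optional[str] = None,
    adapter_fraction: float = 0.0,
) -> tuple[list[FootprintRead], FootprintTruth]:
    """Simulate a footprint library from a transcript.

    Read sequences are copied exactly from the transcript (100% match by
    construction), with lengths uniform in ``spec.read_len_range``; reads
    overrunning the 3' end are truncated there (and may then fall below
    the length filter downstream — a realistic edge effect). Optional
    contamination for negative tests: ``mismatch_rate`` substitutes one
    base per affected read, ``adapter_fraction`` appends ``adapter`` to
    affected reads.
    """
    if rng is None:
        rng = spec.rng(stream=2)
    scheme = build_region_scheme(t, a, spec.upstream_offset, spec.downstream_offset)
    positions, truth = simulate_footprint_positions(spec, scheme, rng)
    lo, hi = spec.read_len_range
    lengths = rng.integers(lo, hi + 1, size=positions.size)
    reads = []
    for i, (pos, length) in enumerate(zip(positions, lengths)):
        seq = t.seq[pos : pos + length]
        if mismatch_rate and rng.random() < mismatch_rate:
            j = int(rng.integers(len(seq)))
            alternatives = [base for base in "ACGT" if base != seq[j]]
            seq = seq[:j] + alternatives[int(rng.integers(3))] + seq[j + 1 :]
        if adapter and adapter_fraction and rng.random() < adapter_fraction:
            seq = seq + adapter
        reads.append(FootprintRead(id=f"read{i:06d}", seq=seq))
    return reads, truth


@dataclass
class LuciferaseTruth:
    true_percent: float
    base_ratio: float
    noise_sigma: float
    n_replicates: int

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_luciferase(
    spec: SyntheticSpec, rng: Optional[np.random.Generator] = None
):
    """Simulate a per-replicate dual-luciferase table.

    No-stop replicate ratios are log-normal around ``base_ratio``;
    with-stop ratios are log-normal around ``base_ratio * pi`` where
    ``pi = true_percent / 100``. RLuc readings are drawn per replicate and
    FLuc follows as ratio * RLuc, so the table carries raw paired
    luminescence values, not just ratios.
    """
    import pandas as pd

    if rng is None:
        rng = spec.rng(stream=3)
    pi = spec.true_percent / 100.0
    rows = []
    for construct, mean_ratio in (("no_stop", spec.base_ratio), ("with_stop", spec.base_ratio * pi)):
        for rep in range(1, spec.n_replicates + 1):
            rluc = 1e6 * np.exp(rng.normal(0.0, 0.1))
            ratio = mean_ratio * np.exp(rng.normal(0.0, spec.noise_sigma))
            rows.append(
                {
                    "construct": construct,
                    "replicate": f"rep{rep}",
                    "fluc": ratio * rluc,
                    "rluc": rluc,
                }
            )
    table = pd.DataFrame(rows, columns=["construct", "replicate", "fluc", "rluc"])
    truth = LuciferaseTruth(
        true_percent=spec.true_percent,
        base_ratio=spec.base_ratio,
        noise_sigma=spec.noise_sigma,
        n_replicates=spec.n_replicates,
    )
    return table, truth


@dataclass
class OrthologTruth:
    base_peptide: str
    substitution_prob: float
    mutated: np.ndarray = field(repr=False)  # (n_species, n_columns) bool

    def to_dict(self) -> dict:
        return {
            "base_peptide": self.base_peptide,
            "substitution_prob": self.substitution_prob,
            "n_mutations_per_species": self.mutated.sum(axis=1).tolist(),
        }


def simulate_ortholog_peptides(
    spec: SyntheticSpec,
    base_peptide: str,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[str], OrthologTruth]:
    """Ortholog panel: each species copies the base peptide with i.i.d.
    per-column substitutions to a uniformly random different residue."""
    if rng is None:
        rng = spec.rng(stream=4)
    base = np.array(list(base_peptide))
    n_cols = base.size
    mutated = rng.random((spec.n_species, n_cols)) < spec.substitution_prob
    peptides = []
    for s in range(spec.n_species):
        row = base.copy()
        for j in np.nonzero(mutated[s])[0]:
            alternatives = [aa for aa in _AMINO_ACIDS if aa != row[j]]
            row[j] = alternatives[int(rng.integers(len(alternatives)))]
        peptides.append("".join(row))
    truth = OrthologTruth(
        base_peptide=base_peptide,
        substitution_prob=spec.substitution_prob,
        mutated=mutated,
    )
    return peptides, truth


def write_fastq(reads: list[FootprintRead], path: Union[Path, str]) -> None:
    """Write reads as plain FASTQ with uniform placeholder qualities."""
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.seq), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = [40] * read.length
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_fasta(ids: list[str], seqs: list[str], path: Union[Path, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in zip(ids, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")
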
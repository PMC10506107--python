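"""Transcript models and inter-stop-codon region (ISR) discovery.

A transcript supporting termination-codon readthrough (TCR) carries, in its
3'UTR and in the reading frame of the CDS, a second stop codon downstream of
the canonical one. The segment between the two stops — the inter-stop-codon
region (ISR) — encodes the C-terminal extension appended to the canonical
protein when a ribosome decodes the first stop as sense.

Coordinates are 0-based, half-open throughout. ``cds_end`` points one past
the last nucleotide of the canonical stop codon, so the canonical stop
("stop 1") occupies ``seq[cds_end - 3:cds_end]`` and the in-frame scan for
the downstream stop ("stop 2") starts at ``cds_end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: flag set on an annotation when the 3'UTR contains no in-frame stop codon
NO_DOWNSTREAM_STOP = "no_downstream_stop"


class TranscriptError(ValueError):
    """A transcript record violates its structural invariants."""


class AnnotationError(ValueError):
    """An ISR annotation is inconsistent with its transcript."""


@dataclass
class TranscriptModel:
    """One transcript's sequence plus CDS coordinates.

    Parameters
    ----------
    id
        Transcript label (must match the annotation table).
    seq
        Nucleotide sequence over {A, C, G, T}. ``U`` is accepted on input
        and normalized to ``T``; case is normalized to upper.
    cds_start
        0-based index of the first nucleotide of the start codon.
    cds_end
        0-based exclusive index one past the last nucleotide of the
        canonical stop codon.

    Raises
    ------
    TranscriptError
        If the CDS is out of bounds, its length is not a multiple of 3, or
        it does not end in a canonical stop codon.
    """

    id: str
    seq: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.seq = str(self.seq).upper().replace("U", "T")
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise TranscriptError(
                f"{self.id}: sequence contains non-ACGT characters {sorted(bad)}"
            )
        if not (0 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise TranscriptError(
                f"{self.id}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"sequence bounds [0, {len(self.seq)})"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise TranscriptError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} "
                "is not divisible by 3"
            )
        if self.stop1_codon not in STOP_CODONS:
            raise TranscriptError(
                f"{self.id}: no canonical stop codon at CDS end "
                f"(found {self.stop1_codon!r})"
            )

    @property
    def stop1_start(self) -> int:
        """0-based index of the first nucleotide of the canonical stop."""
        return self.cds_end - 3

    @property
    def stop1_codon(self) -> str:
        return self.seq[self.cds_end - 3 : self.cds_end]

    @property
    def cds_len_aa(self) -> int:
        """Length of the canonical protein in amino acids (stop excluded)."""
        return (self.cds_end - self.cds_start) // 3 - 1


@dataclass
class IsrAnnotation:
    """Location of the downstream in-frame stop and the predicted extension.

    ``stop2_start`` and the ISR fields are ``None`` when the scan reached
    the transcript 3' end without finding an in-frame stop codon; ``flag``
    is then :data:`NO_DOWNSTREAM_STOP`.
    """

    transcript_id: str
    stop1_start: int
    stop2_start: Optional[int]
    isr_start: Optional[int]
    isr_end: Optional[int]
    isr_len_nt: Optional[int]
    extension_len_aa: Optional[int]
    extension_peptide: Optional[str]
    flag: Optional[str] = None

    @property
    def has_isr(self) -> bool:
        return self.stop2_start is not None


def find_downstream_inframe_stop(t: TranscriptModel) -> IsrAnnotation:
    """Scan 3' of the canonical stop, in the CDS frame, for the next stop.

    Triplets are read starting at ``cds_end`` toward the transcript 3' end;
    the first triplet in {TAA, TAG, TGA} is stop 2. Only the CDS frame is
    scanned: out-of-frame readthrough produces no extension product, so
    other frames are not modeled.

    Returns an annotation with the ISR interval (the nucleotides strictly
    between the two stop codons) and the translated extension peptide, or a
    flagged annotation when no in-frame stop exists before the 3' end.
    """
    pos = t.cds_end
    while pos + 3 <= len(t.seq):
        if t.seq[pos : pos + 3] in STOP_CODONS:
            isr_len = pos - t.cds_end
            ann = IsrAnnotation(
                transcript_id=t.id,
                stop1_start=t.stop1_start,
                stop2_start=pos,
                isr_start=t.cds_end,
                isr_end=pos,
                isr_len_nt=isr_len,
                extension_len_aa=isr_len // 3,
                extension_peptide=None,
            )
            ann.extension_peptide = translate_isr(t, ann)
            return ann
        pos += 3
    return IsrAnnotation(
        transcript_id=t.id,
        stop1_start=t.stop1_start,
        stop2_start=None,
        isr_start=None,
        isr_end=None,
        isr_len_nt=None,
        extension_len_aa=None,
        extension_peptide=None,
        flag=NO_DOWNSTREAM_STOP,
    )


def translate_isr(t: TranscriptModel, a: IsrAnnotation) -> str:
    """Translate the ISR with the standard genetic code.

    Raises
    ------
    AnnotationError
        If the annotation carries no ISR, or an internal stop codon is
        encountered (which signals inconsistent, e.g. hand-edited,
        coordinates — the scan guarantees the first in-frame stop is
        stop 2).
    """
    if not a.has_isr:
        raise AnnotationError(f"{a.transcript_id}: annotation has no ISR")
    region = t.seq[a.isr_start : a.isr_end]
    peptide = str(Seq(region).translate())
    if "*" in peptide:
        raise AnnotationError(
            f"{a.transcript_id}: internal stop codon in ISR "
            f"[{a.isr_start}, {a.isr_end}) — inconsistent annotation"
        )
    return peptide


def extended_isoform_length(canonical_aa: int, extension_aa: int) -> int:
    """Length in amino acids of the readthrough product.

    The extended isoform is the canonical protein plus the ISR-encoded
    extension, e.g. 81 + 89 = 170 aa and 54 + 89 = 143 aa for the two
    alternatively spliced neuronatin isoforms.
    """
    if canonical_aa < 0 or extension_aa < 0:
        raise ValueError("amino-acid lengths must be non-negative")
    return canonical_aa + extension_aa


def load_transcripts(fasta_path: Path | str, cds_table_path: Path | str) -> list[TranscriptModel]:
    """Load transcripts from FASTA plus a CDS coordinate table.

    The table is TSV with columns ``transcript_id``, ``cds_start``,
    ``cds_end`` (0-based, half-open; ``#`` comment lines allowed), or BED
    (no header, first three columns transcript_id/start/end) when the file
    name ends in ``.bed``.

    Every FASTA record must have a table row and vice versa; a missing id
    on either side is a hard error naming the id, and records violating
    :class:`TranscriptModel` invariants (e.g. a CDS not ending in a stop
    codon, which signals mis-annotation) are rejected.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    cds_table_path = Path(cds_table_path)
    if cds_table_path.suffix.lower() == ".bed":
        table = pd.read_csv(
            cds_table_path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["transcript_id", "cds_start", "cds_end"],
        )
    else:
        table = pd.read_csv(cds_table_path, sep="\t", comment="#")
        missing_cols = {"transcript_id", "cds_start", "cds_end"} - set(table.columns)
        if missing_cols:
            raise ValueError(f"CDS table missing columns: {sorted(missing_cols)}")
    annotated = set(table["transcript_id"].astype(str))
    for seq_id in seqs:
        if seq_id not in annotated:
            raise KeyError(f"transcript {seq_id!r} present in FASTA but absent from CDS table")
    models = []
    for row in table.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in seqs:
            raise KeyError(f"transcript {tid!r} present in CDS table but absent from FASTA")
        models.append(
            TranscriptModel(id=tid, seq=seqs[tid], cds_start=int(row.cds_start), cds_end=int(row.cds_end))
        )
    return models


def annotations_to_frame(annotations: list[IsrAnnotation]) -> pd.DataFrame:
    """Tabulate annotations (internal 0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id,
                "stop1_start": a.stop1_start,
                "stop2_start": a.stop2_start,
                "isr_start": a.isr_start,
                "isr_end": a.isr_end,
                "isr_len_nt": a.isr_len_nt,
                "extension_len_aa": a.extension_len_aa,
                "extension_peptide": a.extension_peptide,
                "flag": a.flag,
            }
            for a in annotations
        ]
    )
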
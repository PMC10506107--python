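"""Cross-species conservation scoring of ISR-encoded extension peptides.

Evolutionary conservation of the peptide encoded downstream of a canonical
stop codon is a classic readthrough signature: a 3'UTR under no coding
constraint drifts, while an ISR that is actually translated stays conserved
across species.

Unaligned peptides are first brought to equal length by pairwise global
alignment of each sequence against the first (reference) sequence with
identity scoring (match +1, mismatch 0, gap -1), then stacked into a
pseudo-MSA on the reference coordinate system (columns where the reference
is gapped, i.e. insertions relative to the reference, are dropped).
Pre-aligned input — all rows already the same length — bypasses alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

GAP = "-"


@dataclass
class ConservationProfile:
    """Per-column conservation of a stack of orthologous peptides.

    ``column_identity[i]`` is the fraction of non-gap residues in column
    ``i`` that match the column's majority residue (ties broken
    alphabetically); ``conserved_mask[i]`` thresholds it at ``tau``.
    """

    species_ids: list[str]
    aligned_peptides: list[str]
    column_identity: np.ndarray
    conserved_mask: np.ndarray
    majority_residue: list[str]
    tau: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_peptides[0]) if self.aligned_peptides else 0

    def to_frame(self) -> pd.DataFrame:
        """One row per alignment column (1-based positions for reporting)."""
        return pd.DataFrame(
            {
                "position": np.arange(1, self.n_columns + 1),
                "majority_residue": self.majority_residue,
                "identity": self.column_identity,
                "conserved": self.conserved_mask,
            }
        )


def _make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global", match_score=1.0, mismatch_score=0.0, gap_score=-1.0
    )


def align_to_reference(peptides: Sequence[str]) -> list[str]:
    """Stack peptides into a pseudo-MSA on the first sequence's coordinates.

    Each non-reference peptide is globally aligned to ``peptides[0]``
    (match +1, mismatch 0, gap -1; the aligner's first optimal alignment is
    taken) and projected onto reference columns by discarding columns where
    the reference carries a gap. Every output row therefore has the
    reference's ungapped length.
    """
    ref = peptides[0]
    aligner = _make_aligner()
    rows = [ref]
    for query in peptides[1:]:
        aln = aligner.align(ref, query)[0]
        ref_row, query_row = str(aln[0]), str(aln[1])
        projected = "".join(q for r, q in zip(ref_row, query_row) if r != GAP)
        rows.append(projected)
    return rows


def score_conservation(
    peptides: Sequence[str],
    tau: float = 0.8,
    species_ids: Optional[Sequence[str]] = None,
    prealigned: Optional[bool] = None,
) -> ConservationProfile:
    """Compute per-column identity and a conserved mask at threshold ``tau``.

    Parameters
    ----------
    peptides
        Two or more amino-acid strings, optionally gapped. If
        ``prealigned`` is None (default) the input is treated as aligned
        when all rows already have equal length, otherwise it is aligned
        pairwise to the first sequence.
    tau
        Identity threshold in (0, 1] above which a column counts as
        conserved. Default 0.8.
    """
    peptides = [str(p).upper() for p in peptides]
    if len(peptides) < 2:
        raise ValueError("conservation undefined for a single sequence")
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    if species_ids is None:
        species_ids = [f"species_{i + 1}" for i in range(len(peptides))]
    elif len(species_ids) != len(peptides):
        raise ValueError("species_ids and peptides lengths differ")

    if prealigned is None:
        prealigned = len({len(p) for p in peptides}) == 1
    if prealigned:
        if len({len(p) for p in peptides}) != 1:
            raise ValueError("prealigned input requires equal-length rows")
        rows = peptides
    else:
        rows = align_to_reference(peptides)

    n_cols = len(rows[0])
    identity = np.zeros(n_cols)
    majority = []
    for j in range(n_cols):
        residues = [row[j] for row in rows if row[j] != GAP]
        if not residues:
            identity[j] = 0.0
            majority.append(GAP)
            continue
        counts = Counter(residues)
        top = max(counts.values())
        best = min(res for res, c in counts.items() if c == top)  # alphabetical tie-break
        identity[j] = top / len(residues)
        majority.append(best)

    return ConservationProfile(
        species_ids=list(species_ids),
        aligned_peptides=list(rows),
        column_identity=identity,
        conserved_mask=identity >= tau,
        majority_residue=majority,
        tau=tau,
    )
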
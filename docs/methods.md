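# Methods

## Scope and model

`tcr-kit` treats termination-codon readthrough (TCR) as a single-transcript
phenomenon with three observable signatures: (i) an in-frame stop codon
downstream of the canonical one whose intervening sequence (the ISR) encodes
a conserved peptide, (ii) ribosome-footprint density in the ISR above the
distal-3′UTR background, and (iii) luminescence from a reporter placed
downstream of the test stop codon. The package computes each signature and
provides matched synthetic generators; it does not model genome coordinates,
spliced alignment, codon-specific readthrough efficiencies (e.g. the higher
leakiness of UGA), or phylogeny-aware conservation.

## Coordinates and ISR discovery

All internal coordinates are 0-based half-open; human-readable reports use
1-based positions. A transcript record is `(seq, cds_start, cds_end)` with
`cds_end` one past the canonical stop codon; records whose CDS length is not
a codon multiple or does not end in TAA/TAG/TGA are rejected as
mis-annotated. The downstream-stop scan reads triplets starting at
`cds_end`, in the CDS frame only, and takes the first stop codon. Only the
CDS frame is scanned because out-of-frame reporter constructs yield
background-level signal — readthrough produces an extension only in frame.
A transcript whose 3′UTR contains no in-frame stop is flagged rather than
erroring, since that is a biological observation (no defined extension), not
an input defect. Translation uses the standard genetic code via biopython;
an internal stop during ISR translation is a hard error because it can only
arise from hand-edited coordinates.

The extended-isoform length is plain addition of canonical and extension
codon counts, reproducing the published 81 + 89 = 170 and 54 + 89 = 143
arithmetic. Note a documented discrepancy in the source material: the mouse
ISR is given as 276 nt (92 codons) yet 89 aa is added to both mouse
isoforms; the addition is implemented as printed and the generator's
`isr_len` controls which ISR length any synthetic transcript actually has.

## Conservation scoring

Orthologous extension peptides are stacked into a pseudo-MSA: each sequence
is globally aligned to the first (reference) with identity scoring
(match +1, mismatch 0, gap −1; biopython's `PairwiseAligner`, first optimal
alignment) and projected onto reference columns by discarding columns where
the reference is gapped. This deliberately simple, fully specified scheme
keeps results reproducible where a published alignment method is not
available; pre-aligned (equal-length) input bypasses alignment, and the
permutation-invariance property is guaranteed for that path. Column identity
is the fraction of non-gap residues matching the column's majority residue
(ties broken alphabetically); the conserved mask thresholds identity at
τ = 0.8 by default — a conventional "mostly identical" cutoff, configurable
because shading thresholds in published alignment figures are rarely stated.

## Footprint analysis

Reads are 3′-adapter trimmed by exact match (cut at the leftmost full
adapter occurrence or adapter-prefix suffix of ≥ 3 nt) — a minimal trimmer
by design, since production libraries arrive pre-trimmed; then filtered to
≥ 24 nt and no N; then mapped by exact substring search on the sense strand
(footprints derive from mRNA). Exactly one occurrence maps the read; zero is
unmapped; two or more is ambiguous and excluded from densities but counted,
so the accounting invariant `assigned + unmapped + ambiguous + filtered =
input` holds for every run and is asserted in tests.

Region assignment uses the read's **5′-end position** against the partition
5′UTR `[0, cds_start)`, CDS body `[cds_start, stop1 − u)`, ISR window
`[stop1 − u, stop2 − d)`, distal 3′UTR `[stop2 − d, L)` with defaults
`u = 12`, `d = 22`. The 12-nt upstream offset matches the canonical distance
from a footprint's 5′ end to the ribosomal P-site, making the window a
P-site proxy; the offsets are configuration values so sensitivity can be
tested, and the upstream offset is measured from the first nucleotide of the
stop codon. A majority-overlap assignment rule is available behind a flag.
Degenerate windows (ISR shorter than `d − u − 3` nt) are rejected with the
numeric minimum. Density is reads per nucleotide of region length; the
cross-library readout is a two-tailed Welch *t* test between the ISR and
distal-3′UTR density vectors, treating libraries as independent samples
(a paired variant exists behind a flag).

## Reporter quantification

%TCR is `100 · mean(with-stop ratios) / mean(no-stop ratios)` — mean of
per-replicate FLuc/RLuc ratios within each construct, then the quotient —
because the published example arithmetic (0.0705/0.6347 → 11.1 %) is
reproducible only under this reading. No background subtraction is applied
by default (an optional vector-only construct can be subtracted). Display
truncates percentages to one decimal: truncation, not round-half, is the
only one-decimal convention consistent with all three published example
values (0.0273/0.3748 = 7.2839 prints as 7.2); full precision is kept
internally. The estimate is scale-invariant and equals exactly 100 % when
the two constructs coincide.

Welch, pooled-variance Student and paired t-tests are provided through one
surface (scipy-backed); the degenerate all-identical case returns t = 0,
p = 1 rather than NaN, since "no difference and no variability" is a
no-signal observation, not an undefined one. ΔΔCt fold change is
`2^(−ΔΔCt)`; densitometry normalization is band/loading.

## Synthetic generators

The generators define the study conditions and are deterministic given
(seed, spec), with independent RNG streams per generator so adding one does
not perturb another.

* **Transcript**: 120-nt 5′UTR, 246-nt CDS (81 codons + stop, matching the
  short neuronatin isoform), 276-nt ISR (mouse length), UGA canonical stop,
  planted TAA downstream stop, 399-nt distal 3′UTR. CDS-interior and ISR
  codons are drawn uniformly from the 61 non-stop codons, so the planted
  stop is provably the first in-frame stop.
* **Footprints**: read 5′-end positions are Poisson per nucleotide with
  intensity `d` on the CDS body, `b + r·d` on the ISR window and `b`
  elsewhere (defaults `d = 0.05`, `b = 5·10⁻⁴` reads/nt, `r = 0.1`),
  rescaled so the expected library size equals `n_reads` (default 50,000);
  the rescaling preserves every density ratio the estimators use. Lengths
  are uniform on 24–34 nt; sequences are copied verbatim from the
  transcript, so 100 % mapping holds by construction, with optional
  mismatch/adapter contamination for negative tests. The 5′-end position is
  the generative primitive, mirroring the assignment rule, so recovery of
  `r̂ = (ISR − 3′UTR)/CDS density` is well-posed. Reads drawn near the 3′
  terminus are truncated at the transcript end (and may then fall below the
  length filter); null-calibration experiments therefore consume generator
  positions directly, where no terminal edge effect exists that could bias
  the ISR-vs-3′UTR null.
* **Luciferase**: no-stop ratios log-normal around 0.63 (cosmetically near
  the published no-stop mean 0.6347), with-stop around `0.63 · π` with
  π = 11.1 % by default, σ = 0.2 on the log scale, 6 replicates; RLuc
  readings are drawn per replicate and FLuc follows as ratio × RLuc.
* **Orthologs**: 8 species copying a base peptide with i.i.d. per-column
  substitution probability 0.1 to a uniformly random different residue;
  the truth record lists mutated columns.

What the generators do **not** emulate: rRNA contamination, ligation and
nuclease bias, UMI structure, reads spanning splice junctions, codon-level
pausing, and plate-position effects in luminescence. Passing tests therefore
demonstrate correctness of the computational procedure under its stated
sampling model, not robustness to every artefact of real libraries.

## Experiment sizes and numerical choices

Simulation-based checks use: 15 libraries of 10,000 reads for the tenfold
ISR-contrast comparison (region counts in the hundreds, ample for the
contrast); 10 seeds × 50,000 reads per readthrough fraction for recovery;
200 simulations × 15 libraries of 5,000 reads for null calibration; 200
tables for luciferase recovery — sizes chosen so Monte-Carlo error is small
relative to the tolerance each property states. Oracle-equivalence checks
run on ≥ 1,000 random instances with the t-test compared to a from-scratch
textbook implementation at 10⁻⁹. Ties, degenerate inputs and empty streams
are defined rather than erroring wherever the empty case is scientifically
meaningful (zero reads → zero densities; empty construct list → error).

## Limitations

Single-transcript exact matching only (no aligner, no multi-gene
quantification); multi-mapping reads are counted but never placed;
conservation is reference-anchored, so insertions relative to the reference
are invisible to the profile; the readthrough estimator assumes the
piecewise-constant density model and will be biased by strong codon-level
pausing near the stop.
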
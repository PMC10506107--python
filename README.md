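# tcr-kit

Tools for detecting and quantifying **termination-codon readthrough (TCR)**
on single transcripts. Some mRNAs carry, in the reading frame of their CDS,
a second stop codon downstream of the canonical one; when a ribosome decodes
the canonical stop as sense, translation continues through the
**inter-stop-codon region (ISR)** and appends a C-terminal extension to the
protein. `tcr-kit` implements the three computational readouts used to
establish such an event — for example on neuronatin, whose mouse transcript
carries a 276-nt ISR and whose human ISR of 267 nt encodes an 89-aa
extension (so the 81- and 54-aa canonical isoforms extend to 170 and 143 aa):

1. **ISR discovery and conservation** (`transcripts`, `conservation`): scan
   in-frame triplets 3′ of the canonical stop, translate the ISR, and score
   per-column identity of the predicted extension peptide across orthologs.
2. **Ribosome-footprint region densities** (`riboprofile`): length-filter
   (≥ 24 nt) and exact-match (100%) map footprint reads to the transcript,
   assign each read's 5′ end to 5′UTR / CDS / ISR window / distal 3′UTR —
   the ISR window runs from 12 nt upstream of the canonical stop to 22 nt
   upstream of the downstream stop — and compare ISR density (reads/nt)
   with the distal-3′UTR background across libraries by a two-tailed Welch
   *t* test.
3. **Dual-luciferase readthrough efficiency** (`reporter`):

   ```
   %TCR = 100 · mean(FLuc/RLuc, with-stop) / mean(FLuc/RLuc, no-stop)
   ```

   e.g. 0.0705/0.6347 → 11.1 % in Neuro-2a cells, with the paired ΔΔCt and
   densitometry helpers used alongside such assays.

A deterministic synthetic-data generator (`simulate`) produces transcripts
with a planted downstream stop, footprint libraries with region-specific
Poisson read densities, noisy luciferase tables and ortholog peptide panels,
each with a machine-readable truth record, so the whole pipeline is testable
offline.

Audience: computational biologists screening transcripts for readthrough
candidates, and bench groups quantifying reporter assays reproducibly.

## Worked example

Simulate a footprint library on a neuronatin-like transcript (276-nt ISR,
10 % readthrough) and run the three analyses:

```bash
tcr-kit simulate footprints --seed 7 --out demo        # transcript + FASTQ + truth
tcr-kit simulate luciferase --seed 7 --out demo
tcr-kit scan-isr --fasta demo/transcript.fasta --cds demo/cds.tsv --out demo/scan
tcr-kit ribo-density --fastq demo/footprints.fastq \
    --fasta demo/transcript.fasta --cds demo/cds.tsv --out demo/dens
tcr-kit reporter-tcr --table demo/luciferase.tsv \
    --with-stop with_stop --no-stop no_stop
```

prints (seed 7, 20,000 requested reads):

```
scan-isr: 1 transcripts, 1 with an ISR
footprints: 19940 reads = 19920 assigned + 0 unmapped + 0 ambiguous + 20 filtered
%TCR = 11.0% (with-stop mean 0.0763, no-stop mean 0.6902; Welch t=-7.386, p=0.000679)
```

The scan line confirms one downstream in-frame stop was found
(`demo/scan/isr_annotations.tsv` records its position, the 276-nt ISR and
the 92-aa extension peptide). The density line is the read-accounting audit:
every input read is either assigned to a region or explained as unmapped,
ambiguous or filtered. The reporter line is the readthrough efficiency —
here the simulation's true 11.1 % recovered as 11.0 % from six noisy
replicates, with the Welch test confirming the with-stop and no-stop
constructs differ. `tcr-kit run --config cfg.yaml` chains the stages and
writes a `manifest.json` (config hash, input checksums, per-stage counts)
for reproducibility; `tcr-kit ribo-compare` pools per-library density
tables into the ISR-vs-3′UTR Welch comparison.

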
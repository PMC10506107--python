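"""Pipeline orchestration: wire the stages together and write a manifest.

Three analyses are supported, run in order for whichever inputs the config
provides: ISR scan (+ optional conservation), footprint region densities
(+ ISR-vs-3'UTR comparison when >= 2 libraries), and dual-luciferase
readthrough quantification. Each run writes a ``manifest.json`` recording
the config hash, package and Python versions, input checksums, and
per-stage read accounting — re-running an identical manifest reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .config import RunConfig
from .conservation import score_conservation
from .reporter import fluc_rluc_ratios, percent_tcr, read_luciferase_tsv, welch_ttest
from .riboprofile import compare_isr_vs_utr, process_library, read_fastq
from .transcripts import annotations_to_frame, find_downstream_inframe_stop, load_transcripts

log = logging.getLogger("tcrkit")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    config_sha256: str
    tcrkit_version: str
    python_version: str
    inputs: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Manifest:
    """Execute the configured stages and write outputs plus a manifest.

    Raises on any stage error (callers map that to a non-zero exit).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_json = config.model_dump_json()
    manifest = Manifest(
        config_sha256=hashlib.sha256(config_json.encode()).hexdigest(),
        tcrkit_version=__version__,
        python_version=platform.python_version(),
    )
    for path in [config.fasta, config.cds, config.peptides, config.luciferase, *config.fastq]:
        if path is not None:
            manifest.inputs[str(path)] = _sha256(Path(path))

    annotations = {}
    transcripts = {}
    if config.fasta and config.cds:
        models = load_transcripts(config.fasta, config.cds)
        anns = [find_downstream_inframe_stop(t) for t in models]
        transcripts = {t.id: t for t in models}
        annotations = {a.transcript_id: a for a in anns}
        frame = annotations_to_frame(anns)
        frame.to_csv(outdir / "isr_annotations.tsv", sep="\t", index=False)
        with open(outdir / "extension_peptides.fasta", "w") as handle:
            for a in anns:
                if a.has_isr and a.extension_peptide:
                    handle.write(f">{a.transcript_id}\n{a.extension_peptide}\n")
        stage = {
            "name": "scan-isr",
            "n_transcripts": len(models),
            "n_with_isr": sum(a.has_isr for a in anns),
        }
        log.info("scan-isr: %d transcripts, %d with an ISR", len(models), stage["n_with_isr"])
        manifest.stages.append(stage)

    if config.peptides:
        records = list(SeqIO.parse(str(config.peptides), "fasta"))
        profile = score_conservation(
            [str(r.seq) for r in records],
            tau=config.tau,
            species_ids=[r.id for r in records],
        )
        profile.to_frame().to_csv(outdir / "conservation.tsv", sep="\t", index=False)
        manifest.stages.append(
            {
                "name": "conservation",
                "n_species": len(records),
                "n_conserved_columns": int(profile.conserved_mask.sum()),
            }
        )

    if config.fastq:
        if not transcripts:
            raise ValueError("footprint analysis requires fasta and cds inputs")
        tid, t = next(iter(transcripts.items()))
        a = annotations[tid]
        tables = []
        for fq in config.fastq:
            reads = read_fastq(fq)
            table = process_library(
                reads,
                t,
                a,
                dataset_id=Path(fq).stem,
                min_len=config.min_read_len,
                adapter=config.adapter,
                upstream_offset=config.upstream_offset,
                downstream_offset=config.downstream_offset,
                search_revcomp=config.strand == "both",
                assignment_rule=config.assignment_rule,
            )
            table.to_frame().to_csv(outdir / f"density_{table.dataset_id}.tsv", sep="\t", index=False)
            log.info(
                "ribo-density %s: %d reads = %d assigned + %d unmapped + %d ambiguous + %d filtered",
                table.dataset_id, table.total_reads, sum(table.counts.values()),
                table.n_unmapped, table.n_ambiguous, table.n_filtered,
            )
            tables.append(table)
        stage = {
            "name": "ribo-density",
            "n_libraries": len(tables),
            "accounting": {
                tab.dataset_id: {
                    "total": tab.total_reads,
                    "assigned": sum(tab.counts.values()),
                    "unmapped": tab.n_unmapped,
                    "ambiguous": tab.n_ambiguous,
                    "filtered": tab.n_filtered,
                }
                for tab in tables
            },
        }
        manifest.stages.append(stage)
        if len(tables) >= 2:
            comparison = compare_isr_vs_utr(tables, paired=config.paired_comparison)
            comparison.to_frame().to_csv(outdir / "isr_vs_utr.tsv", sep="\t", index=False)
            (outdir / "isr_vs_utr_summary.txt").write_text(comparison.summary_line() + "\n")
            manifest.stages.append(
                {
                    "name": "ribo-compare",
                    "n_datasets": comparison.n_datasets,
                    "t": comparison.t_statistic,
                    "p": comparison.p_value,
                }
            )

    if config.luciferase:
        table = read_luciferase_tsv(config.luciferase)
        with_ratios = fluc_rluc_ratios(table, config.with_stop)
        no_ratios = fluc_rluc_ratios(table, config.no_stop)
        background = (
            fluc_rluc_ratios(table, config.background) if config.background else None
        )
        estimate = percent_tcr(with_ratios, no_ratios, background=background)
        test = welch_ttest(with_ratios, no_ratios)
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "with_stop": config.with_stop,
                    "no_stop": config.no_stop,
                    "percent_tcr": estimate.percent_tcr,
                    "with_stop_mean": estimate.with_stop_mean,
                    "no_stop_mean": estimate.no_stop_mean,
                    "n_with": estimate.n_with,
                    "n_no": estimate.n_no,
                    "t": test.statistic,
                    "df": test.df,
                    "p": test.p_value,
                }
            ]
        ).to_csv(outdir / "readthrough_estimate.tsv", sep="\t", index=False)
        log.info("reporter-tcr: %s (n=%d vs n=%d)", estimate, estimate.n_with, estimate.n_no)
        manifest.stages.append(
            {"name": "reporter-tcr", "percent_tcr": estimate.percent_tcr, "p": test.p_value}
        )

    manifest.write(outdir / "manifest.json")
    return manifest
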
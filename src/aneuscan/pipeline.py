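"""End-to-end orchestration: baseline -> normalize -> QC -> segment -> call
-> cohort statistics, with a manifest that pins config, seed and versions.

Identical config + inputs produce byte-identical outputs; every output
names the thresholds that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import CINCaller, QC_FAILED, annotate_genes, summarize_arms
from .genome import BinGrid, GenomeDefinition, make_bins, toy_genome
from .io import (
    write_bin_counts,
    write_call_bed,
    write_fastq,
    write_json,
    write_profile_tsv,
    write_seg,
)
from .microbial import MicrobialReference, ScreenParams, screen_sample
from .normalize import CoverageNormalizer, qc_sample
from .segmentation import CBSSegmenter
from .simulate import (
    SimConfig,
    default_case_specs,
    make_qc_failure_sample,
    simulate_cohort,
    spike_microbial_reads,
)
from .stats import build_cohort_table, proportion_summary, subtype_association

__all__ = ["PipelineConfig", "run_pipeline", "simulate_dataset"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline constants in one serializable record."""

    bin_size: int = 200_000
    qc_threshold: float = 0.38
    alpha: float = 0.05
    n_permutations: int = 1000
    min_seg_bins: int = 3
    merge_tol: float = 0.0
    z_gain: float = 3.0
    z_loss: float = -3.0
    min_event_bins: int = 50
    cin_min_aberrant_fraction: float = 0.0
    arm_coverage_threshold: float = 0.5
    max_mismatches: int = 1
    min_reads_exclusive: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    outdir,
    grid: BinGrid,
    control_matrix: np.ndarray,
    case_matrix: np.ndarray,
    sample_ids: list[str],
    config: PipelineConfig | None = None,
    subtypes: dict[str, str] | None = None,
    gene_loci=None,
    microbial_reads: dict[str, list[str]] | None = None,
    microbial_reference: MicrobialReference | None = None,
    log=lambda msg: None,
) -> dict:
    """Run all stages and write per-module outputs plus a manifest.

    Returns the manifest dict.  QC-failed samples are logged and skipped
    downstream but still appear in the sample reports.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    normalizer = CoverageNormalizer().fit(control_matrix)
    segmenter = CBSSegmenter(
        alpha=config.alpha,
        n_permutations=config.n_permutations,
        min_seg_bins=config.min_seg_bins,
        merge_tol=config.merge_tol,
        seed=config.seed,
    )
    caller = CINCaller(
        z_gain=config.z_gain,
        z_loss=config.z_loss,
        min_event_bins=config.min_event_bins,
        cin_min_aberrant_fraction=config.cin_min_aberrant_fraction,
        arm_coverage_threshold=config.arm_coverage_threshold,
    )

    results = []
    segments_by_sample: dict[str, list] = {}
    gene_rows = []
    case_matrix = np.asarray(case_matrix, dtype=float)
    for i, sid in enumerate(sample_ids):
        profile = normalizer.profile(case_matrix[i], sample_id=sid)
        qc = qc_sample(profile, grid, threshold=config.qc_threshold)
        write_profile_tsv(outdir / f"{sid}.profile.tsv", grid, profile)
        if not qc.passed:
            log(f"{sid}: QC failed (statistic {qc.statistic:.3f}), skipped")
            results.append(
                caller.predict_sample([], qc, grid, profile.usable_mask, sid)
            )
            continue
        segments = segmenter.segment(profile, grid)
        segments_by_sample[sid] = segments
        result = caller.predict_sample(
            segments, qc, grid, profile.usable_mask, sid
        )
        results.append(result)
        write_call_bed(outdir / f"{sid}.calls.bed", result.called_segments, sid)
        if gene_loci:
            loci = [
                l
                for l in gene_loci
                if l.chrom in grid.genome
                and l.start < grid.genome[l.chrom].length
            ]
            row = {"sample_id": sid}
            row.update(
                annotate_genes(result.called_segments, loci, grid, profile.usable_mask)
            )
            gene_rows.append(row)
        log(f"{sid}: {result.status}, {len(segments)} segments")

    write_seg(outdir / "segments.seg", segments_by_sample)
    write_json(
        outdir / "sample_reports.json", {r.sample_id: r.to_dict() for r in results}
    )
    if gene_rows:
        pd.DataFrame(gene_rows).to_csv(outdir / "gene_calls.tsv", sep="\t", index=False)

    evaluable = [r for r in results if r.status != QC_FAILED]
    cohort: dict = {"n_samples": len(results), "n_evaluable": len(evaluable)}
    if evaluable:
        arm_freq = summarize_arms(results, grid)
        arm_freq.to_csv(outdir / "arm_frequencies.tsv", sep="\t")
        n_pos = sum(r.status == "CIN-positive" for r in evaluable)
        cohort["cin_positive_percent"] = proportion_summary(n_pos, len(evaluable))
    if subtypes and evaluable:
        table, dropped = build_cohort_table(results, subtypes)
        pd.DataFrame(
            table.counts, index=table.row_labels, columns=table.col_labels
        ).to_csv(outdir / "cohort_table.tsv", sep="\t")
        if len(table.row_labels) - ("N/A" in table.row_labels) >= 2:
            test = subtype_association(table)
            cohort["subtype_chi_square"] = test.to_dict()
            cohort["subtype_chi_square"]["excludes_undetermined"] = True
        cohort["n_qc_dropped"] = dropped
    if microbial_reads and microbial_reference:
        screens = {}
        params = ScreenParams(
            max_mismatches=config.max_mismatches,
            min_reads_exclusive=config.min_reads_exclusive,
        )
        for sid, reads in microbial_reads.items():
            screens[sid] = screen_sample(reads, microbial_reference, params).to_dict()
        write_json(outdir / "microbial_screen.json", screens)
        cohort["microbial_screened"] = len(screens)
    write_json(outdir / "cohort_report.json", cohort)

    manifest = {
        "tool": "aneuscan",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_controls": int(np.asarray(control_matrix).shape[0]),
        "n_cases": len(sample_ids),
        "n_bins": grid.n_bins,
        "statuses": {r.sample_id: r.status for r in results},
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    write_json(outdir / "manifest.json", manifest)
    return manifest


def simulate_dataset(
    outdir,
    genome: GenomeDefinition | None = None,
    sim_config: SimConfig | None = None,
    n_cases: int = 10,
    n_qc_failures: int = 0,
    bin_size: int = 200_000,
    spike_reference: MicrobialReference | None = None,
    spike_counts: dict[str, int] | None = None,
) -> dict:
    """Write a simulated dataset: control/case TSVs, truth JSON, spike FASTQs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = genome or toy_genome()
    sim_config = sim_config or SimConfig()
    grid = make_bins(genome, bin_size)
    specs = default_case_specs(grid, n_cases)
    controls, cases, truth = simulate_cohort(grid, sim_config, specs)
    control_ids = [f"control_{i:03d}" for i in range(controls.shape[0])]
    write_bin_counts(outdir / "controls.tsv", grid, controls, control_ids)
    case_ids = list(truth.sample_ids)
    for q in range(n_qc_failures):
        noisy = make_qc_failure_sample(grid, sim_config, sample_index=q)
        cases = np.vstack([cases, noisy[None, :]])
        case_ids.append(f"qcfail_{q:03d}")
        truth.sample_ids.append(f"qcfail_{q:03d}")
        truth.events.append([])
        truth.expected_log2 = np.vstack(
            [truth.expected_log2, np.zeros((1, grid.n_bins))]
        )
        truth.qc_mode.append(True)
    truth.qc_mode = truth.qc_mode or [False] * n_cases
    write_bin_counts(outdir / "cases.tsv", grid, cases, case_ids)
    if spike_reference and spike_counts:
        for sid, n in spike_counts.items():
            reads = spike_microbial_reads(
                n, spike_reference, mismatches_per_read=0, seed=sim_config.seed
            )
            write_fastq(outdir / f"{sid}.spike.fastq", reads, prefix=sid)
            truth.microbial_spikes[sid] = n
    write_json(outdir / "truth.json", truth.to_dict())
    genome_df = pd.DataFrame(
        [(c.name, c.length, c.centromere_mid) for c in genome.chromosomes],
        columns=["chrom", "length", "centromere_mid"],
    )
    genome_df.to_csv(outdir / "genome.tsv", sep="\t", index=False)
    return {
        "n_controls": controls.shape[0],
        "n_cases": len(case_ids),
        "n_bins": grid.n_bins,
        "outdir": str(outdir),
    }
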
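"""Readers and writers for the pipeline's on-disk formats.

Dialects: BED and the bin-count TSV are 0-based half-open (the internal
frame); SEG output converts to 1-based inclusive starts as segmentation
viewers expect.  FASTA/FASTQ go through Biopython; bin counts can
optionally be extracted from a coordinate-sorted, indexed alignment file
with pysam (read-start positions, primary alignments, MAPQ >= 20).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import SampleCINResult
from .genome import BinGrid
from .microbial import MicrobialReference
from .normalize import NormalizedProfile
from .segmentation import Segment

__all__ = [
    "write_bin_counts",
    "read_bin_counts",
    "write_profile_tsv",
    "write_seg",
    "write_call_bed",
    "write_fastq",
    "read_reads",
    "read_reference_fasta",
    "write_reference_fasta",
    "count_reads_in_bins",
    "write_json",
]

MIN_MAPQ = 20


def write_bin_counts(path, grid: BinGrid, counts: np.ndarray, sample_ids: list[str]) -> None:
    """Bin-count TSV: chrom, start, end, then one column per sample."""
    counts = np.asarray(counts)
    df = grid.table[["chrom", "start", "end"]].copy()
    for i, sid in enumerate(sample_ids):
        df[sid] = counts[i]
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts(path, grid: BinGrid | None = None) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a bin-count TSV; returns (bin table, counts (samples x bins), ids)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"bin-count TSV must have columns {sorted(required)}")
    sample_ids = [c for c in df.columns if c not in ("chrom", "start", "end")]
    if grid is not None:
        if len(df) != grid.n_bins or not (
            (df["chrom"].to_numpy() == grid.chrom).all()
            and (df["start"].to_numpy() == grid.start).all()
        ):
            raise ValueError("bin-count rows do not match the bin grid")
    counts = df[sample_ids].to_numpy(dtype=float).T
    return df[["chrom", "start", "end"]], counts, sample_ids


def write_profile_tsv(path, grid: BinGrid, profile: NormalizedProfile) -> None:
    df = grid.table[["chrom", "start", "end"]].copy()
    df["raw"] = profile.raw if profile.raw is not None else np.nan
    df["z"] = profile.z
    df["log2_ratio"] = profile.log2_ratio
    df["usable"] = profile.usable_mask.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_seg(path, segments_by_sample: dict[str, list[Segment]]) -> None:
    """SEG format: ID, chrom, loc.start (1-based inclusive), loc.end,
    num.mark, seg.mean."""
    rows = []
    for sid, segments in segments_by_sample.items():
        for s in segments:
            rows.append((sid, s.chrom, s.start + 1, s.end, s.n_bins, round(s.seg_mean, 6)))
    pd.DataFrame(
        rows, columns=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    ).to_csv(path, sep="\t", index=False)


def write_call_bed(path, called: list[tuple[Segment, str]], sample_id: str) -> None:
    """BED of calls (0-based half-open): chrom, start, end, call, seg_mean."""
    with open(path, "w") as fh:
        fh.write(f'track name="{sample_id}" description="copy-number calls"\n')
        for seg, call in called:
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{call}\t{seg.seg_mean:.4f}\n"
            )


def write_fastq(path, reads: list[str], prefix: str = "read") -> None:
    """Reads with uniform quality 'I' (Q40)."""
    records = []
    for i, seq in enumerate(reads):
        rec = SeqRecord(Seq(seq), id=f"{prefix}_{i}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_reads(path) -> list[str]:
    """Read sequences from FASTA or FASTQ (sniffed from the extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def read_reference_fasta(path, label: str | None = None) -> MicrobialReference:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return MicrobialReference(
        label=label or rec.id, sequence=str(rec.seq).upper(), source_id=rec.id
    )


def write_reference_fasta(path, reference: MicrobialReference) -> None:
    rec = SeqRecord(
        Seq(reference.sequence), id=reference.source_id or reference.label,
        description=reference.label,
    )
    SeqIO.write([rec], path, "fasta")


def count_reads_in_bins(bam_path, grid: BinGrid, min_mapq: int = MIN_MAPQ) -> np.ndarray:
    """Per-bin read counts from a coordinate-sorted, indexed alignment file.

    Counts primary-alignment read-start positions with MAPQ >= min_mapq.
    """
    import pysam  # deferred: alignment input is optional

    counts = np.zeros(grid.n_bins)
    slices = grid.chrom_slices()
    bin_size = grid.bin_size
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for chrom, sl in slices.items():
            if chrom not in bam.references:
                continue
            for read in bam.fetch(chrom):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.mapping_quality < min_mapq
                ):
                    continue
                b = sl.start + read.reference_start // bin_size
                if sl.start <= b < sl.stop:
                    counts[b] += 1
    return counts


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sample_report(result: SampleCINResult) -> dict:
    return result.to_dict()
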
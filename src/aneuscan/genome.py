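"""Genome definition, fixed-width bin grid, arm assignment and gene loci.

The bin grid is the coordinate frame for everything downstream: coverage
normalization, segmentation and copy-number calling all operate on the
ordered sequence of fixed-width (default 200 kb) genomic bins defined here.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GenomeDefinition",
    "BinGrid",
    "GeneLocus",
    "make_bins",
    "assign_arm",
    "gene_bins",
    "load_genome_tsv",
    "load_gene_loci_tsv",
    "hg19_genome",
    "hg19_gene_loci",
    "toy_genome",
]

DEFAULT_BIN_SIZE = 200_000


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere_mid: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not (0 < self.centromere_mid < self.length):
            raise ValueError(
                f"chromosome {self.name}: centromere_mid must lie strictly "
                f"inside (0, {self.length})"
            )


@dataclass(frozen=True)
class GenomeDefinition:
    """Ordered chromosomes; the order fixes genome-wide bin ordering."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)


@dataclass(frozen=True)
class GeneLocus:
    symbol: str
    chrom: str
    start: int
    end: int
    cytoband_label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.symbol}: start must be < end")


@dataclass
class BinGrid:
    """Ordered fixed-width genomic bins with chromosome-arm labels.

    ``table`` columns: chrom, start, end, arm, width.  Bins are sorted by
    (chromosome order in the genome, start); every base of every chromosome
    belongs to exactly one bin and terminal partial bins keep their true
    width.
    """

    genome: GenomeDefinition
    bin_size: int
    table: pd.DataFrame = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.table["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.table["end"].to_numpy()

    @property
    def arm(self) -> np.ndarray:
        return self.table["arm"].to_numpy()

    @property
    def arm_name(self) -> np.ndarray:
        """Arm identifier per bin, e.g. ``'chr13q'``."""
        return (self.table["chrom"] + self.table["arm"]).to_numpy()

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous global-index slice of each chromosome's bins."""
        out: dict[str, slice] = {}
        chroms = self.chrom
        for name in self.genome.names:
            idx = np.flatnonzero(chroms == name)
            out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins overlapping [start, end) on ``chrom``."""
        if chrom not in self.genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        mask = (self.chrom == chrom) & (self.start < end) & (self.end > start)
        return np.flatnonzero(mask)


def assign_arm(start: int, end: int, chromosome: Chromosome) -> str:
    """p/q label of a bin from its midpoint vs the centromere midpoint.

    A midpoint exactly at the centromere is labelled q (fixed tie rule).
    """
    midpoint = (start + end) / 2
    return "p" if midpoint < chromosome.centromere_mid else "q"


def make_bins(genome: GenomeDefinition, bin_size: int = DEFAULT_BIN_SIZE) -> BinGrid:
    """Tile each chromosome with fixed-width bins.

    Terminal partial bins are retained with their true width, so bin widths
    per chromosome always sum to the chromosome length.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom in genome.chromosomes:
        starts = np.arange(0, chrom.length, bin_size)
        ends = np.minimum(starts + bin_size, chrom.length)
        for s, e in zip(starts, ends):
            rows.append(
                (chrom.name, int(s), int(e), assign_arm(int(s), int(e), chrom), int(e - s))
            )
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm", "width"])
    return BinGrid(genome=genome, bin_size=bin_size, table=table)


def gene_bins(locus: GeneLocus, grid: BinGrid) -> np.ndarray:
    """Global indices of all grid bins overlapping the gene locus."""
    if locus.chrom not in grid.genome:
        raise KeyError(f"gene {locus.symbol}: unknown chromosome {locus.chrom!r}")
    chrom_len = grid.genome[locus.chrom].length
    if locus.start >= chrom_len:
        raise ValueError(f"gene {locus.symbol}: locus outside gridded coordinates")
    idx = grid.bins_overlapping(locus.chrom, locus.start, locus.end)
    if idx.size == 0:
        raise ValueError(f"gene {locus.symbol}: no overlapping bins")
    return idx


# ---------------------------------------------------------------------------
# I/O and bundled definitions


def load_genome_tsv(path) -> GenomeDefinition:
    """Read a genome definition TSV with columns chrom, length, centromere_mid."""
    df = pd.read_csv(path, sep="\t", comment="#")
    chroms = tuple(
        Chromosome(str(r.chrom), int(r.length), int(r.centromere_mid))
        for r in df.itertuples()
    )
    return GenomeDefinition(chroms)


def load_gene_loci_tsv(path) -> list[GeneLocus]:
    """Read gene loci from a BED-like TSV: chrom, start, end, symbol[, cytoband]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneLocus(
            symbol=str(r.symbol),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            cytoband_label=str(getattr(r, "cytoband", "")),
        )
        for r in df.itertuples()
    ]


def _data_path(name: str):
    return importlib.resources.files("aneuscan.data").joinpath(name)


def hg19_genome() -> GenomeDefinition:
    """Bundled hg19-style genome: chr1-22 and chrX lengths + centromere midpoints."""
    return load_genome_tsv(_data_path("hg19_genome.tsv"))


def hg19_gene_loci() -> list[GeneLocus]:
    """Bundled hg19 placements of EGFR, MYC, ERBB2, SMAD4 and DCC.

    Note SMAD4 and DCC are both on 18q in hg19; conflicting 14q placements
    circulate in the literature and are not adopted here.
    """
    return load_gene_loci_tsv(_data_path("genes_hg19.tsv"))


def toy_genome(n_chroms: int = 6) -> GenomeDefinition:
    """Small desk-scale genome used by the simulator and the test-suite.

    Chromosome names mirror the arms most often aberrant in colorectal
    adenomas (7, 8, 13, 14, 18, 20) so planted events read naturally, but
    lengths are scaled down to keep the grid near 2,500 bins.
    """
    spec = [
        ("chr7", 120_000_000, 60_000_000),
        ("chr8", 100_000_000, 45_000_000),
        ("chr13", 80_000_000, 18_000_000),
        ("chr14", 80_000_000, 18_000_000),
        ("chr18", 60_000_000, 17_000_000),
        ("chr20", 60_000_000, 27_000_000),
    ]
    if not 1 <= n_chroms <= len(spec):
        raise ValueError(f"n_chroms must be in [1, {len(spec)}]")
    return GenomeDefinition(tuple(Chromosome(*row) for row in spec[:n_chroms]))
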
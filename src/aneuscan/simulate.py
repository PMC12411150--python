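"""Synthetic low-pass WGS cohorts with planted copy-number ground truth.

The generator emulates the statistical structure the normalization step
assumes: every sample shares a per-bin baseline expectation (lognormal
bin effects standing in for mappability/GC structure), around which
per-bin read counts are drawn negative-binomially.  Case samples carry
planted copy-number events that multiply the bin expectation by

    purity * copies / 2 + (1 - purity)

so a 4-copy gain at purity 1 doubles coverage (expected log2 ratio 1.0),
while low purity dilutes events toward neutrality.  A QC-failure mode
adds independent per-bin multiplicative jitter large enough to trip the
adjacent-bin noise gate, and microbial spike-ins plant reads copied from
a reference sequence with a controlled number of substitutions.

One global seed fans out to per-sample substreams keyed by sample index,
so extending a cohort never reshuffles existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid
from .microbial import MicrobialReference

__all__ = [
    "SimConfig",
    "CNVEvent",
    "SimTruth",
    "simulate_cohort",
    "make_qc_failure_sample",
    "spike_microbial_reads",
    "arm_event",
    "default_case_specs",
    "expected_log2_ratio",
]

_BASELINE_STREAM = 0  # substream key for the shared per-bin baseline
_CONTROL_OFFSET = 1_000
_CASE_OFFSET = 2_000
_QC_OFFSET = 3_000


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_controls: int = 20
    depth_mean: float = 200.0
    dispersion: float = 50.0  # NB overdispersion: var = mu + mu^2 / dispersion
    bin_effect_sd: float = 0.05  # natural-log sd of the shared per-bin baseline
    noise_inflation: float = 2.0 ** 0.5  # QC-failure jitter: log2 sd = log2(this)
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2 (baseline stdev must exist)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must be in [0, 1]")
        if self.bin_effect_sd < 0:
            raise ValueError("bin_effect_sd must be >= 0")


@dataclass(frozen=True)
class CNVEvent:
    """A planted copy-number event; total_copies=2 is neutral."""

    chrom: str
    start: int
    end: int
    total_copies: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("event start must be < end")
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted next to simulated counts."""

    sample_ids: list[str]
    events: list[list[CNVEvent]]  # per case sample
    expected_log2: np.ndarray = field(repr=False)  # (n_cases, n_bins)
    qc_mode: list[bool] = field(default_factory=list)
    microbial_spikes: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "events": [
                [
                    {
                        "chrom": e.chrom,
                        "start": e.start,
                        "end": e.end,
                        "total_copies": e.total_copies,
                    }
                    for e in evs
                ]
                for evs in self.events
            ],
            "expected_log2": self.expected_log2.round(6).tolist(),
            "qc_mode": list(self.qc_mode),
            "microbial_spikes": self.microbial_spikes,
        }


def expected_log2_ratio(total_copies: int, purity: float) -> float:
    """Expected log2 copy ratio inside an event at the given tumor purity."""
    frac = purity * total_copies / 2.0 + (1.0 - purity)
    if frac <= 0:
        frac = 1e-12  # complete homozygous loss at purity 1
    return float(np.log2(frac))


def _baseline(grid: BinGrid, config: SimConfig) -> np.ndarray:
    """Shared per-bin expected count; lognormal bin effects, mean depth_mean.

    Partial terminal bins scale with their width (fewer mappable positions).
    """
    rng = np.random.default_rng([config.seed, _BASELINE_STREAM])
    sd = config.bin_effect_sd
    effects = np.exp(rng.normal(0.0, sd, grid.n_bins) - sd * sd / 2.0)
    width_frac = grid.table["width"].to_numpy() / grid.bin_size
    return config.depth_mean * effects * width_frac


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p).astype(np.float64)


def _event_factor(
    grid: BinGrid, events: list[CNVEvent], purity: float
) -> tuple[np.ndarray, np.ndarray]:
    """(multiplicative coverage factor, expected log2 ratio) per bin."""
    factor = np.ones(grid.n_bins)
    covered = np.zeros(grid.n_bins, dtype=bool)
    for ev in events:
        if ev.chrom not in grid.genome:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        if ev.end > grid.genome[ev.chrom].length:
            raise ValueError(f"event {ev} extends past chromosome end")
        idx = grid.bins_overlapping(ev.chrom, ev.start, ev.end)
        if covered[idx].any():
            raise ValueError("overlapping events within one sample")
        covered[idx] = True
        factor[idx] = purity * ev.total_copies / 2.0 + (1.0 - purity)
    with np.errstate(divide="ignore"):
        exp_log2 = np.log2(np.maximum(factor, 1e-12))
    return factor, exp_log2


def simulate_cohort(
    grid: BinGrid,
    config: SimConfig,
    case_specs: list[list[CNVEvent]] | None = None,
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Draw a control cohort and case samples with planted events.

    Returns (control_matrix, case_matrix, truth); matrices are
    (n_samples, n_bins) float arrays of read counts.
    """
    case_specs = case_specs or []
    baseline = _baseline(grid, config)
    controls = np.empty((config.n_controls, grid.n_bins))
    for s in range(config.n_controls):
        rng = np.random.default_rng([config.seed, _CONTROL_OFFSET + s])
        controls[s] = _nb_draw(rng, baseline, config.dispersion)
    cases = np.empty((len(case_specs), grid.n_bins))
    expected_log2 = np.zeros_like(cases)
    for s, events in enumerate(case_specs):
        factor, exp_l2 = _event_factor(grid, events, config.purity)
        rng = np.random.default_rng([config.seed, _CASE_OFFSET + s])
        cases[s] = _nb_draw(rng, baseline * factor, config.dispersion)
        expected_log2[s] = exp_l2
    truth = SimTruth(
        sample_ids=[f"case_{s:03d}" for s in range(len(case_specs))],
        events=[list(evs) for evs in case_specs],
        expected_log2=expected_log2,
        qc_mode=[False] * len(case_specs),
    )
    return controls, cases, truth


def make_qc_failure_sample(
    grid: BinGrid, config: SimConfig, sample_index: int = 0
) -> np.ndarray:
    """A copy-neutral sample with per-bin jitter that trips the noise gate.

    The jitter is independent multiplicative noise with log2 standard
    deviation log2(noise_inflation); at the default (sd 0.5) the median
    absolute adjacent-bin log2 difference concentrates near
    median|N(0, 0.5*sqrt(2))| ~ 0.48, above the 0.38 gate.
    """
    if config.noise_inflation <= 1:
        raise ValueError("noise_inflation must be > 1 for the QC-failure mode")
    baseline = _baseline(grid, config)
    rng = np.random.default_rng([config.seed, _QC_OFFSET + sample_index])
    jitter_sd_log2 = np.log2(config.noise_inflation)
    jitter = 2.0 ** rng.normal(0.0, jitter_sd_log2, grid.n_bins)
    return _nb_draw(rng, baseline * jitter, config.dispersion)


def spike_microbial_reads(
    n_reads: int,
    reference: MicrobialReference,
    mismatches_per_read: int = 0,
    seed: int = 0,
    read_length: int = 100,
) -> list[str]:
    """Reads copied from the reference with exactly the requested number of
    substitutions at random positions."""
    if read_length > len(reference):
        raise ValueError("read length exceeds reference length")
    if mismatches_per_read < 0:
        raise ValueError("mismatches_per_read must be >= 0")
    rng = np.random.default_rng([seed, 4_000])
    bases = "ACGT"
    reads = []
    seq = reference.sequence.upper()
    for _ in range(n_reads):
        start = int(rng.integers(0, len(seq) - read_length + 1))
        read = list(seq[start : start + read_length])
        pos = rng.choice(read_length, size=mismatches_per_read, replace=False)
        for p in pos:
            alternatives = [b for b in bases if b != read[p]]
            read[p] = alternatives[int(rng.integers(0, len(alternatives)))]
        reads.append("".join(read))
    return reads


# ---------------------------------------------------------------------------
# event helpers


def arm_event(grid: BinGrid, chrom: str, arm: str, total_copies: int) -> CNVEvent:
    """Whole-arm event spanning the p or q arm of a chromosome."""
    chromosome = grid.genome[chrom]
    if arm == "p":
        return CNVEvent(chrom, 0, chromosome.centromere_mid, total_copies)
    if arm == "q":
        return CNVEvent(chrom, chromosome.centromere_mid, chromosome.length, total_copies)
    raise ValueError("arm must be 'p' or 'q'")


def default_case_specs(grid: BinGrid, n_cases: int = 10) -> list[list[CNVEvent]]:
    """Event menu mirroring the arm lesions recurrent in colorectal adenomas:
    gains of 13q, 7 (both arms), 8q and 20q; losses of 18q and 14q.  Flat
    (event-free) cases pad the list when the menu is exhausted."""
    g = grid.genome
    menu: list[list[CNVEvent]] = []
    if "chr13" in g:
        menu.append([arm_event(grid, "chr13", "q", 4)])
    if "chr7" in g:
        menu.append([arm_event(grid, "chr7", "p", 4), arm_event(grid, "chr7", "q", 4)])
    if "chr8" in g:
        menu.append([arm_event(grid, "chr8", "q", 4)])
    if "chr20" in g:
        menu.append([arm_event(grid, "chr20", "q", 4)])
    if "chr18" in g:
        menu.append([arm_event(grid, "chr18", "q", 1)])
    if "chr14" in g:
        menu.append([arm_event(grid, "chr14", "q", 1)])
    if not menu:
        # generic genome: alternate a q-arm gain and a q-arm loss
        names = g.names
        menu.append([arm_event(grid, names[0], "q", 4)])
        menu.append([arm_event(grid, names[min(1, len(names) - 1)], "q", 1)])
    # alternate planted/flat so half the cohort is copy-neutral
    return [
        menu[(i // 2) % len(menu)] if i % 2 == 0 else [] for i in range(n_cases)
    ]
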
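"""Control-cohort coverage normalization and the sample-quality gate.

Per-bin read counts of a sample are standardized against a cohort of
control samples:

    z_bin = (coverage_raw - mean(coverage_controls)) / stdev(coverage_controls)

with the per-bin mean and standard deviation (n-1 denominator) taken across
the control samples.  A log2 copy ratio, log2(coverage_raw / control mean),
is computed alongside; the z-score vector feeds segmentation while the log2
ratio feeds the quality gate and reporting.

The quality gate rejects a sample when the median absolute difference of
the log2 copy ratio between adjacent bins (within chromosomes) exceeds a
threshold, 0.38 by default; a noisy, jittery profile produces large
bin-to-bin jumps even when no real copy-number change is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .genome import BinGrid

__all__ = [
    "CoverageNormalizer",
    "NormalizedProfile",
    "QCReport",
    "build_baseline",
    "normalize_sample",
    "qc_sample",
    "QC_THRESHOLD_DEFAULT",
]

QC_THRESHOLD_DEFAULT = 0.38
#: log2 ratio of a zero-count bin is computed from this pseudocount
ZERO_COUNT_PSEUDOCOUNT = 0.5


@dataclass
class NormalizedProfile:
    """Per-bin z-scores and log2 copy ratios for one sample.

    Masked (unusable-baseline) bins are NaN in both vectors, never zero.
    """

    sample_id: str
    z: np.ndarray
    log2_ratio: np.ndarray
    usable_mask: np.ndarray
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.z) == len(self.log2_ratio) == len(self.usable_mask)):
            raise ValueError("profile vectors must have equal length")
        if not np.all(np.isfinite(self.z[self.usable_mask])):
            raise ValueError("z must be finite on usable bins")

    @property
    def n_bins(self) -> int:
        return len(self.z)


@dataclass
class QCReport:
    """Outcome of the adjacent-bin noise gate for one sample."""

    sample_id: str
    statistic: float
    threshold: float = QC_THRESHOLD_DEFAULT
    passed: bool = True

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "statistic": float(self.statistic),
            "threshold": float(self.threshold),
            "passed": bool(self.passed),
        }


class CoverageNormalizer(BaseEstimator, TransformerMixin):
    """Standardize per-bin coverage against a control cohort.

    ``fit`` consumes the control count matrix of shape
    ``(n_controls, n_bins)`` and stores the per-bin baseline;
    ``transform`` maps sample count rows to z-scores.  Bins whose control
    mean or control standard deviation is zero are unusable and come out
    as NaN.

    Attributes
    ----------
    mean_ : ndarray of shape (n_bins,)
        Per-bin mean raw coverage across controls.
    std_ : ndarray of shape (n_bins,)
        Per-bin sample standard deviation (ddof=1) across controls.
    usable_mask_ : ndarray of bool, shape (n_bins,)
        True where ``std_ > 0`` and ``mean_ > 0``.
    n_controls_ : int
    """

    def __init__(self, pseudocount: float = ZERO_COUNT_PSEUDOCOUNT):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64, ensure_min_samples=2)
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise ValueError("control counts must be finite and non-negative")
        self.n_controls_ = X.shape[0]
        self.n_bins_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=1)
        self.usable_mask_ = (self.std_ > 0) & (self.mean_ > 0)
        if not self.usable_mask_.any():
            raise ValueError("all bins unusable: controls are degenerate")
        return self

    def transform(self, X) -> np.ndarray:
        """Z-score matrix; NaN at unusable bins."""
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=np.float64, ensure_2d=True)
        if X.shape[1] != self.n_bins_:
            raise ValueError(
                f"sample has {X.shape[1]} bins, baseline has {self.n_bins_}"
            )
        z = np.full_like(X, np.nan)
        m = self.usable_mask_
        z[:, m] = (X[:, m] - self.mean_[m]) / self.std_[m]
        return z

    def log2_ratio(self, X) -> np.ndarray:
        """log2(coverage / baseline mean); zero counts use the pseudocount."""
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=np.float64, ensure_2d=True)
        ratio = np.full_like(X, np.nan)
        m = self.usable_mask_
        num = np.where(X[:, m] > 0, X[:, m], self.pseudocount)
        ratio[:, m] = np.log2(num / self.mean_[m])
        return ratio

    def profile(self, counts, sample_id: str = "sample") -> NormalizedProfile:
        """Full per-sample profile (z + log2 ratio + mask) for one count vector."""
        counts = np.asarray(counts, dtype=np.float64).reshape(1, -1)
        return NormalizedProfile(
            sample_id=sample_id,
            z=self.transform(counts)[0],
            log2_ratio=self.log2_ratio(counts)[0],
            usable_mask=self.usable_mask_.copy(),
            raw=counts[0],
        )


def build_baseline(control_matrix) -> CoverageNormalizer:
    """Fit a :class:`CoverageNormalizer` on a (n_controls, n_bins) count matrix."""
    return CoverageNormalizer().fit(control_matrix)


def normalize_sample(
    counts, baseline: CoverageNormalizer, sample_id: str = "sample"
) -> NormalizedProfile:
    return baseline.profile(counts, sample_id=sample_id)


def qc_sample(
    profile: NormalizedProfile,
    grid: BinGrid,
    threshold: float = QC_THRESHOLD_DEFAULT,
) -> QCReport:
    """Adjacent-bin noise gate.

    The statistic is the median over all within-chromosome pairs of
    consecutive usable bins of |log2_ratio[i+1] - log2_ratio[i]|.  The
    sample passes iff the statistic does not exceed the threshold (a value
    exactly at the threshold passes).
    """
    if profile.n_bins != grid.n_bins:
        raise ValueError("profile length does not match grid")
    diffs: list[np.ndarray] = []
    for sl in grid.chrom_slices().values():
        lr = profile.log2_ratio[sl]
        lr = lr[profile.usable_mask[sl]]
        if lr.size >= 2:
            diffs.append(np.abs(np.diff(lr)))
    if not diffs:
        raise ValueError("too few usable bins to form any adjacent pair")
    stat = float(np.median(np.concatenate(diffs)))
    return QCReport(
        sample_id=profile.sample_id,
        statistic=stat,
        threshold=threshold,
        passed=stat <= threshold,
    )
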
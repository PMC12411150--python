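"""Circular binary segmentation (CBS) with permutation-based significance.

The segmenter recursively partitions each chromosome's normalized signal
(z-scores) into segments of constant mean.  At each step the interval is
treated as a circle and the arc maximizing the magnitude of the pooled
two-sample t-statistic between the arc and its complement is located; the
split is accepted when a permutation test on the interval deems the
statistic significant (p < alpha), and the resulting parts are segmented
recursively.  Chromosome ends break the circle, so the algorithm runs
per chromosome.

Unusable bins (degenerate control baseline) are dropped before
segmentation; segment bin indices refer to each chromosome's sequence of
usable bins while genomic coordinates map back through the bin grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid
from .normalize import NormalizedProfile

__all__ = [
    "SegmentationParams",
    "Segment",
    "cbs_split_statistic",
    "permutation_p",
    "segment_profile",
    "CBSSegmenter",
]


@dataclass(frozen=True)
class SegmentationParams:
    alpha: float = 0.05
    n_permutations: int = 1000
    min_seg_bins: int = 3
    max_depth: int = 25
    merge_tol: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_seg_bins < 1:
            raise ValueError("min_seg_bins must be >= 1")
        if self.merge_tol < 0:
            raise ValueError("merge_tol must be >= 0")


@dataclass
class Segment:
    """A contiguous run of usable bins with constant estimated copy state.

    ``start_bin``/``end_bin`` are half-open indices into the chromosome's
    usable-bin sequence (so segments of one chromosome tile it exactly);
    ``grid_start``/``grid_end`` are half-open global bin-grid indices and
    ``start``/``end`` genomic base pairs.  ``p_value`` is the permutation p
    of the split that created the segment, 1.0 for an unsplit root.
    """

    chrom: str
    start_bin: int
    end_bin: int
    seg_mean: float
    p_value: float
    start: int = 0
    end: int = 0
    grid_start: int = 0
    grid_end: int = 0

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def abs_seg_mean(self) -> float:
        return abs(self.seg_mean)


# ---------------------------------------------------------------------------
# split statistic


def _max_arc_t(
    x: np.ndarray, min_bins: int, edge_constrained: bool
) -> tuple[int, int, float] | None:
    """Best arc (i, j] of the circularized vector by |pooled-t| magnitude.

    Arcs are enumerated as linear windows x[i:j] with both arc and
    complement holding at least ``min_bins`` points; a wrapped arc is
    equivalent to the complement of a linear one and yields the same
    statistic, and an arc ending at n encodes the same partition as the
    arc (0, i], so only the latter canonical representative is scored.
    With ``edge_constrained`` the two complement flanks
    x[:i] and x[j:] must additionally each be empty or >= min_bins long
    (the rule used inside the recursion so every resulting part is a
    viable segment).  Ties resolve to the smaller i, then smaller j.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2 * min_bins:
        return None
    xc = x - x.mean()  # centering improves cancellation; t is invariant
    cs = np.concatenate(([0.0], np.cumsum(xc)))
    css = np.concatenate(([0.0], np.cumsum(xc * xc)))
    total, total_ss = cs[n], css[n]
    best_t, best_i, best_j = -1.0, -1, -1
    for m in range(min_bins, n - min_bins + 1):
        # arcs ending exactly at n (i > 0) are complements of arcs starting
        # at 0 and encode the same partition; enumerate only the canonical
        # representative so float noise cannot flip the tie-break
        i = np.arange(0, n - m)
        j = i + m
        if edge_constrained:
            ok = ((i == 0) | (i >= min_bins)) & (n - j >= min_bins)
            i, j = i[ok], j[ok]
        if i.size == 0:
            continue
        s = cs[j] - cs[i]
        ss = css[j] - css[i]
        m2 = n - m
        mean_diff = np.abs(s / m - (total - s) / m2)
        ss1 = np.maximum(ss - s * s / m, 0.0)
        ss2 = np.maximum((total_ss - ss) - (total - s) ** 2 / m2, 0.0)
        sp2 = (ss1 + ss2) / (n - 2) if n > 2 else np.zeros_like(ss1)
        denom = np.sqrt(sp2 * (1.0 / m + 1.0 / m2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(
                denom > 0, mean_diff / denom, np.where(mean_diff > 0, np.inf, 0.0)
            )
        k = int(np.argmax(t))  # first occurrence -> smallest i at this m
        tk = float(t[k])
        if tk > best_t or (
            tk == best_t
            and (i[k] < best_i or (i[k] == best_i and j[k] < best_j))
        ):
            best_t, best_i, best_j = tk, int(i[k]), int(j[k])
    if best_i < 0:
        return None
    return best_i, best_j, best_t


def _max_arc_t_many(
    X: np.ndarray, min_bins: int, edge_constrained: bool
) -> np.ndarray:
    """Row-wise max arc |t| for a batch of signals (B, n).

    Same statistic and constraints as :func:`_max_arc_t` without the
    argmax bookkeeping; used to score permutation batches.
    """
    B, n = X.shape
    if n < 2 * min_bins:
        return np.zeros(B)
    Xc = X - X.mean(axis=1, keepdims=True)
    CS = np.concatenate([np.zeros((B, 1)), np.cumsum(Xc, axis=1)], axis=1)
    CSS = np.concatenate([np.zeros((B, 1)), np.cumsum(Xc * Xc, axis=1)], axis=1)
    total = CS[:, -1:]
    total_ss = CSS[:, -1:]
    best = np.zeros(B)
    for m in range(min_bins, n - min_bins + 1):
        i = np.arange(0, n - m)  # canonical arcs only, as in _max_arc_t
        j = i + m
        if edge_constrained:
            ok = ((i == 0) | (i >= min_bins)) & (n - j >= min_bins)
            i, j = i[ok], j[ok]
        if i.size == 0:
            continue
        s = CS[:, j] - CS[:, i]
        ss = CSS[:, j] - CSS[:, i]
        m2 = n - m
        mean_diff = np.abs(s / m - (total - s) / m2)
        ss1 = np.maximum(ss - s * s / m, 0.0)
        ss2 = np.maximum((total_ss - ss) - (total - s) ** 2 / m2, 0.0)
        sp2 = (ss1 + ss2) / (n - 2) if n > 2 else np.zeros_like(ss1)
        denom = np.sqrt(sp2 * (1.0 / m + 1.0 / m2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(
                denom > 0, mean_diff / denom, np.where(mean_diff > 0, np.inf, 0.0)
            )
        np.maximum(best, t.max(axis=1), out=best)
    return best


def cbs_split_statistic(
    signal, min_seg_bins: int = 3
) -> tuple[int, int, float]:
    """Optimal circular split of a signal vector.

    Returns (i, j, T): the arc (i, j] maximizing the magnitude of the
    pooled two-sample t-statistic between arc and complement, both parts
    at least ``min_seg_bins`` long.  Degenerate zero-variance comparisons
    score +inf when the means differ and 0 otherwise.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 2 * min_seg_bins:
        raise ValueError(
            f"signal of length {x.size} too short for min_seg_bins={min_seg_bins}"
        )
    res = _max_arc_t(x, min_seg_bins, edge_constrained=False)
    assert res is not None
    return res


def _permutation_counting(
    x: np.ndarray,
    t_observed: float,
    params: SegmentationParams,
    rng: np.random.Generator,
    edge_constrained: bool,
    early_stop: bool,
) -> tuple[bool, float]:
    """Permutation test of a split; returns (accepted, p).

    p uses the add-one estimator (1 + #{max-T >= T_obs}) / (1 + B).  With
    ``early_stop`` the loop terminates as soon as the exceedance count
    makes rejection impossible — the accept/reject decision is identical
    to the full run (the count only grows), and accepted splits always
    run the full B permutations so their reported p is exact.
    """
    n_perm = params.n_permutations
    stop_count = params.alpha * (1 + n_perm) - 1
    count = 0
    done = 0
    chunk = 100
    while done < n_perm:
        b = min(chunk, n_perm - done)
        XP = rng.permuted(np.broadcast_to(x, (b, x.size)), axis=1)
        ts = _max_arc_t_many(XP, params.min_seg_bins, edge_constrained)
        count += int((ts >= t_observed).sum())
        done += b
        if early_stop and count > stop_count:
            return False, (1 + count) / (1 + done)
    p = (1 + count) / (1 + n_perm)
    return p < params.alpha, p


def permutation_p(
    signal, t_observed: float, params: SegmentationParams
) -> float:
    """Exact (full-shuffle) permutation p-value of an observed split statistic."""
    x = np.asarray(signal, dtype=np.float64)
    rng = np.random.default_rng(params.seed)
    _, p = _permutation_counting(
        x, t_observed, params, rng, edge_constrained=False, early_stop=False
    )
    return p


# ---------------------------------------------------------------------------
# recursive segmentation


def _segment_interval(
    x: np.ndarray,
    lo: int,
    hi: int,
    p_created: float,
    params: SegmentationParams,
    rng: np.random.Generator,
    depth: int,
) -> list[tuple[int, int, float]]:
    n = hi - lo
    if depth >= params.max_depth or n < 2 * params.min_seg_bins:
        return [(lo, hi, p_created)]
    res = _max_arc_t(x[lo:hi], params.min_seg_bins, edge_constrained=True)
    if res is None or res[2] <= 0:
        return [(lo, hi, p_created)]
    i, j, t_obs = res
    accepted, p = _permutation_counting(
        x[lo:hi], t_obs, params, rng, edge_constrained=True, early_stop=True
    )
    if not accepted:
        return [(lo, hi, p_created)]
    cuts = [lo, lo + i, lo + j, hi]
    out: list[tuple[int, int, float]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b > a:
            out.extend(_segment_interval(x, a, b, p, params, rng, depth + 1))
    return out


def _merge_close(
    pieces: list[tuple[int, int, float]], x: np.ndarray, tol: float
) -> list[tuple[int, int, float]]:
    if tol <= 0 or len(pieces) < 2:
        return pieces
    merged = [pieces[0]]
    for piece in pieces[1:]:
        lo_p, hi_p, p_p = merged[-1]
        lo_c, hi_c, p_c = piece
        if abs(x[lo_p:hi_p].mean() - x[lo_c:hi_c].mean()) < tol:
            merged[-1] = (lo_p, hi_c, max(p_p, p_c))
        else:
            merged.append(piece)
    return merged


class CBSSegmenter:
    """Per-chromosome recursive circular binary segmentation.

    Parameters mirror :class:`SegmentationParams`; ``segment`` consumes a
    :class:`~aneuscan.normalize.NormalizedProfile` and returns the list of
    :class:`Segment` tiling each chromosome's usable bins.  Follows the
    scikit-learn parameter protocol (get_params/set_params) so thresholds
    can be tuned through standard tooling, though segmentation itself is
    per-sample and not a matrix transform.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_permutations: int = 1000,
        min_seg_bins: int = 3,
        max_depth: int = 25,
        merge_tol: float = 0.0,
        seed: int = 0,
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.min_seg_bins = min_seg_bins
        self.max_depth = max_depth
        self.merge_tol = merge_tol
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "min_seg_bins": self.min_seg_bins,
            "max_depth": self.max_depth,
            "merge_tol": self.merge_tol,
            "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            alpha=self.alpha,
            n_permutations=self.n_permutations,
            min_seg_bins=self.min_seg_bins,
            max_depth=self.max_depth,
            merge_tol=self.merge_tol,
            seed=self.seed,
        )

    def segment(self, profile: NormalizedProfile, grid: BinGrid) -> list[Segment]:
        if profile.n_bins != grid.n_bins:
            raise ValueError("profile length does not match grid")
        if not profile.usable_mask.any():
            raise ValueError("profile has no usable bins")
        params = self._params()
        segments: list[Segment] = []
        for ci, (chrom, sl) in enumerate(grid.chrom_slices().items()):
            usable = np.flatnonzero(profile.usable_mask[sl]) + sl.start
            if usable.size == 0:
                continue
            x = profile.z[usable]
            rng = np.random.default_rng([params.seed, ci])
            pieces = _segment_interval(x, 0, x.size, 1.0, params, rng, 0)
            pieces = _merge_close(pieces, x, params.merge_tol)
            for lo, hi, p in pieces:
                g_lo, g_hi = int(usable[lo]), int(usable[hi - 1])
                segments.append(
                    Segment(
                        chrom=chrom,
                        start_bin=lo,
                        end_bin=hi,
                        seg_mean=float(x[lo:hi].mean()),
                        p_value=float(p),
                        start=int(grid.start[g_lo]),
                        end=int(grid.end[g_hi]),
                        grid_start=g_lo,
                        grid_end=g_hi + 1,
                    )
                )
        return segments


def segment_profile(
    profile: NormalizedProfile,
    grid: BinGrid,
    params: SegmentationParams | None = None,
) -> list[Segment]:
    """Segment a normalized profile; thin wrapper over :class:`CBSSegmenter`."""
    params = params or SegmentationParams()
    seg = CBSSegmenter(**{
        "alpha": params.alpha,
        "n_permutations": params.n_permutations,
        "min_seg_bins": params.min_seg_bins,
        "max_depth": params.max_depth,
        "merge_tol": params.merge_tol,
        "seed": params.seed,
    })
    return seg.segment(profile, grid)
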
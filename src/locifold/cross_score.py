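"""Directional long-range contact profiles (Cross-score), peak calling,
orientation-matched CBE assignment, and insulation-gap detection.

For every genomic bin the Cross-score sums the contact frequency with its
upstream neighbours and, separately, its downstream neighbours within a
cohesin-scale separation window (default 30 kb - 1 Mb).  Bins that anchor
loops or contact stripes stand out as peaks; a peak in the downstream profile
marks an anchor whose loops extend downstream, which under the convergent
CTCF rule corresponds to a forward-oriented CBE (and vice versa for upstream
peaks and reverse CBEs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contact_core import ContactMatrix, DistanceDecay, coarsen, expected_by_distance
from .cbe_annotation import CBEAnnotation

__all__ = [
    "CrossScoreParams",
    "CrossScoreProfile",
    "ProfilePeak",
    "MatchReport",
    "GapInterval",
    "compute_cross_score",
    "call_profile_peaks",
    "match_peaks_to_cbes",
    "detect_score_gap",
]

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class CrossScoreParams:
    bin_size: int = 2_000
    d_min: int = 30_000
    d_max: int = 1_000_000
    normalization: str = "raw"     # "raw" | "obs_over_exp"
    use_balanced: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValueError("need 0 < d_min < d_max")
        if self.d_min < self.bin_size:
            raise ValueError("d_min must be >= bin_size")
        if self.normalization not in ("raw", "obs_over_exp"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def window_bins(self) -> tuple[int, int]:
        """Inclusive separation window in bins."""
        lo = -(-self.d_min // self.bin_size)      # ceil
        hi = self.d_max // self.bin_size
        return lo, hi


@dataclass
class CrossScoreProfile:
    """Per-bin upstream/downstream long-range contact scores.

    ``up``/``down`` carry NaN at masked bins.  ``edge_flag`` marks bins whose
    separation window extends past the locus on either side (partial sums);
    a bin is masked only when more than half of its combined two-sided window
    falls off-locus or on masked partner bins.
    """

    bins: "object"                  # GenomicBins
    up: np.ndarray
    down: np.ndarray
    valid: np.ndarray               # bool mask
    edge_flag: np.ndarray           # bool
    params: CrossScoreParams

    def side(self, which: str) -> np.ndarray:
        return self.up if which == UP else self.down

    def to_bedgraph(self, which: str, path) -> None:
        x = self.side(which)
        df = self.bins.to_frame()
        df["score"] = x
        df.dropna().to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class ProfilePeak:
    bin: int
    side: str          # "up" | "down"
    height: float
    prominence: float
    pos: int           # bin midpoint, bp


def compute_cross_score(matrix: ContactMatrix, params: CrossScoreParams) -> CrossScoreProfile:
    """Directional windowed contact sums for every bin.

    ``up[i] = sum_{j<i, d_min <= (i-j)*bs <= d_max} C(j, i)`` and mirror for
    ``down``.  With ``normalization="obs_over_exp"`` each pixel is divided by
    the per-diagonal expected value before summation.  Matrices binned finer
    than ``params.bin_size`` are coarsened by pixel aggregation first.
    """
    bs = matrix.bins.bin_size
    if bs > params.bin_size:
        raise ValueError(f"matrix bin size {bs} exceeds requested {params.bin_size}")
    if params.bin_size % bs:
        raise ValueError(f"matrix bin size {bs} does not divide {params.bin_size}")
    if bs < params.bin_size:
        matrix = coarsen(matrix, params.bin_size // bs)

    n = matrix.n
    dense = matrix.to_dense(balanced=params.use_balanced)
    if params.use_balanced:
        dense = np.nan_to_num(dense, nan=0.0)
    valid_bins = matrix.valid_mask
    if params.normalization == "obs_over_exp":
        decay = expected_by_distance(matrix, balanced=params.use_balanced)
        seps = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        with np.errstate(divide="ignore", invalid="ignore"):
            dense = np.where(decay.values[seps] > 0, dense / decay.values[seps], 0.0)
    dense = np.where(np.outer(valid_bins, valid_bins), dense, 0.0)

    lo, hi = params.window_bins
    # windowed sums along each row via prefix sums
    csum = np.concatenate([np.zeros((n, 1)), np.cumsum(dense, axis=1)], axis=1)

    def row_window_sum(i: int, j0: int, j1: int) -> float:
        """sum of dense[i, j0:j1+1], clipped to [0, n)."""
        a, b = max(j0, 0), min(j1, n - 1)
        if a > b:
            return 0.0
        return float(csum[i, b + 1] - csum[i, a])

    up = np.empty(n)
    down = np.empty(n)
    valid = np.zeros(n, dtype=bool)
    edge = np.zeros(n, dtype=bool)
    width = hi - lo + 1
    vcum = np.concatenate([[0], np.cumsum(valid_bins.astype(int))])

    def count_valid(j0: int, j1: int) -> int:
        a, b = max(j0, 0), min(j1, n - 1)
        if a > b:
            return 0
        return int(vcum[b + 1] - vcum[a])

    for i in range(n):
        up[i] = row_window_sum(i, i - hi, i - lo)
        down[i] = row_window_sum(i, i + lo, i + hi)
        edge[i] = (i - hi < 0) or (i + hi > n - 1)
        n_ok = count_valid(i - hi, i - lo) + count_valid(i + lo, i + hi)
        valid[i] = valid_bins[i] and (n_ok >= width)   # >= half of the 2*width two-sided window
    up[~valid] = np.nan
    down[~valid] = np.nan
    return CrossScoreProfile(matrix.bins, up, down, valid, edge, params)


def _prominence(x: np.ndarray, i: int) -> float:
    """Height of x[i] above the higher of its two flanking minima
    (scan outward until a value above x[i] or the profile boundary)."""
    h = x[i]
    lo_l = h
    for j in range(i - 1, -1, -1):
        v = x[j]
        if np.isnan(v):
            continue
        if v > h:
            break
        lo_l = min(lo_l, v)
    lo_r = h
    for j in range(i + 1, len(x)):
        v = x[j]
        if np.isnan(v):
            continue
        if v > h:
            break
        lo_r = min(lo_r, v)
    return h - max(lo_l, lo_r)


def call_profile_peaks(profile: CrossScoreProfile, span: int = 5,
                       min_prominence: float = 1.0) -> list[ProfilePeak]:
    """Strict local maxima within +-``span`` bins, prominence-filtered.

    A bin qualifies when its score strictly exceeds every other unmasked score
    within ``span`` bins on its side's profile and its prominence (height
    above the higher flanking minimum) exceeds ``min_prominence`` standard
    deviations of the unmasked profile.  Returned sorted by position, both
    sides interleaved.
    """
    peaks: list[ProfilePeak] = []
    mid = (profile.bins.starts + profile.bins.ends) // 2
    for side in (UP, DOWN):
        x = profile.side(side)
        finite = np.isfinite(x)
        if not finite.any():
            import warnings

            warnings.warn(f"all-masked {side} profile; no peaks", stacklevel=2)
            continue
        sd = float(np.nanstd(x))
        thr = min_prominence * sd
        n = len(x)
        for i in range(n):
            if not finite[i] or x[i] <= 0:
                continue
            w0, w1 = max(0, i - span), min(n, i + span + 1)
            window = x[w0:w1]
            others = np.delete(window, i - w0)
            others = others[np.isfinite(others)]
            if others.size and not np.all(x[i] > others):
                continue
            prom = _prominence(x, i)
            if prom > thr:
                peaks.append(ProfilePeak(i, side, float(x[i]), float(prom), int(mid[i])))
    return sorted(peaks, key=lambda p: (p.bin, p.side))


@dataclass
class MatchReport:
    matched: list[tuple[ProfilePeak, int, int]]   # (peak, cbe row index, distance bp)
    orphan_peaks: list[ProfilePeak]
    orphan_cbes: list[int]                        # cbe row indices

    @property
    def n_matched(self) -> int:
        return len(self.matched)


_SIDE_FOR_ORIENT = {"+": DOWN, "-": UP}


def match_peaks_to_cbes(peaks: Sequence[ProfilePeak], cbes: CBEAnnotation,
                        tolerance: int = 4_000) -> MatchReport:
    """Assign each peak the nearest orientation-matching CBE within ``tolerance`` bp.

    Downstream peaks pair with forward CBEs, upstream peaks with reverse CBEs
    (convergent-rule correspondence).  Assignment is greedy by distance (ties:
    higher CBE score, then leftmost CBE); every CBE is used at most once.
    """
    tab = cbes.table
    cand = []
    for p in peaks:
        for ci, row in tab.iterrows():
            if _SIDE_FOR_ORIENT[row["orientation"]] != p.side:
                continue
            d = abs(int(row["position"]) - p.pos)
            if d <= tolerance:
                cand.append((d, -float(row.get("score", 0.0)), int(row["position"]), p, int(ci)))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_peaks: set[int] = set()
    used_cbes: set[int] = set()
    matched = []
    for d, _negscore, _pos, p, ci in cand:
        pid = id(p)
        if pid in used_peaks or ci in used_cbes:
            continue
        used_peaks.add(pid)
        used_cbes.add(ci)
        matched.append((p, ci, d))
    orphan_peaks = [p for p in peaks if id(p) not in used_peaks]
    orphan_cbes = [int(ci) for ci in tab.index if ci not in used_cbes]
    return MatchReport(matched, orphan_peaks, orphan_cbes)


@dataclass(frozen=True)
class GapInterval:
    start_bin: int
    end_bin: int          # half-open
    mean_depth: float     # mean of min(up, down) inside the run

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def detect_score_gap(profile: CrossScoreProfile, low_quantile: float = 0.1,
                     min_run: int = 5, smooth_bins: int = 1) -> list[GapInterval]:
    """Maximal runs of >= ``min_run`` unmasked bins low on *both* profiles.

    "Low" means below the ``low_quantile`` quantile of each side's unmasked
    scores; such runs mark insulated segments (e.g. a 3'-terminal regulatory
    loop cut off from the V cluster).  On sparse maps, where single bins are
    dominated by Poisson zeros, ``smooth_bins`` > 1 applies a centered
    rolling mean to both profiles before thresholding.
    """
    up, down, valid = profile.up, profile.down, profile.valid
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        up = np.convolve(np.nan_to_num(up), kernel, mode="same")
        down = np.convolve(np.nan_to_num(down), kernel, mode="same")
    if not valid.any():
        return []
    # quantile thresholds from full-window (non-edge) bins, so that bins with
    # trivially truncated windows do not drag the quantiles to zero
    interior = valid & ~profile.edge_flag
    ref = interior if interior.any() else valid
    qu = np.nanquantile(up[ref], low_quantile)
    qd = np.nanquantile(down[ref], low_quantile)
    low = valid & (up < qu) & (down < qd)
    gaps: list[GapInterval] = []
    i = 0
    n = len(low)
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < n and low[j]:
            j += 1
        if j - i >= min_run:
            depth = float(np.mean(np.minimum(up[i:j], down[i:j])))
            gaps.append(GapInterval(i, j, depth))
        i = j
    return gaps
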
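"""Contact-map statistics: P(s) curves and slopes, differential maps, stripe
quantification, compartment eigenvector and saddle strength, simplified loop
calling, loop overlap and length summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .contact_core import ContactMatrix, expected_by_distance

__all__ = [
    "ContactFrequencyCurve",
    "LoopCall",
    "CompartmentTrack",
    "contact_frequency_curve",
    "curve_slope",
    "differential_map",
    "stripe_profile",
    "compartment_eigenvector",
    "compartment_strength",
    "call_loops_simple",
    "loop_overlap",
    "loop_length_stats",
]

LOG_STEP = 0.1   # width of each genomic-distance bin on the log10 scale


@dataclass
class ContactFrequencyCurve:
    """Contact fraction per 0.1-decade bin of genomic separation.

    ``fractions`` sum to 1 over the counted range; normalization is per
    analyzed region (recorded in ``domain``).  ``pair_counts`` holds the
    number of bin pairs falling in each separation bin, so that
    ``mean_per_pair`` is the average contact frequency per pair — the
    quantity whose log-log derivative is the P(s) slope.
    """

    edges_bp: np.ndarray       # len = n_bins + 1
    fractions: np.ndarray
    pair_counts: np.ndarray
    domain: str = "region"

    @property
    def centers_bp(self) -> np.ndarray:
        return np.sqrt(self.edges_bp[:-1] * self.edges_bp[1:])

    @property
    def mean_per_pair(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.pair_counts > 0, self.fractions / self.pair_counts, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dist_lo": self.edges_bp[:-1], "dist_hi": self.edges_bp[1:],
                             "fraction": self.fractions, "n_pairs": self.pair_counts})


def contact_frequency_curve(matrix: ContactMatrix, min_dist: int, max_dist: int,
                            ) -> ContactFrequencyCurve:
    """Log-binned intrachromosomal contact-frequency distribution, P(s).

    Every pixel with separation in [min_dist, max_dist] contributes its count
    to the 0.1-decade bin containing log10(separation); totals are divided by
    the grand total so the fractions sum to 1.
    """
    if not (0 < min_dist < max_dist):
        raise ValueError("need 0 < min_dist < max_dist")
    if min_dist < matrix.bins.bin_size:
        raise ValueError("min_dist must be >= bin size")
    p = matrix.pixels
    sep = (p["bin2_id"] - p["bin1_id"]).to_numpy() * matrix.bins.bin_size
    counts = p["count"].to_numpy()
    keep = (sep >= min_dist) & (sep <= max_dist)
    sep, counts = sep[keep], counts[keep]
    if counts.sum() == 0:
        raise ValueError("no contacts in the requested distance range")
    lo = np.log10(min_dist)
    n_bins = int(np.ceil((np.log10(max_dist) - lo) / LOG_STEP))
    edges = 10 ** (lo + LOG_STEP * np.arange(n_bins + 1))
    idx = np.minimum(((np.log10(sep) - lo) / LOG_STEP).astype(int), n_bins - 1)
    totals = np.bincount(idx, weights=counts, minlength=n_bins)
    # bin pairs per separation bin (s in bins of bin_size; n - s pairs each)
    n = matrix.n
    all_s = np.arange(1, n) * matrix.bins.bin_size
    in_range = (all_s >= min_dist) & (all_s <= max_dist)
    s_idx = np.minimum(((np.log10(all_s[in_range]) - lo) / LOG_STEP).astype(int), n_bins - 1)
    pair_counts = np.bincount(s_idx, weights=(n - np.arange(1, n))[in_range],
                              minlength=n_bins)
    return ContactFrequencyCurve(edges, totals / totals.sum(), pair_counts,
                                 domain=f"{matrix.bins.chrom}:{matrix.bins.region[1]}-{matrix.bins.region[2]}")


def curve_slope(curve: ContactFrequencyCurve) -> np.ndarray:
    """Centered finite-difference P(s) slope on log-log axes.

    The derivative is taken on the per-pair mean contact frequency (the
    contact-probability curve), not on the summed fractions, so a power law
    ``P(s) ~ s^-a`` yields a flat slope of ``-a``.  Empty curve bins
    propagate NaN.  Requires >= 3 nonzero bins.
    """
    f = curve.mean_per_pair
    f = np.where(np.isfinite(f), f, 0.0)
    if np.count_nonzero(f) < 3:
        raise ValueError("need at least 3 nonzero curve bins for a slope")
    with np.errstate(divide="ignore"):
        logf = np.where(f > 0, np.log10(np.where(f > 0, f, 1.0)), np.nan)
    logd = np.log10(curve.centers_bp)
    slope = np.full_like(f, np.nan)
    slope[1:-1] = (logf[2:] - logf[:-2]) / (logd[2:] - logd[:-2])
    return slope


def differential_map(A: ContactMatrix, B: ContactMatrix, pseudocount: float = 1.0,
                     depth_match: bool = True) -> np.ndarray:
    """Per-pixel log2((A + p)/(B + p)) dense map.

    With ``depth_match`` both matrices are first scaled to the same total
    (deterministic analogue of read down-sampling).  Pixels on bins masked in
    either input are NaN.
    """
    if A.bins.to_frame().shape != B.bins.to_frame().shape or \
            not (A.bins.starts == B.bins.starts).all():
        raise ValueError("matrices are on different bin tables")
    da, db = A.to_dense(), B.to_dense()
    if depth_match:
        target = (A.total + B.total) / 2.0
        da = da * (target / A.total)
        db = db * (target / B.total)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2((da + pseudocount) / (db + pseudocount))
    bad = ~(A.valid_mask & B.valid_mask)
    out[bad, :] = np.nan
    out[:, bad] = np.nan
    return out


@dataclass
class StripeTrack:
    """Mean contact between each bin of a span and a fixed anchor."""

    span: tuple[int, int]          # half-open bin range
    values: np.ndarray             # len = span width; NaN on masked bins
    mode: str                      # "raw" | "obs_over_exp"

    @property
    def span_bins(self) -> np.ndarray:
        return np.arange(*self.span)


def stripe_profile(matrix: ContactMatrix, anchor: tuple[int, int], span: tuple[int, int],
                   mode: str = "obs_over_exp", balanced: bool = False) -> StripeTrack:
    """Quantify a contact stripe: mean contact of every span bin with the anchor.

    ``anchor`` and ``span`` are half-open genomic intervals in bp, snapped
    outward to bin boundaries.  In obs/exp mode each contact is divided by
    the expected value at its separation before averaging.
    """
    a0, a1 = matrix.bins.snap_interval(*anchor)
    s0, s1 = matrix.bins.snap_interval(*span)
    valid = matrix.valid_mask
    if not valid[a0:a1].any():
        raise ValueError("anchor interval is fully masked")
    dense = matrix.to_dense(balanced=balanced)
    if balanced:
        dense = np.nan_to_num(dense, nan=0.0)
    if mode == "obs_over_exp":
        decay = expected_by_distance(matrix, balanced=balanced)
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    anchor_bins = np.arange(a0, a1)[valid[a0:a1]]
    vals = np.full(s1 - s0, np.nan)
    for k, b in enumerate(range(s0, s1)):
        if not valid[b]:
            continue
        obs = dense[b, anchor_bins]
        if mode == "obs_over_exp":
            exp = decay.values[np.abs(anchor_bins - b)]
            with np.errstate(divide="ignore", invalid="ignore"):
                obs = np.where(exp > 0, obs / exp, np.nan)
        vals[k] = np.nanmean(obs) if np.isfinite(obs).any() else np.nan
    return StripeTrack((s0, s1), vals, mode)


@dataclass
class CompartmentTrack:
    """First eigenvector of the contact-correlation matrix; positive = A (active)."""

    values: np.ndarray             # NaN on masked bins
    eigenvalue: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def compartment_eigenvector(matrix: ContactMatrix, phasing: np.ndarray,
                            balanced: bool = False, impute: bool = False) -> CompartmentTrack:
    """Leading eigenvector of the obs/exp Pearson-correlation matrix,
    sign-fixed to correlate positively with an active-chromatin phasing track.

    Masked bins are NaN in the output (optionally linearly interpolated with
    ``impute=True``).
    """
    valid = matrix.valid_mask
    idx = np.flatnonzero(valid)
    if len(idx) < 20:
        raise ValueError("need >= 20 unmasked bins for compartment analysis")
    dense = matrix.to_dense(balanced=balanced)
    if balanced:
        dense = np.nan_to_num(dense, nan=0.0)
    decay = expected_by_distance(matrix, balanced=balanced)
    n = matrix.n
    seps = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(decay.values[seps] > 0, dense / decay.values[seps], 0.0)
    sub = oe[np.ix_(idx, idx)]
    if np.allclose(sub.std(axis=1), 0.0):
        raise ValueError("degenerate obs/exp matrix (no contrast between bins)")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    w, v = np.linalg.eigh(corr)
    ev = v[:, -1]
    ph = np.asarray(phasing, dtype=float)[idx]
    finite = np.isfinite(ph)
    if finite.sum() >= 2 and np.corrcoef(ev[finite], ph[finite])[0, 1] < 0:
        ev = -ev
    out = np.full(n, np.nan)
    out[idx] = ev
    if impute:
        bad = ~np.isfinite(out)
        out[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), out[~bad])
    return CompartmentTrack(out, float(w[-1]))


def compartment_strength(matrix: ContactMatrix, track: CompartmentTrack,
                         n_quantiles: int = 50, corner_frac: float = 0.2,
                         balanced: bool = False) -> tuple[np.ndarray, float]:
    """Saddle analysis: mean obs/exp per eigenvector-quantile pair and a
    scalar strength = mean(AA, BB corners) / mean(AB corners), corners being
    the outer ``corner_frac`` of quantiles.
    """
    valid = matrix.valid_mask & track.valid
    idx = np.flatnonzero(valid)
    if n_quantiles > len(idx):
        raise ValueError(f"n_quantiles={n_quantiles} exceeds {len(idx)} unmasked bins")
    dense = matrix.to_dense(balanced=balanced)
    if balanced:
        dense = np.nan_to_num(dense, nan=0.0)
    decay = expected_by_distance(matrix, balanced=balanced)
    n = matrix.n
    seps = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(decay.values[seps] > 0, dense / decay.values[seps], np.nan)
    ranks = pd.Series(track.values[idx]).rank(method="first").to_numpy() - 1
    q = np.minimum((ranks * n_quantiles / len(idx)).astype(int), n_quantiles - 1)
    saddle = np.full((n_quantiles, n_quantiles), np.nan)
    sub = oe[np.ix_(idx, idx)]
    np.fill_diagonal(sub, np.nan)
    for qi in range(n_quantiles):
        sel_i = q == qi
        for qj in range(qi, n_quantiles):
            block = sub[np.ix_(sel_i, q == qj)]
            m = np.nanmean(block) if np.isfinite(block).any() else np.nan
            saddle[qi, qj] = saddle[qj, qi] = m
    k = max(1, int(round(corner_frac * n_quantiles)))
    bb = saddle[:k, :k]
    aa = saddle[-k:, -k:]
    ab = saddle[:k, -k:]
    strength = float((np.nanmean(aa) + np.nanmean(bb)) / (2 * np.nanmean(ab)))
    return saddle, strength


@dataclass(frozen=True)
class LoopCall:
    """Punctate enrichment: two one-bin anchors, anchor1 upstream of anchor2."""

    chrom: str
    a1_start: int
    a1_end: int
    a2_start: int
    a2_end: int
    score: float

    def __post_init__(self) -> None:
        if self.a1_start >= self.a2_start:
            raise ValueError("anchor1 must be upstream of anchor2")

    @property
    def length(self) -> int:
        """Anchor-midpoint distance (resolution-robust loop length)."""
        return ((self.a2_start + self.a2_end) - (self.a1_start + self.a1_end)) // 2


def _box_sum(x: np.ndarray, r: int) -> np.ndarray:
    """Sum of x over (2r+1)^2 windows, zero-padded."""
    c = np.cumsum(np.cumsum(np.pad(x, ((1, 0), (1, 0))), axis=0), axis=1)
    n = x.shape[0]
    i = np.arange(n)
    lo = np.clip(i - r, 0, n)
    hi = np.clip(i + r + 1, 0, n)
    return c[np.ix_(hi, hi)] - c[np.ix_(lo, hi)] - c[np.ix_(hi, lo)] + c[np.ix_(lo, lo)]


def call_loops_simple(matrix: ContactMatrix, window: int = 5, min_enrichment: float = 2.0,
                      min_separation: int = 40_000, core: int = 1,
                      min_count: float = 4.0, balanced: bool = False) -> list[LoopCall]:
    """Ring-enrichment loop caller (simplified punctate-contact detection).

    A pixel is called when its obs/exp value (i) exceeds ``min_enrichment``
    times the mean obs/exp of the surrounding ring (the +-``window`` frame
    excluding a +-``core`` protected centre), (ii) is the maximum within
    the +-``window`` box, and (iii) carries at least ``min_count`` raw
    counts (suppressing single-read shot noise at extreme separations where
    the expected value is vanishing).  Calls whose anchors both lie within
    ``window`` bins of a stronger call are merged into it.
    """
    dense = matrix.to_dense(balanced=balanced)
    if balanced:
        dense = np.nan_to_num(dense, nan=0.0)
    decay = expected_by_distance(matrix, balanced=balanced)
    n = matrix.n
    seps = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(decay.values[seps] > 0, dense / decay.values[seps], 0.0)
    valid = np.outer(matrix.valid_mask, matrix.valid_mask).astype(float)
    oe = oe * valid

    ring_sum = _box_sum(oe, window) - _box_sum(oe, core)
    ring_cnt = _box_sum(valid, window) - _box_sum(valid, core)
    with np.errstate(divide="ignore", invalid="ignore"):
        ring_mean = np.where(ring_cnt > 0, ring_sum / ring_cnt, np.nan)
    local_max = oe >= ndimage.maximum_filter(oe, size=2 * window + 1, mode="constant")

    raw = matrix.to_dense()
    min_sep_bins = max(1, min_separation // matrix.bins.bin_size)
    cand = np.argwhere(local_max & (oe > 0) & (seps >= min_sep_bins) & (raw >= min_count)
                       & np.isfinite(ring_mean) & (oe > min_enrichment * np.maximum(ring_mean, 1e-300)))
    cand = [(int(i), int(j)) for i, j in cand if i < j]

    b = matrix.bins
    calls = []
    for i, j in cand:
        enr = oe[i, j] / ring_mean[i, j] if ring_mean[i, j] > 0 else np.inf
        calls.append((enr, i, j))
    calls.sort(reverse=True)
    kept: list[tuple[float, int, int]] = []
    for enr, i, j in calls:
        if any(abs(i - ki) <= window and abs(j - kj) <= window for _, ki, kj in kept):
            continue
        kept.append((enr, i, j))
    return sorted(
        (LoopCall(b.chrom, int(b.starts[i]), int(b.ends[i]),
                  int(b.starts[j]), int(b.ends[j]), float(enr))
         for enr, i, j in kept),
        key=lambda L: (L.a1_start, L.a2_start))


def _reciprocal(a0: int, a1: int, b0: int, b1: int, f: float) -> bool:
    ov = min(a1, b1) - max(a0, b0)
    return ov > 0 and ov >= f * (a1 - a0) and ov >= f * (b1 - b0)


def loop_overlap(A: Sequence[LoopCall], B: Sequence[LoopCall], min_reciprocal: float = 0.9,
                 ) -> dict[str, list[LoopCall]]:
    """Partition two loop lists into common/unique by reciprocal anchor overlap.

    Two loops are "common" when *both* anchor pairs overlap reciprocally by at
    least ``min_reciprocal`` of each anchor's width; each loop pairs at most
    once (greedy in input order).
    """
    used_b: set[int] = set()
    common_a, unique_a = [], []
    for la in A:
        hit = None
        for k, lb in enumerate(B):
            if k in used_b:
                continue
            if (_reciprocal(la.a1_start, la.a1_end, lb.a1_start, lb.a1_end, min_reciprocal)
                    and _reciprocal(la.a2_start, la.a2_end, lb.a2_start, lb.a2_end, min_reciprocal)):
                hit = k
                break
        if hit is None:
            unique_a.append(la)
        else:
            used_b.add(hit)
            common_a.append(la)
    common_b = [lb for k, lb in enumerate(B) if k in used_b]
    unique_b = [lb for k, lb in enumerate(B) if k not in used_b]
    return {"common_a": common_a, "common_b": common_b,
            "unique_a": unique_a, "unique_b": unique_b}


def loop_length_stats(loops: Sequence[LoopCall]) -> dict[str, float]:
    """Median, quartiles, 1.5 x IQR whisker bounds and count of loop lengths."""
    if not loops:
        warnings.warn("empty loop list; statistics undefined", stacklevel=2)
        return {"count": 0, "median": np.nan, "q1": np.nan, "q3": np.nan,
                "whisker_lo": np.nan, "whisker_hi": np.nan}
    lengths = np.array([l.length for l in loops], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    iqr = q3 - q1
    in_lo = lengths[lengths >= q1 - 1.5 * iqr]
    in_hi = lengths[lengths <= q3 + 1.5 * iqr]
    return {"count": int(len(lengths)), "median": float(med), "q1": float(q1),
            "q3": float(q3), "whisker_lo": float(in_lo.min()), "whisker_hi": float(in_hi.max())}
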
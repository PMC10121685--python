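"""Binned cis contact matrices: data model, text I/O, balancing, expected-by-distance.

Conventions
-----------
* Coordinates are 0-based half-open (BED).  Matrix axes are bin indices into a
  :class:`GenomicBins` table; bins are uniform except possibly the last.
* Only the upper triangle is stored (``bin1_id <= bin2_id``); symmetric queries
  are answered by index swap.
* Unmappable bins carry a NaN balancing weight and are excluded from every
  downstream statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenomicBins",
    "ContactMatrix",
    "DistanceDecay",
    "load_contact_data",
    "write_contact_data",
    "balance_ice",
    "expected_by_distance",
    "fetch_region",
    "coarsen",
]


class ContactDataError(ValueError):
    """Malformed bins/pixels input; the message names the offending record."""


@dataclass(frozen=True)
class GenomicBins:
    """Ordered, contiguous, uniform bins on one chromosome.

    All bins have width ``bin_size`` except possibly the last, which may be
    truncated at the region end.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    bin_size: int

    def __post_init__(self) -> None:
        s, e = np.asarray(self.starts, dtype=np.int64), np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", s)
        object.__setattr__(self, "ends", e)
        if len(s) == 0:
            raise ContactDataError("empty bin table")
        if np.any(e <= s):
            i = int(np.flatnonzero(e <= s)[0])
            raise ContactDataError(f"bin {i} has end <= start ({s[i]}, {e[i]})")
        if np.any(s[1:] != e[:-1]):
            i = int(np.flatnonzero(s[1:] != e[:-1])[0])
            raise ContactDataError(f"bins {i} and {i + 1} are not contiguous/sorted")
        widths = e - s
        if np.any(widths[:-1] != self.bin_size) or widths[-1] > self.bin_size:
            i = int(np.flatnonzero(np.append(widths[:-1] != self.bin_size, widths[-1] > self.bin_size))[0])
            raise ContactDataError(f"bin {i} width {widths[i]} != bin_size {self.bin_size}")

    @classmethod
    def from_region(cls, chrom: str, start: int, end: int, bin_size: int) -> "GenomicBins":
        edges = np.arange(start, end, bin_size, dtype=np.int64)
        return cls(chrom, edges, np.minimum(edges + bin_size, end), bin_size)

    @classmethod
    def read_bed(cls, path: str | Path) -> "GenomicBins":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                         names=["chrom", "start", "end"])
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ContactDataError(f"bins span multiple chromosomes: {list(chroms)} (cis-only model)")
        widths = (df["end"] - df["start"]).to_numpy()
        bin_size = int(widths[0]) if len(widths) == 1 else int(np.max(widths[:-1]))
        return cls(str(chroms[0]), df["start"].to_numpy(), df["end"].to_numpy(), bin_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.starts, "end": self.ends})

    def write_bed(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    @property
    def n(self) -> int:
        return len(self.starts)

    @property
    def region(self) -> tuple[str, int, int]:
        return self.chrom, int(self.starts[0]), int(self.ends[-1])

    def index_of(self, pos: int) -> int:
        """Bin index containing genomic position ``pos``."""
        c, lo, hi = self.region
        if not lo <= pos < hi:
            raise ContactDataError(f"position {pos} outside bins {c}:{lo}-{hi}")
        return min(int((pos - lo) // self.bin_size), self.n - 1)

    def snap_interval(self, start: int, end: int) -> tuple[int, int]:
        """Half-open bin-index range covering [start, end), snapped outward."""
        c, lo, hi = self.region
        if end <= lo or start >= hi:
            raise ContactDataError(f"interval {start}-{end} does not intersect bins {c}:{lo}-{hi}")
        i0 = self.index_of(max(start, lo))
        i1 = self.index_of(min(end, hi) - 1) + 1
        return i0, i1


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact counts, upper triangle only.

    ``pixels`` has integer columns ``bin1_id <= bin2_id`` and float ``count``;
    ``weights`` (optional) holds per-bin multiplicative balancing factors with
    NaN marking unmappable bins.
    """

    bins: GenomicBins
    pixels: pd.DataFrame
    weights: Optional[np.ndarray] = None
    balance_converged: Optional[bool] = None

    def __post_init__(self) -> None:
        p = self.pixels
        p = pd.DataFrame({
            "bin1_id": p["bin1_id"].astype(np.int64),
            "bin2_id": p["bin2_id"].astype(np.int64),
            "count": p["count"].astype(float),
        }).reset_index(drop=True)
        n = self.bins.n
        bad = (p["bin1_id"] < 0) | (p["bin2_id"] >= n) | (p["bin1_id"] > p["bin2_id"])
        if bad.any():
            r = p[bad].iloc[0]
            raise ContactDataError(
                f"pixel ({int(r.bin1_id)}, {int(r.bin2_id)}) invalid for {n} bins (need 0 <= i <= j < n)")
        if (p["count"] < 0).any():
            r = p[p["count"] < 0].iloc[0]
            raise ContactDataError(f"negative count {r['count']} at pixel ({int(r.bin1_id)}, {int(r.bin2_id)})")
        if p.duplicated(["bin1_id", "bin2_id"]).any():
            r = p[p.duplicated(["bin1_id", "bin2_id"])].iloc[0]
            raise ContactDataError(f"duplicate pixel ({int(r.bin1_id)}, {int(r.bin2_id)})")
        self.pixels = p.sort_values(["bin1_id", "bin2_id"], ignore_index=True)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != n:
                raise ContactDataError("weights length does not match bin count")

    @property
    def n(self) -> int:
        return self.bins.n

    @property
    def total(self) -> float:
        return float(self.pixels["count"].sum())

    @property
    def valid_mask(self) -> np.ndarray:
        """True for bins usable in statistics (finite balancing weight)."""
        if self.weights is None:
            return np.ones(self.n, dtype=bool)
        return np.isfinite(self.weights)

    def to_dense(self, balanced: bool = False) -> np.ndarray:
        """Full symmetric dense array; masked rows/cols are NaN when balanced."""
        m = np.zeros((self.n, self.n))
        i = self.pixels["bin1_id"].to_numpy()
        j = self.pixels["bin2_id"].to_numpy()
        c = self.pixels["count"].to_numpy()
        m[i, j] = c
        m[j, i] = c
        if balanced:
            if self.weights is None:
                raise ContactDataError("matrix has no balancing weights; run balance_ice first")
            m = m * np.outer(self.weights, self.weights)
        return m

    def with_pixels(self, pixels: pd.DataFrame) -> "ContactMatrix":
        return ContactMatrix(self.bins, pixels, None if self.weights is None else self.weights.copy())


@dataclass
class DistanceDecay:
    """Per-diagonal expected contact: mean count over valid bin pairs at each separation."""

    bin_size: int
    values: np.ndarray  # values[d] = expected count at separation d bins

    def at_separation(self, d_bins: np.ndarray | int) -> np.ndarray | float:
        return self.values[d_bins]

    def at_distance(self, d_bp: int) -> float:
        return float(self.values[d_bp // self.bin_size])


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, comment="#")


def load_contact_data(bins_source: str | Path, pixels_source: str | Path,
                      fmt: str = "auto") -> ContactMatrix:
    """Load a contact matrix from a bins BED and either triplet or dense text pixels.

    ``fmt`` is ``"triplets"``, ``"dense"`` or ``"auto"``.  Auto resolves a file
    with exactly ``n_bins`` columns as dense, otherwise as (i, j, count)
    triplets with 0-based bin indices.  Dense input is folded to the upper
    triangle by averaging entries (i, j) and (j, i).
    """
    bins = GenomicBins.read_bed(bins_source)
    df = _read_table(pixels_source)
    if fmt == "auto":
        fmt = "dense" if (df.shape[1] == bins.n and df.shape[0] == bins.n and bins.n != 3) else \
              ("triplets" if df.shape[1] == 3 else "dense")
    if fmt == "triplets":
        if df.shape[1] != 3:
            raise ContactDataError(f"triplet pixels need 3 columns, got {df.shape[1]}")
        idx = df.iloc[:, :2].to_numpy()
        if not np.allclose(idx, np.round(idx)):
            raise ContactDataError("triplet bin indices must be integers")
        i, j = idx[:, 0].astype(np.int64), idx[:, 1].astype(np.int64)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        pixels = (pd.DataFrame({"bin1_id": lo, "bin2_id": hi, "count": df.iloc[:, 2].to_numpy(float)})
                  .groupby(["bin1_id", "bin2_id"], as_index=False)["count"].sum())
        return ContactMatrix(bins, pixels)
    dense = df.to_numpy(dtype=float)
    if dense.shape != (bins.n, bins.n):
        raise ContactDataError(f"dense matrix shape {dense.shape} does not match {bins.n} bins")
    folded = (dense + dense.T) / 2.0
    iu, ju = np.triu_indices(bins.n)
    c = folded[iu, ju]
    keep = c != 0
    return ContactMatrix(bins, pd.DataFrame({"bin1_id": iu[keep], "bin2_id": ju[keep], "count": c[keep]}))


def write_contact_data(matrix: ContactMatrix, bins_path: str | Path, pixels_path: str | Path) -> None:
    """Write the bins BED3 and the upper-triangle (i, j, count) triplet TSV."""
    matrix.bins.write_bed(bins_path)
    matrix.pixels.to_csv(pixels_path, sep="\t", header=False, index=False)


def balance_ice(matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5) -> ContactMatrix:
    """Iterative correction: multiplicative per-bin weights equalizing marginals.

    Bins with zero raw marginal are masked (NaN weight) before iteration.
    Convergence = relative spread of balanced marginals below ``tol``; a
    non-converged result is returned with ``balance_converged=False`` and a
    warning.
    """
    dense = matrix.to_dense()
    marg0 = dense.sum(axis=1)
    mask = marg0 > 0
    w = np.ones(matrix.n)
    sub = dense[np.ix_(mask, mask)]
    ws = np.ones(sub.shape[0])
    converged = False
    for _ in range(max_iter):
        m = (sub * np.outer(ws, ws)).sum(axis=1)
        mean = m[m > 0].mean()
        if np.max(np.abs(m / mean - 1.0)) < tol:
            converged = True
            break
        ws = ws / np.sqrt(np.where(m > 0, m / mean, 1.0))
    if not converged:
        warnings.warn(f"iterative correction did not converge in {max_iter} iterations; "
                      "weights are partial", stacklevel=2)
    w[mask] = ws
    w[~mask] = np.nan
    return ContactMatrix(matrix.bins, matrix.pixels.copy(), weights=w, balance_converged=converged)


def expected_by_distance(matrix: ContactMatrix, balanced: bool = False) -> DistanceDecay:
    """Mean contact per *valid* bin pair at each separation (per-diagonal expected).

    The denominator at separation ``d`` counts all unmasked bin pairs ``(i, i+d)``,
    not only nonzero pixels.
    """
    dense = matrix.to_dense(balanced=balanced)
    valid = matrix.valid_mask
    dense = np.where(np.outer(valid, valid), dense, 0.0)
    n = matrix.n
    values = np.zeros(n)
    for d in range(n):
        pair_ok = valid[: n - d] & valid[d:]
        denom = int(pair_ok.sum())
        values[d] = np.diagonal(dense, offset=d).sum() / denom if denom else 0.0
    return DistanceDecay(matrix.bins.bin_size, values)


def fetch_region(matrix: ContactMatrix, chrom: str, start: int, end: int) -> ContactMatrix:
    """Sub-matrix over the bins covering [start, end), snapped outward to bin edges."""
    if chrom != matrix.bins.chrom:
        raise ContactDataError(f"chromosome {chrom!r} not in bins ({matrix.bins.chrom!r})")
    i0, i1 = matrix.bins.snap_interval(start, end)
    b = matrix.bins
    sub_bins = GenomicBins(b.chrom, b.starts[i0:i1], b.ends[i0:i1], b.bin_size)
    p = matrix.pixels
    keep = (p["bin1_id"] >= i0) & (p["bin2_id"] < i1)
    sub = p[keep].copy()
    sub["bin1_id"] -= i0
    sub["bin2_id"] -= i0
    w = None if matrix.weights is None else matrix.weights[i0:i1].copy()
    return ContactMatrix(sub_bins, sub, weights=w)


def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate to ``factor``-fold larger bins by summing pixel counts."""
    if factor == 1:
        return matrix
    b = matrix.bins
    c, lo, hi = b.region
    new_bins = GenomicBins.from_region(c, lo, hi, b.bin_size * factor)
    p = matrix.pixels
    i = (p["bin1_id"] // factor).to_numpy()
    j = (p["bin2_id"] // factor).to_numpy()
    agg = (pd.DataFrame({"bin1_id": i, "bin2_id": j, "count": p["count"].to_numpy()})
           .groupby(["bin1_id", "bin2_id"], as_index=False)["count"].sum())
    return ContactMatrix(new_bins, agg)
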
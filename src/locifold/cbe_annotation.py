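"""Oriented CTCF-binding-element (CBE) annotation.

Scans genomic sequence with a CTCF position-weight matrix on both strands,
then assigns motif hits to ChIP peak summits to produce the oriented CBE
annotation consumed by the directional contact-profile analysis.  Motif
significance uses a log-odds score threshold, with an optional empirical
p-value calibrated on shuffled-sequence nulls in place of an analytic score
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "MotifHit",
    "CTCFPeak",
    "CBEAnnotation",
    "scan_pwm",
    "assign_motifs_to_peaks",
    "empirical_score_threshold",
    "read_narrowpeak",
]

_ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])   # A<->T, C<->G


@dataclass(frozen=True)
class PWM:
    """Log-odds position-weight matrix over A, C, G, T.

    ``scores[k, a]`` is the log2-odds of letter ``a`` at motif position ``k``
    against the background distribution.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.ndim != 2 or s.shape[1] != 4 or s.shape[0] < 4:
            raise ValueError("PWM needs shape (L >= 4, 4)")
        if not np.all(np.isfinite(s)):
            raise ValueError("PWM scores must be finite")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[a] for a in self.scores.argmax(axis=1))

    @classmethod
    def from_probabilities(cls, probs: np.ndarray, background: Optional[np.ndarray] = None,
                           pseudo: float = 1e-3) -> "PWM":
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(np.log2((probs + pseudo) / bg[None, :]))

    @classmethod
    def read(cls, path: str | Path, background: Optional[np.ndarray] = None) -> "PWM":
        """Read a MEME-minimal motif or a plain whitespace probability matrix."""
        text = Path(path).read_text()
        if "letter-probability matrix" in text:
            rows, capture = [], False
            for line in text.splitlines():
                if "letter-probability matrix" in line:
                    capture = True
                    continue
                if capture:
                    parts = line.split()
                    if len(parts) == 4:
                        try:
                            rows.append([float(x) for x in parts])
                        except ValueError:
                            break
                    elif rows:
                        break
            mat = np.array(rows)
        else:
            mat = np.array([[float(x) for x in line.split()]
                            for line in text.splitlines() if line.strip() and not line.startswith("#")])
            if mat.shape[1] != 4 and mat.shape[0] == 4:
                mat = mat.T
        return cls.from_probabilities(mat, background)

    def reverse_complement(self) -> "PWM":
        return PWM(self.scores[::-1, _COMPLEMENT])


@dataclass(frozen=True)
class MotifHit:
    start: int      # 0-based position of the window on the forward strand
    strand: str     # "+" | "-"
    score: float

    def center(self, length: int) -> int:
        return self.start + length // 2


@dataclass(frozen=True)
class CTCFPeak:
    start: int
    end: int
    summit: int     # absolute bp
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError(f"summit {self.summit} outside peak [{self.start}, {self.end})")


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    out = np.full(len(seq), -1, dtype=np.int8)
    for c, i in _CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(c)] = i
    return out


def scan_pwm(sequence: str, pwm: PWM, min_score: float,
             offset: int = 0) -> list[MotifHit]:
    """All windows on both strands scoring >= ``min_score``.

    Windows containing non-ACGT letters are skipped.  Reverse-strand windows
    are scored on the reverse complement (equivalently, with the
    reverse-complemented matrix at the same forward coordinates).  ``offset``
    shifts reported positions to genomic coordinates.
    """
    code = _encode(sequence)
    L = pwm.length
    n_win = len(code) - L + 1
    if n_win <= 0:
        return []
    ok = np.ones(n_win, dtype=bool)
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    rc = pwm.reverse_complement().scores
    for k in range(L):
        letters = code[k : k + n_win]
        ok &= letters >= 0
        safe = np.clip(letters, 0, 3)
        fwd += pwm.scores[k, safe]
        rev += rc[k, safe]
    hits = [MotifHit(offset + int(i), "+", float(fwd[i])) for i in np.flatnonzero(ok & (fwd >= min_score))]
    hits += [MotifHit(offset + int(i), "-", float(rev[i])) for i in np.flatnonzero(ok & (rev >= min_score))]
    return sorted(hits, key=lambda h: (h.start, h.strand))


def empirical_score_threshold(pwm: PWM, p_value: float = 0.001, n_samples: int = 200_000,
                              background: Optional[np.ndarray] = None,
                              seed: int = 0) -> float:
    """Score threshold at the given per-window p-value under an i.i.d.
    background-letter null (Monte-Carlo over random windows)."""
    rng = np.random.default_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    letters = rng.choice(4, size=(n_samples, pwm.length), p=bg / bg.sum())
    scores = pwm.scores[np.arange(pwm.length)[None, :], letters].sum(axis=1)
    return float(np.quantile(scores, 1.0 - p_value))


class CBEAnnotation:
    """Oriented CBEs: position (bp), orientation (+ forward / - reverse),
    motif score, source peak id.  Positions sorted."""

    def __init__(self, table: pd.DataFrame):
        req = {"position", "orientation"}
        if not req <= set(table.columns):
            raise ValueError(f"CBE table needs columns {req}")
        bad = ~table["orientation"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid orientation {table.loc[bad, 'orientation'].iloc[0]!r}")
        self.table = table.sort_values("position", ignore_index=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    @property
    def orientations(self) -> np.ndarray:
        return self.table["orientation"].to_numpy()

    @classmethod
    def from_lists(cls, positions: Sequence[int], orientations: Sequence[str],
                   scores: Optional[Sequence[float]] = None,
                   sources: Optional[Sequence[str]] = None) -> "CBEAnnotation":
        return cls(pd.DataFrame({
            "position": list(positions),
            "orientation": list(orientations),
            "score": list(scores) if scores is not None else 0.0,
            "source": list(sources) if sources is not None else ".",
        }))

    def write_bed(self, path: str | Path, chrom: str, half_width: int = 10) -> None:
        t = self.table
        pd.DataFrame({
            "chrom": chrom,
            "start": t["position"] - half_width,
            "end": t["position"] + half_width,
            "name": t.get("source", "."),
            "score": t.get("score", 0.0),
            "strand": t["orientation"],
        }).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(cls, path: str | Path) -> "CBEAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "score", "strand"])
        return cls(pd.DataFrame({
            "position": (df["start"] + df["end"]) // 2,
            "orientation": df["strand"],
            "score": df["score"],
            "source": df["name"],
        }))


def read_narrowpeak(path: str | Path) -> list[CTCFPeak]:
    """BED/narrowPeak reader; summit from column 10 when present, else midpoint."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for _, r in df.iterrows():
        start, end = int(r[1]), int(r[2])
        if df.shape[1] >= 10 and int(r[9]) >= 0:
            summit = start + int(r[9])
        else:
            summit = (start + end) // 2
        peaks.append(CTCFPeak(start, end, summit,
                              float(r[4]) if df.shape[1] > 4 else 0.0,
                              str(r[3]) if df.shape[1] > 3 else "."))
    return peaks


def assign_motifs_to_peaks(hits: Sequence[MotifHit], peaks: Sequence[CTCFPeak],
                           motif_length: int, max_summit_distance: int = 100,
                           ) -> tuple[CBEAnnotation, list[CTCFPeak]]:
    """One oriented element per peak: the best motif within ``max_summit_distance``
    bp of the summit.

    Candidates are ranked by higher score, then smaller summit distance, then
    leftmost position (deterministic, order-independent).  Peaks with no
    candidate are returned unoriented and excluded from the annotation.
    """
    rows = []
    unoriented: list[CTCFPeak] = []
    for pk in peaks:
        best = None
        for h in hits:
            d = abs(h.center(motif_length) - pk.summit)
            if d > max_summit_distance:
                continue
            key = (-h.score, d, h.start)
            if best is None or key < best[0]:
                best = (key, h, d)
        if best is None:
            unoriented.append(pk)
        else:
            _, h, d = best
            rows.append({"position": h.center(motif_length), "orientation": h.strand,
                         "score": h.score, "source": pk.name})
    if rows:
        ann = CBEAnnotation(pd.DataFrame(rows))
    else:
        ann = CBEAnnotation(pd.DataFrame({"position": pd.Series(dtype=int),
                                          "orientation": pd.Series(dtype=str),
                                          "score": pd.Series(dtype=float),
                                          "source": pd.Series(dtype=str)}))
    return ann, unoriented
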
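"""Stochastic 1D loop-extrusion simulator with directional CTCF barriers.

The model: cohesin complexes load on a 1D lattice of genomic bins and extrude
a loop by moving their two legs outward, one or more bins per synchronous time
step.  A leg halts when it reaches the lattice edge or another cohesin's leg
(collision).  Directional barriers represent oriented CTCF-binding elements
(CBEs): a *forward* barrier captures legs travelling leftward (arriving from
downstream, against the arrow), so forward CBEs anchor loops extending
downstream of them; a *reverse* barrier symmetrically captures rightward
legs.  This is the standard convergent-CTCF rule and it makes forward CBEs
produce peaks in the downstream directional contact profile.

Captured legs release stochastically; capture lowers the cohesin's unloading
probability (CTCF-stabilized residence).  The per-step unloading probability
scales linearly with a dimensionless ``wapl_level`` — the abundance of the
cohesin-release factor Wapl — so higher Wapl means shorter residence and
shorter loops.

Ensembles of simulation snapshots are converted to contact maps with three
contributions: the loop base of every cohesin, "interaction-zone" contacts
bridged along chains of collided cohesins (geometrically down-weighted with
chain depth), and a distance-decaying background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .contact_core import ContactMatrix, GenomicBins

__all__ = [
    "Barrier",
    "BarrierSet",
    "ExtrusionParams",
    "SimState",
    "SyntheticMapSpec",
    "step_state",
    "run_ensemble",
    "snapshots_to_contact_map",
    "make_locus_preset",
    "loop_length_distribution",
    "collision_chains",
]

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class Barrier:
    position: int          # bin index
    orientation: str       # "+" (forward) or "-" (reverse)
    capture_prob: float = 0.9
    release_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if not (0.0 <= self.capture_prob <= 1.0 and 0.0 <= self.release_rate <= 1.0):
            raise ValueError("barrier probabilities must lie in [0, 1]")


class BarrierSet:
    """Directional barriers indexed by lattice bin; positions strictly increasing."""

    def __init__(self, barriers: Sequence[Barrier]):
        barriers = sorted(barriers, key=lambda b: b.position)
        pos = [b.position for b in barriers]
        if len(set(pos)) != len(pos):
            raise ValueError("barrier positions must be unique")
        self.barriers = list(barriers)
        self._by_bin = {b.position: b for b in barriers}

    def __len__(self) -> int:
        return len(self.barriers)

    def __iter__(self):
        return iter(self.barriers)

    def at(self, bin_idx: int) -> Barrier | None:
        return self._by_bin.get(bin_idx)

    @property
    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.barriers], dtype=np.int64)

    def to_bed(self, bins: GenomicBins, path) -> None:
        """Ground-truth BED6; strand encodes orientation."""
        rows = [
            (bins.chrom, int(bins.starts[b.position]), int(bins.ends[b.position]),
             f"barrier_{k}", f"{b.capture_prob:.3f}", b.orientation)
            for k, b in enumerate(self.barriers)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class ExtrusionParams:
    """Simulator rates, all per synchronous step.

    ``unload_prob_ref`` is the per-step release probability at ``wapl_level``
    1.0; the effective probability is ``unload_prob_ref * wapl_level``
    (residence time inversely proportional to Wapl abundance).  While any leg
    is CTCF-captured the probability is further multiplied by
    ``ctcf_stabilization`` (<= 1).
    """

    n_bins: int
    bin_size: int = 2000
    loading_rate: float = 0.4          # expected loading attempts per step on the lattice
    extrusion_speed: int = 3           # bins per leg per step
    unload_prob_ref: float = 0.0165
    wapl_level: float = 1.0
    ctcf_stabilization: float = 0.3
    pool_size: Optional[int] = 4       # finite nuclear cohesin pool; None = unlimited
    max_cohesins: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.unload_prob < 1.0):
            raise ValueError(f"effective unload probability {self.unload_prob} outside (0, 1)")
        if self.extrusion_speed < 1 or int(self.extrusion_speed) != self.extrusion_speed:
            raise ValueError("extrusion_speed must be an integer >= 1")
        if self.wapl_level <= 0:
            raise ValueError("wapl_level must be > 0")
        if not (0.0 < self.ctcf_stabilization <= 1.0):
            raise ValueError("ctcf_stabilization must be in (0, 1]")

    @property
    def unload_prob(self) -> float:
        return self.unload_prob_ref * self.wapl_level


class SimState:
    """Cohesin leg positions and capture flags.

    Parallel lists: ``left[i] <= right[i]``; no two legs (of any cohesins)
    share a bin.
    """

    __slots__ = ("left", "right", "left_cap", "right_cap", "occupied")

    def __init__(self):
        self.left: list[int] = []
        self.right: list[int] = []
        self.left_cap: list[bool] = []
        self.right_cap: list[bool] = []
        self.occupied: set[int] = set()

    @property
    def n_cohesins(self) -> int:
        return len(self.left)

    def copy(self) -> "SimState":
        s = SimState()
        s.left = list(self.left)
        s.right = list(self.right)
        s.left_cap = list(self.left_cap)
        s.right_cap = list(self.right_cap)
        s.occupied = set(self.occupied)
        return s

    def check_invariants(self) -> None:
        legs = self.left + self.right
        assert len(set(legs)) == len(legs), "two legs share a bin"
        assert all(l <= r for l, r in zip(self.left, self.right)), "crossed legs"


def _advance_leg(state: SimState, idx: int, side: str, params: ExtrusionParams,
                 barriers: BarrierSet, rng: np.random.Generator) -> None:
    """Move one uncaptured leg up to ``extrusion_speed`` bins outward."""
    step = -1 if side == "left" else +1
    pos = state.left[idx] if side == "left" else state.right[idx]
    # a forward barrier opposes leftward travel; a reverse barrier opposes rightward travel
    opposing = FORWARD if side == "left" else REVERSE
    for _ in range(params.extrusion_speed):
        nxt = pos + step
        if nxt < 0 or nxt >= params.n_bins or nxt in state.occupied:
            break
        state.occupied.discard(pos)
        state.occupied.add(nxt)
        pos = nxt
        bar = barriers.at(pos)
        if bar is not None and bar.orientation == opposing and rng.random() < bar.capture_prob:
            if side == "left":
                state.left_cap[idx] = True
            else:
                state.right_cap[idx] = True
            break
    if side == "left":
        state.left[idx] = pos
    else:
        state.right[idx] = pos


def step_state(state: SimState, params: ExtrusionParams, barriers: BarrierSet,
               rng: np.random.Generator) -> SimState:
    """One synchronous update: move, release, unload, load (in that order)."""
    state = state.copy()
    # 1. movement with barrier capture tests
    for i in range(state.n_cohesins):
        if not state.left_cap[i]:
            _advance_leg(state, i, "left", params, barriers, rng)
        if not state.right_cap[i]:
            _advance_leg(state, i, "right", params, barriers, rng)
    # 2. captured legs release
    for i in range(state.n_cohesins):
        if state.left_cap[i]:
            bar = barriers.at(state.left[i])
            if bar is None or rng.random() < bar.release_rate:
                state.left_cap[i] = False
        if state.right_cap[i]:
            bar = barriers.at(state.right[i])
            if bar is None or rng.random() < bar.release_rate:
                state.right_cap[i] = False
    # 3. unloading (CTCF capture stabilizes residence)
    keep = []
    for i in range(state.n_cohesins):
        u = params.unload_prob
        if state.left_cap[i] or state.right_cap[i]:
            u *= params.ctcf_stabilization
        if rng.random() >= u:
            keep.append(i)
        else:
            state.occupied.discard(state.left[i])
            state.occupied.discard(state.right[i])
    if len(keep) != state.n_cohesins:
        state.left = [state.left[i] for i in keep]
        state.right = [state.right[i] for i in keep]
        state.left_cap = [state.left_cap[i] for i in keep]
        state.right_cap = [state.right_cap[i] for i in keep]
    # 4. loading at adjacent unoccupied bin pairs; with a finite pool the
    # attempt rate scales with the free (unloaded) fraction, so the bound
    # cohesin number saturates near pool_size instead of growing as 1/u
    rate = params.loading_rate
    if params.pool_size is not None:
        rate *= max(0.0, 1.0 - state.n_cohesins / params.pool_size)
    n_new = rng.poisson(rate)
    for _ in range(n_new):
        for _attempt in range(20):
            b = int(rng.integers(0, params.n_bins - 1))
            if b not in state.occupied and (b + 1) not in state.occupied:
                state.left.append(b)
                state.right.append(b + 1)
                state.left_cap.append(False)
                state.right_cap.append(False)
                state.occupied.update((b, b + 1))
                break
    return state


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Ensemble sampling and map-synthesis settings."""

    n_snapshots: int = 300
    burn_in: int = 800
    stride: int = 40               # steps between sampled snapshots
    transitive_depth: int = 3      # max chain depth k for interaction-zone contacts
    transitive_weight: float = 0.5 # per-depth geometric weight w
    background_exponent: float = 1.0   # background contact prob ~ separation^-alpha
    background_fraction: float = 0.3   # background share of total expected signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transitive_depth < 0:
            raise ValueError("transitive_depth must be >= 0")
        if not (0.0 < self.transitive_weight <= 1.0):
            raise ValueError("transitive_weight must be in (0, 1]")
        if self.background_exponent <= 0:
            raise ValueError("background_exponent must be > 0")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in [0, 1)")


def run_ensemble(params: ExtrusionParams, barriers: BarrierSet,
                 spec: SyntheticMapSpec) -> list[SimState]:
    """Burn in, then sample ``n_snapshots`` states at fixed stride; reproducible from seed."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([spec.seed, 0])))
    state = SimState()
    snapshots: list[SimState] = []
    total = spec.burn_in + spec.n_snapshots * spec.stride
    for t in range(total):
        state = step_state(state, params, barriers, rng)
        if state.n_cohesins > params.max_cohesins:
            raise RuntimeError(
                f"cohesin count {state.n_cohesins} exceeds max_cohesins={params.max_cohesins}; "
                "lower loading_rate or raise unload_prob_ref/max_cohesins")
        if t >= spec.burn_in and (t - spec.burn_in) % spec.stride == 0:
            snapshots.append(state.copy())
    return snapshots[: spec.n_snapshots]


def collision_chains(state: SimState) -> list[list[int]]:
    """Connected components of cohesins whose legs are adjacent (distance <= 1 bin).

    Returned as lists of cohesin indices; within each component the adjacency
    graph is used downstream for chain-depth distances.
    """
    n = state.n_cohesins
    legs = []
    for i in range(n):
        legs.append((state.left[i], i))
        legs.append((state.right[i], i))
    legs.sort()
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for (p1, c1), (p2, c2) in zip(legs, legs[1:]):
        if c1 != c2 and p2 - p1 <= 1:
            adj[c1].add(c2)
            adj[c2].add(c1)
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        comp, stack = [], [i]
        seen.add(i)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _chain_pairs(state: SimState, k: int) -> list[tuple[int, int, int]]:
    """(i, j, depth) for cohesin pairs at adjacency-graph distance 1..k."""
    if k == 0 or state.n_cohesins == 0:
        return []
    n = state.n_cohesins
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    legs = []
    for i in range(n):
        legs.append((state.left[i], i))
        legs.append((state.right[i], i))
    legs.sort()
    for (p1, c1), (p2, c2) in zip(legs, legs[1:]):
        if c1 != c2 and p2 - p1 <= 1:
            adj[c1].add(c2)
            adj[c2].add(c1)
    out = []
    for src in range(n):
        dist = {src: 0}
        frontier = [src]
        d = 0
        while frontier and d < k:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
                        if v > src:   # emit each unordered pair once
                            out.append((src, v, d))
            frontier = nxt
    return out


def snapshots_to_contact_map(snapshots: Iterable[SimState], spec: SyntheticMapSpec,
                             bins: GenomicBins) -> ContactMatrix:
    """Accumulate loop-base, chain-bridged, and background contacts into a matrix.

    Per snapshot: every cohesin contributes one contact at its loop base
    ``(left, right)``; every pair of cohesins within chain depth ``k`` of each
    other contributes a bridged contact between the outermost legs of the
    pair, weighted ``w**depth`` (the interaction zone formed by collided
    rings); background contacts are Poisson-sampled with probability
    proportional to ``separation**-alpha``, scaled so the background carries
    ``background_fraction`` of the total expected signal.
    """
    n = bins.n
    counts: dict[tuple[int, int], float] = {}

    def add(i: int, j: int, wgt: float) -> None:
        if i > j:
            i, j = j, i
        counts[(i, j)] = counts.get((i, j), 0.0) + wgt

    bg_rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([spec.seed, 1])))
    seps = np.arange(1, n)
    # per-PAIR contact probability ~ s^-alpha; the separation of a sampled
    # contact is therefore drawn with weight (number of pairs) x s^-alpha
    bg_p = (n - seps) * seps.astype(float) ** (-spec.background_exponent)
    bg_p /= bg_p.sum()
    bf = spec.background_fraction

    for state in snapshots:
        signal = 0.0
        for i in range(state.n_cohesins):
            add(state.left[i], state.right[i], 1.0)
            signal += 1.0
        for a, b, depth in _chain_pairs(state, spec.transitive_depth):
            wgt = spec.transitive_weight ** depth
            lo = min(state.left[a], state.left[b])
            hi = max(state.right[a], state.right[b])
            if lo != hi:
                add(lo, hi, wgt)
                signal += wgt
        if bf > 0.0 and signal > 0.0:
            n_bg = bg_rng.poisson(signal * bf / (1.0 - bf))
            if n_bg:
                s = bg_rng.choice(seps, size=n_bg, p=bg_p)
                starts = (bg_rng.random(n_bg) * (n - s)).astype(np.int64)
                for i0, sep in zip(starts, s):
                    add(int(i0), int(i0 + sep), 1.0)

    if counts:
        ii, jj = zip(*counts.keys())
        pixels = pd.DataFrame({"bin1_id": ii, "bin2_id": jj, "count": list(counts.values())})
    else:
        pixels = pd.DataFrame({"bin1_id": [], "bin2_id": [], "count": []})
    return ContactMatrix(bins, pixels)


def loop_length_distribution(snapshots: Iterable[SimState], bin_size: int) -> np.ndarray:
    """One loop length (right - left) * bin_size per cohesin per snapshot, in bp."""
    lengths = [
        (r - l) * bin_size
        for state in snapshots
        for l, r in zip(state.left, state.right)
    ]
    if not lengths:
        import warnings

        warnings.warn("no cohesins in any snapshot; empty loop-length distribution", stacklevel=2)
    return np.asarray(lengths, dtype=float)


# ---------------------------------------------------------------------------
# Locus presets
# ---------------------------------------------------------------------------

_IGH_SIZE_BP = 2_800_000   # heavy-chain-like locus
_IGK_SIZE_BP = 3_200_000   # kappa-like locus
_BIN_BP = 2_000


def make_locus_preset(kind: str, scale: str = "desk",
                      capture_prob: float = 0.9, release_rate: Optional[float] = None,
                      ) -> tuple[GenomicBins, BarrierSet, pd.DataFrame]:
    """Barrier layouts emulating the two immunoglobulin locus architectures.

    ``igh_like`` (2.8 Mb): forward barriers distributed across the 5' V-gene
    cluster (125 at full scale, 20 at desk scale) converging on two reverse
    pairs near the 3' end (IGCR1-like and 3'CBE-like).

    ``igk_like`` (3.2 Mb): mixed-orientation barriers in the V cluster with a
    reverse-oriented majority in its central part, a reverse pair (Cer-like)
    and a forward pair (Sis-like) near the 3' end, then a barrier-free
    "regulatory loop" segment to the 3' edge.

    Returns bins, barriers, and a ground-truth table (bin, orientation, name).
    Desk-scale barrier spacing is kept >= 12 bins so that neighbouring
    elements are resolvable by the directional-profile peak caller.

    When ``release_rate`` is None a kind-specific default is used: CTCF
    pausing in the heavy-chain-like V cluster is modelled as transient
    (release 0.02 per step) so that extruding legs percolate through the
    dense all-forward array, while kappa-like elements hold captured legs
    longer (release 0.005), giving the stable internal loops of that locus.
    """
    if scale not in ("full", "desk"):
        raise ValueError("scale must be 'full' or 'desk'")
    if release_rate is None:
        release_rate = {"igh_like": 0.02, "igk_like": 0.005}.get(kind, 0.01)

    if kind == "igh_like":
        mk = lambda p, o, c=capture_prob: Barrier(int(p), o, c, release_rate)
        bins = GenomicBins.from_region("chrSynH", 0, _IGH_SIZE_BP, _BIN_BP)
        n = bins.n                      # 1400
        v_hi = int(n * 2.44 / 2.8)      # V cluster = 5' 2.44 Mb
        n_fwd = 125 if scale == "full" else 20
        fwd_pos = np.unique(np.linspace(30, v_hi - 30, n_fwd).round().astype(int))
        barriers = [mk(p, FORWARD) for p in fwd_pos]
        igcr1 = [v_hi + 40, v_hi + 55]          # IGCR1-like reverse pair
        cbe3 = [n - 30, n - 15]                 # 3'CBE-like reverse pair
        names = [f"V_fwd_{i}" for i in range(len(fwd_pos))] + \
                ["IGCR1_a", "IGCR1_b", "3CBE_a", "3CBE_b"]
        barriers += [mk(p, REVERSE, min(1.0, capture_prob + 0.05)) for p in igcr1 + cbe3]
    elif kind == "igk_like":
        # internal kappa-cluster elements capture more weakly than the
        # regulatory Cer/Sis pairs, letting extruding legs sample the whole
        # cluster while the 3' elements anchor persistently
        cap_internal = capture_prob * 0.6
        mk = lambda p, o, c: Barrier(int(p), o, c, release_rate)
        bins = GenomicBins.from_region("chrSynK", 0, _IGK_SIZE_BP, _BIN_BP)
        n = bins.n                      # 1600
        # 18 internal V-cluster barriers; heavily reverse-oriented with a few
        # interspersed forward elements, as in the kappa V cluster
        v_pos = np.linspace(40, 1330, 18).round().astype(int)
        v_orient = [REVERSE, REVERSE, REVERSE, REVERSE, FORWARD,
                    REVERSE, REVERSE, REVERSE, REVERSE, FORWARD,
                    REVERSE, REVERSE, REVERSE, REVERSE, FORWARD,
                    REVERSE, REVERSE, REVERSE]
        barriers = [mk(p, o, cap_internal) for p, o in zip(v_pos, v_orient)]
        cer = [1420, 1440]       # Cer-like reverse pair
        sis = [1480, 1495]       # Sis-like forward pair; barrier-free to 3' edge
        barriers += [mk(p, REVERSE, min(1.0, capture_prob + 0.05)) for p in cer]
        barriers += [mk(p, FORWARD, min(1.0, capture_prob + 0.05)) for p in sis]
        names = [f"V_{o}_{i}" for i, o in enumerate(v_orient)] + \
                ["Cer_a", "Cer_b", "Sis_a", "Sis_b"]
    else:
        raise ValueError(f"unknown preset kind {kind!r}")

    bset = BarrierSet(barriers)
    truth = pd.DataFrame({
        "bin": [b.position for b in bset],
        "orientation": [b.orientation for b in bset],
        "name": [names[[x.position for x in barriers].index(b.position)] for b in bset],
    })
    return bins, bset, truth
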
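"""Degenerate primer-pair candidate enumeration on a consensus sequence.

Candidates are flanking slice pairs of a (possibly degenerate) consensus:
the forward primer is a consensus slice starting at or before the target
window, the reverse primer is the reverse complement of a slice ending at
or after it, and the amplified interval must contain the whole window and
respect product-size bounds.  Each primer must individually pass the
degeneracy cap, the degenerate-position cap and a melting-temperature
acceptance interval; a pair must additionally have balanced midpoint Tms.

Survivors are ranked by a simple additive penalty

    penalty = |len_f - len_opt| + |len_r - len_opt|
            + |midTm_f - tm_opt| + |midTm_r - tm_opt|

with deterministic tie-breaking by (forward start, reverse binding start,
forward length, reverse length).  The enumeration is lazy: the designer's
inner loop usually needs only the best-ranked pair, while the eager
:func:`enumerate_candidates` materialises the full ranked list.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from . import iupac, thermo

__all__ = [
    "PrimerConstraints",
    "DegeneratePrimer",
    "PrimerPair",
    "enumerate_candidates",
    "iter_candidates",
]


@dataclass(frozen=True)
class PrimerConstraints:
    """Design constraints for a degenerate primer pair.

    Temperatures in deg C, lengths and coordinates in bases.  The target
    window is 0-based half-open on the consensus sequence handed to the
    enumerator; the amplified product must contain it entirely.
    """

    tm_opt: float = 52.0
    tm_min: float = 47.0
    tm_max: float = 57.0
    len_opt: int = 20
    len_min: int = 18
    len_max: int = 27
    max_degenerate_positions: int = 8
    max_degeneracy: int = 256
    target_window: tuple[int, int] = (105, 214)
    product_min: int = 200
    product_max: int = 600
    pair_tm_max_diff: float = 5.0
    na_molar: float = 0.05
    primer_conc: float = 50e-9
    allow_degenerate_3prime: bool = True

    def __post_init__(self) -> None:
        if not (self.len_min <= self.len_opt <= self.len_max):
            raise ValueError("len_min <= len_opt <= len_max violated")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("tm_min <= tm_opt <= tm_max violated")
        ws, we = self.target_window
        if not ws < we:
            raise ValueError("target window start must precede its end")
        if not self.product_min < self.product_max:
            raise ValueError("product_min must be < product_max")
        if self.max_degeneracy < 1 or self.max_degenerate_positions < 0:
            raise ValueError("degeneracy caps must be positive")

    def with_window(self, window: tuple[int, int]) -> "PrimerConstraints":
        return replace(self, target_window=window)


@dataclass(frozen=True)
class DegeneratePrimer:
    """One primer in 5'->3' sense.

    ``start`` is the 0-based binding-slice start on the consensus; for a
    reverse primer ``seq`` is the reverse complement of that slice.
    """

    seq: str
    start: int
    orientation: str  # "forward" | "reverse"
    tm_lo: float
    tm_hi: float
    degeneracy: int
    n_degenerate_positions: int

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mid_tm(self) -> float:
        return 0.5 * (self.tm_lo + self.tm_hi)

    @property
    def end(self) -> int:
        """Binding-slice end (exclusive) on the consensus."""
        return self.start + len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse pair with its consensus product interval."""

    fwd: DegeneratePrimer
    rev: DegeneratePrimer
    product_len: int
    penalty: float
    pair_id: str | None = None

    def with_id(self, pair_id: str) -> "PrimerPair":
        return replace(self, pair_id=pair_id)


@dataclass(frozen=True)
class _Slice:
    start: int
    length: int
    binding_seq: str
    degeneracy: int
    npos: int
    tm_lo: float
    tm_hi: float
    pen: float

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def mid(self) -> float:
        return 0.5 * (self.tm_lo + self.tm_hi)


def _feasible_slices(
    consensus: str,
    sizes: np.ndarray,
    c: PrimerConstraints,
    start_lo: int,
    start_hi: int,
    end_lo: int,
    end_hi: int,
    three_prime_is_end: bool,
) -> list[_Slice]:
    """All slices with start in [start_lo, start_hi] and end in [end_lo, end_hi]
    passing the per-primer constraints, cheap filters first."""
    L = len(consensus)
    log_sizes = np.concatenate(([0.0], np.cumsum(np.log2(sizes))))
    cum_npos = np.concatenate(([0], np.cumsum(sizes > 1)))
    log_cap = math.log2(c.max_degeneracy) + 1e-9

    out: list[_Slice] = []
    for length in range(c.len_min, c.len_max + 1):
        lo = max(start_lo, end_lo - length, 0)
        hi = min(start_hi, end_hi - length, L - length)
        if hi < lo:
            continue
        starts = np.arange(lo, hi + 1)
        npos = cum_npos[starts + length] - cum_npos[starts]
        logd = log_sizes[starts + length] - log_sizes[starts]
        ok = (npos <= c.max_degenerate_positions) & (logd <= log_cap)
        if not c.allow_degenerate_3prime:
            tp = starts + length - 1 if three_prime_is_end else starts
            ok &= sizes[tp] == 1
        for s in starts[ok]:
            s = int(s)
            seq = consensus[s : s + length]
            deg = iupac.degeneracy(seq)
            if deg > c.max_degeneracy:
                continue
            tm_lo, tm_hi = thermo.tm_range(
                seq, c.na_molar, c.primer_conc, max_degeneracy=c.max_degeneracy
            )
            if tm_hi < c.tm_min or tm_lo > c.tm_max:
                continue
            mid = 0.5 * (tm_lo + tm_hi)
            pen = abs(length - c.len_opt) + abs(mid - c.tm_opt)
            out.append(
                _Slice(s, length, seq, deg, int(npos[s - lo]), tm_lo, tm_hi, pen)
            )
    return out


def _make_pair(f: _Slice, r: _Slice) -> PrimerPair:
    fwd = DegeneratePrimer(
        f.binding_seq, f.start, "forward", f.tm_lo, f.tm_hi, f.degeneracy, f.npos
    )
    rev = DegeneratePrimer(
        iupac.reverse_complement(r.binding_seq),
        r.start,
        "reverse",
        r.tm_lo,
        r.tm_hi,
        r.degeneracy,
        r.npos,
    )
    return PrimerPair(
        fwd=fwd,
        rev=rev,
        product_len=r.end - f.start,
        penalty=f.pen + r.pen,
    )


def iter_candidates(consensus: str, c: PrimerConstraints) -> Iterator[PrimerPair]:
    """Yield constraint-passing primer pairs in ranked order (lazy).

    Ordering: ascending penalty, ties by (fwd start, rev binding start,
    fwd length, rev length).  Raises if the target window falls outside
    the consensus; yields nothing when no pair passes.
    """
    consensus = iupac.normalize(consensus)
    L = len(consensus)
    ws, we = c.target_window
    if not (0 <= ws < we <= L):
        raise ValueError(
            f"target window ({ws}, {we}) outside consensus of length {L}"
        )
    sizes = iupac.POPCOUNT[iupac.encode_mask(consensus)]

    # Forward: starts at/before the window start; cannot start so far left
    # that even the shortest product overshoots product_max.
    fwd = _feasible_slices(
        consensus, sizes, c,
        start_lo=max(0, we - c.product_max), start_hi=ws,
        end_lo=0, end_hi=L,
        three_prime_is_end=True,
    )
    # Reverse binding slice: ends at/after the window end, bounded by the
    # longest admissible product.
    rev = _feasible_slices(
        consensus, sizes, c,
        start_lo=0, start_hi=L,
        end_lo=we, end_hi=min(L, ws + c.product_max),
        three_prime_is_end=False,
    )
    if not fwd or not rev:
        return

    fwd.sort(key=lambda s: (s.pen, s.start, s.length))
    rev.sort(key=lambda s: (s.pen, s.start, s.length))

    def feasible(f: _Slice, r: _Slice) -> bool:
        if r.start < f.end:
            return False
        product = r.end - f.start
        if not (c.product_min <= product <= c.product_max):
            return False
        return abs(f.mid - r.mid) <= c.pair_tm_max_diff

    # Best-first frontier over the (fwd-rank, rev-rank) grid.
    heap: list[tuple[float, int, int]] = [(fwd[0].pen + rev[0].pen, 0, 0)]
    seen = {(0, 0)}
    while heap:
        p = heap[0][0]
        bucket: list[tuple[int, int]] = []
        # Drain every grid node tied at penalty p so ties can be ordered
        # by coordinates rather than by heap extraction order.
        while heap and heap[0][0] == p:
            _, i, j = heapq.heappop(heap)
            bucket.append((i, j))
            for ni, nj in ((i + 1, j), (i, j + 1)):
                if ni < len(fwd) and nj < len(rev) and (ni, nj) not in seen:
                    seen.add((ni, nj))
                    heapq.heappush(heap, (fwd[ni].pen + rev[nj].pen, ni, nj))
        pairs = [(fwd[i], rev[j]) for i, j in bucket]
        pairs.sort(key=lambda fr: (fr[0].start, fr[1].start, fr[0].length, fr[1].length))
        for f, r in pairs:
            if feasible(f, r):
                yield _make_pair(f, r)


def enumerate_candidates(consensus: str, c: PrimerConstraints) -> list[PrimerPair]:
    """Full ranked list of constraint-passing primer pairs (eager)."""
    return list(iter_candidates(consensus, c))
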
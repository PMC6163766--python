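"""In silico PCR: degenerate primer site finding and virtual amplification.

Primer binding is ungapped: a primer of length n binds a template window
iff the number of positions whose IUPAC code sets do not intersect is at
most floor(mismatch_fraction * n).  Fraction 0 therefore means exact
degenerate matching (the removal criterion inside the panel designer) and
0.10 reproduces a relaxed 10%-mismatch screen.  No indels are modelled.

Matching is vectorised over template positions with a 4-bit base-mask
encoding, so scanning whole collections stays fast in pure numpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import iupac
from .primers import PrimerPair

__all__ = ["AmpliconHit", "CoverageMap", "find_sites", "amplify", "panel_coverage"]


@dataclass(frozen=True)
class AmpliconHit:
    """One virtual amplification event on one template.

    ``fwd_pos``/``rev_pos`` are 0-based template coordinates of each
    primer's 5' end (so on the '+' strand fwd_pos < rev_pos, and the
    product spans [fwd_pos, rev_pos] inclusive).
    """

    template_id: str
    pair_id: str | None
    strand: str  # "+" | "-"
    fwd_pos: int
    rev_pos: int
    product_len: int
    fwd_mismatches: int
    rev_mismatches: int
    product_seq: str


def _as_mask(template) -> np.ndarray:
    if isinstance(template, np.ndarray):
        return template
    return iupac.encode_mask(iupac.normalize(template))


def _scan(pmask: np.ndarray, tmask: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """(window start, mismatches) for every window within the tolerance."""
    n = len(pmask)
    if len(tmask) < n:
        return []
    win = sliding_window_view(tmask, n)
    mm = ((win & pmask) == 0).sum(axis=1)
    pos = np.nonzero(mm <= max_mm)[0]
    return [(int(p), int(mm[p])) for p in pos]


def find_sites(
    primer: str, template, max_mismatch_fraction: float = 0.0
) -> list[tuple[int, str, int]]:
    """All ungapped binding sites of a degenerate primer on both strands.

    Returns ``(position, strand, mismatches)`` triples where ``position``
    is the 0-based start of the matched window in forward template
    coordinates; strand '-' means the primer binds the reverse strand
    (its reverse complement matches the forward template there).  A
    palindromic primer reports each duplex site once, on '+'.
    """
    if not 0.0 <= max_mismatch_fraction <= 1.0:
        raise ValueError("mismatch fraction must be in [0, 1]")
    pseq = iupac.normalize(primer)
    pmask = iupac.encode_mask(pseq)
    tmask = _as_mask(template)
    if len(pmask) > len(tmask):
        return []
    max_mm = math.floor(max_mismatch_fraction * len(pmask))
    hits = [(p, "+", m) for p, m in _scan(pmask, tmask, max_mm)]
    rc = iupac.revcomp_mask(pmask)
    if not np.array_equal(rc, pmask):  # skip '-' for palindromes
        hits += [(p, "-", m) for p, m in _scan(rc, tmask, max_mm)]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _amplify_one_strand(
    fwd_mask: np.ndarray,
    rev_rc_mask: np.ndarray,
    tmask: np.ndarray,
    max_mm_f: int,
    max_mm_r: int,
    product_min: int,
    product_max: int,
) -> list[tuple[int, int, int, int]]:
    """(fwd_start, rev_site_start, fwd_mm, rev_mm) on one template strand."""
    lf, lr = len(fwd_mask), len(rev_rc_mask)
    fsites = _scan(fwd_mask, tmask, max_mm_f)
    if not fsites:
        return []
    rsites = _scan(rev_rc_mask, tmask, max_mm_r)
    if not rsites:
        return []
    rpos = np.array([p for p, _ in rsites])
    out = []
    for i, mmf in fsites:
        jlo = max(i + lf, i + product_min - lr)
        jhi = i + product_max - lr
        a = int(np.searchsorted(rpos, jlo, side="left"))
        b = int(np.searchsorted(rpos, jhi, side="right"))
        for j, mmr in rsites[a:b]:
            out.append((i, j, mmf, mmr))
    return out


def amplify(
    pair: PrimerPair,
    template: str,
    max_mismatch_fraction: float = 0.0,
    product_min: int = 1,
    product_max: int = 10**9,
    template_id: str = "",
) -> list[AmpliconHit]:
    """Virtual PCR of one primer pair on one template, both strands.

    Every combination of a forward site and a compatible downstream
    reverse site (the reverse primer's reverse complement matching the
    template) within the product-size bounds yields a hit.  Overlapping
    primer footprints never amplify.
    """
    if not 0.0 <= max_mismatch_fraction <= 1.0:
        raise ValueError("mismatch fraction must be in [0, 1]")
    tseq = iupac.normalize(template)
    tmask = _as_mask(tseq)
    L = len(tmask)
    fwd_mask = iupac.encode_mask(pair.fwd.seq)
    rev_rc_mask = iupac.revcomp_mask(iupac.encode_mask(pair.rev.seq))
    lf, lr = len(fwd_mask), len(rev_rc_mask)
    max_mm_f = math.floor(max_mismatch_fraction * lf)
    max_mm_r = math.floor(max_mismatch_fraction * lr)

    hits: list[AmpliconHit] = []
    for i, j, mmf, mmr in _amplify_one_strand(
        fwd_mask, rev_rc_mask, tmask, max_mm_f, max_mm_r, product_min, product_max
    ):
        hits.append(
            AmpliconHit(
                template_id=template_id,
                pair_id=pair.pair_id,
                strand="+",
                fwd_pos=i,
                rev_pos=j + lr - 1,
                product_len=j + lr - i,
                fwd_mismatches=mmf,
                rev_mismatches=mmr,
                product_seq=tseq[i : j + lr],
            )
        )
    rc_seq = iupac.reverse_complement(tseq)
    rc_mask = iupac.revcomp_mask(tmask)
    for i, j, mmf, mmr in _amplify_one_strand(
        fwd_mask, rev_rc_mask, rc_mask, max_mm_f, max_mm_r, product_min, product_max
    ):
        hits.append(
            AmpliconHit(
                template_id=template_id,
                pair_id=pair.pair_id,
                strand="-",
                fwd_pos=L - 1 - i,
                rev_pos=L - j - lr,
                product_len=j + lr - i,
                fwd_mismatches=mmf,
                rev_mismatches=mmr,
                product_seq=rc_seq[i : j + lr],
            )
        )
    hits.sort(key=lambda h: (min(h.fwd_pos, h.rev_pos), h.strand, h.product_len))
    return hits


@dataclass
class CoverageMap:
    """Pair -> amplified target ids and target -> amplifying pairs."""

    by_pair: dict[str, set[str]] = field(default_factory=dict)
    by_target: dict[str, set[str]] = field(default_factory=dict)

    @property
    def covered(self) -> set[str]:
        return {t for t, ps in self.by_target.items() if ps}

    def issubset_of(self, other: "CoverageMap") -> bool:
        return all(
            ids <= other.by_pair.get(pid, set()) for pid, ids in self.by_pair.items()
        )


def _id_seq(item) -> tuple[str, str]:
    if hasattr(item, "id") and hasattr(item, "cds"):
        return item.id, item.cds
    sid, seq = item
    return sid, seq


def panel_coverage(
    pairs: Sequence[PrimerPair],
    collection: Iterable,
    max_mismatch_fraction: float = 0.0,
    product_min: int = 1,
    product_max: int = 10**9,
) -> CoverageMap:
    """Which collection members does each pair amplify?

    ``collection`` items are ``(id, sequence)`` tuples or objects with
    ``id``/``cds`` attributes.  A target counts as covered when at least
    one pair amplifies it (each template counted once per pair).
    """
    cov = CoverageMap()
    items = [_id_seq(x) for x in collection]
    cov.by_target = {sid: set() for sid, _ in items}
    for pair in pairs:
        pid = pair.pair_id or f"pair@{pair.fwd.start}"
        cov.by_pair[pid] = set()
        for sid, seq in items:
            if amplify(
                pair, seq, max_mismatch_fraction, product_min, product_max, sid
            ):
                cov.by_pair[pid].add(sid)
                cov.by_target[sid].add(pid)
    return cov
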
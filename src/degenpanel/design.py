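"""Greedy, abundance-seeded, similarity-guided primer panel design.

The designer converts a collection of homologous protein-coding genes into
an ordered set of degenerate primer pairs that, by construction, amplify
every designable member of the collection in silico with zero mismatches:

1. Seed a cluster with the most abundant remaining sequence.
2. Grow the cluster by testing every other remaining sequence once, in
   order of increasing protein p-distance to the seed: a candidate joins
   if the cluster's degenerate consensus still yields a primer pair that
   passes all constraints and amplifies every cluster member exactly;
   otherwise it is rejected (and stays available for later clusters).
3. Store the best pair of the final cluster, then remove the cluster
   members and every other remaining sequence the pair amplifies exactly
   (the greedy set-cover sweep).
4. Repeat with the next most abundant seed until the collection is empty.
   A seed on which not even a single-sequence design succeeds is recorded
   as undesignable, never silently dropped.

Alignment handling deviates from per-iteration realignment: a single
master nucleotide alignment, obtained by threading the input protein
alignment, is subset per cluster.  This keeps the whole procedure
deterministic and aligner-free; the target window is expressed in master
alignment nucleotide columns and mapped into each cluster consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import codon, iupac
from .pcr import CoverageMap, amplify, panel_coverage
from .primers import PrimerConstraints, PrimerPair, iter_candidates

__all__ = [
    "TargetSeq",
    "GuideOrder",
    "Panel",
    "IterationLog",
    "DesignError",
    "build_guide_distances",
    "select_seed",
    "grow_cluster",
    "design_panel",
    "prune_outgroup_only_pairs",
    "abundance_weighted_coverage",
]


class DesignError(ValueError):
    """Inconsistent designer inputs or a broken construction invariant."""


@dataclass(frozen=True)
class TargetSeq:
    """One collection member.

    ``abundance`` follows read-mapping semantics (mapped reads divided by
    gene length) but any non-negative weight works; it drives seed choice
    and abundance-weighted coverage.  ``outgroup`` marks sequences used
    only to root/contextualise the collection, enabling outgroup-only
    pair pruning.
    """

    id: str
    cds: str
    abundance: float = 1.0
    outgroup: bool = False

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"negative abundance for {self.id!r}")
        object.__setattr__(self, "cds", iupac.normalize(self.cds))


@dataclass
class GuideOrder:
    """Pairwise protein p-distances and per-seed similarity orderings."""

    ids: tuple[str, ...]
    dist: np.ndarray  # symmetric, zero diagonal

    def distance(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.dist[ia, ib])

    def ordering(
        self,
        seed_id: str,
        candidate_ids: Iterable[str],
        abundances: Mapping[str, float],
    ) -> list[str]:
        """Candidates by ascending distance to the seed; ties broken by
        descending abundance, then lexicographic id."""
        i = self.ids.index(seed_id)
        idx = {sid: j for j, sid in enumerate(self.ids)}
        return sorted(
            candidate_ids,
            key=lambda c: (self.dist[i, idx[c]], -abundances.get(c, 0.0), c),
        )


def build_guide_distances(pal: codon.ProteinAlignment) -> GuideOrder:
    """p-distance (mismatch fraction over mutually non-gap columns) for
    every row pair; pairs sharing no column get distance 1."""
    if len(pal) < 2:
        raise DesignError("guide distances need at least two aligned rows")
    mat = np.array([list(r) for r in pal.rows], dtype="U1")
    nongap = mat != "-"
    n = len(pal)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                d = 1.0
            else:
                d = float((mat[i, both] != mat[j, both]).mean())
            dist[i, j] = dist[j, i] = d
    return GuideOrder(ids=pal.ids, dist=dist)


def select_seed(remaining: Iterable[TargetSeq]) -> TargetSeq:
    """Most abundant member; ties broken by lexicographically smallest id."""
    pool = list(remaining)
    if not pool:
        raise DesignError("cannot select a seed from an empty collection")
    return min(pool, key=lambda t: (-t.abundance, t.id))


@dataclass(frozen=True)
class IterationLog:
    """Audit record of one cluster-growth iteration."""

    seed_id: str
    members: tuple[str, ...]  # in join order, seed first
    rejected: tuple[str, ...]
    pair_id: str | None
    swept: tuple[str, ...]  # non-members removed by the exact-match sweep


@dataclass
class Panel:
    """Ordered primer pairs with their strict coverage bookkeeping."""

    pairs: list[PrimerPair]
    coverage: CoverageMap
    undesignable: set[str]
    log: list[IterationLog] = field(default_factory=list)
    outgroup_only: tuple[str, ...] = ()
    constraints: PrimerConstraints | None = None


class _DesignContext:
    """Master alignment as a bitmask matrix plus per-member CDS strings."""

    def __init__(
        self,
        collection: Sequence[TargetSeq],
        pal: codon.ProteinAlignment,
        constraints: PrimerConstraints,
        max_pair_checks: int,
    ):
        self.constraints = constraints
        self.max_pair_checks = max_pair_checks
        self.targets = {t.id: t for t in collection}
        rows = [(t.id, pal.row(t.id)) for t in collection]
        sub_pal = codon.ProteinAlignment(rows)
        self.master = codon.thread_codons(sub_pal, {t.id: t.cds for t in collection})
        self.row_index = {rid: k for k, rid in enumerate(self.master.ids)}
        self.masks = np.stack(
            [iupac.encode_mask(r, allow_gaps=True) for r in self.master.rows]
        )
        ws, we = constraints.target_window
        if not (0 <= ws < we <= self.master.width):
            raise DesignError(
                f"target window ({ws}, {we}) outside the {self.master.width}-column "
                "master nucleotide alignment"
            )

    def mask_of(self, rid: str) -> np.ndarray:
        return self.masks[self.row_index[rid]]

    def try_design(
        self, or_mask: np.ndarray, member_ids: Sequence[str]
    ) -> PrimerPair | None:
        """Best-ranked pair on the cluster consensus that amplifies every
        member exactly, or None when the cluster is undesignable."""
        c = self.constraints
        kept = np.nonzero(or_mask)[0]
        if kept.size == 0:
            return None
        consensus = iupac.decode_mask(or_mask[kept])
        ws, we = c.target_window
        wlo = int(np.searchsorted(kept, ws, side="left"))
        whi = int(np.searchsorted(kept, we - 1, side="right"))
        if whi <= wlo:
            return None  # window columns all gapped out of this cluster
        local = c.with_window((wlo, whi))
        cds_list = [self.targets[m].cds for m in member_ids]
        for k, pair in enumerate(iter_candidates(consensus, local)):
            if k >= self.max_pair_checks:
                break
            if all(
                amplify(pair, cds, 0.0, c.product_min, c.product_max)
                for cds in cds_list
            ):
                return pair
        return None


def grow_cluster(
    seed: TargetSeq,
    remaining: Mapping[str, TargetSeq],
    guide: GuideOrder,
    constraints: PrimerConstraints,
    ctx: _DesignContext | None = None,
) -> tuple[list[str], PrimerPair | None, list[str]]:
    """Grow one cluster around ``seed`` in guide order.

    Returns (members in join order, best pair or None, rejected ids).
    Every member of ``remaining`` is tested exactly once; a rejected
    candidate stays available for later clusters.
    """
    if seed.id not in remaining:
        raise DesignError(f"seed {seed.id!r} is not in the remaining set")
    if ctx is None:
        pool = sorted(remaining.values(), key=lambda t: t.id)
        pal = codon.ProteinAlignment(
            [(t.id, codon.translate(t.cds).rstrip("*")) for t in pool]
        )
        ctx = _DesignContext(pool, pal, constraints, max_pair_checks=25)

    members = [seed.id]
    or_mask = ctx.mask_of(seed.id).copy()
    best = ctx.try_design(or_mask, members)
    rejected: list[str] = []
    if best is None:
        return members, None, rejected

    abundances = {t.id: t.abundance for t in remaining.values()}
    order = guide.ordering(
        seed.id, (rid for rid in remaining if rid != seed.id), abundances
    )
    for cand in order:
        trial = or_mask | ctx.mask_of(cand)
        d = ctx.try_design(trial, members + [cand])
        if d is not None:
            or_mask = trial
            members.append(cand)
            best = d
        else:
            rejected.append(cand)
    return members, best, rejected


def design_panel(
    collection: Sequence[TargetSeq],
    pal: codon.ProteinAlignment,
    constraints: PrimerConstraints | None = None,
    *,
    removal_requires_product: bool = True,
    max_pair_checks: int = 25,
) -> Panel:
    """Run the full agglomerative design loop until the collection is empty.

    The returned panel satisfies, by construction: strict (0-mismatch)
    coverage of every target outside ``undesignable``; disjoint cluster
    member sets; dense pair ids PP1, PP2, ... in emission order; and
    byte-identical output for identical inputs regardless of the order in
    which the collection is supplied.
    """
    constraints = constraints or PrimerConstraints()
    if not collection:
        raise DesignError("empty target collection")
    ids = [t.id for t in collection]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate target ids in collection")
    missing = set(ids) - set(pal.ids)
    if missing:
        raise DesignError(f"alignment lacks rows for target(s): {sorted(missing)}")

    order = sorted(collection, key=lambda t: t.id)  # input order must not matter
    ctx = _DesignContext(order, pal, constraints, max_pair_checks)
    guide = build_guide_distances(
        codon.ProteinAlignment([(t.id, pal.row(t.id)) for t in order])
    ) if len(order) > 1 else None

    remaining: dict[str, TargetSeq] = {t.id: t for t in order}
    pairs: list[PrimerPair] = []
    undesignable: set[str] = set()
    log: list[IterationLog] = []
    n_emitted = 0
    sweep_min = constraints.product_min if removal_requires_product else 1
    sweep_max = constraints.product_max if removal_requires_product else 10**9

    while remaining:
        seed = select_seed(remaining.values())
        if guide is None or len(remaining) == 1:
            members = [seed.id]
            best = ctx.try_design(ctx.mask_of(seed.id), members)
            rejected: list[str] = []
        else:
            members, best, rejected = grow_cluster(
                seed, remaining, guide, constraints, ctx
            )
        if best is None:
            undesignable.add(seed.id)
            remaining.pop(seed.id)
            log.append(IterationLog(seed.id, tuple(members), tuple(rejected), None, ()))
            continue
        n_emitted += 1
        pair = best.with_id(f"PP{n_emitted}")
        pairs.append(pair)
        member_set = set(members)
        swept = tuple(
            rid
            for rid in sorted(remaining)
            if rid not in member_set
            and amplify(pair, remaining[rid].cds, 0.0, sweep_min, sweep_max)
        )
        for rid in list(member_set) + list(swept):
            remaining.pop(rid)
        log.append(
            IterationLog(seed.id, tuple(members), tuple(rejected), pair.pair_id, swept)
        )

    coverage = panel_coverage(
        pairs, order, 0.0, constraints.product_min, constraints.product_max
    )
    # A sequence that could not seed a design may still be amplified by a
    # pair emitted later; it is then covered, not undesignable.
    undesignable -= coverage.covered
    uncovered = set(ids) - coverage.covered - undesignable
    if uncovered:
        raise DesignError(
            "construction invariant broken: designed pairs fail to amplify "
            f"{sorted(uncovered)}"
        )
    return Panel(
        pairs=pairs,
        coverage=coverage,
        undesignable=undesignable,
        log=log,
        constraints=constraints,
    )


def prune_outgroup_only_pairs(panel: Panel, collection: Sequence[TargetSeq]) -> Panel:
    """Drop pairs whose strict amplification set is non-empty and purely
    outgroup; pair ids are not renumbered.  Targets left uncovered by the
    pruning are reported on ``panel.outgroup_only``."""
    outgroup_ids = {t.id for t in collection if t.outgroup}
    dropped_targets: set[str] = set()
    kept: list[PrimerPair] = []
    for pair in panel.pairs:
        cov = panel.coverage.by_pair.get(pair.pair_id or "", set())
        if cov and cov <= outgroup_ids:
            dropped_targets |= cov
        else:
            kept.append(pair)
    kept_ids = {p.pair_id for p in kept}
    by_pair = {pid: s for pid, s in panel.coverage.by_pair.items() if pid in kept_ids}
    by_target = {
        t: {pid for pid in ps if pid in kept_ids}
        for t, ps in panel.coverage.by_target.items()
    }
    new_cov = CoverageMap(by_pair=by_pair, by_target=by_target)
    outgroup_only = tuple(sorted(dropped_targets - new_cov.covered))
    return Panel(
        pairs=kept,
        coverage=new_cov,
        undesignable=set(panel.undesignable),
        log=list(panel.log),
        outgroup_only=outgroup_only,
        constraints=panel.constraints,
    )


def abundance_weighted_coverage(panel: Panel, collection: Sequence[TargetSeq]) -> float:
    """Sum of abundances of covered targets over the total abundance."""
    total = sum(t.abundance for t in collection)
    if total == 0:
        return 0.0
    covered = panel.coverage.covered
    return sum(t.abundance for t in collection if t.id in covered) / total
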
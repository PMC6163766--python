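"""Codon-aware synthetic gene-family generation.

Stands in for an empirical collection of homologous marker genes mined
from metagenomes: a single ancestral CDS radiates into clades (clade
consensus sequences), whose members are drawn by further per-site
substitution.  Designated "conserved window" codon intervals mutate at a
low rate everywhere, emulating the conserved core of a protein domain;
the rest of the gene mutates fast between clades and slowly within them.
Substitutions are codon-aware: a proposal that would create an in-frame
stop codon is redrawn among the remaining alternative bases (and the site
left untouched if every alternative creates a stop), so every generated
CDS translates cleanly and can be threaded through the trivial
column-wise protein alignment, which is exact because no indels are
simulated.

Abundance weights are drawn log-normally per member, mimicking the highly
skewed read-recruitment profiles of environmental gene collections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import codon, iupac
from .design import Panel, TargetSeq
from .pcr import amplify

__all__ = [
    "FamilySpec",
    "simulate_family",
    "simulate_decoys",
    "simulate_incompatible_clades",
    "split_members",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic gene family.

    ``conserved_windows`` are half-open codon intervals mutating at
    ``p_cons`` per site both between and within clades.  Outside the
    windows, sites mutate at ``p_var_between`` on the ancestor-to-clade
    branches and ``p_var_within`` on the clade-to-member branches.
    ``members_per_clade`` may be a single int or one count per clade.
    """

    n_clades: int = 12
    members_per_clade: int | tuple[int, ...] = 17
    gene_len: int = 400  # codons
    conserved_windows: tuple[tuple[int, int], ...] = ((35, 75),)
    p_cons: float = 0.01
    p_var_between: float = 0.15
    p_var_within: float = 0.02
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    n_outgroup: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clades < 1 or self.gene_len < 1:
            raise ValueError("need at least one clade and a positive gene length")
        counts = self.clade_sizes()
        if any(c < 1 for c in counts):
            raise ValueError("every clade needs at least one member")
        for lo, hi in self.conserved_windows:
            if not (0 <= lo < hi <= self.gene_len):
                raise ValueError(f"conserved window ({lo}, {hi}) outside the gene")
        for p in (self.p_cons, self.p_var_between, self.p_var_within):
            if not 0.0 <= p <= 1.0:
                raise ValueError("substitution probabilities must be in [0, 1]")
        if self.n_outgroup < 0:
            raise ValueError("n_outgroup must be non-negative")

    def clade_sizes(self) -> tuple[int, ...]:
        if isinstance(self.members_per_clade, int):
            return (self.members_per_clade,) * self.n_clades
        if len(self.members_per_clade) != self.n_clades:
            raise ValueError("members_per_clade length must equal n_clades")
        return tuple(self.members_per_clade)


def split_members(total: int, n_clades: int) -> tuple[int, ...]:
    """Split a total member count into near-equal per-clade counts."""
    base, extra = divmod(total, n_clades)
    return tuple(base + (1 if i < extra else 0) for i in range(n_clades))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _site_rates(spec: FamilySpec, between: bool) -> np.ndarray:
    """Per-nucleotide substitution probability along the gene."""
    rates = np.full(
        3 * spec.gene_len, spec.p_var_between if between else spec.p_var_within
    )
    for lo, hi in spec.conserved_windows:
        rates[3 * lo : 3 * hi] = spec.p_cons
    return rates


def _mutate(seq: str, rates: np.ndarray, rng: np.random.Generator) -> str:
    """Per-site substitution with in-frame stop avoidance."""
    out = list(seq)
    hit = np.nonzero(rng.random(len(seq)) < rates)[0]
    for pos in hit:
        current = out[pos]
        alts = [b for b in _BASES if b != current]
        # deterministic draw order: permute then take the first non-stop
        for k in rng.permutation(3):
            b = alts[int(k)]
            cstart = 3 * (pos // 3)
            trial = out[cstart:pos] + [b] + out[pos + 1 : cstart + 3]
            if "".join(trial) not in _STOPS:
                out[pos] = b
                break
        # all three alternatives create a stop: leave the site untouched
    return "".join(out)


def simulate_family(
    spec: FamilySpec,
) -> tuple[list[TargetSeq], codon.ProteinAlignment, dict[str, int]]:
    """Generate a family: (collection, protein alignment, clade truth).

    Outgroup members (clade label -1) descend from an independent random
    ancestor and are flagged ``outgroup=True``.  All randomness flows from
    ``spec.rng_seed``; identical specs give byte-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ancestor = _random_cds(rng, spec.gene_len)
    between = _site_rates(spec, between=True)
    within = _site_rates(spec, between=False)

    collection: list[TargetSeq] = []
    truth: dict[str, int] = {}
    counter = 0
    for clade, size in enumerate(spec.clade_sizes()):
        clade_consensus = _mutate(ancestor, between, rng)
        for _ in range(size):
            cds = _mutate(clade_consensus, within, rng)
            abundance = float(
                rng.lognormal(spec.abundance_mu, spec.abundance_sigma)
            )
            sid = f"g{counter:04d}"
            counter += 1
            collection.append(TargetSeq(id=sid, cds=cds, abundance=abundance))
            truth[sid] = clade
    for _ in range(spec.n_outgroup):
        og_ancestor = _random_cds(rng, spec.gene_len)
        cds = _mutate(og_ancestor, within, rng)
        abundance = float(rng.lognormal(spec.abundance_mu, spec.abundance_sigma))
        sid = f"g{counter:04d}"
        counter += 1
        collection.append(
            TargetSeq(id=sid, cds=cds, abundance=abundance, outgroup=True)
        )
        truth[sid] = -1

    pal = codon.ProteinAlignment(
        [(t.id, codon.translate(t.cds)) for t in collection]
    )
    return collection, pal, truth


def simulate_incompatible_clades(
    k: int,
    members_per_clade: int,
    gene_len: int = 400,
    rng_seed: int = 0,
    min_window_mismatches: int = 9,
    window_len: int = 18,
) -> tuple[list[TargetSeq], codon.ProteinAlignment, dict[str, int]]:
    """k internally-identical clades guaranteed mutually primer-incompatible.

    Each clade is an independent random CDS, rejection-sampled so that
    every ``window_len``-mer of any merged pair of clades contains at
    least ``min_window_mismatches`` differing sites — one more than the
    default degenerate-position cap, so no cross-clade consensus window
    can ever yield a primer.  Members within a clade are identical, hence
    each clade designs on a degeneracy-1 consensus.
    """
    if k < 1 or members_per_clade < 1:
        raise ValueError("need at least one clade and one member per clade")
    rng = np.random.default_rng(rng_seed)
    L = 3 * gene_len
    clade_seqs: list[str] = []
    clade_masks: list[np.ndarray] = []
    while len(clade_seqs) < k:
        cds = _random_cds(rng, gene_len)
        arr = np.frombuffer(cds.encode(), dtype=np.uint8)
        ok = True
        for other in clade_masks:
            diff = (arr != other).astype(np.int64)
            window_sums = np.convolve(diff, np.ones(window_len, dtype=np.int64), "valid")
            if window_sums.min() < min_window_mismatches:
                ok = False
                break
        if ok:
            clade_seqs.append(cds)
            clade_masks.append(arr)

    collection: list[TargetSeq] = []
    truth: dict[str, int] = {}
    counter = 0
    for clade, cds in enumerate(clade_seqs):
        for _ in range(members_per_clade):
            sid = f"g{counter:04d}"
            counter += 1
            collection.append(TargetSeq(id=sid, cds=cds, abundance=1.0))
            truth[sid] = clade
    pal = codon.ProteinAlignment(
        [(t.id, codon.translate(t.cds)) for t in collection]
    )
    return collection, pal, truth


def simulate_decoys(
    n: int,
    length: int,
    rng_seed: int,
    forbidden: Panel | None = None,
    max_tries: int = 200,
) -> list[tuple[str, str]]:
    """Uniform-random decoy sequences no panel pair amplifies exactly.

    Candidates amplified by any pair of ``forbidden`` at mismatch
    fraction 0 are rejection-sampled away.
    """
    if n < 0 or length < 1:
        raise ValueError("need n >= 0 and a positive length")
    rng = np.random.default_rng(rng_seed)
    pairs = forbidden.pairs if forbidden is not None else []
    if forbidden is not None and forbidden.constraints is not None:
        pmin = forbidden.constraints.product_min
        pmax = forbidden.constraints.product_max
    else:
        pmin, pmax = 1, 10**9
    out: list[tuple[str, str]] = []
    for i in range(n):
        for _ in range(max_tries):
            seq = "".join(_BASES[j] for j in rng.integers(0, 4, size=length))
            if not any(amplify(p, seq, 0.0, pmin, pmax) for p in pairs):
                out.append((f"decoy{i:04d}", seq))
                break
        else:
            raise RuntimeError(
                f"could not sample a panel-free decoy in {max_tries} tries"
            )
    return out
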
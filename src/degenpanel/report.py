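"""Specificity screening and genotype census reporting.

Two read-only views over the in silico PCR engine:

* :func:`screen_specificity` runs every panel pair against a decoy
  collection at a strict mismatch fraction and lists every virtual
  amplicon — useful to check a panel does not amplify off-target
  sequence collections.
* :func:`genotype_census` counts, per assembly set, the distinct amplicon
  product sequences (deduplicated at 100% identity) any pair recovers —
  the number of genotypes a shotgun assembly would reveal for the locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .design import Panel
from .iupac import reverse_complement
from .pcr import AmpliconHit, amplify

__all__ = ["SpecificityReport", "screen_specificity", "genotype_census"]


@dataclass
class SpecificityReport:
    """Full hit listing plus the number of decoy templates amplified."""

    hits: list[AmpliconHit] = field(default_factory=list)
    n_templates_amplified: int = 0
    n_templates_screened: int = 0

    @property
    def clean(self) -> bool:
        return self.n_templates_amplified == 0


def _bounds(panel: Panel) -> tuple[int, int]:
    if panel.constraints is not None:
        return panel.constraints.product_min, panel.constraints.product_max
    return 1, 10**9


def screen_specificity(
    panel: Panel,
    decoys: Iterable[tuple[str, str]],
    max_mismatch_fraction: float = 0.0,
) -> SpecificityReport:
    """Amplify every decoy with every panel pair at the given fraction."""
    if not panel.pairs:
        raise ValueError("cannot screen an empty panel")
    pmin, pmax = _bounds(panel)
    report = SpecificityReport()
    amplified: set[str] = set()
    for did, seq in decoys:
        report.n_templates_screened += 1
        for pair in panel.pairs:
            hits = amplify(pair, seq, max_mismatch_fraction, pmin, pmax, did)
            if hits:
                amplified.add(did)
                report.hits.extend(hits)
    report.n_templates_amplified = len(amplified)
    return report


def genotype_census(
    panel: Panel,
    assemblies: Sequence[Iterable[tuple[str, str]]],
    max_mismatch_fraction: float = 0.0,
) -> dict:
    """Distinct amplifiable genotypes per assembly set.

    A genotype is a unique amplicon product sequence (100% identity);
    duplicated records or multiple hits yielding the same product count
    once.  Returns per-sample counts and a mean/min/max summary.
    """
    if not assemblies:
        raise ValueError("need at least one assembly set")
    pmin, pmax = _bounds(panel)
    counts: list[int] = []
    for assembly in assemblies:
        products: set[str] = set()
        for sid, seq in assembly:
            for pair in panel.pairs:
                for hit in amplify(pair, seq, max_mismatch_fraction, pmin, pmax, sid):
                    # strand-canonical so the same locus amplified in either
                    # orientation is one genotype
                    p = hit.product_seq
                    products.add(min(p, reverse_complement(p)))
        counts.append(len(products))
    return {
        "per_sample": counts,
        "mean": sum(counts) / len(counts),
        "min": min(counts),
        "max": max(counts),
    }
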
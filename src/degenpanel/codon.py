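"""Codon-aware alignment threading and IUPAC consensus construction.

A protein multiple alignment of homologous coding genes, together with
their CDS sequences, determines a codon-level nucleotide alignment: each
aligned residue is replaced by its source codon and each gap by three gap
characters (back-translation threading).  A nucleotide alignment is then
reduced to a single degenerate consensus: per column, the minimal IUPAC
code covering the union of plain bases observed among non-gap entries.
By construction every member of the alignment matches the consensus with
zero mismatches over its non-gap span — the property the downstream primer
designer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from . import iupac

__all__ = [
    "ProteinAlignment",
    "NucleotideAlignment",
    "ThreadingError",
    "translate",
    "thread_codons",
    "column_consensus",
    "alignment_consensus",
    "subset_alignment",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X-")


class ThreadingError(ValueError):
    """CDS and aligned protein row disagree."""


def _check_rows(ids: Sequence[str], rows: Sequence[str], kind: str) -> None:
    if len(ids) != len(rows):
        raise ValueError("ids and rows differ in length")
    if not ids:
        raise ValueError(f"empty {kind} alignment")
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ids in {kind} alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{kind} alignment rows have unequal lengths: {sorted(lengths)}")


@dataclass(frozen=True)
class ProteinAlignment:
    """Aligned amino-acid rows ('-' for gaps, 'X' tolerated)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __init__(self, entries: Iterable[tuple[str, str]]):
        entries = list(entries)
        ids = tuple(e[0] for e in entries)
        rows = tuple(e[1].upper() for e in entries)
        _check_rows(ids, rows, "protein")
        for rid, row in zip(ids, rows):
            bad = set(row) - _AA_ALPHABET
            if bad:
                raise ValueError(f"row {rid!r}: unexpected residue(s) {sorted(bad)}")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(rid) from None


@dataclass(frozen=True)
class NucleotideAlignment:
    """Aligned IUPAC nucleotide rows ('-' for gaps)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __init__(self, entries: Iterable[tuple[str, str]]):
        entries = list(entries)
        ids = tuple(e[0] for e in entries)
        rows = tuple(iupac.normalize(e[1], allow_gaps=True) for e in entries)
        _check_rows(ids, rows, "nucleotide")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(rid) from None


def translate(cds: str, frame: int = 0) -> str:
    """Standard-genetic-code translation; a trailing partial codon is ignored.

    Codons containing ambiguity codes translate to the unique residue all
    their expansions agree on, else to 'X'.  Stop codons give '*'.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    cds = iupac.normalize(cds)
    if not cds:
        raise ValueError("empty CDS")
    out = []
    for i in range(frame, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        aa = _CODON_TO_AA.get(codon)
        if aa is None:
            residues = {_CODON_TO_AA[v] for v in iupac.expand(codon, limit=64)}
            aa = residues.pop() if len(residues) == 1 else "X"
        out.append(aa)
    return "".join(out)


def thread_codons(
    pal: ProteinAlignment, cds_by_id: Mapping[str, str]
) -> NucleotideAlignment:
    """Back-translate a protein alignment using each row's source CDS.

    Precondition: translating each CDS in frame 0 (after dropping one
    optional terminal stop codon) reproduces the row's ungapped protein.
    A residue 'X' in the alignment accepts any codon.
    """
    entries = []
    for rid, prow in zip(pal.ids, pal.rows):
        if rid not in cds_by_id:
            raise ThreadingError(f"no CDS provided for alignment row {rid!r}")
        cds = iupac.normalize(cds_by_id[rid])
        if len(cds) % 3 != 0:
            raise ThreadingError(f"CDS for {rid!r} has length {len(cds)} not divisible by 3")
        aa = translate(cds)
        if aa.endswith("*"):
            aa = aa[:-1]
            cds = cds[:-3]
        ungapped = prow.replace("-", "")
        if len(aa) != len(ungapped):
            raise ThreadingError(
                f"row {rid!r}: CDS encodes {len(aa)} residues but the aligned "
                f"protein has {len(ungapped)}"
            )
        k = 0
        out = []
        for col, res in enumerate(prow):
            if res == "-":
                out.append("---")
                continue
            codon = cds[3 * k : 3 * k + 3]
            obs = aa[k]
            if res != obs and res != "X" and obs != "X":
                raise ThreadingError(
                    f"row {rid!r}, alignment column {col}: protein says {res!r} "
                    f"but codon {codon} encodes {obs!r}"
                )
            out.append(codon)
            k += 1
        entries.append((rid, "".join(out)))
    return NucleotideAlignment(entries)


def column_consensus(column: Iterable[str]) -> str:
    """Minimal IUPAC code covering the union of non-gap bases in a column.

    Returns '-' iff every entry is a gap.  Order-independent.
    """
    union: set[str] = set()
    n = 0
    for ch in column:
        n += 1
        if ch == "-":
            continue
        union |= iupac.code_set(ch)
    if n == 0:
        raise ValueError("empty column")
    if not union:
        return "-"
    return iupac.code_for_set(union)


def alignment_consensus(na: NucleotideAlignment) -> tuple[str, list[int]]:
    """Per-column consensus with all-gap columns removed.

    Returns ``(consensus, column_map)`` where ``column_map[i]`` is the
    original alignment column of consensus position ``i``.
    """
    consensus = []
    col_map = []
    for j in range(na.width):
        c = column_consensus(row[j] for row in na.rows)
        if c == "-":
            continue
        consensus.append(c)
        col_map.append(j)
    return "".join(consensus), col_map


def subset_alignment(na: NucleotideAlignment, ids: Iterable[str]) -> NucleotideAlignment:
    """Rows of ``na`` restricted to ``ids``; columns gone all-gap are dropped."""
    wanted = set(ids)
    if not wanted:
        raise ValueError("cannot subset an alignment to zero rows")
    unknown = wanted - set(na.ids)
    if unknown:
        raise KeyError(f"unknown alignment id(s): {sorted(unknown)}")
    rows = [(rid, row) for rid, row in zip(na.ids, na.rows) if rid in wanted]
    keep = [
        j for j in range(na.width) if any(row[j] != "-" for _, row in rows)
    ]
    return NucleotideAlignment(
        (rid, "".join(row[j] for j in keep)) for rid, row in rows
    )
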
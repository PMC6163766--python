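"""File formats: FASTA, primer TSV, abundance TSV, coverage JSON.

FASTA goes through Biopython; the TSV layouts are flat and embed the
resolved run configuration as '#' header comments for provenance.
Coordinates in user-facing tables are 1-based inclusive; everything in
memory is 0-based half-open.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import Panel
from .primers import DegeneratePrimer, PrimerPair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "write_primer_tsv",
    "read_primer_tsv",
    "write_primer_fasta",
    "write_coverage_json",
]

PRIMER_TSV_COLUMNS = [
    "pair_id",
    "fwd_seq", "fwd_start", "fwd_tm_lo", "fwd_tm_hi", "fwd_degeneracy", "fwd_n_degenerate",
    "rev_seq", "rev_start", "rev_tm_lo", "rev_tm_hi", "rev_degeneracy", "rev_n_degenerate",
    "product_len", "penalty",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) records; wrapped or single-line, case preserved upstream."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_abundance_tsv(path: str | Path) -> dict[str, float]:
    """id -> weight; lines starting with '#' are comments."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, value = line.split("\t")[:2]
            out[sid] = float(value)
    return out


def write_abundance_tsv(path: str | Path, abundances: Mapping[str, float]) -> None:
    with open(path, "w") as fh:
        fh.write("#id\tabundance\n")
        for sid in sorted(abundances):
            fh.write(f"{sid}\t{abundances[sid]:.6g}\n")


def _config_header(config: Mapping | None) -> str:
    if not config:
        return ""
    return "# config: " + json.dumps(dict(config), sort_keys=True) + "\n"


def write_primer_tsv(
    path: str | Path, pairs: Iterable[PrimerPair], config: Mapping | None = None
) -> None:
    """One row per pair; starts are 1-based inclusive binding-slice starts."""
    with open(path, "w", newline="") as fh:
        fh.write(_config_header(config))
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PRIMER_TSV_COLUMNS)
        for p in pairs:
            w.writerow(
                [p.pair_id]
                + _primer_fields(p.fwd)
                + _primer_fields(p.rev)
                + [p.product_len, f"{p.penalty:.4f}"]
            )


def _primer_fields(d: DegeneratePrimer) -> list:
    return [
        d.seq,
        d.start + 1,
        f"{d.tm_lo:.2f}",
        f"{d.tm_hi:.2f}",
        d.degeneracy,
        d.n_degenerate_positions,
    ]


def read_primer_tsv(path: str | Path) -> list[PrimerPair]:
    """Rebuild pairs from a primer TSV (Tm values as written, 2 dp)."""
    pairs: list[PrimerPair] = []
    with open(path) as fh:
        rows = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        fwd = DegeneratePrimer(
            seq=row["fwd_seq"],
            start=int(row["fwd_start"]) - 1,
            orientation="forward",
            tm_lo=float(row["fwd_tm_lo"]),
            tm_hi=float(row["fwd_tm_hi"]),
            degeneracy=int(row["fwd_degeneracy"]),
            n_degenerate_positions=int(row["fwd_n_degenerate"]),
        )
        rev = DegeneratePrimer(
            seq=row["rev_seq"],
            start=int(row["rev_start"]) - 1,
            orientation="reverse",
            tm_lo=float(row["rev_tm_lo"]),
            tm_hi=float(row["rev_tm_hi"]),
            degeneracy=int(row["rev_degeneracy"]),
            n_degenerate_positions=int(row["rev_n_degenerate"]),
        )
        pairs.append(
            PrimerPair(
                fwd=fwd,
                rev=rev,
                product_len=int(row["product_len"]),
                penalty=float(row["penalty"]),
                pair_id=row["pair_id"],
            )
        )
    return pairs


def write_primer_fasta(path: str | Path, pairs: Iterable[PrimerPair]) -> None:
    """Primers as FASTA with ids PPn_F / PPn_R."""
    records = []
    for p in pairs:
        pid = p.pair_id or "PP?"
        records.append((f"{pid}_F", p.fwd.seq))
        records.append((f"{pid}_R", p.rev.seq))
    write_fasta(path, records)


def write_coverage_json(
    path: str | Path, panel: Panel, config: Mapping | None = None
) -> None:
    payload = {
        "config": dict(config) if config else None,
        "n_pairs": len(panel.pairs),
        "coverage_by_pair": {
            pid: sorted(ids) for pid, ids in panel.coverage.by_pair.items()
        },
        "covered": sorted(panel.coverage.covered),
        "undesignable": sorted(panel.undesignable),
        "outgroup_only": list(panel.outgroup_only),
        "log": [
            {
                "seed": entry.seed_id,
                "members": list(entry.members),
                "rejected": list(entry.rejected),
                "pair_id": entry.pair_id,
                "swept": list(entry.swept),
            }
            for entry in panel.log
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
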
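"""Nearest-neighbor DNA melting temperatures.

Implements duplex Tm from the unified nearest-neighbor thermodynamic
parameter set (SantaLucia 1998), with the entropic salt correction

    dS' = dS + 0.368 * (N - 1) * ln[Na+]

and the two-state formula

    Tm(K) = dH / (dS' + R * ln(C / 4))

where dH is in cal/mol, dS in cal/(mol*K), R = 1.987 cal/(K*mol), C is the
total oligonucleotide concentration and the factor 4 assumes the primer is
not self-complementary and is in excess over its target — the usual PCR
situation.  Defaults are [Na+] = 50 mM and C = 50 nM.

For degenerate primers the Tm of the pool is summarised as the (min, max)
over the full expansion of the IUPAC string; computing the exact range is
cheap because panel design caps degeneracy at a few hundred variants.
"""

from __future__ import annotations

import math

import numpy as np

from . import iupac

__all__ = ["melting_temperature", "tm_range", "GAS_CONSTANT"]

#: Gas constant in cal/(K*mol).
GAS_CONSTANT = 1.987

# Unified NN parameters: propagation enthalpy (kcal/mol) and entropy
# (cal/mol/K) for the ten Watson-Crick stacks, written 5'->3' top strand.
_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "AC": (-8.4, -22.4),
    "AG": (-7.8, -21.0),
    "TA": (-7.2, -21.3),
    "TT": (-7.9, -22.2),
    "TC": (-8.2, -22.2),
    "TG": (-8.5, -22.7),
    "CA": (-8.5, -22.7),
    "CT": (-7.8, -21.0),
    "CC": (-8.0, -19.9),
    "CG": (-10.6, -27.2),
    "GA": (-8.2, -22.2),
    "GT": (-8.4, -22.4),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

# Duplex initiation with a terminal A·T or G·C pair.
_INIT = {
    "A": (2.3, 4.1),
    "T": (2.3, 4.1),
    "C": (0.1, -2.8),
    "G": (0.1, -2.8),
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_CHARS = "ACGT"

# 4x4 lookup tables indexed by (first base, second base) of a stack.
_DH_TABLE = np.zeros((4, 4))
_DS_TABLE = np.zeros((4, 4))
for _pair, (_dh, _ds) in _NN.items():
    _DH_TABLE[_BASE_INDEX[_pair[0]], _BASE_INDEX[_pair[1]]] = _dh
    _DS_TABLE[_BASE_INDEX[_pair[0]], _BASE_INDEX[_pair[1]]] = _ds
_INIT_DH = np.array([_INIT[c][0] for c in _IDX_CHARS])
_INIT_DS = np.array([_INIT[c][1] for c in _IDX_CHARS])

MIN_PRIMER_LEN = 8


def _tm_from_indices(mat: np.ndarray, na_molar: float, primer_conc: float) -> np.ndarray:
    """Tm (deg C) for each row of an integer-encoded (k, L) base matrix."""
    n = mat.shape[1]
    dh = _DH_TABLE[mat[:, :-1], mat[:, 1:]].sum(axis=1)
    ds = _DS_TABLE[mat[:, :-1], mat[:, 1:]].sum(axis=1)
    dh = dh + _INIT_DH[mat[:, 0]] + _INIT_DH[mat[:, -1]]
    ds = ds + _INIT_DS[mat[:, 0]] + _INIT_DS[mat[:, -1]]
    ds = ds + 0.368 * (n - 1) * math.log(na_molar)
    tm_k = (dh * 1000.0) / (ds + GAS_CONSTANT * math.log(primer_conc / 4.0))
    return tm_k - 273.15


def _encode_plain(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError:
        raise iupac.IupacError(
            f"melting_temperature requires a plain A/C/G/T sequence, got {seq!r}; "
            "use tm_range for degenerate primers"
        ) from None


def melting_temperature(
    seq: str, na_molar: float = 0.05, primer_conc: float = 50e-9
) -> float:
    """Nearest-neighbor Tm (deg C) of a plain-base primer.

    Parameters
    ----------
    seq : plain A/C/G/T string, length >= 8 (shorter duplexes are outside
        the two-state model's comfort zone and are rejected).
    na_molar : monovalent cation concentration in mol/L.
    primer_conc : total oligonucleotide concentration in mol/L.
    """
    seq = iupac.normalize(seq)
    if len(seq) < MIN_PRIMER_LEN:
        raise ValueError(f"primer too short for NN Tm: {len(seq)} < {MIN_PRIMER_LEN}")
    mat = _encode_plain(seq)[None, :]
    return float(_tm_from_indices(mat, na_molar, primer_conc)[0])


_TM_RANGE_CACHE: dict[tuple[str, float, float], tuple[float, float]] = {}


def tm_range(
    seq: str,
    na_molar: float = 0.05,
    primer_conc: float = 50e-9,
    max_degeneracy: int = 1024,
) -> tuple[float, float]:
    """(min, max) Tm over the full expansion of a degenerate primer.

    For a degeneracy-1 primer both values equal the plain Tm.  Refuses
    strings whose degeneracy exceeds ``max_degeneracy``.
    """
    seq = iupac.normalize(seq)
    key = (seq, na_molar, primer_conc)
    hit = _TM_RANGE_CACHE.get(key)
    if hit is not None:
        return hit
    if len(seq) < MIN_PRIMER_LEN:
        raise ValueError(f"primer too short for NN Tm: {len(seq)} < {MIN_PRIMER_LEN}")
    d = iupac.degeneracy(seq)
    if d > max_degeneracy:
        raise iupac.IupacError(
            f"degeneracy {d} exceeds tm_range cap {max_degeneracy}"
        )
    pools = [sorted(_BASE_INDEX[b] for b in iupac.IUPAC_SETS[ch]) for ch in seq]
    # Cartesian expansion as an integer matrix, built column-wise.
    mat = np.empty((d, len(seq)), dtype=np.intp)
    reps = d
    for j, pool in enumerate(pools):
        reps //= len(pool)
        tile = np.repeat(np.array(pool, dtype=np.intp), reps)
        mat[:, j] = np.tile(tile, d // (reps * len(pool)))
    tms = _tm_from_indices(mat, na_molar, primer_conc)
    out = (float(tms.min()), float(tms.max()))
    _TM_RANGE_CACHE[key] = out
    return out
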
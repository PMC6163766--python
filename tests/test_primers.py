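import numpy as np
import pytest

from degenpanel import iupac
from degenpanel.primers import PrimerConstraints, enumerate_candidates
from degenpanel.thermo import melting_temperature


def _plain_20mer_with_midrange_tm(rng):
    while True:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        if 49.0 < melting_temperature(seq) < 55.0:
            return seq


def test_flank_pair_has_zero_penalty_and_ranks_first():
    """Two unique plain 20-mer flanks around an undesignable N-core: the
    flank pair is the unique penalty-0 candidate when tm_opt equals their Tm."""
    rng = np.random.default_rng(17)
    f = _plain_20mer_with_midrange_tm(rng)
    consensus = f + "N" * 160 + iupac.reverse_complement(f)
    tm = melting_temperature(f)
    c = PrimerConstraints(
        tm_opt=tm, tm_min=tm - 5, tm_max=tm + 5,
        target_window=(20, 180), product_min=150, product_max=250,
    )
    cands = enumerate_candidates(consensus, c)
    assert cands, "expected at least the flank pair"
    best = cands[0]
    assert best.penalty == pytest.approx(0.0, abs=1e-9)
    assert (best.fwd.start, len(best.fwd)) == (0, 20)
    assert (best.rev.start, len(best.rev)) == (180, 20)
    assert best.fwd.seq == f
    assert best.rev.seq == f  # rev primer = revcomp of the revcomp(f) slice
    assert best.product_len == 200
    # penalty 0 is unique: every other candidate pays length or Tm penalty
    assert all(p.penalty > 1e-9 for p in cands[1:])


def test_all_n_consensus_yields_nothing():
    c = PrimerConstraints(target_window=(100, 150), product_min=100, product_max=300)
    assert enumerate_candidates("N" * 400, c) == []


def test_window_outside_consensus_is_an_error():
    c = PrimerConstraints(target_window=(100, 150))
    with pytest.raises(ValueError, match="window"):
        enumerate_candidates("ACGT" * 20, c)


def test_ranking_is_deterministic():
    rng = np.random.default_rng(23)
    consensus = "".join("ACGT"[i] for i in rng.integers(0, 4, 320))
    c = PrimerConstraints(target_window=(120, 170), product_min=150, product_max=300)
    a = enumerate_candidates(consensus, c)
    b = enumerate_candidates(consensus, c)
    assert a == b


def _brute_force(consensus, c):
    """Independent re-derivation: filter all slice pairs with plain
    predicates built on expand() + per-variant Tm, then sort by the
    documented penalty and tie-break order."""
    L = len(consensus)
    ws, we = c.target_window

    def slices(start_range, end_lo, end_hi):
        out = []
        for fl in range(c.len_min, c.len_max + 1):
            for fs in start_range:
                end = fs + fl
                if end > L or end < end_lo or end > end_hi:
                    continue
                s = consensus[fs:end]
                if iupac.degeneracy(s) > c.max_degeneracy:
                    continue
                if iupac.degenerate_positions(s) > c.max_degenerate_positions:
                    continue
                tms = [
                    melting_temperature(v, c.na_molar, c.primer_conc)
                    for v in iupac.expand(s, limit=c.max_degeneracy)
                ]
                lo, hi = min(tms), max(tms)
                if hi < c.tm_min or lo > c.tm_max:
                    continue
                out.append((fs, fl, 0.5 * (lo + hi)))
        return out

    fwd = slices(range(0, ws + 1), 0, L)
    rev = slices(range(0, L), we, L)
    pairs = []
    for fs, fl, fmid in fwd:
        for rs, rl, rmid in rev:
            if rs < fs + fl:
                continue
            product = rs + rl - fs
            if not (c.product_min <= product <= c.product_max):
                continue
            if abs(fmid - rmid) > c.pair_tm_max_diff:
                continue
            pen = (
                abs(fl - c.len_opt) + abs(rl - c.len_opt)
                + abs(fmid - c.tm_opt) + abs(rmid - c.tm_opt)
            )
            pairs.append((pen, fs, rs, fl, rl))
    pairs.sort()
    return pairs


@pytest.mark.parametrize("seed", [101, 202, 303])
def test_enumeration_matches_brute_force_on_small_consensi(seed):
    rng = np.random.default_rng(seed)
    ambig = "RYSWKM"
    seq = ["ACGT"[i] for i in rng.integers(0, 4, 260)]
    for pos in rng.choice(260, size=20, replace=False):
        seq[pos] = ambig[int(rng.integers(6))]
    consensus = "".join(seq)
    c = PrimerConstraints(
        target_window=(100, 140), product_min=150, product_max=250
    )
    got = [
        (p.penalty, p.fwd.start, p.rev.start, len(p.fwd), len(p.rev))
        for p in enumerate_candidates(consensus, c)
    ]
    expected = _brute_force(consensus, c)
    assert len(got) == len(expected)
    for g, e in zip(got, expected):
        assert g[1:] == e[1:]
        assert g[0] == pytest.approx(e[0], abs=1e-9)


def test_emitted_candidates_satisfy_all_constraints_independently():
    rng = np.random.default_rng(31)
    ambig = "RYSWKMN"
    seq = ["ACGT"[i] for i in rng.integers(0, 4, 300)]
    for pos in rng.choice(300, size=25, replace=False):
        seq[pos] = ambig[int(rng.integers(7))]
    consensus = "".join(seq)
    c = PrimerConstraints(target_window=(110, 160), product_min=150, product_max=280)
    ws, we = c.target_window
    for p in enumerate_candidates(consensus, c):
        for d in (p.fwd, p.rev):
            assert c.len_min <= len(d) <= c.len_max
            assert iupac.degeneracy(d.seq) == d.degeneracy <= c.max_degeneracy
            assert (
                iupac.degenerate_positions(d.seq)
                == d.n_degenerate_positions
                <= c.max_degenerate_positions
            )
            assert d.tm_hi >= c.tm_min and d.tm_lo <= c.tm_max
        assert p.fwd.start <= ws
        assert p.rev.end >= we
        assert p.rev.start >= p.fwd.end
        assert c.product_min <= p.product_len <= c.product_max
        assert abs(p.fwd.mid_tm - p.rev.mid_tm) <= c.pair_tm_max_diff
        # the reverse primer is stored 5'->3': its revcomp is the consensus slice
        assert (
            iupac.reverse_complement(p.rev.seq)
            == consensus[p.rev.start : p.rev.end]
        )


def test_constraint_validation():
    with pytest.raises(ValueError):
        PrimerConstraints(len_min=21, len_opt=20)
    with pytest.raises(ValueError):
        PrimerConstraints(target_window=(50, 50))
    with pytest.raises(ValueError):
        PrimerConstraints(product_min=600, product_max=600)
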